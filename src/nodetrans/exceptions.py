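"""Exception hierarchy shared across the package."""


class NodeTransError(Exception):
    """Base class for all nodetrans errors."""


class FormatError(NodeTransError):
    """A file or table does not conform to the expected dialect."""


class ValidationError(NodeTransError):
    """Input data violate a structural invariant (ordering, duplicates, NaN...)."""


class ConfigError(NodeTransError):
    """A configuration object is internally inconsistent."""


class NoConstrictionError(NodeTransError):
    """A diameter profile contains no detectable nodal constriction."""
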