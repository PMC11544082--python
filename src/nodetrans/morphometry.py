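"""Nodal and internodal morphometry.

Two entry points: :func:`summarize_measurements` aggregates manual
diameter/length measurement tables hierarchically (axon means, then animal
means, plus the internode-to-node diameter ratio), and
:func:`detect_constriction` locates the nodal constriction in a sampled
diameter profile with a half-depth boundary rule: the node extends over
the contiguous region where the diameter stays below
``d_min + fraction * (internode_diameter - d_min)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NoConstrictionError, ValidationError

MEASURE_TYPES = ("internode_diameter", "node_diameter", "node_length")


@dataclass
class ConstrictionResult:
    node_center_s: float
    node_length: float
    node_diameter: float
    internode_diameter: float


@dataclass
class DiameterProfile:
    """Axon diameter versus axial position, uniformly sampled (μm)."""

    s: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.s.shape != self.d.shape or self.s.ndim != 1:
            raise ValidationError("s and d must be 1D arrays of equal length")
        ds = np.diff(self.s)
        if len(ds) == 0 or not np.allclose(ds, ds[0], rtol=0, atol=1e-9):
            raise ValidationError("diameter profile must be uniformly sampled")
        if np.any(self.d <= 0):
            raise ValidationError("diameters must be positive")

    @property
    def grid_um(self) -> float:
        return float(self.s[1] - self.s[0])

    @property
    def span_um(self) -> float:
        return float(self.s[-1] - self.s[0])


@dataclass
class MorphometrySummary:
    per_axon: pd.DataFrame       # (animal_id, axon_id, measure_type) -> mean
    per_animal: pd.DataFrame     # (animal_id, measure_type) -> mean of axon means
    ratio_per_axon: pd.Series    # internode/node diameter per axon
    ratio_per_animal: pd.Series
    warnings: list
    errors: pd.DataFrame         # excluded rows


def summarize_measurements(table: pd.DataFrame) -> MorphometrySummary:
    """Hierarchical means of a manual measurement table.

    ``table`` has columns ``animal_id, axon_id, measure_type, value_um``
    with ``measure_type`` one of ``internode_diameter``, ``node_diameter``,
    ``node_length``. Non-positive values are excluded with an error
    record. Warnings are emitted when an animal has fewer than ten
    measurements of a type or fewer than three axons.
    """
    required = ("animal_id", "axon_id", "measure_type", "value_um")
    for col in required:
        if col not in table.columns:
            raise ValidationError(f"measurement table: missing column {col}")
    bad_type = ~table["measure_type"].isin(MEASURE_TYPES)
    if bad_type.any():
        raise ValidationError(
            f"unknown measure_type values: "
            f"{sorted(table.loc[bad_type, 'measure_type'].unique())}"
        )
    invalid = table["value_um"] <= 0
    errors = table[invalid].copy()
    tab = table[~invalid]

    per_axon = (
        tab.groupby(["animal_id", "axon_id", "measure_type"])["value_um"]
        .mean()
        .rename("mean_um")
        .to_frame()
    )
    per_animal = (
        per_axon.groupby(["animal_id", "measure_type"])["mean_um"]
        .mean()
        .rename("mean_um")
        .to_frame()
    )

    wide = per_axon["mean_um"].unstack("measure_type")
    if {"internode_diameter", "node_diameter"} <= set(wide.columns):
        ratio_per_axon = (wide["internode_diameter"] / wide["node_diameter"]).dropna()
    else:
        ratio_per_axon = pd.Series(dtype=float)
    ratio_per_axon.name = "internode_node_ratio"
    ratio_per_animal = (
        ratio_per_axon.groupby("animal_id").mean()
        if len(ratio_per_axon)
        else pd.Series(dtype=float)
    )

    warn_list = []
    for (animal, measure), g in tab.groupby(["animal_id", "measure_type"]):
        if len(g) < 10:
            warn_list.append(
                f"animal {animal!r}: only {len(g)} {measure} measurement(s) (<10)"
            )
        n_axons = g["axon_id"].nunique()
        if n_axons < 3:
            warn_list.append(
                f"animal {animal!r}: only {n_axons} axon(s) with {measure} (<3)"
            )
    for w in warn_list:
        warnings.warn(w, stacklevel=2)
    return MorphometrySummary(
        per_axon=per_axon,
        per_animal=per_animal,
        ratio_per_axon=ratio_per_axon,
        ratio_per_animal=ratio_per_animal,
        warnings=warn_list,
        errors=errors,
    )


def _moving_average(d: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge reflection; window forced odd."""
    if window <= 1:
        return d
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.pad(d, half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def detect_constriction(profile: DiameterProfile,
                        half_depth_fraction: float = 0.5,
                        smooth_window_um: float = 0.5,
                        min_relative_depth: float = 0.10,
                        internode_distance_um: float = 10.0) -> ConstrictionResult:
    """Locate the nodal constriction in a diameter profile.

    The node centre is the diameter minimum (ties resolve to the sample
    nearest the profile midpoint); the internodal diameter is the mean
    over samples at least ``internode_distance_um`` from the centre; the
    node length is the width of the contiguous region around the minimum
    where the (lightly smoothed) diameter stays at or below
    ``d_min + half_depth_fraction * (internode - d_min)``, with linearly
    interpolated boundary crossings.

    Raises :class:`NoConstrictionError` when the relative depth of the
    dip is below ``min_relative_depth`` (e.g. a constant profile).
    """
    if profile.span_um < 20.0 - 1e-9:
        raise ValidationError("diameter profile must span >= 20 um")
    s, d = profile.s, profile.d
    step = profile.grid_um
    w = max(1, int(round(smooth_window_um / step)))
    ds = _moving_average(d, w)

    d_min = ds.min()
    candidates = np.nonzero(ds <= d_min + 1e-12)[0]
    midpoint = 0.5 * (s[0] + s[-1])
    i_min = candidates[int(np.argmin(np.abs(s[candidates] - midpoint)))]
    center = float(s[i_min])

    far = np.abs(s - center) >= internode_distance_um
    if not far.any():
        raise ValidationError("profile too short to estimate internodal diameter")
    internode = float(ds[far].mean())
    depth = internode - d_min
    if depth < min_relative_depth * internode:
        raise NoConstrictionError(
            f"no constriction: relative depth {depth / internode:.3f} "
            f"< {min_relative_depth}"
        )
    thr = d_min + half_depth_fraction * depth

    i = i_min
    while i > 0 and ds[i - 1] <= thr:
        i -= 1
    if i == 0:
        left = float(s[0])
    else:
        frac = (ds[i - 1] - thr) / (ds[i - 1] - ds[i])
        left = float(s[i - 1] + frac * step)
    j = i_min
    n = len(s)
    while j < n - 1 and ds[j + 1] <= thr:
        j += 1
    if j == n - 1:
        right = float(s[-1])
    else:
        frac = (ds[j + 1] - thr) / (ds[j + 1] - ds[j])
        right = float(s[j + 1] - frac * step)
    return ConstrictionResult(
        node_center_s=center,
        node_length=right - left,
        node_diameter=float(d_min),
        internode_diameter=internode,
    )


def read_diameter_profile_tsv(path) -> DiameterProfile:
    df = pd.read_csv(path, sep="\t")
    for col in ("s_um", "d_um"):
        if col not in df.columns:
            raise ValidationError(f"diameter profile {path}: missing column {col}")
    df = df.sort_values("s_um")
    return DiameterProfile(s=df["s_um"].to_numpy(float), d=df["d_um"].to_numpy(float))


def write_diameter_profile_tsv(profile: DiameterProfile, path) -> None:
    pd.DataFrame({"s_um": profile.s, "d_um": profile.d}).to_csv(
        path, sep="\t", index=False
    )
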