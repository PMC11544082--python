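"""End-to-end pipelines, hierarchical aggregation and summary reports.

These functions wire the analysis modules together the way a study would
run them: project tracks onto the axon axis, build and trim step records,
qualify tracks, bin, summarise per subdomain, and derive the
percent-difference quantities used to describe nodal effects (e.g.
``100 * (1 - v_node / v_proximal)``). Aggregation is hierarchical:
per-axon means first, then an unweighted mean of axon means per animal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import flux_direction as fd
from . import kinematics as kin
from . import intensity_profile as ip
from .exceptions import ValidationError
from .track_io import AxialTrack, AxonGeometry, Track, project_to_axis, split_on_gaps

logger = logging.getLogger("nodetrans")


@dataclass
class KinematicsResult:
    """Output of the kinematics pipeline on one dataset."""

    steps: pd.DataFrame
    summary: pd.DataFrame           # per-subdomain pooled summary
    profile: pd.DataFrame           # per-bin table
    qc: dict = field(default_factory=dict)


@dataclass
class MitoResult:
    """Output of the mitochondrial pipeline: per-direction kinematics plus
    directionality, flux and length statistics."""

    steps: pd.DataFrame
    labels: list
    summaries: dict                 # direction -> per-subdomain summary
    fractions: dict
    flux: fd.FluxResult
    lengths: pd.DataFrame | None
    qc: dict = field(default_factory=dict)


def aggregate_hierarchy(df: pd.DataFrame, value_col: str,
                        axon_col: str = "axon_id",
                        animal_col: str = "animal_id",
                        min_axons: int = 3) -> tuple[pd.Series, pd.Series]:
    """Per-axon means, then unweighted per-animal means of axon means.

    Empty groups are excluded; animals with fewer than ``min_axons`` axons
    trigger a warning.
    """
    d = df.dropna(subset=[value_col])
    if len(d) == 0:
        raise ValidationError("no values to aggregate")
    per_axon = d.groupby([animal_col, axon_col])[value_col].mean()
    per_animal = per_axon.groupby(animal_col).mean()
    counts = per_axon.groupby(animal_col).size()
    for animal, n in counts.items():
        if n < min_axons:
            warnings.warn(f"animal {animal!r}: only {n} axon(s) (<{min_axons})",
                          stacklevel=2)
    return per_axon, per_animal


# ---------------------------------------------------------------------------
# track-level pipelines
# ---------------------------------------------------------------------------

def prepare_tracks(tracks: list[Track], geometry: AxonGeometry,
                   cfg: kin.AnalysisConfig) -> tuple[list[AxialTrack], dict]:
    """Project onto the axis and split long gaps; returns axial tracks + counts."""
    atracks: list[AxialTrack] = []
    n_in = len(tracks)
    for tr in tracks:
        for piece in split_on_gaps(tr, cfg.max_gap_frames):
            atracks.append(project_to_axis(piece, geometry))
    qc = {"tracks_in": n_in, "tracks_after_gap_split": len(atracks)}
    return atracks, qc


def _trimmed_qualified_steps(atracks: list[AxialTrack], cfg: kin.AnalysisConfig,
                             ) -> tuple[pd.DataFrame, dict, dict]:
    """Per-track step building, terminal-pause trimming and qualification.

    Returns the concatenated accepted steps, per-track trimmed steps (all
    tracks, accepted or not) and QC counts.
    """
    accepted = []
    trimmed_by_track: dict = {}
    n_qualified = 0
    reasons: dict = {}
    for at in atracks:
        steps = kin.compute_step_records(at, cfg)
        steps = kin.trim_terminal_pauses(steps, cfg)
        trimmed_by_track[at.track_id] = steps
        qual = kin.qualify_track(steps, cfg)
        reasons[qual.reason] = reasons.get(qual.reason, 0) + 1
        if qual.accepted:
            n_qualified += 1
            accepted.append(steps)
    all_steps = (
        pd.concat(accepted, ignore_index=True)
        if accepted
        else pd.DataFrame(columns=kin.STEP_COLUMNS)
    )
    qc = {"tracks_qualified": n_qualified, "rejection_reasons": reasons}
    return all_steps, trimmed_by_track, qc


def run_kinematics_pipeline(tracks: list[Track], geometry: AxonGeometry,
                            cfg: kin.AnalysisConfig | None = None,
                            ) -> KinematicsResult:
    """Full node-centred kinematics analysis of one dataset.

    Projection, gap splitting, step records, terminal-pause trimming,
    track qualification, 2 μm binning, and pooled per-subdomain and
    per-bin summaries.
    """
    cfg = cfg or kin.AnalysisConfig()
    atracks, qc = prepare_tracks(tracks, geometry, cfg)
    steps, _, qc2 = _trimmed_qualified_steps(atracks, cfg)
    qc.update(qc2)
    if len(steps) == 0:
        raise ValidationError("no qualified tracks: nothing to summarise")
    steps = kin.assign_bins(steps, cfg)
    summary = kin.summarize_kinematics(steps, cfg, by="subdomain")
    profile = kin.bin_profile(steps, cfg)
    logger.info("kinematics: %s", qc)
    return KinematicsResult(steps=steps, summary=summary, profile=profile, qc=qc)


def run_mito_pipeline(tracks: list[Track], geometry: AxonGeometry,
                      cfg: kin.AnalysisConfig | None = None,
                      video_duration_s: float | None = None) -> MitoResult:
    """Directional mitochondrial analysis of one dataset.

    Classifies every track (anterograde / retrograde / stationary), then
    summarises kinematics per direction, counts distinct moving
    mitochondria per subdomain and direction, normalises to per-minute
    flux, and summarises lengths per motility class and region.
    """
    cfg = cfg or kin.AnalysisConfig()
    atracks, qc = prepare_tracks(tracks, geometry, cfg)
    _, trimmed, qc2 = _trimmed_qualified_steps(atracks, cfg)
    qc.update(qc2)
    labels = [fd.classify_motility(steps, cfg) if len(steps) else
              fd.MotilityLabel(at.track_id, "stationary", 0.0)
              for at, steps in ((a, trimmed[a.track_id]) for a in atracks)]
    by_id = {l.track_id: l.label for l in labels}

    moving_steps = [trimmed[at.track_id] for at in atracks
                    if by_id[at.track_id] in fd.DIRECTIONS
                    and len(trimmed[at.track_id])]
    if not moving_steps:
        raise ValidationError("no motile mitochondria in dataset")
    steps = pd.concat(moving_steps, ignore_index=True)
    steps = kin.assign_bins(steps, cfg)
    steps["direction"] = steps["track_id"].map(by_id)

    summaries = {
        direction: kin.summarize_kinematics(
            steps[steps["direction"] == direction], cfg, by="subdomain")
        for direction in fd.DIRECTIONS
        if (steps["direction"] == direction).any()
    }
    fractions = fd.direction_fraction(labels)
    counts = fd.count_directional_movements(steps, labels)
    if video_duration_s is None:
        durations = {tr.video_duration_s for tr in tracks}
        video_duration_s = max(durations)
    flux = fd.flux_per_minute(counts, video_duration_s)
    lengths = None
    if any(tr.length_um is not None for tr in tracks):
        lengths = fd.length_summary(atracks, labels)
    logger.info("mito: %s", qc)
    return MitoResult(steps=steps, labels=labels, summaries=summaries,
                      fractions=fractions, flux=flux, lengths=lengths, qc=qc)


def run_profile_pipeline(profiles: list[ip.LineProfile],
                         background_method: str = "percentile",
                         mirror_range: tuple[float, float] | None = None,
                         ) -> dict:
    """Background subtraction, normalisation, averaging and peak metrics.

    Uses the ``"region"`` background method automatically when every
    profile carries off-axon background samples and no method was forced.
    """
    if not profiles:
        raise ValidationError("no profiles given")
    if background_method == "percentile" and all(
        p.background_samples is not None for p in profiles
    ):
        background_method = "region"
    rel = [ip.normalize_relative(ip.subtract_background(p, method=background_method))
           for p in profiles]
    mean_profile = ip.average_profiles(rel)
    metrics = ip.peak_metrics(mean_profile)
    if mirror_range is None:
        mirror_range = ip.DEFAULT_MIRROR_RANGES.get(profiles[0].channel, (1.0, 11.0))
    mirrored = ip.mirrored_region_stats(rel, mirror_range)
    return {
        "relative_profiles": rel,
        "mean_profile": mean_profile,
        "peak": metrics,
        "mirrored": mirrored,
        "background_method": background_method,
    }


# ---------------------------------------------------------------------------
# percent-difference report
# ---------------------------------------------------------------------------

def percent_metrics(summary: pd.DataFrame) -> dict:
    """Nodal percent differences from a per-subdomain summary.

    Returns the standard report quantities, NaN when a term is missing:

    - ``slowdown_node_vs_proximal`` = 100 * (1 - v_node / v_proximal)
    - ``slowdown_node_vs_distal``   = 100 * (1 - v_node / v_distal)
    - ``proximal_excess_vs_distal`` = 100 * (v_proximal / v_distal - 1)
    - ``pause_reduction_proximal``  = 100 * (1 - pf_proximal / pf_node)
    - ``pause_reduction_distal``    = 100 * (1 - pf_distal / pf_node)
    """
    def get(sub, col):
        try:
            return float(summary.loc[sub, col])
        except KeyError:
            return float("nan")

    v = {s: get(s, "mean_moving_velocity") for s in kin.SUBDOMAINS}
    pf = {s: get(s, "pause_relative_frequency") for s in kin.SUBDOMAINS}
    return {
        "slowdown_node_vs_proximal": 100.0 * (1.0 - v["center"] / v["proximal"]),
        "slowdown_node_vs_distal": 100.0 * (1.0 - v["center"] / v["distal"]),
        "proximal_excess_vs_distal": 100.0 * (v["proximal"] / v["distal"] - 1.0),
        "pause_reduction_proximal": 100.0 * (1.0 - pf["proximal"] / pf["center"]),
        "pause_reduction_distal": 100.0 * (1.0 - pf["distal"] / pf["center"]),
    }


def plot_bin_profile(profile: pd.DataFrame, path) -> None:
    """Node-centred transport profile: moving velocity and pause frequency."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(8, 4))
    ax2 = ax1.twinx()
    ax2.bar(profile["s_center"], profile["pause_relative_frequency"],
            width=1.8, color="0.8", label="pause frequency")
    ax1.plot(profile["s_center"], profile["mean_moving_velocity"],
             color="purple", marker="o", ms=3, label="mean moving velocity")
    ax1.set_xlabel("distance from node center (um)")
    ax1.set_ylabel("mean moving velocity (um/s)")
    ax2.set_ylabel("relative pause frequency")
    ax1.axvspan(-2, 2, color="lightgreen", alpha=0.3)
    ax1.set_zorder(ax2.get_zorder() + 1)
    ax1.patch.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
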