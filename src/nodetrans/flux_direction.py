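"""Mitochondrial directionality, per-region flux and length statistics.

Motile mitochondria are labelled anterograde or retrograde by the sign of
their net axial displacement over non-pause steps; tracks without a
qualifying moving run, or with negligible net displacement, are stationary.
Flux counts distinct moving organelles per subdomain and direction,
normalised to video duration (per minute). Length statistics compare
stationary versus motile mitochondria per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kinematics import AnalysisConfig, qualify_track
from .track_io import AxialTrack

DIRECTIONS = ("anterograde", "retrograde")
MOTILITY_CLASSES = ("stationary", "anterograde", "retrograde")
LENGTH_REGIONS = ("proximal", "distal")


@dataclass(frozen=True)
class MotilityLabel:
    track_id: object
    label: str  # anterograde | retrograde | stationary
    net_axial_displacement: float


@dataclass
class FluxResult:
    """Directional flux per subdomain and pooled across subdomains.

    ``per_subdomain`` has one row per (subdomain, direction) with columns
    ``n_mitochondria`` and ``flux_per_minute``; ``pooled`` maps direction
    to the mean of the three subdomain fluxes.
    """

    per_subdomain: pd.DataFrame
    pooled: dict
    video_minutes: float


def classify_motility(steps: pd.DataFrame, cfg: AnalysisConfig) -> MotilityLabel:
    """Label one track (trimmed steps) as anterograde/retrograde/stationary.

    Stationary: no run of >= ``min_consecutive_moving_frames`` moving
    steps, or net axial displacement below
    ``cfg.stationary_net_threshold``. Otherwise the label is the sign of
    the summed axial delta over non-pause steps (+ = anterograde). An
    exact zero with a qualifying run falls back to the majority sign of
    moving steps; a remaining tie is stationary, with a warning.
    """
    track_id = steps["track_id"].iloc[0] if len(steps) else None
    qual = qualify_track(steps, cfg)
    moving = steps.loc[~steps["is_pause"], "axial_delta"]
    net = float(moving.sum()) if len(moving) else 0.0
    if not qual.accepted or abs(net) < cfg.stationary_net_threshold:
        return MotilityLabel(track_id, "stationary", net)
    if net > 0:
        return MotilityLabel(track_id, "anterograde", net)
    if net < 0:
        return MotilityLabel(track_id, "retrograde", net)
    # net exactly zero: majority sign of moving steps
    signs = np.sign(moving.to_numpy())
    balance = int((signs > 0).sum()) - int((signs < 0).sum())
    if balance > 0:
        return MotilityLabel(track_id, "anterograde", net)
    if balance < 0:
        return MotilityLabel(track_id, "retrograde", net)
    warnings.warn(f"track {track_id!r}: direction tie, labelled stationary",
                  stacklevel=2)
    return MotilityLabel(track_id, "stationary", net)


def count_directional_movements(steps: pd.DataFrame,
                                labels: list[MotilityLabel]) -> pd.DataFrame:
    """Distinct moving mitochondria per subdomain and direction.

    A mitochondrion counts at most once per (subdomain, direction) cell --
    it contributes wherever it has >= 1 non-pause step, regardless of
    revisits. ``steps`` is the concatenated, binned step table of all
    tracks.
    """
    direction = {l.track_id: l.label for l in labels if l.label in DIRECTIONS}
    d = steps[
        (~steps["is_pause"])
        & steps["subdomain"].isin(["proximal", "center", "distal"])
        & steps["track_id"].isin(direction)
    ].copy()
    d["direction"] = d["track_id"].map(direction)
    counts = (
        d.groupby(["subdomain", "direction"])["track_id"].nunique()
        if len(d)
        else pd.Series(dtype=int)
    )
    idx = pd.MultiIndex.from_product(
        [["proximal", "center", "distal"], list(DIRECTIONS)],
        names=["subdomain", "direction"],
    )
    return counts.reindex(idx, fill_value=0).rename("n_mitochondria").to_frame()


def flux_per_minute(counts: pd.DataFrame, video_duration_s: float) -> FluxResult:
    """Normalise directional counts to organelles per minute.

    ``flux = count * 60 / duration``; the pooled value per direction is the
    mean of the three subdomain fluxes.
    """
    if video_duration_s <= 0:
        raise ValidationError("video duration must be positive")
    per = counts.copy()
    per["flux_per_minute"] = per["n_mitochondria"] * 60.0 / video_duration_s
    pooled = {
        direction: float(per.xs(direction, level="direction")["flux_per_minute"].mean())
        for direction in DIRECTIONS
    }
    return FluxResult(per_subdomain=per, pooled=pooled,
                      video_minutes=video_duration_s / 60.0)


def direction_fraction(labels: list[MotilityLabel]) -> dict:
    """Anterograde/retrograde fractions of motile tracks (sum to 1)."""
    n_a = sum(1 for l in labels if l.label == "anterograde")
    n_r = sum(1 for l in labels if l.label == "retrograde")
    if n_a + n_r == 0:
        raise ValidationError("direction fractions undefined: no motile track")
    total = n_a + n_r
    return {"anterograde": n_a / total, "retrograde": n_r / total}


def track_region(atrack: AxialTrack) -> str:
    """Region of a track for length analysis: modal subdomain of its spots.

    Only proximal and distal are reported; spots in the nodal centre group
    with distal. Based on spot positions so that stationary tracks (which
    have no steps after trimming) are still assignable.
    """
    s = atrack.s[atrack.valid]
    if len(s) == 0:
        s = atrack.s
    n_prox = int((s < -2.0).sum())
    n_dist = int((s >= -2.0).sum())
    return "proximal" if n_prox > n_dist else "distal"


def length_summary(atracks: list[AxialTrack], labels: list[MotilityLabel],
                   min_n: int = 10,
                   min_stationary_span_fraction: float = 0.5) -> pd.DataFrame:
    """Mean mitochondrial length per motility class and region.

    Track length is the mean of its per-spot ``length_um`` values. Classes
    with no length data are excluded with a warning; cells with fewer than
    ``min_n`` organelles are reported but flagged. A stationary
    mitochondrion must by definition remain in place, so stationary-
    labelled tracks observed for less than
    ``min_stationary_span_fraction`` of the video (brief passers-by
    truncated at the field of view) are not treated as stationary
    organelles and are excluded.
    """
    by_id = {l.track_id: l.label for l in labels}
    rows = []
    n_missing = 0
    for at in atracks:
        tr = at.track
        if tr.length_um is None or not np.isfinite(tr.length_um).any():
            n_missing += 1
            continue
        if (by_id.get(tr.track_id, "stationary") == "stationary"
                and tr.video_duration_s
                and (tr.t[-1] - tr.t[0])
                < min_stationary_span_fraction * tr.video_duration_s):
            continue
        rows.append(
            {
                "track_id": tr.track_id,
                "motility_class": by_id.get(tr.track_id, "stationary"),
                "region": track_region(at),
                "length_um": float(np.nanmean(tr.length_um)),
            }
        )
    if n_missing:
        warnings.warn(f"{n_missing} track(s) without length measurements excluded",
                      stacklevel=2)
    if not rows:
        raise ValidationError("no mitochondrial lengths available")
    d = pd.DataFrame(rows)
    if (d["length_um"] <= 0).any():
        raise ValidationError("mitochondrial lengths must be positive")
    g = d.groupby(["motility_class", "region"])["length_um"]
    out = pd.DataFrame({"mean_length_um": g.mean(), "n": g.size()})
    idx = pd.MultiIndex.from_product(
        [list(MOTILITY_CLASSES), list(LENGTH_REGIONS)],
        names=["motility_class", "region"],
    )
    out = out.reindex(idx)
    out["n"] = out["n"].fillna(0).astype(int)
    out["below_min_n"] = out["n"] < min_n
    return out
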