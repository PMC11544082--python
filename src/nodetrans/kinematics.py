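"""Transport-dynamics quantification around the node of Ranvier.

The analysis follows the field's standard tracking conventions: a *pause*
is a frame-to-frame interval in which a previously motile organelle moves
at <= 0.1 μm/s; runs of >= 10 consecutive pause steps touching either end
of a track ("terminal pauses") are trimmed; only tracks with at least one
run of >= 10 consecutive moving frames qualify for analysis. Qualified
steps are binned every 2 μm across an 80 μm window centred on the node and
partitioned into the proximal internode (38 μm), the nodal constriction
(4 μm) and the distal internode (38 μm). The *mean moving velocity* of a
location is the mean frame-to-frame speed over its non-pause steps; the
*relative pause frequency* is the fraction of steps in that location that
are pauses.

Steps are represented as a :class:`pandas.DataFrame` with one row per
consecutive spot pair (columns documented in :func:`compute_step_records`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .track_io import AxialTrack

SUBDOMAINS = ("proximal", "center", "distal")

STEP_COLUMNS = [
    "animal_id", "axon_id", "track_id", "organelle",
    "frame_from", "frame_to", "dt", "displacement_2d", "speed",
    "axial_delta", "s_mid", "is_pause", "is_gap",
]


@dataclass
class AnalysisConfig:
    """Thresholds and window layout of the kinematics analysis.

    All lengths in μm, times in seconds, speeds in μm/s. The 80 μm window
    is split 38 / 4 / 38 into proximal internode, nodal constriction and
    distal internode; bins are 2 μm wide with edges aligned at s = 0.
    """

    pause_speed_threshold: float = 0.1
    min_consecutive_moving_frames: int = 10
    terminal_pause_min_frames: int = 10
    min_tracks_per_axon: int = 20
    min_tracks_per_axon_retro_mito: int = 10
    window_half_width: float = 40.0
    bin_width: float = 2.0
    internode_length: float = 38.0
    node_length: float = 4.0
    stationary_net_threshold: float = 2.0
    max_gap_frames: int = 2

    def __post_init__(self) -> None:
        if abs(2 * self.internode_length + self.node_length
               - 2 * self.window_half_width) > 1e-9:
            raise ValidationError(
                "2*internode_length + node_length must equal 2*window_half_width"
            )
        n_bins = 2 * self.window_half_width / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValidationError("bin_width must divide the window exactly")

    @property
    def n_bins(self) -> int:
        return int(round(2 * self.window_half_width / self.bin_width))

    @property
    def node_half_length(self) -> float:
        return self.node_length / 2.0


@dataclass
class QualificationResult:
    accepted: bool
    reason: str
    max_moving_run: int = 0


# ---------------------------------------------------------------------------
# step construction
# ---------------------------------------------------------------------------

def compute_step_records(atrack: AxialTrack, cfg: AnalysisConfig) -> pd.DataFrame:
    """One record per consecutive pair of valid spots of one track.

    Speed is the 2D Euclidean displacement over the elapsed time; the axial
    delta and the midpoint position ``s_mid`` come from the projected
    coordinate. A missing intermediate frame yields a single spanning
    record flagged ``is_gap``. Raises :class:`ValidationError` on
    non-positive time intervals.
    """
    tr = atrack.track
    idx = np.nonzero(atrack.valid)[0]
    if len(idx) < 2:
        return pd.DataFrame(columns=STEP_COLUMNS)
    f = tr.frames[idx]
    t = tr.t[idx]
    x = tr.x[idx]
    y = tr.y[idx]
    s = atrack.s[idx]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError(f"track {tr.track_id!r}: non-positive frame interval")
    disp = np.hypot(np.diff(x), np.diff(y))
    speed = disp / dt
    df = pd.DataFrame(
        {
            "animal_id": tr.animal_id,
            "axon_id": tr.axon_id,
            "track_id": tr.track_id,
            "organelle": tr.organelle_class,
            "frame_from": f[:-1],
            "frame_to": f[1:],
            "dt": dt,
            "displacement_2d": disp,
            "speed": speed,
            "axial_delta": np.diff(s),
            "s_mid": (s[:-1] + s[1:]) / 2.0,
            "is_pause": speed <= cfg.pause_speed_threshold,
            "is_gap": np.diff(f) > 1,
        }
    )
    return df


def trim_terminal_pauses(steps: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Remove terminal pause runs of >= ``terminal_pause_min_frames`` steps.

    Maximal runs of consecutive pause steps touching either end of the
    track are removed when long enough, iterating until no such terminal
    run remains. May return an empty frame when the whole track pauses.
    """
    steps = steps.sort_values("frame_from").reset_index(drop=True)
    thr = cfg.terminal_pause_min_frames
    while len(steps):
        p = steps["is_pause"].to_numpy()
        k = 0
        while k < len(p) and p[k]:
            k += 1
        m = 0
        while m < len(p) and p[len(p) - 1 - m]:
            m += 1
        changed = False
        if k >= thr and k < len(p):
            steps = steps.iloc[k:].reset_index(drop=True)
            changed = True
        elif k >= thr:  # whole track is one pause run
            return steps.iloc[0:0]
        p = steps["is_pause"].to_numpy()
        m = 0
        while m < len(p) and p[len(p) - 1 - m]:
            m += 1
        if m >= thr and m < len(p):
            steps = steps.iloc[: len(p) - m].reset_index(drop=True)
            changed = True
        elif m >= thr:
            return steps.iloc[0:0]
        if not changed:
            break
    return steps


def _max_moving_run(is_pause: np.ndarray, is_gap: np.ndarray) -> int:
    """Longest run of consecutive non-pause steps over contiguous frames.

    A pause resets the run; a gap-spanning step starts a fresh run of
    length one (its frames are not consecutive with the preceding step).
    """
    best = run = 0
    for p, g in zip(is_pause, is_gap):
        if p:
            run = 0
        elif g:
            run = 1
        else:
            run += 1
        best = max(best, run)
    return best


def qualify_track(steps: pd.DataFrame, cfg: AnalysisConfig) -> QualificationResult:
    """Accept a trimmed track iff it moves for >= 10 consecutive frames."""
    if len(steps) == 0:
        return QualificationResult(False, "empty_after_trimming", 0)
    run = _max_moving_run(steps["is_pause"].to_numpy(), steps["is_gap"].to_numpy())
    if run >= cfg.min_consecutive_moving_frames:
        return QualificationResult(True, "ok", run)
    return QualificationResult(False, "no_qualifying_run", run)


def check_axon_counts(counts: dict, cfg: AnalysisConfig) -> pd.DataFrame:
    """Check per-axon organelle counts against the study's minima.

    ``counts`` maps ``(axon_id, organelle_class, direction)`` to the number
    of qualified tracks. The minimum is 20 per axon, relaxed to 10 for
    retrogradely moving mitochondria. Returns a table with a boolean
    ``passed`` column; callers decide whether to warn (default downstream
    behaviour) or exclude.
    """
    rows = []
    for (axon_id, organelle, direction), n in counts.items():
        minimum = (
            cfg.min_tracks_per_axon_retro_mito
            if organelle == "mitochondrion" and direction == "retrograde"
            else cfg.min_tracks_per_axon
        )
        rows.append(
            {
                "axon_id": axon_id,
                "organelle": organelle,
                "direction": direction,
                "n_tracks": n,
                "minimum": minimum,
                "passed": n >= minimum,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binning and summaries
# ---------------------------------------------------------------------------

def assign_bins(steps: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Assign each step to a 2 μm bin and an axonal subdomain by ``s_mid``.

    Bins are half-open ``[edge, edge + bin_width)`` from -40 to +40, except
    that s_mid = +40 falls in the last bin. Subdomains: proximal
    ``[-40, -2)``, center ``[-2, +2]`` (ties at +-2 go to the node), distal
    ``(+2, +40]``; anything beyond the window is ``outside`` and excluded
    from summaries.
    """
    steps = steps.copy()
    s = steps["s_mid"].to_numpy()
    W = cfg.window_half_width
    h = cfg.node_half_length
    bin_idx = np.floor((s + W) / cfg.bin_width).astype(int)
    bin_idx = np.where(s == W, cfg.n_bins - 1, bin_idx)
    inside = (s >= -W) & (s <= W)
    bin_idx = np.where(inside, bin_idx, -1)
    sub = np.full(len(s), "outside", dtype=object)
    sub[(s >= -W) & (s < -h)] = "proximal"
    sub[(s >= -h) & (s <= h)] = "center"
    sub[(s > h) & (s <= W)] = "distal"
    steps["bin_index"] = bin_idx
    steps["subdomain"] = sub
    return steps


def summarize_kinematics(steps: pd.DataFrame, cfg: AnalysisConfig,
                         by: str = "subdomain",
                         group_keys: tuple = (),
                         pause_freq_mode: str = "per_location") -> pd.DataFrame:
    """Per-location step counts, pause frequency and mean moving velocity.

    Parameters
    ----------
    by
        ``"subdomain"`` or ``"bin"``.
    group_keys
        Extra grouping columns (e.g. ``("animal_id", "axon_id")``) for
        hierarchical summaries.
    pause_freq_mode
        ``"per_location"`` (default): pauses / steps within the location --
        the regional analogue of the time-paused formula. ``"share_of_pauses"``:
        pauses in the location / all pauses in the group.

    Locations with zero moving steps report NaN velocity (missing, not 0).
    """
    if by not in ("subdomain", "bin"):
        raise ValueError("by must be 'subdomain' or 'bin'")
    loc = "subdomain" if by == "subdomain" else "bin_index"
    d = steps[steps["subdomain"] != "outside"]
    keys = list(group_keys) + [loc]
    grouped = d.groupby(keys, sort=True)
    out = pd.DataFrame(
        {
            "n_steps": grouped.size(),
            "n_pauses": grouped["is_pause"].sum(),
        }
    )
    moving = d[~d["is_pause"]].groupby(keys, sort=True)["speed"].mean()
    out["n_moving"] = out["n_steps"] - out["n_pauses"]
    out["mean_moving_velocity"] = moving.reindex(out.index)
    if pause_freq_mode == "per_location":
        out["pause_relative_frequency"] = out["n_pauses"] / out["n_steps"]
    elif pause_freq_mode == "share_of_pauses":
        if group_keys:
            total = out.groupby(level=list(range(len(group_keys))))["n_pauses"].transform("sum")
        else:
            total = out["n_pauses"].sum()
        out["pause_relative_frequency"] = out["n_pauses"] / total
    else:
        raise ValueError(f"unknown pause_freq_mode {pause_freq_mode!r}")
    if by == "subdomain" and not group_keys:
        out = out.reindex([s for s in SUBDOMAINS if s in out.index])
    return out


def bin_profile(steps: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-bin profile table (bin centre, velocity, pause frequency, n).

    Mirrors the node-centred transport-profile plot: one row per 2 μm bin
    across the 80 μm window, including empty bins (NaN velocity).
    """
    summ = summarize_kinematics(steps, cfg, by="bin")
    idx = pd.RangeIndex(cfg.n_bins, name="bin_index")
    summ = summ.reindex(idx)
    summ[["n_steps", "n_pauses", "n_moving"]] = (
        summ[["n_steps", "n_pauses", "n_moving"]].fillna(0).astype(int)
    )
    centers = -cfg.window_half_width + (np.arange(cfg.n_bins) + 0.5) * cfg.bin_width
    summ.insert(0, "s_center", centers)
    return summ.reset_index()


def pearson_speed_diameter(values: np.ndarray | list) -> tuple[float, float]:
    """Pearson correlation between per-axon speeds and axonal diameters.

    ``values`` is a sequence of (speed, diameter) pairs; returns
    ``(r, two_tailed_p)`` where p comes from the t-distribution with n-2
    degrees of freedom. Requires >= 3 pairs with variation in both
    variables.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("expected an (n, 2) array of (speed, diameter) pairs")
    if len(arr) < 3:
        raise ValidationError("Pearson correlation requires >= 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Pearson correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
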