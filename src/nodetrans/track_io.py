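"""Reading, writing and axial projection of organelle particle tracks.

Tracks are time-ordered 2D spot sequences produced by an upstream tracking
tool (semi-automatic or manual). All positions are in micrometres and all
times in seconds. Node-centred analysis requires a signed axial coordinate
``s``: the arclength distance along the axon centerline from the node
centre, positive toward the distal (muscle) side. :func:`project_to_axis`
computes ``s`` by orthogonal projection of each spot onto a centerline
polyline.

The on-disk track dialect is a UTF-8 comma-separated table with a header and
the columns ``axon_id, track_id, frame, t_s, x_um, y_um, organelle`` plus
the optional columns ``animal_id, intensity, length_um, video_duration_s``.
A read-only subset of TrackMate's XML export is supported as an alternative
input format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .exceptions import FormatError, ValidationError

ORGANELLE_CLASSES = ("endosome", "mitochondrion")

REQUIRED_COLUMNS = ("axon_id", "track_id", "frame", "t_s", "x_um", "y_um", "organelle")
OPTIONAL_COLUMNS = ("animal_id", "intensity", "length_um", "video_duration_s")

#: spatial unit names accepted in TrackMate XML, with conversion factor to μm
_TRACKMATE_UNITS = {
    "micron": 1.0,
    "microns": 1.0,
    "micrometer": 1.0,
    "micrometre": 1.0,
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,
}


@dataclass(frozen=True)
class Spot:
    """A single localisation of one organelle in one frame."""

    frame: int
    t: float
    x: float
    y: float
    intensity: float | None = None
    length_um: float | None = None


@dataclass
class Track:
    """Time-ordered 2D spot sequence for one organelle.

    Spot attributes are stored as parallel arrays; the :attr:`spots`
    property materialises :class:`Spot` objects on demand.

    Parameters
    ----------
    track_id
        Identifier, unique within an axon.
    organelle_class
        ``"endosome"`` or ``"mitochondrion"``.
    frames, t, x, y
        Per-spot frame index, time (s) and position (μm). Frames and times
        must be strictly increasing; positions must be finite.
    intensity, length_um
        Optional per-spot fluorescence intensity (a.u.) and organelle
        length (μm, mitochondria).
    video_duration_s
        Duration of the source video; defaults to the time span of the
        track and must not be shorter than it.
    """

    track_id: object
    organelle_class: str
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray | None = None
    length_um: np.ndarray | None = None
    axon_id: object = "axon0"
    animal_id: object = "animal0"
    video_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if self.length_um is not None:
            self.length_um = np.asarray(self.length_um, dtype=float)
        if self.organelle_class not in ORGANELLE_CLASSES:
            raise ValidationError(
                f"track {self.track_id!r}: unknown organelle class "
                f"{self.organelle_class!r} (expected one of {ORGANELLE_CLASSES})"
            )
        n = len(self.frames)
        if n < 2:
            raise ValidationError(f"track {self.track_id!r}: needs >= 2 spots, got {n}")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if len(arr) != n:
                raise ValidationError(
                    f"track {self.track_id!r}: column {name} has length "
                    f"{len(arr)}, expected {n}"
                )
        if not np.isfinite(self.x).all() or not np.isfinite(self.y).all():
            raise ValidationError(f"track {self.track_id!r}: non-finite position")
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError(
                f"track {self.track_id!r}: frame indices not strictly increasing"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"track {self.track_id!r}: time not strictly increasing"
            )
        span = float(self.t[-1] - self.t[0])
        if self.video_duration_s is None:
            self.video_duration_s = span
        elif self.video_duration_s < span - 1e-9:
            raise ValidationError(
                f"track {self.track_id!r}: video_duration_s shorter than track span"
            )

    @property
    def n_spots(self) -> int:
        return len(self.frames)

    @property
    def spots(self) -> list[Spot]:
        out = []
        for i in range(self.n_spots):
            out.append(
                Spot(
                    frame=int(self.frames[i]),
                    t=float(self.t[i]),
                    x=float(self.x[i]),
                    y=float(self.y[i]),
                    intensity=None if self.intensity is None else float(self.intensity[i]),
                    length_um=None if self.length_um is None else float(self.length_um[i]),
                )
            )
        return out


@dataclass
class AxonGeometry:
    """Axon centerline with the node position and the distal direction.

    ``distal_sign`` is +1 when increasing arclength along the polyline
    points away from the soma (toward the muscle), -1 otherwise.
    """

    centerline: np.ndarray
    node_center_arclength: float
    distal_sign: int = 1

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValidationError("centerline must be an (n, 2) polyline")
        if len(self.centerline) < 2:
            raise ValidationError("centerline needs >= 2 vertices")
        if not np.isfinite(self.centerline).all():
            raise ValidationError("centerline has non-finite vertices")
        if self.total_length <= 0:
            raise ValidationError("centerline has zero total length")
        if not (0.0 <= self.node_center_arclength <= self.total_length + 1e-9):
            raise ValidationError(
                "node_center_arclength outside [0, centerline length]"
            )
        if self.distal_sign not in (-1, 1):
            raise ValidationError("distal_sign must be +1 or -1")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)

    @property
    def vertex_arclengths(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def total_length(self) -> float:
        return float(self.vertex_arclengths[-1])

    def to_dict(self) -> dict:
        return {
            "centerline": self.centerline.tolist(),
            "node_center_arclength": float(self.node_center_arclength),
            "distal_sign": int(self.distal_sign),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxonGeometry":
        return cls(
            centerline=np.asarray(d["centerline"], dtype=float),
            node_center_arclength=float(d["node_center_arclength"]),
            distal_sign=int(d.get("distal_sign", 1)),
        )


@dataclass
class AxialTrack:
    """A :class:`Track` with node-centred signed axial coordinates.

    ``s`` is the signed arclength from the node centre (+ = distal);
    ``lateral`` the perpendicular distance of the spot from the centerline.
    ``valid`` marks spots within the allowed lateral distance.
    """

    track: Track
    s: np.ndarray
    lateral: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.s), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.track.n_spots
        if len(self.s) != n or len(self.lateral) != n or len(self.valid) != n:
            raise ValidationError("axial arrays must match the number of spots")
        if not np.isfinite(self.s).all():
            raise ValidationError("axial coordinate s has non-finite values")

    @property
    def track_id(self):
        return self.track.track_id


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def read_tracks_table(path) -> list[Track]:
    """Read the CSV track dialect into a list of :class:`Track`.

    One track is built per ``(axon_id, track_id)`` pair, with spots sorted
    by frame. Duplicated ``(axon_id, track_id, frame)`` rows and
    non-monotone times raise :class:`ValidationError`; missing required
    columns raise :class:`FormatError` naming the columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"track table {path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        return []
    dup = df.duplicated(subset=["axon_id", "track_id", "frame"])
    if dup.any():
        bad = df.loc[dup, ["axon_id", "track_id", "frame"]].iloc[0].tolist()
        raise ValidationError(
            f"track table {path}: duplicated (axon_id, track_id, frame) row {bad}"
        )
    tracks: list[Track] = []
    for (axon_id, track_id), g in df.groupby(["axon_id", "track_id"], sort=True):
        g = g.sort_values("frame")
        kwargs = {}
        if "intensity" in g.columns and g["intensity"].notna().any():
            kwargs["intensity"] = g["intensity"].to_numpy(float)
        if "length_um" in g.columns and g["length_um"].notna().any():
            kwargs["length_um"] = g["length_um"].to_numpy(float)
        duration = None
        if "video_duration_s" in g.columns and g["video_duration_s"].notna().any():
            duration = float(g["video_duration_s"].iloc[0])
        tracks.append(
            Track(
                track_id=track_id,
                organelle_class=str(g["organelle"].iloc[0]),
                frames=g["frame"].to_numpy(int),
                t=g["t_s"].to_numpy(float),
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
                axon_id=axon_id,
                animal_id=g["animal_id"].iloc[0] if "animal_id" in g.columns else "animal0",
                video_duration_s=duration,
                **kwargs,
            )
        )
    return tracks


def write_tracks_table(tracks: list[Track], path) -> None:
    """Write tracks to the CSV dialect; round-trips with :func:`read_tracks_table`."""
    rows = []
    for tr in tracks:
        if not np.isfinite(tr.x).all() or not np.isfinite(tr.y).all():
            raise ValidationError(f"track {tr.track_id!r}: refusing to write NaN position")
        for i in range(tr.n_spots):
            rows.append(
                {
                    "axon_id": tr.axon_id,
                    "track_id": tr.track_id,
                    "frame": int(tr.frames[i]),
                    "t_s": float(tr.t[i]),
                    "x_um": float(tr.x[i]),
                    "y_um": float(tr.y[i]),
                    "organelle": tr.organelle_class,
                    "animal_id": tr.animal_id,
                    "intensity": np.nan if tr.intensity is None else float(tr.intensity[i]),
                    "length_um": np.nan if tr.length_um is None else float(tr.length_um[i]),
                    "video_duration_s": tr.video_duration_s,
                }
            )
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TrackMate XML subset
# ---------------------------------------------------------------------------

def read_trackmate_xml(path, organelle_class: str = "endosome",
                       axon_id: object = "axon0",
                       animal_id: object = "animal0") -> list[Track]:
    """Read a TrackMate-style XML file (subset) into tracks.

    Only ``POSITION_X``, ``POSITION_Y``, ``POSITION_T``, ``FRAME`` and the
    edge-based track membership are used; every other attribute is ignored.
    Positions are converted to μm using the model's ``spatialunits`` field
    (only micrometre units are accepted). Spots referenced by no track are
    dropped with a warning; edges referencing unknown spot IDs raise
    :class:`FormatError` listing the IDs.
    """
    tree = etree.parse(str(path))
    model = tree.find(".//Model")
    if model is None:
        raise FormatError(f"{path}: no <Model> element")
    units = (model.get("spatialunits") or "").strip().lower()
    if units not in _TRACKMATE_UNITS:
        raise FormatError(f"{path}: unknown spatial units {units!r}")
    factor = _TRACKMATE_UNITS[units]

    spots: dict[int, tuple[int, float, float, float]] = {}
    for spot in model.iter("Spot"):
        sid = int(spot.get("ID"))
        spots[sid] = (
            int(float(spot.get("FRAME"))),
            float(spot.get("POSITION_T")),
            float(spot.get("POSITION_X")) * factor,
            float(spot.get("POSITION_Y")) * factor,
        )

    tracks: list[Track] = []
    used: set[int] = set()
    for trk in model.iter("Track"):
        tid = trk.get("TRACK_ID")
        members: set[int] = set()
        dangling: list[int] = []
        for edge in trk.iter("Edge"):
            for key in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                sid = int(edge.get(key))
                if sid in spots:
                    members.add(sid)
                else:
                    dangling.append(sid)
        if dangling:
            raise FormatError(
                f"{path}: track {tid}: edges reference unknown spot IDs "
                f"{sorted(set(dangling))}"
            )
        if not members:
            continue
        used |= members
        rows = sorted((spots[sid] for sid in members), key=lambda r: r[0])
        frames, t, x, y = (np.array(col) for col in zip(*rows))
        tracks.append(
            Track(
                track_id=int(tid) if tid is not None and tid.isdigit() else tid,
                organelle_class=organelle_class,
                frames=frames,
                t=t,
                x=x,
                y=y,
                axon_id=axon_id,
                animal_id=animal_id,
            )
        )
    n_orphans = len(set(spots) - used)
    if n_orphans:
        warnings.warn(
            f"{path}: dropped {n_orphans} spot(s) referenced by no track",
            stacklevel=2,
        )
    return tracks


# ---------------------------------------------------------------------------
# axial projection
# ---------------------------------------------------------------------------

def project_to_axis(track: Track, geom: AxonGeometry,
                    max_lateral_um: float = 10.0) -> AxialTrack:
    """Project spots onto the centerline to obtain node-centred coordinates.

    For each spot the nearest point over all polyline segments is found;
    ``s = distal_sign * (arclength of that point - node_center_arclength)``
    and the lateral offset is the perpendicular (Euclidean) distance to it.
    Ties between equidistant segments resolve to the lower arclength.
    Spots farther than ``max_lateral_um`` from the centerline are flagged
    invalid and excluded downstream, with a warning.
    """
    P = np.stack([track.x, track.y], axis=1)  # (n, 2)
    A = geom.centerline[:-1]                  # (m, 2)
    D = np.diff(geom.centerline, axis=0)      # (m, 2)
    L2 = (D ** 2).sum(axis=1)
    L2 = np.where(L2 == 0, 1.0, L2)           # degenerate zero-length segments
    seg_len = geom.segment_lengths
    cum = geom.vertex_arclengths[:-1]

    ap = P[:, None, :] - A[None, :, :]                       # (n, m, 2)
    tt = np.clip((ap * D[None]).sum(-1) / L2[None], 0.0, 1.0)
    foot = A[None] + tt[..., None] * D[None]
    dist = np.linalg.norm(P[:, None, :] - foot, axis=-1)      # (n, m)

    # np.argmin keeps the first (lowest-arclength) segment among exact ties
    j = np.argmin(dist, axis=1)
    i = np.arange(len(P))
    arclen = cum[j] + tt[i, j] * seg_len[j]
    s = geom.distal_sign * (arclen - geom.node_center_arclength)
    lateral = dist[i, j]
    valid = lateral <= max_lateral_um
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(
            f"track {track.track_id!r}: {n_bad} spot(s) farther than "
            f"{max_lateral_um} um from the centerline were excluded",
            stacklevel=2,
        )
    return AxialTrack(track=track, s=s, lateral=lateral, valid=valid)


def split_on_gaps(track: Track, max_gap_frames: int = 2) -> list[Track]:
    """Split a track wherever more than ``max_gap_frames`` frames are missing.

    Tracking tools permit gap closing; short gaps (<= ``max_gap_frames``
    frame intervals) are retained as single spanning steps downstream,
    while longer gaps split the track into independent tracks (suffixes
    ``/0``, ``/1``... appended to the track id). Fragments with fewer than
    two spots are discarded.
    """
    cut = np.nonzero(np.diff(track.frames) > max_gap_frames)[0] + 1
    if len(cut) == 0:
        return [track]
    pieces = []
    bounds = np.concatenate([[0], cut, [track.n_spots]])
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi - lo < 2:
            continue
        pieces.append(
            Track(
                track_id=f"{track.track_id}/{k}",
                organelle_class=track.organelle_class,
                frames=track.frames[lo:hi],
                t=track.t[lo:hi],
                x=track.x[lo:hi],
                y=track.y[lo:hi],
                intensity=None if track.intensity is None else track.intensity[lo:hi],
                length_um=None if track.length_um is None else track.length_um[lo:hi],
                axon_id=track.axon_id,
                animal_id=track.animal_id,
                video_duration_s=track.video_duration_s,
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# geometry config I/O
# ---------------------------------------------------------------------------

def load_geometry(path) -> AxonGeometry:
    """Load an :class:`AxonGeometry` from a YAML config block."""
    with open(path) as fh:
        return AxonGeometry.from_dict(yaml.safe_load(fh))


def save_geometry(geom: AxonGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(geom.to_dict(), fh)


def flip_distal_sign(geom: AxonGeometry) -> AxonGeometry:
    """Return the same geometry with the distal direction reversed."""
    return replace(geom, distal_sign=-geom.distal_sign)
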