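"""Track I/O, TrackMate ingest and axial projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nodetrans.exceptions import FormatError, ValidationError
from nodetrans.track_io import (
    AxonGeometry,
    Track,
    flip_distal_sign,
    project_to_axis,
    read_trackmate_xml,
    read_tracks_table,
    split_on_gaps,
    write_tracks_table,
)
from .conftest import make_track


def _tracks_equal(a: Track, b: Track) -> bool:
    return (
        a.track_id == b.track_id
        and a.organelle_class == b.organelle_class
        and a.axon_id == b.axon_id
        and np.array_equal(a.frames, b.frames)
        and np.allclose(a.t, b.t)
        and np.allclose(a.x, b.x)
        and np.allclose(a.y, b.y)
    )


class TestTabularDialect:
    def test_two_row_file_single_track(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "axon_id,track_id,frame,t_s,x_um,y_um,organelle\n"
            "ax0,1,0,0.0,1.0,2.0,endosome\n"
            "ax0,1,1,0.5,1.5,2.0,endosome\n"
        )
        tracks = read_tracks_table(p)
        assert len(tracks) == 1
        assert tracks[0].n_spots == 2
        assert tracks[0].spots[1].x == 1.5

    def test_round_trip(self, tmp_path):
        tracks = [
            make_track([0, 1, 2, 3], track_id=1, axon_id="ax0"),
            make_track([5, 4, 3], y=[1, 1, 2], track_id=2, axon_id="ax1",
                       organelle="mitochondrion",
                       length_um=np.array([1.1, 1.1, 1.1])),
        ]
        p = tmp_path / "t.csv"
        write_tracks_table(tracks, p)
        back = read_tracks_table(p)
        assert len(back) == 2
        for a, b in zip(tracks, sorted(back, key=lambda t: t.track_id)):
            assert _tracks_equal(a, b)
        assert np.allclose(back[-1].length_um, 1.1)

    def test_duplicate_frame_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "axon_id,track_id,frame,t_s,x_um,y_um,organelle\n"
            "ax0,1,0,0.0,1.0,2.0,endosome\n"
            "ax0,1,0,0.5,1.5,2.0,endosome\n"
        )
        with pytest.raises(ValidationError, match="duplicated"):
            read_tracks_table(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("axon_id,track_id,frame,t_s,x_um,organelle\na,1,0,0,1,e\n")
        with pytest.raises(FormatError, match="y_um"):
            read_tracks_table(p)

    def test_non_monotone_time_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "axon_id,track_id,frame,t_s,x_um,y_um,organelle\n"
            "ax0,1,0,1.0,1.0,2.0,endosome\n"
            "ax0,1,1,0.5,1.5,2.0,endosome\n"
        )
        with pytest.raises(ValidationError, match="time"):
            read_tracks_table(p)

    def test_empty_dataset_header_only(self, tmp_path):
        p = tmp_path / "t.csv"
        write_tracks_table([], p)
        assert p.read_text().startswith("axon_id,track_id,frame")
        assert read_tracks_table(p) == []

    def test_nan_position_refused(self, tmp_path):
        tr = make_track([0, 1, 2])
        tr.x[1] = np.nan  # bypass constructor validation
        with pytest.raises(ValidationError, match="NaN"):
            write_tracks_table([tr], tmp_path / "t.csv")


_XML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<TrackMate version="7.0">
  <Model spatialunits="{units}" timeunits="sec">
    <AllSpots>
      <SpotsInFrame frame="0">{spots0}</SpotsInFrame>
      <SpotsInFrame frame="1">{spots1}</SpotsInFrame>
      <SpotsInFrame frame="2">{spots2}</SpotsInFrame>
    </AllSpots>
    <AllTracks>
      <Track TRACK_ID="0" NUMBER_SPOTS="3">
        <Edge SPOT_SOURCE_ID="10" SPOT_TARGET_ID="11"/>
        <Edge SPOT_SOURCE_ID="11" SPOT_TARGET_ID="12"/>
      </Track>
    </AllTracks>
    <FilteredTracks><TrackID TRACK_ID="0"/></FilteredTracks>
  </Model>
</TrackMate>
"""


def _spot(sid, frame, t, x, y):
    return (f'<Spot ID="{sid}" FRAME="{frame}" POSITION_T="{t}" '
            f'POSITION_X="{x}" POSITION_Y="{y}" QUALITY="1.0"/>')


class TestTrackMate:
    def _write(self, tmp_path, units="micron", extra_spot=""):
        xml = _XML_TEMPLATE.format(
            units=units,
            spots0=_spot(10, 0, 0.0, 1.0, 2.0) + extra_spot,
            spots1=_spot(11, 1, 0.5, 1.5, 2.0),
            spots2=_spot(12, 2, 1.0, 2.0, 2.1),
        )
        p = tmp_path / "tm.xml"
        p.write_text(xml)
        return p

    def test_minimal_fixture(self, tmp_path):
        tracks = read_trackmate_xml(self._write(tmp_path))
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.n_spots == 3
        assert np.allclose(tr.x, [1.0, 1.5, 2.0])
        assert np.allclose(tr.t, [0.0, 0.5, 1.0])

    def test_cross_reader_equivalence(self, tmp_path):
        """The same 3-spot track read from XML and from CSV must be equal."""
        xml_tracks = read_trackmate_xml(self._write(tmp_path), axon_id="ax0")
        csv = tmp_path / "t.csv"
        write_tracks_table(xml_tracks, csv)
        csv_tracks = read_tracks_table(csv)
        assert len(csv_tracks) == len(xml_tracks) == 1
        assert _tracks_equal(xml_tracks[0], csv_tracks[0])

    def test_orphan_spot_dropped_with_warning(self, tmp_path):
        p = self._write(tmp_path, extra_spot=_spot(99, 0, 0.0, 9.0, 9.0))
        with pytest.warns(UserWarning, match="1 spot"):
            tracks = read_trackmate_xml(p)
        assert len(tracks) == 1
        assert tracks[0].n_spots == 3

    def test_dangling_edge_lists_ids(self, tmp_path):
        xml = _XML_TEMPLATE.format(
            units="micron",
            spots0=_spot(10, 0, 0.0, 1.0, 2.0),
            spots1=_spot(11, 1, 0.5, 1.5, 2.0),
            spots2="",
        )
        p = tmp_path / "tm.xml"
        p.write_text(xml)
        with pytest.raises(FormatError, match="12"):
            read_trackmate_xml(p)

    def test_unknown_units_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="pixel"):
            read_trackmate_xml(self._write(tmp_path, units="pixel"))


def _dense_projection_oracle(geom: AxonGeometry, point, n=100_001):
    """Brute-force nearest point among densely sampled centerline points."""
    arcs = np.linspace(0.0, geom.total_length, n)
    va = geom.vertex_arclengths
    px = np.interp(arcs, va, geom.centerline[:, 0])
    py = np.interp(arcs, va, geom.centerline[:, 1])
    d = np.hypot(px - point[0], py - point[1])
    i = int(np.argmin(d))
    return geom.distal_sign * (arcs[i] - geom.node_center_arclength), d[i]


class TestProjection:
    def test_axis_aligned(self, straight_geom):
        tr = make_track([60.0, 61.0], y=[1.0, 0.0])
        at = project_to_axis(tr, straight_geom)
        assert at.s[0] == pytest.approx(10.0)
        assert at.lateral[0] == pytest.approx(1.0)

    def test_spot_at_node_center(self, straight_geom):
        at = project_to_axis(make_track([50.0, 51.0]), straight_geom)
        assert at.s[0] == pytest.approx(0.0, abs=1e-12)

    def test_bent_polyline_matches_dense_oracle(self):
        geom = AxonGeometry(
            centerline=np.array([[0, 0], [30, 10], [60, 5], [100, 25]], float),
            node_center_arclength=40.0,
            distal_sign=1,
        )
        rng = np.random.default_rng(42)
        pts = rng.uniform([0, -5], [100, 30], size=(12, 2))
        tr = make_track(pts[:, 0], y=pts[:, 1])
        at = project_to_axis(tr, geom, max_lateral_um=np.inf)
        for i, p in enumerate(pts):
            s_ref, lat_ref = _dense_projection_oracle(geom, p)
            assert abs(at.s[i] - s_ref) <= 0.01
            assert abs(at.lateral[i] - lat_ref) <= 0.01

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_polylines_match_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_vert = int(rng.integers(2, 6))
        verts = np.cumsum(rng.uniform([5, -3], [20, 3], size=(n_vert, 2)), axis=0)
        geom = AxonGeometry(centerline=verts, node_center_arclength=0.0)
        p = rng.uniform(verts.min(0) - 5, verts.max(0) + 5)
        tr = make_track([p[0], p[0] + 0.1], y=[p[1], p[1]])
        at = project_to_axis(tr, geom, max_lateral_um=np.inf)
        s_ref, _ = _dense_projection_oracle(geom, p)
        assert abs(at.s[0] - s_ref) <= 0.01

    def test_flipping_distal_sign_negates_s(self, straight_geom):
        tr = make_track([60.0, 30.0, 55.0])
        a = project_to_axis(tr, straight_geom)
        b = project_to_axis(tr, flip_distal_sign(straight_geom))
        assert np.allclose(a.s, -b.s)

    def test_far_spot_flagged(self, straight_geom):
        tr = make_track([60.0, 61.0], y=[0.0, 20.0])
        with pytest.warns(UserWarning, match="excluded"):
            at = project_to_axis(tr, straight_geom)
        assert at.valid.tolist() == [True, False]


class TestSplitOnGaps:
    def test_long_gap_splits(self):
        tr = make_track(np.arange(6, dtype=float))
        tr.frames = np.array([0, 1, 2, 6, 7, 8])  # 4-frame jump
        tr.t = tr.frames * 0.5
        parts = split_on_gaps(tr, max_gap_frames=2)
        assert [p.n_spots for p in parts] == [3, 3]

    def test_short_gap_kept(self):
        tr = make_track(np.arange(4, dtype=float))
        tr.frames = np.array([0, 1, 3, 4])
        tr.t = tr.frames * 0.5
        assert len(split_on_gaps(tr, max_gap_frames=2)) == 1
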