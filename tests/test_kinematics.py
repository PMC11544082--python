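"""Pause detection, trimming, qualification, binning and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nodetrans.exceptions import ValidationError
from nodetrans.kinematics import (
    AnalysisConfig,
    assign_bins,
    bin_profile,
    check_axon_counts,
    compute_step_records,
    pearson_speed_diameter,
    qualify_track,
    summarize_kinematics,
    trim_terminal_pauses,
)
from nodetrans.track_io import Track
from .conftest import make_axial, make_track, steps_frame


class TestStepRecords:
    def test_slow_displacement_is_pause(self, straight_geom, cfg):
        # 0.04 um in 0.5 s -> 0.08 um/s, at or below the 0.1 um/s threshold
        at = make_axial([0.0, 0.04 / 1.0], straight_geom, dt=0.5)
        steps = compute_step_records(at, cfg)
        assert steps["speed"].iloc[0] == pytest.approx(0.08)
        assert bool(steps["is_pause"].iloc[0])

    def test_straight_run_speeds(self, straight_geom, cfg):
        at = make_axial(np.arange(5) * 1.0, straight_geom, dt=0.5)
        steps = compute_step_records(at, cfg)
        assert np.allclose(steps["speed"], 2.0)
        assert not steps["is_pause"].any()

    def test_gap_spanning_step(self, straight_geom, cfg):
        tr = make_track([50.0, 51.0, 53.0], dt=1.0)
        tr.frames = np.array([1, 2, 4])
        tr.t = tr.frames * 1.0
        from nodetrans.track_io import project_to_axis

        steps = compute_step_records(project_to_axis(tr, straight_geom), cfg)
        assert len(steps) == 2
        gap = steps.iloc[1]
        assert gap["dt"] == pytest.approx(2.0)
        assert gap["speed"] == pytest.approx(1.0)
        assert bool(gap["is_gap"])

    def test_speed_uses_2d_displacement(self, straight_geom, cfg):
        from nodetrans.track_io import project_to_axis

        tr = make_track([50.0, 50.3], y=[0.0, 0.4], dt=0.5)
        steps = compute_step_records(project_to_axis(tr, straight_geom), cfg)
        assert steps["speed"].iloc[0] == pytest.approx(1.0)  # hypot(0.3, 0.4)/0.5
        assert steps["axial_delta"].iloc[0] == pytest.approx(0.3)

    def test_non_monotone_time_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="time"):
            Track(track_id="t", organelle_class="endosome",
                  frames=[0, 1], t=[1.0, 0.5], x=[0, 1], y=[0, 0])


class TestTrimming:
    def test_long_terminal_pause_removed(self, cfg):
        steps = steps_frame([2.0] * 18 + [0.05] * 12)
        out = trim_terminal_pauses(steps, cfg)
        assert len(out) == 18
        assert not out["is_pause"].any()

    def test_short_terminal_pause_kept(self, cfg):
        steps = steps_frame([2.0] * 21 + [0.05] * 9)
        assert len(trim_terminal_pauses(steps, cfg)) == 30

    def test_all_pauses_trimmed_to_empty(self, cfg):
        steps = steps_frame([0.05] * 12)
        assert len(trim_terminal_pauses(steps, cfg)) == 0

    def test_leading_pause_removed(self, cfg):
        steps = steps_frame([0.05] * 10 + [2.0] * 5)
        out = trim_terminal_pauses(steps, cfg)
        assert len(out) == 5

    def test_interior_pause_runs_retained(self, cfg):
        steps = steps_frame([2.0] * 3 + [0.05] * 15 + [2.0] * 3)
        assert len(trim_terminal_pauses(steps, cfg)) == 21

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_trimming_idempotent(self, pauses):
        cfg = AnalysisConfig()
        speeds = [0.05 if p else 2.0 for p in pauses]
        once = trim_terminal_pauses(steps_frame(speeds), cfg)
        twice = trim_terminal_pauses(once, cfg)
        pd.testing.assert_frame_equal(once, twice)


class TestQualification:
    def test_ten_consecutive_moving_accepted(self, cfg):
        q = qualify_track(steps_frame([2.0] * 10), cfg)
        assert q.accepted and q.reason == "ok"

    def test_alternating_rejected(self, cfg):
        speeds = ([2.0] * 5 + [0.05]) * 6
        q = qualify_track(steps_frame(speeds), cfg)
        assert not q.accepted and q.reason == "no_qualifying_run"

    def test_empty_rejected(self, cfg):
        q = qualify_track(steps_frame([]), cfg)
        assert not q.accepted and q.reason == "empty_after_trimming"

    def test_gap_breaks_consecutive_run(self, cfg):
        gaps = np.zeros(10, bool)
        gaps[5] = True
        q = qualify_track(steps_frame([2.0] * 10, gaps=gaps), cfg)
        assert not q.accepted


class TestAxonCounts:
    def test_minima(self, cfg):
        counts = {
            ("ax0", "endosome", "retrograde"): 20,
            ("ax1", "mitochondrion", "retrograde"): 10,
            ("ax2", "endosome", "retrograde"): 19,
            ("ax3", "mitochondrion", "anterograde"): 19,
        }
        out = check_axon_counts(counts, cfg).set_index("axon_id")
        assert bool(out.loc["ax0", "passed"])
        assert bool(out.loc["ax1", "passed"])      # relaxed retro-mito minimum
        assert not bool(out.loc["ax2", "passed"])
        assert not bool(out.loc["ax3", "passed"])  # antero mito needs 20


class TestBinning:
    @pytest.mark.parametrize(
        "s_mid, bin_index, subdomain",
        [
            (-39.0, 0, "proximal"),
            (0.0, 20, "center"),
            (2.5, 21, "distal"),
            (-2.0, 19, "center"),   # ties at the node edge go to the center
            (2.0, 21, "center"),
            (40.0, 39, "distal"),
            (41.0, -1, "outside"),
            (-40.0, 0, "proximal"),
        ],
    )
    def test_bin_and_subdomain(self, cfg, s_mid, bin_index, subdomain):
        steps = assign_bins(steps_frame([2.0], s_mid=s_mid), cfg)
        assert steps["bin_index"].iloc[0] == bin_index
        assert steps["subdomain"].iloc[0] == subdomain


class TestSummaries:
    def test_hand_computed_bin(self, cfg):
        steps = assign_bins(steps_frame([0.05] * 3 + [2.0] * 7, s_mid=-5.0), cfg)
        out = summarize_kinematics(steps, cfg)
        row = out.loc["proximal"]
        assert row["pause_relative_frequency"] == pytest.approx(0.3)
        assert row["mean_moving_velocity"] == pytest.approx(2.0)

    def test_all_paused_velocity_missing(self, cfg):
        steps = assign_bins(steps_frame([0.05] * 5, s_mid=0.0), cfg)
        out = summarize_kinematics(steps, cfg)
        assert out.loc["center", "pause_relative_frequency"] == 1.0
        assert np.isnan(out.loc["center", "mean_moving_velocity"])

    def test_conservation(self, cfg):
        rng = np.random.default_rng(0)
        steps = assign_bins(
            steps_frame(rng.uniform(0, 3, 500), s_mid=rng.uniform(-45, 45, 500)),
            cfg,
        )
        out = summarize_kinematics(steps, cfg)
        assert (out["n_pauses"] + out["n_moving"]).equals(out["n_steps"])
        inside = (steps["subdomain"] != "outside").sum()
        assert out["n_steps"].sum() == inside

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    def test_threshold_monotonicity(self, thr_a, thr_b):
        """Raising the pause threshold never lowers any bin's pause rate."""
        lo, hi = sorted([thr_a, thr_b])
        rng = np.random.default_rng(7)
        speeds = rng.uniform(0, 3, 300)
        s_mid = rng.uniform(-40, 40, 300)
        outs = []
        for thr in (lo, hi):
            cfg = AnalysisConfig(pause_speed_threshold=thr)
            steps = steps_frame(speeds, s_mid=s_mid, threshold=thr)
            outs.append(summarize_kinematics(assign_bins(steps, cfg), cfg, by="bin"))
        merged = outs[0]["pause_relative_frequency"].align(
            outs[1]["pause_relative_frequency"], join="inner"
        )
        assert (merged[1] >= merged[0] - 1e-12).all()

    def test_permutation_invariance(self, cfg):
        rng = np.random.default_rng(3)
        steps = assign_bins(
            steps_frame(rng.uniform(0, 3, 200), s_mid=rng.uniform(-40, 40, 200)),
            cfg,
        )
        shuffled = steps.sample(frac=1.0, random_state=5).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            summarize_kinematics(steps, cfg), summarize_kinematics(shuffled, cfg)
        )

    def test_share_of_pauses_mode_sums_to_one(self, cfg):
        rng = np.random.default_rng(11)
        steps = assign_bins(
            steps_frame(rng.uniform(0, 0.3, 400), s_mid=rng.uniform(-40, 40, 400)),
            cfg,
        )
        out = summarize_kinematics(steps, cfg, pause_freq_mode="share_of_pauses")
        assert out["pause_relative_frequency"].sum() == pytest.approx(1.0)

    def test_bin_profile_covers_window(self, cfg):
        steps = assign_bins(steps_frame([2.0] * 5, s_mid=1.0), cfg)
        prof = bin_profile(steps, cfg)
        assert len(prof) == 40
        assert prof["s_center"].iloc[0] == pytest.approx(-39.0)
        assert prof["s_center"].iloc[-1] == pytest.approx(39.0)
        assert prof["n_steps"].sum() == 5


class TestPearson:
    def test_exactly_linear(self):
        r, p = pearson_speed_diameter([(1, 2), (2, 4), (3, 6)])
        assert r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        pairs = np.array([(1, 2), (2, 1), (3, 3), (4, 5)], float)
        x, y = pairs[:, 0], pairs[:, 1]
        # independent computation from covariance / variances
        r_ref = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        from scipy import stats

        t = r_ref * np.sqrt((len(x) - 2) / (1 - r_ref**2))
        p_ref = 2 * stats.t.sf(abs(t), len(x) - 2)
        r, p = pearson_speed_diameter(pairs)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            pearson_speed_diameter([(1, 2), (2, 3)])

    def test_constant_input(self):
        with pytest.raises(ValidationError):
            pearson_speed_diameter([(1, 2), (1, 3), (1, 4)])


class TestConfig:
    def test_window_partition_invariant(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(internode_length=30.0)  # 2*30+4 != 80

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(bin_width=3.0)
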