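"""Excursion heuristics: velocity rule, novelty rule, gap relabelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kitetrails import classifier, geometry
from kitetrails.classifier import (
    ClassifierConfig,
    classify,
    excursion_summary,
    novelty_rule,
    novelty_rule_bruteforce,
    relabel_gaps,
    velocity_rule,
)

CFG = ClassifierConfig()


class TestVelocityRule:
    @pytest.mark.parametrize(
        "r,v_r,v_theta,expected",
        [
            (50.0, 20.0, 10.0, True),  # fast radial, slow angular, outside buffer
            (25.0, 50.0, 0.0, False),  # inside the 30 km nest buffer: vetoed
            (50.0, 20.0, 80.0, False),  # angular velocity too high
            (50.0, 4.0, 10.0, False),  # radial speed below threshold
            (50.0, -20.0, 10.0, True),  # fast inbound leg counts with |v_r|
        ],
    )
    def test_cases(self, r, v_r, v_theta, expected):
        fired = velocity_rule([v_r], [v_theta], [True], [r], CFG)
        assert bool(fired[0]) is expected

    def test_signed_mode_ignores_inbound(self):
        cfg = ClassifierConfig(use_absolute_v_r=False)
        assert not velocity_rule([-20.0], [10.0], [True], [50.0], cfg)[0]
        assert velocity_rule([20.0], [10.0], [True], [50.0], cfg)[0]

    def test_undefined_velocity_never_fires(self):
        assert not velocity_rule([np.nan], [np.nan], [False], [50.0], CFG)[0]


class TestNoveltyRule:
    def test_far_from_everything(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [40.0, 0.0]])
        r = np.hypot(xy[:, 0], xy[:, 1])
        fired = novelty_rule(xy, r, CFG)
        assert list(fired) == [False, False, True]

    def test_revisit_not_novel(self):
        xy = np.array([[0.0, 0.0], [40.0, 0.0], [40.5, 0.0]])
        r = np.hypot(xy[:, 0], xy[:, 1])
        assert not novelty_rule(xy, r, CFG)[2]

    def test_first_fix_never_novel(self):
        xy = np.array([[40.0, 0.0]])
        assert not novelty_rule(xy, np.array([40.0]), CFG)[0]

    def test_inside_buffer_vetoed(self):
        xy = np.array([[0.0, 0.0], [25.0, 0.0]])
        assert not novelty_rule(xy, np.array([0.0, 25.0]), CFG)[1]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_grid_index_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 4, size=(300, 2)), axis=0)
        r = np.hypot(xy[:, 0], xy[:, 1])
        np.testing.assert_array_equal(
            novelty_rule(xy, r, CFG), novelty_rule_bruteforce(xy, r, CFG)
        )


class TestRelabelGaps:
    def _run(self, pattern, max_gap=3):
        labels = np.array(["excursion" if c == "E" else "settlement" for c in pattern])
        rules = np.array(["velocity" if c == "E" else "none" for c in pattern])
        cfg = ClassifierConfig(max_gap_fixes=max_gap)
        out, rout = relabel_gaps(labels, rules, cfg)
        return "".join("E" if v == "excursion" else "S" for v in out), rout

    def test_single_gap_bridged(self):
        out, rules = self._run("ESE")
        assert out == "EEE"
        assert rules[1] == "gapfill"

    def test_run_of_three_bridged(self):
        assert self._run("ESSSE")[0] == "EEEEE"

    def test_run_of_four_unchanged(self):
        assert self._run("ESSSSE")[0] == "ESSSSE"

    def test_leading_run_not_flanked(self):
        assert self._run("SSE")[0] == "SSE"

    def test_trailing_run_not_flanked(self):
        assert self._run("ESS")[0] == "ESS"

    def test_excursion_labels_never_revert(self):
        out, _ = self._run("EEEE")
        assert out == "EEEE"

    @given(st.text(alphabet="ES", min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_idempotent(self, pattern):
        once, _ = self._run(pattern)
        twice, _ = self._run(once)
        assert once == twice

    @given(st.text(alphabet="ES", min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_only_short_flanked_runs_change(self, pattern):
        out, rules = self._run(pattern)
        for i, (a, b) in enumerate(zip(pattern, out)):
            if a == "E":
                assert b == "E"
            elif b == "E":
                assert rules[i] == "gapfill"


WORKED_XY = np.array(
    [
        [0.0, 0.0],  # nest
        [1.0, 0.0],
        [2.0, 1.0],
        [50.0, 0.0],  # fast departure: velocity rule
        [75.0, 0.0],  # still travelling
        [76.0, 1.0],  # brief pause, bridged by gapfill
        [100.0, 0.0],  # travelling again
        [101.0, 1.0],  # 3-fix stay at the far point ...
        [101.0, -1.0],
        [100.0, -2.0],  # ... bridged by gapfill (run of exactly 3)
        [60.0, 0.0],  # fast return leg: |v_r| large
        [20.0, 0.0],  # inside the 30 km buffer: vetoed despite speed
    ]
)
WORKED_T = np.array([0.0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11, 12])
# Hand-derived by applying the three rules fix by fix (backward differences,
# wrapped angles, all-previous-fix distances) to the coordinates above.
WORKED_LABELS = "SSSEEEEEEEES"
WORKED_RULES = [
    "none", "none", "none",
    "velocity", "velocity", "gapfill", "velocity",
    "gapfill", "gapfill", "gapfill",
    "velocity", "none",
]


class TestClassify:
    def test_worked_out_and_back_journey(self, km_trajectory):
        traj = km_trajectory(WORKED_XY, WORKED_T)
        labels, rules = classify(traj)
        got = "".join("E" if v == "excursion" else "S" for v in labels)
        assert got == WORKED_LABELS
        assert list(rules) == WORKED_RULES

    def test_signed_vr_turns_return_leg_over_to_novelty(self, km_trajectory):
        traj = km_trajectory(WORKED_XY, WORKED_T)
        labels, rules = classify(traj, ClassifierConfig(use_absolute_v_r=False))
        assert labels[10] == "excursion"
        assert rules[10] == "novelty"  # 10 km from any earlier fix

    def test_sedentary_bird_no_excursions(self, km_trajectory):
        rng = np.random.default_rng(5)
        xy = rng.normal(0.0, 2.0, size=(50, 2))
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(50) * 4.0)
        labels, rules = classify(traj)
        assert set(labels) == {"settlement"}
        assert set(rules) == {"none"}

    def test_rotation_invariance(self, km_trajectory):
        ang = np.radians(73.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        traj = km_trajectory(WORKED_XY, WORKED_T)
        traj_rot = km_trajectory(WORKED_XY @ rot.T, WORKED_T)
        labels, _ = classify(traj)
        labels_rot, _ = classify(traj_rot)
        assert list(labels) == list(labels_rot)

    def test_first_fix_never_excursion(self, km_trajectory):
        traj = km_trajectory(WORKED_XY, WORKED_T)
        labels, _ = classify(traj)
        assert labels[0] == "settlement"

    def test_threshold_monotonicity(self, km_trajectory):
        """Raising v_r / novelty thresholds or shrinking the v_theta ceiling
        never increases the pre-gapfill excursion count."""
        rng = np.random.default_rng(11)
        xy = np.cumsum(rng.normal(0, 8, size=(80, 2)), axis=0)
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(80) * 2.0)

        def count(cfg):
            labels, rules = classify(traj, cfg)
            return int(np.sum((labels == "excursion") & (rules != "gapfill")))

        base = count(ClassifierConfig(max_gap_fixes=0))
        assert count(ClassifierConfig(v_r_thresh_kmh=10, max_gap_fixes=0)) <= base
        assert count(ClassifierConfig(novelty_dist_km=6, max_gap_fixes=0)) <= base
        assert count(ClassifierConfig(v_theta_thresh_degh=20, max_gap_fixes=0)) <= base

    def test_pre_gapfill_excursions_all_outside_buffer(self, km_trajectory):
        rng = np.random.default_rng(13)
        xy = np.cumsum(rng.normal(0, 10, size=(120, 2)), axis=0)
        xy[0] = 0.0
        traj = km_trajectory(xy, np.arange(120) * 3.0)
        labels, rules = classify(traj)
        track = geometry.project(traj)
        r = np.hypot(track.x, track.y)
        non_gap = (labels == "excursion") & (rules != "gapfill")
        assert np.all(r[non_gap] > 30.0)


class TestConfigValidation:
    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            ClassifierConfig(nest_buffer_km=0.0)
        with pytest.raises(ValueError):
            ClassifierConfig(max_gap_fixes=-1)


class TestExcursionSummary:
    @pytest.mark.parametrize(
        "n,e,pct",
        [(1594, 181, 11.4), (1995, 135, 6.8), (48, 3, 6.3), (500, 0, 0.0)],
    )
    def test_percentage_rounding(self, n, e, pct):
        labels = ["excursion"] * e + ["settlement"] * (n - e)
        df = excursion_summary([("b", labels)])
        assert float(df.loc[df.bird_id == "b", "pct_excursion"].iloc[0]) == pct

    def test_totals_row(self):
        df = excursion_summary(
            [("a", ["excursion", "settlement"]), ("b", ["settlement"] * 3)]
        )
        total = df[df.bird_id == "total"].iloc[0]
        assert total.n_fixes == 5 and total.n_excursion == 1
        assert float(total.pct_excursion) == 20.0

    def test_empty_input(self):
        df = excursion_summary([])
        assert len(df) == 0
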