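import numpy as np
import pandas as pd
import pytest

from quiescell.fate import (FateClassifier, classify_fate, couple_ph_mobility,
                            inheritance_index, survival_fraction)
from quiescell.foci import MobilityLossEvent
from quiescell.ph import PhDropFit
from quiescell.phases import PhaseSegmentation


def _segmentation():
    return PhaseSegmentation(breakpoints=np.array([5.5, 13.9, 31.6]),
                             slopes=np.array([0.5, 0.0, 0.14, 0.0]),
                             doubling_times_min=np.array([84, np.nan, 307, np.nan]),
                             sse=0.0, t_range=(0.0, 48.0))


def _drop(t_half, ph_after=5.8, detected=True):
    half_width = 2.0
    return PhDropFit(t_start=t_half - half_width, t_end=t_half + half_width,
                     t_half=t_half, ph_before=7.0, ph_after=ph_after,
                     drop_detected=detected, sse=0.01, pvalue=1e-6)


class TestFateCalls:
    def test_early_crash_is_r_minus(self):
        call = classify_fate(_drop(8.0), _segmentation())
        assert call.fate == "R_minus"

    def test_late_crash_is_r_plus(self):
        call = classify_fate(_drop(40.0), _segmentation())
        assert call.fate == "R_plus"

    def test_early_decline_to_plateau_is_not_a_crash(self):
        # the universal fermentation decline ends high; growth decides
        call = classify_fate(_drop(4.0, ph_after=6.9), _segmentation(),
                             r_phase_fold=2.0)
        assert call.fate == "R_plus"

    def test_no_drop_with_growth_is_r_plus(self):
        call = classify_fate(None, _segmentation(), r_phase_fold=1.9)
        assert call.fate == "R_plus"

    def test_no_drop_flat_area_over_full_r_phase_is_r_minus(self):
        call = classify_fate(None, _segmentation(), r_phase_fold=1.02,
                             track_end_time=48.0)
        assert call.fate == "R_minus"

    def test_short_flat_track_unclassified(self):
        call = classify_fate(None, _segmentation(), r_phase_fold=None,
                             track_end_time=10.0)
        assert call.fate == "unclassified"

    def test_missing_segmentation_raises(self):
        with pytest.raises(ValueError, match="segmentation"):
            FateClassifier().classify(_drop(8.0), None)


class TestInheritanceIndex:
    def test_pure_colonies_give_exactly_zero(self):
        fates = np.repeat([0, 1, 0, 1], 10)
        colonies = np.repeat(np.arange(4), 10)
        assert inheritance_index(fates, colonies) == 0.0

    def test_two_balanced_colonies_hand_value(self):
        # colonies of 10 with 5 ones each: within s^2 = 25/90,
        # pooled s^2 = 100/380 -> ratio 1.0556 (hand computation)
        fates = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 5)
        colonies = np.repeat([0, 1], 10)
        assert inheritance_index(fates, colonies) == pytest.approx(
            (25 / 90) / (100 / 380))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_assignment_expectation_near_one(self, seed):
        rng = np.random.default_rng(seed)
        fates = (rng.random((100, 15)) < 0.12).astype(float).ravel()
        colonies = np.repeat(np.arange(100), 15)
        assert inheritance_index(fates, colonies) == pytest.approx(1.0, abs=0.05)

    def test_identical_fates_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            inheritance_index(np.ones(20), np.repeat([0, 1], 10))

    def test_single_colony_rejected(self):
        with pytest.raises(ValueError, match="two microcolonies"):
            inheritance_index(np.array([0, 1, 0, 1]), np.zeros(4))


class TestSurvival:
    def test_all_true_gives_one(self):
        out = survival_fraction([True] * 12)
        assert out["fraction"].iloc[0] == 1.0
        assert out["ci_high"].iloc[0] == 1.0

    def test_stratified_fractions_and_ordering(self):
        rng = np.random.default_rng(4)
        strata = np.repeat(["R_minus", "R_plus"], 300)
        p = np.where(strata == "R_plus", 0.8, 0.3)
        flags = rng.random(600) < p
        out = survival_fraction(flags, strata).set_index("stratum")
        assert abs(out.loc["R_plus", "fraction"] - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 300)
        assert abs(out.loc["R_minus", "fraction"] - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 300)
        assert out.loc["R_minus", "fraction"] < out.loc["R_plus", "fraction"]
        assert (out["ci_low"] <= out["fraction"]).all()
        assert (out["fraction"] <= out["ci_high"]).all()


class TestCoupling:
    def _trajectory(self, tid=1):
        t = np.arange(40.0, 60.0, 1.0)
        ph = np.interp(t, [40, 48, 52, 60], [7.0, 7.0, 5.8, 5.8])
        return pd.DataFrame({"track_id": tid, "time": t, "ph": ph})

    def test_ph_interpolated_at_loss_time(self):
        traj = self._trajectory()
        # fitted decline crosses 6.0 at t = 51.33; gel at the same moment
        t_gel = 48 + (7.0 - 6.0) / (7.0 - 5.8) * 4.0
        events = {1: MobilityLossEvent(1, t_gel, "changepoint", 0.9)}
        drops = {1: PhDropFit(48, 52, 50, 7.0, 5.8, True, 0.0, 1e-9)}
        records, summary = couple_ph_mobility(drops, events, traj)
        assert records["ph_at_loss"].iloc[0] == pytest.approx(6.0, abs=0.05)
        assert summary["pooled"]["median_ph_at_loss"] == pytest.approx(6.0, abs=0.05)

    def test_loss_outside_span_excluded(self):
        traj = self._trajectory()
        events = {1: MobilityLossEvent(1, 99.0, "changepoint", 0.9)}
        records, summary = couple_ph_mobility({}, events, traj)
        assert len(records) == 0

    def test_shuffled_pairing_decorrelates(self):
        rng = np.random.default_rng(5)
        n = 60
        t_half = np.sort(rng.uniform(30, 46, n))
        trajs = []
        drops, events = {}, {}
        for i, th in enumerate(t_half):
            t = np.arange(0.0, 48.0, 1.0)
            ph = np.interp(t, [0, th - 1, th + 1, 48], [7.0, 7.0, 5.8, 5.8])
            trajs.append(pd.DataFrame({"track_id": i, "time": t, "ph": ph}))
            drops[i] = PhDropFit(th - 1, th + 1, th, 7.0, 5.8, True, 0.0, 1e-9)
        traj = pd.concat(trajs, ignore_index=True)

        matched = {i: MobilityLossEvent(i, t_half[i], "changepoint", 1.0)
                   for i in range(n)}
        _, s_matched = couple_ph_mobility(drops, matched, traj)
        assert s_matched["pearson_r"] > 0.99

        perm = rng.permutation(n)
        shuffled = {i: MobilityLossEvent(i, t_half[perm[i]], "changepoint", 1.0)
                    for i in range(n)}
        _, s_shuffled = couple_ph_mobility(drops, shuffled, traj)
        assert abs(s_shuffled["pearson_r"]) < 0.3
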