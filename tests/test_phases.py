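import itertools

import numpy as np
import pandas as pd
import pytest

from quiescell.config import SimulationConfig
from quiescell.lineage import simulate_counts
from quiescell.phases import (GrowthPhaseSegmenter, detect_phases,
                              doubling_time_from_segment, single_cell_growth)


def test_two_segment_noiseless_break_recovered():
    t = np.arange(0, 12.0, 0.25)
    slope = np.log(2) / 1.4
    y = np.exp(slope * np.minimum(t, 5.5))
    seg = detect_phases(t, y, n_breakpoints=1)
    assert seg.breakpoints[0] == pytest.approx(5.5, abs=0.25)
    assert seg.slopes[0] == pytest.approx(slope, rel=1e-6)
    assert abs(seg.slopes[1]) < 1e-8


def test_single_exponential_slope_recovered_exactly():
    t = np.linspace(0, 10, 40)
    rate = 0.37
    seg = detect_phases(t, np.exp(rate * t + 1.0), n_breakpoints=0)
    assert seg.slopes[0] == pytest.approx(rate, abs=1e-10)


def test_doubling_time_conversion_and_flags():
    t = np.linspace(0, 10, 30)
    seg = detect_phases(t, np.exp(np.log(2) * t), n_breakpoints=0)
    assert doubling_time_from_segment(seg, 0) == pytest.approx(60.0, rel=1e-9)
    flat = detect_phases(t, np.full_like(t, 5.0), n_breakpoints=0)
    assert np.isnan(doubling_time_from_segment(flat, 0))
    with pytest.raises(IndexError):
        doubling_time_from_segment(seg, 1)


def test_sse_non_increasing_in_breakpoint_count():
    rng = np.random.default_rng(1)
    cfg = SimulationConfig(seed=1)
    t, counts = simulate_counts(cfg, rng, noise=0.05)
    t, counts = t[::4], counts[::4]
    sses = [detect_phases(t, counts, n_breakpoints=k).sse for k in range(4)]
    assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))


def test_breakpoint_error_shrinks_with_noise():
    cfg = SimulationConfig(seed=2)
    errs = []
    for noise in (0.10, 0.03, 0.0):
        t, counts = simulate_counts(cfg, np.random.default_rng(3), noise=noise)
        seg = detect_phases(t, counts, n_breakpoints=3)
        errs.append(np.abs(seg.breakpoints - np.array(cfg.phase_times)).max())
    assert errs[2] <= errs[0] + 1e-9
    assert errs[2] < 0.3


def test_exhaustive_fit_matches_brute_force_oracle():
    # independent oracle: interpolation-basis least squares per placement
    rng = np.random.default_rng(4)
    t = np.linspace(0, 20, 48)
    y_true = np.interp(t, [0, 7, 14, 20], [0.0, 3.0, 3.2, 5.0])
    counts = np.exp(y_true + rng.normal(0, 0.05, t.size))
    y = np.log(counts)

    def interp_sse(i, j):
        knots_t = [t[0], t[i], t[j], t[-1]]
        X = np.column_stack([
            np.interp(t, knots_t, np.eye(4)[k]) for k in range(4)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ coef) ** 2))

    best = min(((interp_sse(i, j), i, j)
                for i, j in itertools.combinations(range(3, 45), 2)
                if j - i >= 3), key=lambda x: x[0])
    seg = GrowthPhaseSegmenter(n_breakpoints=2).fit(t, counts)
    assert seg.sse_ == pytest.approx(best[0], abs=1e-8)
    assert np.allclose(seg.breakpoints_, [t[best[1]], t[best[2]]])


def test_coarse_to_fine_agrees_with_exhaustive_on_long_series():
    cfg = SimulationConfig(seed=5)
    t, counts = simulate_counts(cfg, np.random.default_rng(6), noise=0.05)
    t, counts = t[::3], counts[::3]
    exhaustive = GrowthPhaseSegmenter(n_breakpoints=3,
                                      max_exhaustive=100_000).fit(t, counts)
    coarse = GrowthPhaseSegmenter(n_breakpoints=3,
                                  max_exhaustive=2_000).fit(t, counts)
    # the refined grid search must land within one sample of the optimum
    assert np.abs(coarse.breakpoints_ - exhaustive.breakpoints_).max() <= 0.75 + 1e-9


@pytest.mark.parametrize("bad", [
    dict(counts=[1, 2, 0, 4, 5, 6, 7, 8, 9], match="positive"),
    dict(counts=[1] * 5, match="at least"),
])
def test_invalid_series_rejected(bad):
    t = np.arange(len(bad["counts"]), dtype=float)
    with pytest.raises(ValueError, match=bad["match"]):
        detect_phases(t, bad["counts"], n_breakpoints=1)


def test_single_cell_growth_normalisation():
    cfg = SimulationConfig(seed=7)
    t, counts = simulate_counts(cfg, np.random.default_rng(8), noise=0.02)
    seg = detect_phases(t, counts, n_breakpoints=3)
    frames = np.arange(0, 97)
    times = frames * 0.5
    # constant-area track stays at fold 1; a track doubling over R doubles
    const = pd.DataFrame({"track_id": 1, "frame": frames, "time": times,
                          "area_total": 80.0})
    grow = pd.DataFrame({"track_id": 2, "frame": frames, "time": times,
                         "area_total": 80.0 * (1 + np.clip(
                             (times - 13.9) / (31.6 - 13.9), 0, 1))})
    feats = pd.concat([const, grow], ignore_index=True)
    series, summary = single_cell_growth(feats, seg)
    s1 = series[series["track_id"] == 1]
    assert np.allclose(s1["fold_area"], 1.0)
    folds = dict(zip(summary["track_id"], summary["r_phase_fold"]))
    assert folds[1] == pytest.approx(1.0, abs=1e-6)
    assert folds[2] == pytest.approx(2.0, abs=0.1)
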