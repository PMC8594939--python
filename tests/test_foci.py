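import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from quiescell.foci import (MobilityChangepointDetector, aggregate_displacement,
                            aggregate_foci_fraction, detect_foci,
                            focus_centroid, frame_displacement,
                            globularization_score, mobility_loss_time)

pixel_arrays = hnp.arrays(np.float64, st.integers(6, 200),
                          elements=st.floats(-1e5, 1e5, allow_nan=False,
                                             width=32))


def test_score_forced_arithmetic():
    assert globularization_score(np.full(100, 100.0)) == 0.0
    px = np.concatenate([np.full(95, 10.0), np.full(5, 110.0)])
    assert globularization_score(px) == pytest.approx(100.0)


def test_score_requires_six_pixels():
    with pytest.raises(ValueError, match="at least"):
        globularization_score(np.ones(5))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(pixel_arrays, st.floats(-1e4, 1e4, allow_nan=False),
       st.floats(0.01, 100.0))
def test_score_shift_invariant_and_gain_equivariant(px, c, g):
    base = globularization_score(px)
    scale = max(1.0, np.abs(px).max())
    assert globularization_score(px + c) == pytest.approx(base, abs=1e-6 * scale + 1e-6)
    assert globularization_score(px * g) == pytest.approx(g * base,
                                                          rel=1e-9, abs=1e-6 * scale * g)


def test_detect_foci_constant_false_and_contrast_true():
    rng = np.random.default_rng(0)
    assert not detect_foci(np.full(80, 500.0))
    diffuse = 800 + rng.normal(0, 30, 80)
    assert not detect_foci(diffuse, k=4.0)
    with_focus = diffuse.copy()
    with_focus[:5] += 2000.0
    assert detect_foci(with_focus, k=4.0)


def test_focus_centroid_symmetry_and_ties():
    # five bright pixels forming a cross centred at (10, 10)
    coords = np.array([[10, 10], [9, 10], [11, 10], [10, 9], [10, 11],
                       [2, 2], [3, 2], [2, 3]], dtype=float)
    px = np.array([9, 9, 9, 9, 9, 1, 1, 1], dtype=float)
    assert focus_centroid(px, coords) == (10.0, 10.0)
    # two equal blobs: centroid falls between them
    coords2 = np.array([[0, 0]] * 3 + [[10, 0]] * 2 + [[5, 5]] * 5, dtype=float)
    px2 = np.array([9.0] * 5 + [0.0] * 5)
    cx, cy = focus_centroid(px2, coords2)
    assert 0 < cx < 10 and cy == 0.0


def test_displacement_constant_and_linear_motion():
    static = np.tile([3.0, 4.0], (8, 1))
    assert np.allclose(frame_displacement(static), 0.0)
    moving = np.column_stack([np.arange(10) * 3.0, np.zeros(10)])
    assert np.allclose(frame_displacement(moving), 3.0)
    assert frame_displacement(np.array([[1.0, 2.0]])).size == 0


def test_displacement_time_reversal_symmetry():
    rng = np.random.default_rng(1)
    c = rng.normal(size=(50, 2))
    fwd = frame_displacement(c)
    rev = frame_displacement(c[::-1])
    assert np.allclose(rev, fwd[::-1])


def test_brownian_mean_step_is_rayleigh_mean():
    # mean step of a 2-D walk with per-axis variance 2D is sqrt(pi*D)
    rng = np.random.default_rng(2)
    d = 0.5
    steps = rng.normal(0, np.sqrt(2 * d), size=(10_000 + 1, 2))
    disp = frame_displacement(np.cumsum(steps, axis=0))
    assert disp.mean() == pytest.approx(np.sqrt(np.pi * d), rel=0.05)


def test_changepoint_exact_example_and_constant_series():
    disp = np.array([3, 3, 3, 3, 0.2, 0.2, 0.2, 0.2])
    times = np.arange(8.0)
    event = mobility_loss_time(disp, times)
    assert event.t_loss == 4.0
    assert event.method == "changepoint"
    flat = mobility_loss_time(np.full(10, 2.0), np.arange(10.0))
    assert flat.t_loss is None


def test_changepoint_matches_brute_force_over_all_splits():
    rng = np.random.default_rng(3)
    d = np.concatenate([rng.normal(3, 0.3, 14), rng.normal(0.4, 0.1, 11)])
    t = np.arange(d.size, dtype=float)

    def sse_at(k):
        return (np.sum((d[:k] - d[:k].mean()) ** 2)
                + np.sum((d[k:] - d[k:].mean()) ** 2))

    brute = min(range(1, d.size), key=sse_at)
    det = MobilityChangepointDetector(min_segment=1).fit(t, d)
    assert det.split_index_ == brute
    assert det.sse_ == pytest.approx(sse_at(brute), abs=1e-9)


def test_changepoint_requires_enough_points():
    with pytest.raises(ValueError, match="at least"):
        MobilityChangepointDetector().fit([0, 1, 2], [1, 1, 1])


def test_aggregate_displacement_sem():
    import pandas as pd
    rec = pd.DataFrame({"time": [0.1, 0.2, 0.3, 1.4, 1.5],
                        "displacement": [1.0, 2.0, 3.0, 4.0, 6.0]})
    out = aggregate_displacement(rec, bin_hours=1.0)
    assert out["mean"].tolist() == [2.0, 5.0]
    assert out["sem"].iloc[0] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))


def test_aggregate_foci_fraction_all_positive_is_one():
    import pandas as pd
    from quiescell.phases import PhaseSegmentation
    seg = PhaseSegmentation(breakpoints=np.array([5.5, 13.9, 31.6]),
                            slopes=np.zeros(4),
                            doubling_times_min=np.full(4, np.nan),
                            sse=0.0, t_range=(0.0, 48.0))
    rec = pd.DataFrame({
        "track_id": np.repeat([1, 2], 10),
        "time": np.tile(np.linspace(0.5, 47.0, 10), 2),
        "has_foci": True,
        "marker": "Dhh1",
    })
    out = aggregate_foci_fraction(rec, seg)
    assert (out["fraction_with_foci"] == 1.0).all()
    assert set(out["phase"]) == {"F", "DS", "R", "SP"}
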