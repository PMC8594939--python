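import numpy as np
import pytest

from quiescell.config import SimulationConfig
from quiescell.lineage import simulate_lineage
from quiescell.states import (FieldOfViewOverflow, ph_template, place_cells,
                              simulate_marker_states, simulate_ph_trajectories,
                              simulate_random_walk)


@pytest.fixture
def states(small_sim):
    lin = simulate_lineage(small_sim)
    ser = simulate_ph_trajectories(lin, small_sim)
    return lin, simulate_marker_states(ser, small_sim), small_sim


def test_ph_template_hits_the_reported_levels():
    cfg = SimulationConfig()
    # starts around 7.7; R- cells end near 5.8 after the DS
    assert ph_template([0.0], "R_plus", cfg, 40.0)[0] == pytest.approx(7.7)
    assert ph_template([0.0], "R_minus", cfg)[0] == pytest.approx(7.7)
    assert ph_template([14.5], "R_minus", cfg)[0] == pytest.approx(5.8)
    # R+ cells plateau near 6.9 at the DS and peak near 7.2 while respiring
    assert ph_template([5.5], "R_plus", cfg, 40.0)[0] == pytest.approx(6.9)
    t_peak = 13.9 + 0.4 * (31.6 - 13.9)
    assert ph_template([t_peak], "R_plus", cfg, 40.0)[0] == pytest.approx(7.2)
    # terminal crash reaches 5.8 after the drawn SP drop time
    assert ph_template([43.0], "R_plus", cfg, 40.0)[0] == pytest.approx(5.8)


def test_unknown_fate_label_rejected():
    cfg = SimulationConfig()
    with pytest.raises(ValueError, match="fate"):
        ph_template([0.0], "R_question", cfg)


def test_mobility_flips_exactly_at_gel_and_never_reverts(states):
    _, ser, cfg = states
    for _, cell in ser.groupby("cell_id"):
        ph = cell["ph_true"].to_numpy()
        mobile = cell["mobile"].to_numpy()
        gel = ph <= cfg.ph_gel
        if gel.any():
            first = np.argmax(gel)
            assert not mobile[first:].any()
            assert mobile[:first].all()
        else:
            assert mobile.all()


def test_foci_hysteresis_wave_for_threshold_7_marker():
    cfg = SimulationConfig(n_founders=1, divisions_enabled=False,
                           fraction_r_minus=0.0, ph_jitter_sd=0.0,
                           sp_drop_time_distribution=(8.0, 0.0), seed=3)
    lin = simulate_lineage(cfg)
    ser = simulate_marker_states(simulate_ph_trajectories(lin, cfg), cfg)
    cell = ser[ser["cell_id"] == 1].set_index("time")
    t_ds_start, t_ds_end, t_sp_start = cfg.phase_times
    # present during the DS (pH 6.9 <= 7)
    ds = cell[(cell.index > t_ds_start + 0.5) & (cell.index < t_ds_end)]
    assert ds["foci_Dhh1"].all()
    # dissolved around the mid-respiration pH peak (7.2 > 7 + hysteresis)
    mid_r = cell[np.isclose(cell.index, t_ds_end + 0.4 * (t_sp_start - t_ds_end),
                            atol=0.3)]
    assert not mid_r["foci_Dhh1"].any()
    # reappears during the SP crash (drop runs 39.6-41.6 h here)
    assert cell[cell.index > t_sp_start + 10.1]["foci_Dhh1"].all()
    # threshold-6 marker appears only with the crash to the gel point
    assert not cell[cell.index < t_sp_start]["foci_Cdc28"].any()
    assert cell[cell.index > t_sp_start + 10.1]["foci_Cdc28"].all()


def test_mito_states_by_fate(states):
    lin, ser, cfg = states
    t_ds_start, t_ds_end, _ = cfg.phase_times
    fates = dict(zip(lin["cell_id"], lin["fate"]))
    pre = ser[ser["time"] < t_ds_start]
    assert set(pre["mito_state"]) == {"tubular"}
    resp = ser[(ser["time"] > t_ds_end + 1.0)]
    for cid, cell in resp.groupby("cell_id"):
        expected = "fragmented" if fates[cid] == "R_plus" else "globular"
        assert set(cell["mito_state"]) == {expected}


def test_random_walk_step_variance_matches_2d():
    # per-axis squared step expectation is 2*D per frame
    rng = np.random.default_rng(11)
    d = 0.5
    walk = simulate_random_walk(1000, d, rng)
    steps = np.diff(walk, axis=0)
    assert np.mean(steps ** 2) == pytest.approx(2 * d, rel=0.05)


def test_equal_diffusion_produces_no_mobility_collapse():
    from quiescell.foci import MobilityChangepointDetector
    cfg = SimulationConfig(n_founders=4, divisions_enabled=False,
                           ld_diffusion=(0.5, 0.5), seed=13)
    lin = simulate_lineage(cfg)
    ser = simulate_marker_states(simulate_ph_trajectories(lin, cfg), cfg)
    for _, cell in ser.groupby("cell_id"):
        disp = np.linalg.norm(
            np.diff(cell[["ld_x", "ld_y"]].to_numpy(), axis=0), axis=1)
        det = MobilityChangepointDetector().fit(cell["time"].to_numpy()[:-1], disp)
        assert det.t_loss_ is None


def test_ld_walk_slows_at_the_gel_event(states):
    _, ser, _ = states
    cell = next(g for _, g in ser.groupby("cell_id")
                if (~g["mobile"]).any() and g["mobile"].sum() > 8)
    disp = np.linalg.norm(np.diff(cell[["ld_x", "ld_y"]].to_numpy(), axis=0),
                          axis=1)
    mobile = cell["mobile"].to_numpy()[:-1]
    assert disp[mobile].mean() > 5 * disp[~mobile].mean()


def test_placement_overflow_raises():
    cfg = SimulationConfig(n_founders=40, divisions_enabled=False,
                           image_height=64, image_width=64, seed=1)
    lin = simulate_lineage(cfg)
    with pytest.raises(FieldOfViewOverflow):
        place_cells(lin, cfg, np.random.default_rng(0))


def test_cell_positions_do_not_overlap(states):
    lin, ser, cfg = states
    last = ser[ser["frame"] == ser["frame"].max()]
    xy = last[["x", "y"]].to_numpy()
    r = np.sqrt(last["area"].to_numpy() / np.pi)
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            assert np.linalg.norm(xy[i] - xy[j]) >= r[i] + r[j] - 1.0
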