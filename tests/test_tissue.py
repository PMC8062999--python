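"""Morphogen fields, tissue simulations, boundary metrics and protocols."""

import numpy as np
import pytest

from mirswitch.tissue import (
    MorphogenConfig,
    cell_model,
    cell_steady_states,
    default_initial,
    fate_call,
    knockout,
    make_morphogen_field,
    mrna_overlap_band,
    positional_bifurcation,
    ra_pulse_experiment,
    segregation_index,
    simulate_tissue,
    transition_width,
    boundary_position,
)
from mirswitch.tissue.metrics import (
    A5OFF_C8ON,
    A5ON_C8OFF,
    DOUBLE_OFF,
    DOUBLE_ON,
    MMI_S_THRESHOLDS,
    FateThresholds,
)

from conftest import run_tissue


# -- morphogen field --------------------------------------------------------


def test_backbone_deterministic_and_monotone():
    field = make_morphogen_field(MorphogenConfig(noise_sigma=0.0), seed=3)
    for t in (0.0, 10.0, 50.0):
        ra, fgf = field.backbone(t)
        assert np.all(np.diff(ra) < 0)
        assert np.all(np.diff(fgf) > 0)
        ra2, _ = field.backbone(t)
        assert np.array_equal(ra, ra2)


def test_antiparallel_mirror_symmetry():
    field = make_morphogen_field(MorphogenConfig(), seed=0)
    for t in (0.0, 7.5, 40.0, 80.0):
        ra, fgf = field.backbone(t)
        assert ra[0] == pytest.approx(fgf[-1])
        assert np.allclose(ra, fgf[::-1])


def test_noise_variance_matches_prescription():
    """Across cells at fixed (x, t) the stationary variance of the
    perceived signal is sigma^2 times the squared backbone."""
    cfg = MorphogenConfig(noise_sigma=0.2, noise_tau=1.0, n_columns=100)
    field = make_morphogen_field(cfg, seed=5)
    dt = 0.01
    for _ in range(int(8.0 / dt)):  # burn in well past the correlation time
        field.step_noise(dt)
    ra, _ = field.perceived(10.0)
    backbone, _ = field.backbone(10.0)
    rel = ra[:, 0] / backbone[0]
    assert np.std(rel) == pytest.approx(0.2, rel=0.25)
    assert np.all(ra >= 0.0)


def test_zero_sigma_field_is_noise_free():
    cfg = MorphogenConfig(noise_sigma=0.0)
    field = make_morphogen_field(cfg, seed=1)
    field.step_noise(0.01)
    ra, fgf = field.perceived(1.0)
    ra0, fgf0 = field.backbone(1.0)
    assert np.allclose(ra, ra0[None, :]) and np.allclose(fgf, fgf0[None, :])


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        MorphogenConfig(noise_sigma=-0.1)


# -- simulation -------------------------------------------------------------


def test_quiescent_cells_stay_off():
    cfg = MorphogenConfig(amplitude_max=0.0, amplitude_low=0.0, noise_sigma=0.0)
    spec = cell_model("mmi_S")
    field = make_morphogen_field(cfg, seed=0)
    traj = simulate_tissue(spec, field, t_end=10.0, dt=0.01, seed=0)
    call = fate_call(traj.final["Pa"], traj.final["Pc"], MMI_S_THRESHOLDS)
    assert call.count(DOUBLE_OFF) == 400


def test_simulation_reproducible_under_seed():
    a = run_tissue(cell_model("T_UR"), seed=11, t_end=10.0)
    b = run_tissue(cell_model("T_UR"), seed=11, t_end=10.0)
    for s in a.final:
        assert np.array_equal(a.final[s], b.final[s])


def test_wildtype_pattern(wt_trajectory):
    """Rostral Hoxa5 block, caudal Hoxc8 block, no double-positive cell,
    broad total-mRNA overlap around the protein boundary."""
    Pa, Pc = wt_trajectory.final["Pa"], wt_trajectory.final["Pc"]
    call = fate_call(Pa, Pc, MMI_S_THRESHOLDS)
    assert call.count(DOUBLE_ON) == 0
    a5 = call.position_has(A5ON_C8OFF)
    c8 = call.position_has(A5OFF_C8ON)
    assert a5[:10].all() and not a5[25:].any()
    assert c8[25:].all() and not c8[:10].any()

    band = mrna_overlap_band(
        wt_trajectory.final["Ra"], wt_trajectory.final["Rc"], absolute=0.2
    )
    idx = np.where(band)[0]
    assert len(idx) >= 3
    assert np.all(np.diff(idx) == 1)  # contiguous
    b = boundary_position(Pa, Pc, MMI_S_THRESHOLDS)
    assert idx.min() - 2 <= b <= idx.max() + 2


def test_mir27_knockout_derepresses_caudal_hoxa5(mir27ko_trajectory):
    call = fate_call(
        mir27ko_trajectory.final["Pa"], mir27ko_trajectory.final["Pc"], MMI_S_THRESHOLDS
    )
    double_on = call.position_has(DOUBLE_ON)
    assert double_on[30:].all()
    assert call.count(DOUBLE_ON) > 50


def test_mir196_knockout_shifts_boundary_rostrally(wt_trajectory, mir196ko_trajectory):
    b_wt = boundary_position(
        wt_trajectory.final["Pa"], wt_trajectory.final["Pc"], MMI_S_THRESHOLDS
    )
    b_ko = boundary_position(
        mir196ko_trajectory.final["Pa"], mir196ko_trajectory.final["Pc"], MMI_S_THRESHOLDS
    )
    assert b_ko < b_wt - 1.0


def test_knockout_is_idempotent_and_validates():
    spec = cell_model("mmi_S")
    once = knockout(spec, "miR-27")
    twice = knockout(once, "miR-27")
    assert once == twice
    with pytest.raises(KeyError):
        knockout(spec, "miR-9999")
    with pytest.raises(KeyError):
        knockout(cell_model("T_UR"), "miR-27")


def test_unilateral_model_blurrier_than_cross_repression():
    w_cr = transition_width(*_pa_pc(run_tissue(cell_model("T_CR"), seed=2)))
    w_ur = transition_width(*_pa_pc(run_tissue(cell_model("T_UR"), seed=2)))
    assert w_cr < w_ur


def _pa_pc(traj):
    return traj.final["Pa"], traj.final["Pc"]


# -- metrics ----------------------------------------------------------------


def test_transition_width_extremes():
    step = np.zeros((10, 40))
    step[:, :20] = 1.0
    assert transition_width(step, 1.0 - step) == 0
    flat = np.ones((10, 40))
    assert transition_width(flat, flat) == 40


def test_segregation_index_identity_and_flat():
    prof = np.exp(-np.arange(40) / 8.0)
    assert segregation_index(prof, prof) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        segregation_index(np.ones(40), prof)


def test_segregation_index_protein_sharper_in_titration_model():
    traj = run_tissue(cell_model("mmi_S"), seed=0, cfg=MorphogenConfig(noise_sigma=0.0))
    idx = segregation_index(
        traj.final["Ra"].mean(axis=0), traj.final["Pa"].mean(axis=0)
    )
    assert idx > 1.0


def test_segregation_index_near_one_without_posttranscriptional_layer():
    traj = run_tissue(cell_model("T_CR"), seed=0, cfg=MorphogenConfig(noise_sigma=0.0))
    idx = segregation_index(
        traj.final["Ra"].mean(axis=0), traj.final["Pa"].mean(axis=0)
    )
    assert idx == pytest.approx(1.0, abs=0.2)


# -- protocols --------------------------------------------------------------


def test_positional_bifurcation_tristable_window():
    pb = positional_bifurcation(
        cell_model("mmi_S"),
        make_morphogen_field(MorphogenConfig(), 0),
        thresholds=MMI_S_THRESHOLDS,
    )
    window = np.where(pb.tristable_window())[0]
    assert len(window) >= 3
    assert np.all(np.diff(window) == 1)
    assert 10 < window.mean() < 32  # a mid-domain band


def test_positional_bifurcation_mir27ko_gains_hybrid_state():
    spec = knockout(cell_model("mmi_S"), "miR-27")
    pb = positional_bifurcation(
        spec, make_morphogen_field(MorphogenConfig(), 0), thresholds=MMI_S_THRESHOLDS
    )
    caudal = range(30, 40)
    assert all(DOUBLE_ON in pb.labels_at(i) for i in caudal)
    assert all(A5OFF_C8ON not in pb.labels_at(i) for i in caudal)


def test_positional_bifurcation_unilateral_model_monostable():
    pb = positional_bifurcation(
        cell_model("T_UR"), make_morphogen_field(MorphogenConfig(), 0)
    )
    assert all(pb.n_stable(i) == 1 for i in range(40))


def test_ra_pulse_hysteresis_requires_mir27():
    spec = cell_model("mmi_S")
    wt = ra_pulse_experiment(spec)
    ko = ra_pulse_experiment(spec, mir27_active=False)
    # memory with the miRNA arm intact
    assert wt.persistent and wt.above_threshold
    assert wt.bistable_window is not None
    lo, hi = wt.bistable_window
    assert lo <= 0.005 <= hi
    # reversible tracking without it
    assert not ko.persistent
    assert not ko.above_threshold
    assert ko.bistable_window is None
    # never-pulsed cells stay low in both genotypes
    assert wt.pa_unpulsed < wt.on_threshold
    assert ko.pa_unpulsed < ko.on_threshold


def test_ra_pulse_rejects_bad_levels():
    with pytest.raises(ValueError):
        ra_pulse_experiment(cell_model("mmi_S"), ra_high=0.1, ra_low=0.2)
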