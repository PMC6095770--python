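"""Monodomain solver: operator structure, conservation, stability guard,
quiescence, conduction-velocity physics on the slab fixture."""

import numpy as np
import pytest

from hearts import solver as so
from hearts.errors import (ConfigurationError, ConsistencyError,
                           ParameterError, StabilityError)
from hearts.slab import make_slab, measure_cv, planar_stimulus
from hearts.stimuli import StimulusBox, StimulusConfiguration


def _slab_operator(size=(10, 5, 5), h=1.0, sigma_l=0.4, sigma_t=0.1,
                   fiber=(1, 0, 0)):
    geom, fibers = make_slab(size, h, fiber)
    params = so.SolverParams(sigma_l=sigma_l, sigma_t=sigma_t)
    return geom, fibers, so.build_diffusion_operator(geom, fibers, params)


def test_constant_field_annihilated():
    _, _, op = _slab_operator()
    out = op.apply(np.full(op.n_tissue, 3.7))
    assert np.abs(out).max() < 1e-12


def test_operator_conserves_total_charge():
    rng = np.random.default_rng(0)
    _, _, op = _slab_operator(fiber=(0.6, 0.64, 0.48))
    vm = rng.normal(size=op.n_tissue)
    out = op.apply(vm)
    assert abs(out.sum()) < 1e-10 * np.abs(out).sum()


def test_isotropic_interior_stencil_is_seven_point_laplacian():
    """With sigma_l = sigma_t the interior stencil reduces to sigma/h^2
    times the 7-point Laplacian."""
    h, sigma = 2.0, 0.3
    geom, fibers, op = _slab_operator(size=(10, 10, 10), h=h,
                                      sigma_l=sigma, sigma_t=sigma)
    center = np.array(geom.shape) // 2
    cid = op.tissue_id[tuple(center)]
    vm = np.zeros(op.n_tissue)
    vm[cid] = 1.0
    out = op.apply(vm)
    assert out[cid] == pytest.approx(-6.0 * sigma / h ** 2)
    for nb in op.neighbors[cid]:
        assert out[nb] == pytest.approx(sigma / h ** 2)


def test_single_isolated_voxel_zero_operator():
    _, _, op = _slab_operator(size=(1, 1, 1), h=1.0)
    assert op.n_tissue == 1
    assert op.apply(np.array([5.0]))[0] == 0.0


def test_conductivity_tensor_eigenstructure():
    f = np.array([0.48, 0.6, 0.64])
    geom, fibers = make_slab((4, 4, 4), 1.0, tuple(f))
    cond = so.build_conductivity(
        fibers, np.argwhere(geom.tissue_mask).astype(np.int32), 0.9, 0.2)
    D = cond.tensor(0)
    assert np.allclose(D, D.T)
    assert np.allclose(D @ f, 0.9 * f)
    w = np.linalg.eigvalsh(D)
    assert np.allclose(sorted(w), [0.2, 0.2, 0.9])


def test_missing_fiber_raises_consistency_error():
    geom, fibers = make_slab((6, 3, 3), 1.0)
    fibers.vectors[2, 1, 1] = np.nan
    with pytest.raises(ConsistencyError):
        so.build_diffusion_operator(geom, fibers, so.SolverParams())


def test_unstable_dt_rejected():
    geom, fibers = make_slab((6, 3, 3), 0.25)
    params = so.SolverParams(dt_ms=0.02, sigma_l=3.0, sigma_t=1.0)
    with pytest.raises(StabilityError):
        so.run_simulation(geom, fibers, None, params)


def test_stimulus_box_outside_tissue_rejected():
    geom, fibers = make_slab((10, 5, 5), 1.0)
    box = StimulusBox(center_mm=(100.0, 100.0, 100.0), tag="lost")
    cfg = StimulusConfiguration(name="bad", boxes=[box])
    with pytest.raises(ConfigurationError):
        so.run_simulation(geom, fibers, cfg,
                          so.SolverParams(duration_ms=1.0))


def test_quiescence_without_stimuli():
    """No stimulus: every voxel stays within 0.5 mV of rest for 500 ms."""
    geom, fibers = make_slab((20, 5, 5), 2.5)
    res = so.run_simulation(geom, fibers, None,
                            so.SolverParams(duration_ms=500.0))
    drift = np.abs(res.vm_mv - res.vm_mv[0]).max()
    assert drift < 0.5
    assert np.isnan(res.activation_flat()).all()


def test_diffusion_only_conserves_mean():
    """Diffusion-only mode conserves the spatial mean of Vm to 1e-8
    relative per step (no-flux conservation)."""
    geom, fibers = make_slab((10, 4, 4), 1.0, (0.6, 0.64, 0.48))
    rng = np.random.default_rng(1)
    init = rng.uniform(-90.0, 20.0, geom.tissue_mask.sum())
    params = so.SolverParams(duration_ms=5.0, diffusion_only=True,
                             snapshot_interval_ms=1.0,
                             stop_after_activation_ms=None)
    res = so.run_simulation(geom, fibers, None, params, initial_vm=init)
    means = res.vm_mv.astype(np.float64).mean(axis=1)
    n_steps = params.duration_ms / params.dt_ms
    assert np.abs(means - means[0]).max() / abs(means[0]) < 1e-8 * n_steps


def test_snapshot_times_strictly_increasing():
    geom, fibers = make_slab((10, 4, 4), 2.0)
    res = so.run_simulation(geom, fibers, planar_stimulus(geom),
                            so.SolverParams(duration_ms=30.0))
    assert np.all(np.diff(res.time_ms) > 0)


def test_deterministic_simulation():
    geom, fibers = make_slab((15, 4, 4), 2.0)
    cfg = planar_stimulus(geom)
    params = so.SolverParams(duration_ms=30.0)
    a = so.run_simulation(geom, fibers, cfg, params)
    b = so.run_simulation(geom, fibers, cfg, params)
    assert np.array_equal(a.vm_mv, b.vm_mv)
    assert np.array_equal(a.activation_time_ms, b.activation_time_ms,
                          equal_nan=True)


# --- conduction-velocity physics (slab oracle) ---

# sigma chosen well above the calibration values so the depolarization
# wavelength is long relative to both grid spacings under comparison
_SIGMA_L, _SIGMA_T = 1.0, 0.25


def test_cv_matches_refined_grid():
    """Along-fiber CV at 0.5 mm agrees with the same solver at 4x finer
    spacing within 10%."""
    cv_coarse = measure_cv(0.5, _SIGMA_L, _SIGMA_T, length_mm=20.0,
                           width_mm=2.0, duration_ms=40.0)
    cv_fine = measure_cv(0.125, _SIGMA_L, _SIGMA_T, length_mm=20.0,
                         width_mm=2.0, duration_ms=40.0, dt_ms=0.007)
    assert cv_coarse == pytest.approx(cv_fine, rel=0.10)


def test_cv_anisotropy_follows_sqrt_sigma_ratio():
    """CV_long / CV_trans = sqrt(sigma_l / sigma_t) within 15% on a
    well-resolved slab."""
    cv_l = measure_cv(0.25, _SIGMA_L, _SIGMA_T, length_mm=20.0,
                      width_mm=2.0, duration_ms=40.0)
    cv_t = measure_cv(0.25, _SIGMA_L, _SIGMA_T, along_fiber=False,
                      length_mm=20.0, width_mm=2.0, duration_ms=80.0)
    expected = np.sqrt(_SIGMA_L / _SIGMA_T)
    assert cv_l / cv_t == pytest.approx(expected, rel=0.15)


def test_doubling_sigma_scales_cv_by_sqrt2():
    cv1 = measure_cv(0.25, 0.5, 0.125, length_mm=20.0, width_mm=2.0,
                     duration_ms=60.0)
    cv2 = measure_cv(0.25, 1.0, 0.25, length_mm=20.0, width_mm=2.0,
                     duration_ms=40.0)
    assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.10)


def test_full_heart_activates_within_250_ms(beat_runner):
    """Default 4-seed beat: every tissue voxel activates within 250 ms."""
    res, _ = beat_runner("4")
    at = res.activation_flat()
    assert np.isfinite(at).all()
    assert np.nanmax(at) < 250.0
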