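"""Idealized anatomy: label topology, volume convergence, fibers, IARs,
electrodes."""

import numpy as np
import pytest

from hearts import geometry as geo
from hearts.errors import ParameterError, ResolutionError


def test_default_labels_all_present(heart):
    present = set(np.unique(heart.label_volume))
    assert present == set(range(6))


def test_cavities_enclosed_in_every_axial_slice(heart):
    assert geo.cavities_enclosed(heart)


def test_lv_wall_thicker_than_rv_wall(heart):
    t_lv, t_rv = geo.mean_wall_thickness_mm(heart)
    assert t_lv > t_rv


def test_geometry_deterministic():
    p = geo.GeometryParams(spacing_mm=4.0, rv_wall_thickness_mm=8.0)
    a = geo.build_ventricles(p)
    b = geo.build_ventricles(p)
    assert np.array_equal(a.label_volume, b.label_volume)


def test_zero_wall_thickness_rejected():
    with pytest.raises(ParameterError):
        geo.build_ventricles(geo.GeometryParams(lv_wall_thickness_mm=0.0))


def test_too_coarse_spacing_rejected():
    # spacing must resolve the thinnest (RV) wall at two voxels
    with pytest.raises(ResolutionError):
        geo.build_ventricles(geo.GeometryParams(spacing_mm=4.0))


def test_tissue_volume_agrees_across_spacings(heart):
    """Voxel-counted tissue volume at 2.5 mm and 1 mm agree within 5%
    (both approximate the same continuum shell volume)."""
    fine = geo.build_ventricles(geo.GeometryParams(spacing_mm=1.0))
    rel = abs(heart.tissue_volume_mm3 - fine.tissue_volume_mm3) \
        / fine.tissue_volume_mm3
    assert rel < 0.05


def test_volume_converges_with_refinement():
    """Voxelization volume converges over spacings 4, 2, 1 mm: the
    discretization uncertainty (boundary-shell volume, the O(h) term of
    voxel-center quadrature) shrinks monotonically, and the deviation from a
    fine-grid reference stays within it.  (The signed volume error itself
    oscillates around zero by error cancellation, so the bound, not the
    error, is the monotone quantity.)"""
    from scipy import ndimage
    kw = dict(rv_wall_thickness_mm=8.0)
    ref = geo.build_ventricles(
        geo.GeometryParams(spacing_mm=0.5, **kw)).tissue_volume_mm3
    bounds, errs = [], []
    for h in (4.0, 2.0, 1.0):
        g = geo.build_ventricles(geo.GeometryParams(spacing_mm=h, **kw))
        tissue = g.tissue_mask
        boundary = tissue & ~ndimage.binary_erosion(tissue)
        bounds.append(boundary.sum() * h ** 3)
        errs.append(abs(g.tissue_volume_mm3 - ref))
    assert bounds[0] > bounds[1] > bounds[2]
    assert all(e < b for e, b in zip(errs, bounds))


# --- fibers ---

def test_fiber_vectors_unit_norm_on_tissue(heart, fibers):
    v = fibers.vectors[heart.tissue_mask]
    norms = np.linalg.norm(v, axis=1)
    assert np.all(np.abs(norms - 1.0) < 1e-6)


def test_fibers_undefined_outside_tissue(heart, fibers):
    assert np.isnan(fibers.vectors[~heart.tissue_mask]).all()


def test_helix_angle_linear_in_transmural_depth(heart, fibers):
    """At mid-depth the helix angle is the mean of the endo/epi angles."""
    depth = fibers.transmural_depth
    mid = heart.tissue_mask & (np.abs(depth - 0.5) < 0.05)
    assert mid.any()
    expected = 0.5 * (fibers.alpha_endo_deg + fibers.alpha_epi_deg)
    assert np.nanmean(np.abs(fibers.helix_angle_deg[mid] - expected)) < 5.0


def test_helix_angle_spans_endo_to_epi(heart, fibers):
    """Innermost vs outermost depth deciles have strongly opposite helix
    angles (voxel centers never reach depth 0/1 exactly on a coarse grid)."""
    depth = fibers.transmural_depth[heart.tissue_mask]
    angle = fibers.helix_angle_deg[heart.tissue_mask]
    lo, hi = np.nanpercentile(depth, [10, 90])
    assert np.nanmean(angle[depth <= lo]) > 30.0
    assert np.nanmean(angle[depth >= hi]) < -30.0


def test_fiber_angles_out_of_range_rejected(heart):
    with pytest.raises(ParameterError):
        geo.assign_fibers(heart, alpha_endo_deg=120.0)


# --- IARs ---

def test_four_nonempty_named_iars(iars):
    assert set(iars.masks) == {"S", "LASW", "LPIW", "RAIW"}
    assert all(iars.mask(n).any() for n in iars)


def test_iars_pairwise_disjoint(iars):
    names = list(iars)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert not (iars.mask(a) & iars.mask(b)).any()


def test_iars_in_host_walls(heart, iars):
    lbl = heart.label_volume
    hosts = {"S": geo.SEPTUM, "LASW": geo.LV_WALL, "LPIW": geo.LV_WALL,
             "RAIW": geo.RV_WALL}
    for name, code in hosts.items():
        assert np.all(lbl[iars.mask(name)] == code), name


def test_iars_subendocardial(heart, iars):
    d_lv = heart.distance_to("LV_cavity")
    d_rv = heart.distance_to("RV_cavity")
    sub = heart.subendo_depth_mm
    for name in iars:
        d = d_rv if name == "RAIW" else d_lv
        assert np.all(d[iars.mask(name)] <= sub), name


def test_lpiw_centroid_one_third_apex_to_base(heart, iars):
    pos = heart.world_coords(np.argwhere(iars.mask("LPIW")))
    frac = pos[:, 2].mean() / heart.params.long_axis_mm
    assert abs(frac - 1.0 / 3.0) < 0.1


def test_iar_masks_deterministic(heart):
    a = geo.define_iars(heart)
    b = geo.define_iars(heart)
    for name in a:
        assert np.array_equal(a.mask(name), b.mask(name))


# --- electrodes ---

def test_electrodes_distinct_and_outside_tissue(heart, electrodes):
    pos = [electrodes[k] for k in ("LA", "RA", "LL")]
    lo, hi = heart.tissue_bounding_box_mm()
    for p in pos:
        assert np.any((p < lo) | (p > hi))
    assert len({tuple(p) for p in pos}) == 3


def test_la_ra_symmetric_about_heart_centroid(heart, electrodes):
    c = heart.centroid_mm()
    d_la = np.linalg.norm(electrodes["LA"] - c)
    d_ra = np.linalg.norm(electrodes["RA"] - c)
    assert d_la == pytest.approx(d_ra, rel=1e-9)


def test_electrodes_in_frontal_plane(heart, electrodes):
    c = heart.centroid_mm()
    for k in ("LA", "RA", "LL"):
        assert electrodes[k][1] == pytest.approx(c[1])


def test_small_torso_scale_rejected(heart):
    with pytest.raises(ParameterError):
        geo.place_electrodes(heart, torso_scale_mm=0.0)
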