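"""Stimulus-protocol combinatorics: seed/dense/sparse/BBB configurations."""

import numpy as np
import pytest

from hearts import geometry as geo
from hearts import stimuli as st
from hearts.errors import ConfigurationError, ParameterError


def _centers(cfg, tag=None):
    return np.array([b.center_mm for b in cfg.boxes
                     if tag is None or b.tag == tag])


def test_seed_configurations_cumulative(iars):
    configs = st.seed_configurations(iars)
    assert [c.total for c in configs] == [1, 2, 3, 4]
    assert [c.name for c in configs] == [
        "S", "S/LASW", "S/LASW/LPIW", "S/LASW/LPIW/RAIW"]
    for prev, cur in zip(configs, configs[1:]):
        prev_set = {b.center_mm for b in prev.boxes}
        cur_set = {b.center_mm for b in cur.boxes}
        assert prev_set <= cur_set


def test_seed_onsets_rv_delayed(iars):
    full = st.seed_configurations(iars)[-1]
    for b in full.boxes:
        assert b.onset_ms == (5.0 if b.tag == "RAIW" else 0.0)


def test_all_boxes_eight_cubic_mm(iars):
    for level in range(1, 9):
        cfg = st.dense_configuration(level, iars)
        assert all(b.volume_mm3 == pytest.approx(8.0) for b in cfg.boxes)


def test_dense_level_totals(iars):
    totals = [st.dense_configuration(lv, iars).total for lv in range(1, 9)]
    assert totals == [4, 12, 20, 28, 84, 140, 196, 384]


def test_dense_level4_is_seven_collinear_per_iar(iars):
    """28-stimulus level: per IAR, 7 boxes nested along the apico-basal line
    (collinearity is approximate after snapping onto the curved wall)."""
    cfg = st.dense_configuration(4, iars)
    counts = cfg.counts_by_tag()
    assert counts == {n: 7 for n in geo.IAR_NAMES}
    for name in geo.IAR_NAMES:
        pts = _centers(cfg, name)
        # principal axis explains most of the variance of the line pattern
        c = pts - pts.mean(axis=0)
        svals = np.linalg.svd(c, compute_uv=False)
        assert svals[0] ** 2 / (svals ** 2).sum() > 0.9


def test_dense_levels_nested(iars):
    prev = set()
    for lv in range(1, 9):
        cur = {b.center_mm for b in st.dense_configuration(lv, iars).boxes}
        assert prev <= cur
        prev = cur


def test_sparse_counts(iars):
    assert st.sparse_configuration(4, iars).total == 12     # "28S"
    assert st.sparse_configuration(8, iars).total == 36     # "384S"
    names = [st.sparse_configuration(lv, iars).name for lv in (4, 8)]
    assert names == ["28S", "384S"]


def test_sparse_level2_identical_to_dense(iars):
    dense = st.dense_configuration(2, iars)
    sparse = st.sparse_configuration(2, iars)
    assert sorted(b.center_mm for b in dense.boxes) == \
        sorted(b.center_mm for b in sparse.boxes)


def test_sparse_not_larger_and_same_bounding_box(iars):
    """Sparse keeps each dense level's per-IAR bounding extremes (surface
    layer) with at most as many boxes."""
    for lv in range(2, 9):
        dense = st.dense_configuration(lv, iars)
        sparse = st.sparse_configuration(lv, iars)
        assert sparse.total <= dense.total
        for name in geo.IAR_NAMES:
            dc = np.array([b.center_mm for b in dense.boxes
                           if b.tag == name][:49 if lv == 8 else None])
            sc = _centers(sparse, name)
            assert np.allclose(dc.min(axis=0), sc.min(axis=0))
            assert np.allclose(dc.max(axis=0), sc.max(axis=0))


def test_sparse_28s_interstimulus_spacing(iars):
    """28S adjacent spacing: <= 7 mm in the wall IARs, <= 16 mm apico-basal
    in the septum."""
    cfg = st.sparse_configuration(4, iars)
    for name in geo.IAR_NAMES:
        pts = _centers(cfg, name)
        pts = pts[np.argsort(pts[:, 2])]
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        limit = 16.0 if name == "S" else 7.0
        assert np.all(gaps <= limit + 1.01 * np.sqrt(3) *
                      iars.geometry.spacing_mm), (name, gaps)


def test_box_centers_on_their_iars(heart, iars):
    """Surface-layer box centers lie in their IAR masks; transmural copies
    lie deeper in the same host wall."""
    cfg = st.dense_configuration(8, iars)
    for b in cfg.boxes:
        ijk = tuple(np.floor((np.array(b.center_mm) - heart.origin_mm)
                             / heart.spacing_mm).astype(int))
        in_mask = iars.mask(b.tag)[ijk]
        in_host = heart.label_volume[ijk] == iars.host_labels[b.tag]
        assert in_mask or in_host, b.tag


def test_regeneration_deterministic(iars):
    a = st.dense_configuration(6, iars)
    b = st.dense_configuration(6, iars)
    assert [x.center_mm for x in a.boxes] == [x.center_mm for x in b.boxes]


def test_rbbb_seven_boxes_none_in_rv(heart, iars):
    cfg = st.bbb_configuration("right", iars)
    assert cfg.total == 7
    assert all(b.tag != "RAIW" for b in cfg.boxes)
    for b in cfg.boxes:
        ijk = tuple(np.floor((np.array(b.center_mm) - heart.origin_mm)
                             / heart.spacing_mm).astype(int))
        assert heart.label_volume[ijk] != geo.RV_WALL


def test_lbbb_no_lv_boxes(heart, iars):
    cfg = st.bbb_configuration("left", iars)
    assert all(b.tag in ("RAIW", "S") for b in cfg.boxes)
    assert sum(b.tag == "RAIW" for b in cfg.boxes) == 3
    # the only septal box is the repositioned basal one
    assert sum(b.tag == "S" for b in cfg.boxes) == 1


def test_bbb_basal_septal_box_repositioned_toward_base(iars):
    cfg = st.bbb_configuration("right", iars)
    septal = [b for b in cfg.boxes if b.tag == "S"]
    assert len(septal) == 1
    base12 = st.sparse_configuration(2, iars)
    z_top_12s = max(b.center_mm[2] for b in base12.boxes if b.tag == "S")
    assert septal[0].center_mm[2] > z_top_12s


def test_invalid_bbb_side_rejected(iars):
    with pytest.raises(ParameterError):
        st.bbb_configuration("anterior", iars)


def test_invalid_level_rejected(iars):
    with pytest.raises(ParameterError):
        st.dense_configuration(9, iars)


def test_unknown_configuration_name_rejected(iars):
    with pytest.raises(ConfigurationError):
        st.configuration_by_name("nonsense", iars)


def test_configuration_by_name_resolves_all_sweep_names(iars):
    for name in st.SWEEP_NAMES:
        cfg = st.configuration_by_name(name, iars)
        assert cfg.total == (int(name) if name.isdigit() else cfg.total)


def test_invalid_box_parameters_rejected():
    with pytest.raises(ParameterError):
        st.StimulusBox(center_mm=(0, 0, 0), amplitude=-1.0)
    with pytest.raises(ParameterError):
        st.StimulusBox(center_mm=(0, 0, 0), onset_ms=1500.0)
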