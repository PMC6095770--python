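"""Stimulus configurations modeling Purkinje-myocardial junctions.

Each PMJ is an 8 mm^3 current-injection box (72 uA/uF, 1 ms pulse, 1000 ms
period); boxes in the right-ventricular wall fire 5 ms after the others, per
the experimentally observed right-sided delay.  Configurations:

* seed configurations -- cumulative single stimuli per IAR, added in the
  order S, S/LASW, S/LASW/LPIW, S/LASW/LPIW/RAIW (totals 1..4);
* dense configurations -- regional stimuli layered around every seed, first
  apico-basally, then laterally, finally one transmural layer, with level
  totals 4, 12, 20, 28, 84, 140, 196, 384;
* sparse configurations ("<total>S") -- same per-IAR topographical extent as
  the dense level but keeping only the seed and the peripheral extremes;
* RBBB / LBBB -- derived from the 12-stimulus sparse configuration by
  removing one ventricle's stimuli and repositioning the basal septal
  stimulus toward the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError, PlacementError
from .geometry import IAR_NAMES, IARMap, RV_WALL

#: Pulse parameters shared by every stimulus.
STIM_EDGE_MM = 2.0
STIM_AMPLITUDE = 72.0      # uA/uF
STIM_DURATION_MS = 1.0
STIM_PERIOD_MS = 1000.0
RV_ONSET_DELAY_MS = 5.0

#: Peripheral (sparse) inter-stimulus spacing, mm.  The septal apico-basal
#: value is the 1.6 cm of the study protocol; the septal anterior-posterior
#: spacing is not printed anywhere and is set to half of it so the pattern
#: stays on the septum.
SPARSE_SPACING_WALL_MM = 7.0
SPARSE_SPACING_SEPTUM_AB_MM = 16.0
SPARSE_SPACING_SEPTUM_AP_MM = 8.0
#: Dense spacing is one third of the sparse spacing, so that sparse extremes
#: coincide with dense extremes (3 dense steps per sparse step).
DENSE_SUBDIVISION = 3

DENSE_LEVEL_TOTALS = (4, 12, 20, 28, 84, 140, 196, 384)
#: per-IAR box counts by dense level
DENSE_LEVEL_PER_IAR = (1, 3, 5, 7, 21, 35, 49, 96)


@dataclass(frozen=True)
class StimulusBox:
    """One PMJ model stimulus: an 8 mm^3 box of injected current."""

    center_mm: tuple[float, float, float]
    edge_lengths_mm: tuple[float, float, float] = (STIM_EDGE_MM,) * 3
    amplitude: float = STIM_AMPLITUDE          # uA/uF, positive depolarizes
    duration_ms: float = STIM_DURATION_MS
    period_ms: float = STIM_PERIOD_MS
    onset_ms: float = 0.0
    tag: str = ""                              # IAR the box belongs to

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ParameterError("stimulus amplitude must be positive")
        if not 0 <= self.onset_ms < self.period_ms:
            raise ParameterError("onset must lie in [0, period)")

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.edge_lengths_mm))


@dataclass
class StimulusConfiguration:
    """A named, ordered set of stimulus boxes."""

    name: str
    boxes: list[StimulusBox] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.boxes)

    def counts_by_tag(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.boxes:
            out[b.tag] = out.get(b.tag, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total": self.total,
            "boxes": [{
                "center_mm": list(b.center_mm),
                "edge_lengths_mm": list(b.edge_lengths_mm),
                "amplitude_uA_per_uF": b.amplitude,
                "duration_ms": b.duration_ms,
                "period_ms": b.period_ms,
                "onset_ms": b.onset_ms,
                "iar": b.tag,
            } for b in self.boxes],
        }


def _check_iars(iars: IARMap) -> None:
    for name in IAR_NAMES:
        if name not in iars.masks or not iars.masks[name].any():
            raise ConfigurationError(f"IAR {name} missing or empty")


def _spacing_for(name: str) -> tuple[float, float]:
    """(apico-basal, lateral) sparse spacing for an IAR."""
    if name == "S":
        return SPARSE_SPACING_SEPTUM_AB_MM, SPARSE_SPACING_SEPTUM_AP_MM
    return SPARSE_SPACING_WALL_MM, SPARSE_SPACING_WALL_MM


def _onset_for(iars: IARMap, name: str) -> float:
    return RV_ONSET_DELAY_MS if iars.host_labels[name] == RV_WALL else 0.0


#: a nominal (straight-line) stimulus position farther than this from any
#: admissible host-wall voxel is considered to have left the wall
SNAP_TOLERANCE_MM = 8.0


def _host_positions(iars: IARMap, name: str, transmural: bool) -> np.ndarray:
    """Voxel-center positions (mm) a stimulus in this IAR may snap to:
    the host wall's subendocardial layer, or -- for transmural-layer copies
    -- the deeper host-wall voxels."""
    key = (name, transmural)
    cache = getattr(iars, "_snap_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(iars, "_snap_cache", cache)
    if key not in cache:
        geom = iars.geometry
        if transmural:
            mask = ((geom.label_volume == iars.host_labels[name])
                    & ~iars.host_subendo[name])
        else:
            mask = iars.host_subendo[name]
        idx = np.argwhere(mask)
        cache[key] = geom.world_coords(idx) if idx.size else np.zeros((0, 3))
    return cache[key]


def _box_at(iars: IARMap, name: str, offset_steps: tuple[int, int, int],
            dense: bool) -> StimulusBox:
    """Place a box at integer (apico-basal, lateral, transmural) steps from
    the IAR seed, following the curved wall: the straight-line position in
    the seed's wall frame is snapped to the nearest admissible host-wall
    voxel center."""
    a_hat, c_hat, n_hat = iars.frames[name]
    d_ab, d_lat = _spacing_for(name)
    if dense:
        d_ab, d_lat = d_ab / DENSE_SUBDIVISION, d_lat / DENSE_SUBDIVISION
    d_tm = SPARSE_SPACING_WALL_MM / DENSE_SUBDIVISION
    i_ab, i_lat, i_tm = offset_steps
    nominal = (iars.seed_positions_mm[name]
               + i_ab * d_ab * a_hat + i_lat * d_lat * c_hat
               + i_tm * d_tm * n_hat)
    cand = _host_positions(iars, name, transmural=i_tm != 0)
    if len(cand) == 0:
        raise PlacementError(
            f"no admissible voxels for a transmural stimulus in {name}")
    d2 = ((cand - nominal) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    if d2[k] > SNAP_TOLERANCE_MM ** 2:
        raise PlacementError(
            f"stimulus at steps {offset_steps} exits the {name} host wall "
            f"(nearest wall voxel {np.sqrt(d2[k]):.1f} mm away)")
    pos = cand[k]
    return StimulusBox(center_mm=tuple(float(x) for x in pos),
                       onset_ms=_onset_for(iars, name), tag=name)


def _dense_offsets(level: int) -> list[tuple[int, int, int]]:
    """Integer (apico-basal, lateral, transmural) steps for one IAR at a
    dense level, in a deterministic order (seed first, then by distance)."""
    if level == 1:
        return [(0, 0, 0)]
    if level <= 4:
        half = level - 1            # 1, 2, 3  ->  3, 5, 7 boxes
        lat = [0]
    else:
        half = 3
        lat_half = min(level - 4, 3)  # 1, 2, 3 -> 21, 35, 49 boxes
        lat = list(range(-lat_half, lat_half + 1))
    offs = [(a, l, 0) for a in range(-half, half + 1) for l in lat]
    offs.sort(key=lambda o: (abs(o[0]) + abs(o[1]), o))
    if level == 8:
        surface = [(a, l, 0) for a in range(-3, 4) for l in range(-3, 4)]
        surface.sort(key=lambda o: (abs(o[0]) + abs(o[1]), o))
        offs = surface + [(a, l, 1) for (a, l, _) in surface]
    return offs


def seed_configurations(iars: IARMap) -> list[StimulusConfiguration]:
    """The four cumulative seed configurations: S, S/LASW, S/LASW/LPIW,
    S/LASW/LPIW/RAIW (totals 1, 2, 3, 4)."""
    _check_iars(iars)
    configs = []
    boxes: list[StimulusBox] = []
    for k, name in enumerate(IAR_NAMES):
        boxes = boxes + [_box_at(iars, name, (0, 0, 0), dense=True)]
        configs.append(StimulusConfiguration(
            name="/".join(IAR_NAMES[:k + 1]), boxes=list(boxes)))
    return configs


def _transmural_prune(iars: IARMap, name: str,
                      candidates: list[tuple[int, int, int]],
                      keep: int) -> list[tuple[int, int, int]]:
    """Keep ``keep`` transmural copies: drop those whose center exits tissue,
    then the ones farthest from the seed (deterministic order)."""
    in_tissue = []
    for o in candidates:
        try:
            _box_at(iars, name, o, dense=True)
            in_tissue.append(o)
        except PlacementError:
            continue
    if len(in_tissue) < keep:
        raise PlacementError(
            f"only {len(in_tissue)} transmural stimuli fit in {name}; "
            f"need {keep}")
    in_tissue.sort(key=lambda o: (abs(o[0]) + abs(o[1]), o))
    return in_tissue[:keep]


def dense_configuration(level: int, iars: IARMap) -> StimulusConfiguration:
    """Dense regional configuration at ``level`` in 1..8 (totals 4, 12, 20,
    28, 84, 140, 196, 384).  Levels 2-4 extend apico-basally, 5-7 laterally,
    level 8 adds one transmural layer.  Each level is a superset of the
    previous one."""
    if level not in range(1, 9):
        raise ParameterError(f"dense level must be in 1..8, got {level}")
    _check_iars(iars)
    boxes: list[StimulusBox] = []
    for name in IAR_NAMES:
        offs = _dense_offsets(level)
        if level == 8:
            surface = [o for o in offs if o[2] == 0]
            trans = [o for o in offs if o[2] == 1]
            keep = DENSE_LEVEL_PER_IAR[7] - len(surface)
            offs = surface + _transmural_prune(iars, name, trans, keep)
        for o in offs:
            boxes.append(_box_at(iars, name, o, dense=True))
    cfg = StimulusConfiguration(name=str(DENSE_LEVEL_TOTALS[level - 1]),
                                boxes=boxes)
    expected = DENSE_LEVEL_TOTALS[level - 1]
    if cfg.total != expected:
        raise ConfigurationError(
            f"dense level {level} produced {cfg.total} stimuli, expected "
            f"{expected}")
    return cfg


def _sparse_offsets(level: int) -> list[tuple[int, int, int]]:
    """Sparse pattern per IAR: same bounding extremes as the dense level but
    only seed + peripheral stimuli (line ends for levels 2-4, the 3x3
    corner/edge-midpoint/seed subsample for levels 5-8)."""
    if level == 1:
        return [(0, 0, 0)]
    if level == 2:
        # identical to dense level 2 (the extremes are the whole line)
        return [(0, 0, 0), (-1, 0, 0), (1, 0, 0)]
    if level <= 4:
        half = level - 1
        return [(0, 0, 0), (-half, 0, 0), (half, 0, 0)]
    lat_half = min(level - 4, 3)
    offs = [(a, l, 0) for a in (-3, 0, 3) for l in (-lat_half, 0, lat_half)]
    offs.sort(key=lambda o: (abs(o[0]) + abs(o[1]), o))
    return offs


def sparse_configuration(level: int, iars: IARMap) -> StimulusConfiguration:
    """Sparse counterpart ("NS") of a dense level: per-IAR bounding extent is
    preserved while interior stimuli are dropped."""
    if level not in range(1, 9):
        raise ParameterError(f"sparse level must be in 1..8, got {level}")
    _check_iars(iars)
    boxes = [_box_at(iars, name, o, dense=True)
             for name in IAR_NAMES for o in _sparse_offsets(level)]
    return StimulusConfiguration(
        name=f"{DENSE_LEVEL_TOTALS[level - 1]}S", boxes=boxes)


def bbb_configuration(side: str, iars: IARMap) -> StimulusConfiguration:
    """Bundle-branch-block configuration derived from the 12-stimulus sparse
    configuration: ``side='right'`` (RBBB) removes the right-ventricular
    stimuli, ``side='left'`` (LBBB) the left-ventricular ones; in both, a
    single septal stimulus repositioned toward the base emulates the
    physiological delay distal to the blocked bundle."""
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    _check_iars(iars)
    base = sparse_configuration(2, iars)
    if side == "right":
        kept = [b for b in base.boxes if b.tag in ("LASW", "LPIW")]
    else:
        kept = [b for b in base.boxes if b.tag == "RAIW"]
    # basal septal stimulus, moved one sparse septal step toward the base
    septal = _box_at(iars, "S", (DENSE_SUBDIVISION, 0, 0), dense=True)
    cfg = StimulusConfiguration(name="RBBB" if side == "right" else "LBBB",
                                boxes=kept + [septal])
    return cfg


#: every named configuration of the full sensitivity study
SWEEP_NAMES = ("1", "2", "3", "4", "12", "20", "28", "84", "140", "196", "384")
SPARSE_NAMES = ("12S", "20S", "28S", "84S", "140S", "196S", "384S")


def configuration_by_name(name: str, iars: IARMap) -> StimulusConfiguration:
    """Resolve any configuration name used in the study: seed counts
    ('1'..'4' or 'S', 'S/LASW', ...), dense totals ('12'..'384'), sparse
    totals ('12S'..'384S'), and 'RBBB'/'LBBB'."""
    _check_iars(iars)
    seeds = seed_configurations(iars)
    seed_by_total = {str(c.total): c for c in seeds}
    seed_by_name = {c.name: c for c in seeds}
    if name in seed_by_total:
        return seed_by_total[name]
    if name in seed_by_name:
        return seed_by_name[name]
    if name in ("RBBB", "LBBB"):
        return bbb_configuration("right" if name == "RBBB" else "left", iars)
    sparse = name.endswith("S")
    core = name[:-1] if sparse else name
    try:
        total = int(core)
        level = DENSE_LEVEL_TOTALS.index(total) + 1
    except (ValueError, IndexError):
        raise ConfigurationError(f"unknown stimulus configuration {name!r}")
    return (sparse_configuration if sparse else dense_configuration)(level, iars)
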