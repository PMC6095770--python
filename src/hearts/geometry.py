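"""Idealized biventricular anatomy on a Cartesian grid.

The heart is modeled as two truncated half-ellipsoid shells: a thick-walled
left ventricle and a thinner right-ventricular crescent wrapped onto it,
sharing a septum.  The construction preserves the topological features the
downstream analysis needs -- two enclosed cavities, a septum, an apex-to-base
axis, and room for the four experimentally observed initial-activation
regions (IARs) of the human ventricles: left midseptum (S), left anterior
superior wall (LASW), left posterior inferior wall (LPIW), and right anterior
inferior wall (RAIW).

Axis convention (shared by all modules): x = right -> left of the body,
y = posterior -> anterior, z = apex -> base.  Voxel indices are 0-based and
positions are voxel centers in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ResolutionError, TopologyError

AXIS_CONVENTION = "x:right->left, y:posterior->anterior, z:apex->base"

# Tissue label codes.
BACKGROUND, LV_WALL, RV_WALL, SEPTUM, LV_CAVITY, RV_CAVITY = range(6)
LABEL_NAMES = {
    BACKGROUND: "background", LV_WALL: "LV_wall", RV_WALL: "RV_wall",
    SEPTUM: "septum", LV_CAVITY: "LV_cavity", RV_CAVITY: "RV_cavity",
}
TISSUE_LABELS = (LV_WALL, RV_WALL, SEPTUM)
IAR_NAMES = ("S", "LASW", "LPIW", "RAIW")


@dataclass
class GeometryParams:
    """Dimensions (mm) of the idealized biventricular solid."""

    long_axis_mm: float = 85.0          # apex (z=0) to basal truncation plane
    lv_cavity_radius_mm: float = 22.0
    lv_wall_thickness_mm: float = 12.0
    rv_wall_thickness_mm: float = 5.0
    rv_center_x_mm: float = -12.0       # RV envelope center, x offset
    rv_outer_x_mm: float = 46.0         # RV envelope semiaxes
    rv_outer_y_mm: float = 31.0
    rv_length_fraction: float = 0.78    # RV apical extent / long axis
    #: the RV basal boundary (atrioventricular groove) slopes down from the
    #: septal junction toward the lateral free wall, emulating the groove
    #: sitting below the outflow region; fraction of the long axis dropped
    #: at the far lateral side
    rv_base_drop_fraction: float = 0.06
    spacing_mm: float = 1.0
    subendo_depth_mm: float = 3.0
    margin_mm: float = 3.0

    def validate(self) -> None:
        lengths = {
            "long_axis_mm": self.long_axis_mm,
            "lv_cavity_radius_mm": self.lv_cavity_radius_mm,
            "lv_wall_thickness_mm": self.lv_wall_thickness_mm,
            "rv_wall_thickness_mm": self.rv_wall_thickness_mm,
            "rv_outer_x_mm": self.rv_outer_x_mm,
            "rv_outer_y_mm": self.rv_outer_y_mm,
            "spacing_mm": self.spacing_mm,
            "subendo_depth_mm": self.subendo_depth_mm,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ParameterError(f"{name} must be positive, got {value}")
        if not 0 < self.rv_length_fraction < 1:
            raise ParameterError("rv_length_fraction must be in (0, 1)")
        min_wall = min(self.lv_wall_thickness_mm, self.rv_wall_thickness_mm)
        if self.spacing_mm > min_wall / 2:
            raise ResolutionError(
                f"spacing {self.spacing_mm} mm cannot resolve a "
                f"{min_wall} mm wall (need spacing <= wall/2)")


@dataclass
class TissueGeometry:
    """Voxelized biventricular anatomy with labeled tissue, cavities, surfaces."""

    spacing_mm: float
    shape: tuple[int, int, int]
    label_volume: np.ndarray            # uint8, one of the six label codes
    origin_mm: np.ndarray               # world coordinate of voxel (0,0,0) corner
    subendo_depth_mm: float
    params: GeometryParams
    axis_convention: str = AXIS_CONVENTION
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, TISSUE_LABELS)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Voxel-center world coordinates (mm) for index array of shape (..., 3)."""
        return self.origin_mm + (np.asarray(ijk, dtype=float) + 0.5) * self.spacing_mm

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.meshgrid(*(self.voxel_centers(a) for a in range(3)),
                                 indexing="ij"))

    @property
    def tissue_volume_mm3(self) -> float:
        return float(self.tissue_mask.sum()) * self.spacing_mm ** 3

    def tissue_bounding_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.argwhere(self.tissue_mask)
        lo = self.origin_mm + idx.min(axis=0) * self.spacing_mm
        hi = self.origin_mm + (idx.max(axis=0) + 1) * self.spacing_mm
        return lo, hi

    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.tissue_mask)
        return self.world_coords(idx).mean(axis=0)

    # --- distance fields (mm), cached ---
    def distance_to(self, what: str) -> np.ndarray:
        """Euclidean distance (mm) of every voxel to the nearest voxel of
        ``what`` in {'LV_cavity', 'RV_cavity', 'background', 'endocardium'}."""
        if what not in self._cache:
            lbl = self.label_volume
            if what == "LV_cavity":
                mask = lbl == LV_CAVITY
            elif what == "RV_cavity":
                mask = lbl == RV_CAVITY
            elif what == "background":
                mask = lbl == BACKGROUND
            elif what == "endocardium":
                mask = (lbl == LV_CAVITY) | (lbl == RV_CAVITY)
            else:
                raise ParameterError(f"unknown distance target {what!r}")
            if not mask.any():
                raise TopologyError(f"geometry has no {what} voxels")
            self._cache[what] = ndimage.distance_transform_edt(
                ~mask, sampling=self.spacing_mm)
        return self._cache[what]


def _ellipsoid(X, Y, Z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2
            + ((Z - cz) / az) ** 2) < 1.0


def build_ventricles(params: GeometryParams | None = None) -> TissueGeometry:
    """Construct the idealized two-ellipsoid biventricular label volume.

    Deterministic for fixed parameters.  Raises ParameterError for
    non-positive dimensions and ResolutionError when the spacing cannot
    resolve the thinnest wall.
    """
    params = params or GeometryParams()
    params.validate()
    h = params.spacing_mm
    L = params.long_axis_mm
    a_out = params.lv_cavity_radius_mm + params.lv_wall_thickness_mm
    rv_cx = params.rv_center_x_mm
    rv_ax, rv_ay = params.rv_outer_x_mm, params.rv_outer_y_mm
    rv_az = params.rv_length_fraction * L
    t_rv = params.rv_wall_thickness_mm
    m = params.margin_mm

    xmin = min(-a_out, rv_cx - rv_ax) - m
    xmax = max(a_out, rv_cx + rv_ax) + m
    ymax = max(a_out, rv_ay) + m
    origin = np.array([xmin, -ymax, -m])
    extent = np.array([xmax - xmin, 2 * ymax, L + m])
    shape = tuple(int(np.ceil(e / h)) for e in extent)

    centers = [origin[a] + (np.arange(shape[a]) + 0.5) * h for a in range(3)]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")

    below_base = Z < L
    lv_outer = _ellipsoid(X, Y, Z, (0, 0, L), (a_out, a_out, L)) & below_base
    lv_inner = _ellipsoid(
        X, Y, Z, (0, 0, L),
        (params.lv_cavity_radius_mm, params.lv_cavity_radius_mm,
         L - params.lv_wall_thickness_mm)) & below_base
    rv_outer = _ellipsoid(X, Y, Z, (rv_cx, 0, L), (rv_ax, rv_ay, rv_az)) & below_base
    rv_inner = _ellipsoid(
        X, Y, Z, (rv_cx, 0, L),
        (rv_ax - t_rv, rv_ay - t_rv, rv_az - t_rv)) & below_base
    drop = params.rv_base_drop_fraction
    if drop > 0:
        # slanted basal cut; the cavity is cut one wall thickness deeper so
        # a wall cap keeps it enclosed in every axial slice
        x_sep = rv_cx + 0.5 * rv_ax
        x_far = rv_cx - rv_ax
        w = np.clip((x_sep - X) / (x_sep - x_far), 0.0, 1.0)
        z_top = L * (1.0 - drop * w)
        rv_outer &= Z < z_top
        rv_inner &= Z < z_top - t_rv

    lv_cav = lv_inner
    lv_wall_full = lv_outer & ~lv_inner
    rv_cav = rv_inner & ~lv_outer
    rv_wall = rv_outer & ~rv_inner & ~lv_outer
    # septum: the part of the LV wall that faces the RV cavity, i.e. within
    # one LV wall thickness of it
    d_rv_cav = ndimage.distance_transform_edt(~rv_cav, sampling=h)
    septum = lv_wall_full & (d_rv_cav <= params.lv_wall_thickness_mm + h)
    lv_wall = lv_wall_full & ~septum

    labels = np.zeros(shape, dtype=np.uint8)
    labels[lv_wall] = LV_WALL
    labels[rv_wall] = RV_WALL
    labels[septum] = SEPTUM
    labels[lv_cav] = LV_CAVITY
    labels[rv_cav] = RV_CAVITY

    geom = TissueGeometry(
        spacing_mm=h, shape=shape, label_volume=labels, origin_mm=origin,
        subendo_depth_mm=params.subendo_depth_mm, params=params)
    _validate_geometry(geom)
    return geom


def _validate_geometry(geom: TissueGeometry) -> None:
    lbl = geom.label_volume
    present = set(np.unique(lbl))
    missing = [LABEL_NAMES[c] for c in range(6) if c not in present]
    if missing:
        raise ResolutionError(f"labels missing from volume: {missing}")
    if not cavities_enclosed(geom):
        raise TopologyError("a cavity is not enclosed by wall in some axial slice")
    t_lv, t_rv = mean_wall_thickness_mm(geom)
    if not t_lv > t_rv:
        raise TopologyError(
            f"LV wall ({t_lv:.1f} mm) not thicker than RV wall ({t_rv:.1f} mm)")


def cavities_enclosed(geom: TissueGeometry) -> bool:
    """True if, in every axial (constant-z) slice, cavity voxels are separated
    from the slice border by tissue."""
    lbl = geom.label_volume
    cav = (lbl == LV_CAVITY) | (lbl == RV_CAVITY)
    tissue = geom.tissue_mask
    for k in range(geom.shape[2]):
        if not cav[:, :, k].any():
            continue
        open_space = ~tissue[:, :, k]
        comp, _ = ndimage.label(open_space)
        border_labels = np.unique(np.concatenate([
            comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]]))
        if np.isin(comp[cav[:, :, k]], border_labels).any():
            return False
    return True


def mean_wall_thickness_mm(geom: TissueGeometry) -> tuple[float, float]:
    """Approximate mean free-wall thickness (mm) of LV and RV as twice the
    mean of the maximal inscribed distance-to-boundary over wall voxels."""
    h = geom.spacing_mm
    out = []
    for code in (LV_WALL, RV_WALL):
        wall = geom.label_volume == code
        d = ndimage.distance_transform_edt(wall, sampling=h)
        # thickness ~ 2 * local max of the medial distance
        out.append(2.0 * float(d[wall].max()) if wall.any() else 0.0)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Fibers
# ---------------------------------------------------------------------------

@dataclass
class FiberField:
    """Per-tissue-voxel unit fiber vectors from a rule-based transmural helix.

    ``vectors`` is (nx, ny, nz, 3) with NaN outside tissue; ``helix_angle_deg``
    and ``transmural_depth`` (0 = endocardium, 1 = epicardium) are kept for
    inspection and testing.
    """

    vectors: np.ndarray
    helix_angle_deg: np.ndarray
    transmural_depth: np.ndarray
    alpha_endo_deg: float
    alpha_epi_deg: float

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.vectors[..., 0])


def assign_fibers(geom: TissueGeometry, alpha_endo_deg: float = 60.0,
                  alpha_epi_deg: float = -60.0) -> FiberField:
    """Rule-based fibers: the helix angle varies linearly with normalized
    transmural depth from ``alpha_endo_deg`` at the endocardium to
    ``alpha_epi_deg`` at the epicardium, and vectors are tangent to the wall.
    """
    for a in (alpha_endo_deg, alpha_epi_deg):
        if not -90.0 <= a <= 90.0:
            raise ParameterError(f"helix angle {a} outside [-90, 90] degrees")
    lbl = geom.label_volume
    tissue = geom.tissue_mask
    if not ((lbl == LV_CAVITY).any() and (lbl == BACKGROUND).any()):
        raise TopologyError("geometry lacks endo/epi reference surfaces")

    d_lv = geom.distance_to("LV_cavity")
    d_rv = geom.distance_to("RV_cavity")
    d_bg = geom.distance_to("background")
    d_endo = np.minimum(d_lv, d_rv)

    sep = lbl == SEPTUM
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = d_endo / (d_endo + d_bg)
        depth_sep = d_lv / (d_lv + d_rv)
    depth = np.where(sep, depth_sep, depth)
    depth = np.clip(np.nan_to_num(depth, nan=0.5), 0.0, 1.0)

    # transmural direction: gradient of a signed endo-to-epi potential
    sigma = 1.0
    psi_wall = ndimage.gaussian_filter(d_endo - d_bg, sigma)
    psi_sep = ndimage.gaussian_filter(d_lv - d_rv, sigma)
    n_wall = np.stack(np.gradient(psi_wall, geom.spacing_mm), axis=-1)
    n_sep = np.stack(np.gradient(psi_sep, geom.spacing_mm), axis=-1)
    normal = np.where(sep[..., None], n_sep, n_wall)

    # fall back to the outward radial direction where the gradient degenerates
    X, Y, Z = geom.coordinate_grids()
    radial = np.stack([X, Y, np.zeros_like(Z)], axis=-1)
    norm_n = np.linalg.norm(normal, axis=-1, keepdims=True)
    bad = (norm_n < 1e-8)[..., 0]
    normal = np.where(bad[..., None], radial, normal)
    norm_n = np.linalg.norm(normal, axis=-1, keepdims=True)
    normal = normal / np.maximum(norm_n, 1e-12)

    z_hat = np.array([0.0, 0.0, 1.0])
    circ = np.cross(np.broadcast_to(z_hat, normal.shape), normal)
    norm_c = np.linalg.norm(circ, axis=-1, keepdims=True)
    # near the apex the normal can align with z; fall back to azimuthal
    azim = np.stack([-Y, X, np.zeros_like(Z)], axis=-1)
    circ = np.where((norm_c < 1e-8), azim, circ)
    circ = circ / np.maximum(np.linalg.norm(circ, axis=-1, keepdims=True), 1e-12)
    longi = np.cross(normal, circ)
    longi = longi / np.maximum(np.linalg.norm(longi, axis=-1, keepdims=True), 1e-12)

    alpha = np.deg2rad(alpha_endo_deg + (alpha_epi_deg - alpha_endo_deg) * depth)
    vec = (np.cos(alpha)[..., None] * circ + np.sin(alpha)[..., None] * longi)
    vec = vec / np.maximum(np.linalg.norm(vec, axis=-1, keepdims=True), 1e-12)

    vec = vec.astype(np.float64)
    vec[~tissue] = np.nan
    angle = np.rad2deg(alpha)
    angle[~tissue] = np.nan
    depth_out = depth.copy()
    depth_out[~tissue] = np.nan
    return FiberField(vectors=vec, helix_angle_deg=angle,
                      transmural_depth=depth_out,
                      alpha_endo_deg=alpha_endo_deg, alpha_epi_deg=alpha_epi_deg)


# ---------------------------------------------------------------------------
# Initial activation regions
# ---------------------------------------------------------------------------

def local_wall_frame(geom: TissueGeometry, ijk: tuple[int, int, int],
                     septal: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal wall frame (a_hat, c_hat, n_hat) at a tissue voxel:
    apico-basal tangent, lateral (circumferential) tangent, and transmural
    normal pointing from endocardium toward epicardium (for the septum, from
    the LV toward the RV side)."""
    if septal:
        psi = geom.distance_to("LV_cavity") - geom.distance_to("RV_cavity")
    else:
        psi = np.minimum(geom.distance_to("LV_cavity"),
                         geom.distance_to("RV_cavity")) - geom.distance_to("background")
    psi = ndimage.gaussian_filter(psi, 1.0)
    g = np.array([np.gradient(psi, geom.spacing_mm, axis=a)[ijk] for a in range(3)])
    nrm = np.linalg.norm(g)
    if nrm < 1e-8:
        raise TopologyError(f"degenerate wall normal at voxel {ijk}")
    n_hat = g / nrm
    z_hat = np.array([0.0, 0.0, 1.0])
    a_raw = z_hat - np.dot(z_hat, n_hat) * n_hat
    if np.linalg.norm(a_raw) < 1e-8:
        raise TopologyError(f"wall tangent undefined at voxel {ijk}")
    a_hat = a_raw / np.linalg.norm(a_raw)
    c_hat = np.cross(n_hat, a_hat)
    return a_hat, c_hat, n_hat


@dataclass
class IARMap:
    """The four subendocardial initial-activation regions and their seeds.

    Besides the voxel masks, each region carries its seed position (mm), its
    host tissue label, and the local wall frame at the seed, which downstream
    stimulus protocols use to lay out apico-basal / lateral / transmural
    stimulus grids.
    """

    masks: dict[str, np.ndarray]
    seeds: dict[str, tuple[int, int, int]]   # voxel index of the region seed
    seed_positions_mm: dict[str, np.ndarray]
    frames: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    host_labels: dict[str, int]
    #: full subendocardial voxel mask of each host wall (not radius-limited)
    host_subendo: dict[str, np.ndarray]
    radius_mm: float
    geometry: TissueGeometry

    def __iter__(self) -> Iterator[str]:
        return iter(IAR_NAMES)

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]

    def seed(self, name: str) -> tuple[int, int, int]:
        return self.seeds[name]


def define_iars(geom: TissueGeometry, radius_mm: float = 13.0,
                septal_radius_mm: float = 24.0) -> IARMap:
    """Place the four IARs of the normal human ventricles.

    S: left (LV-facing) side of the midseptum; LASW: anterior superior LV free
    wall near the base; LPIW: posterior inferior paraseptal LV wall about one
    third of the apex-base distance; RAIW: anterior inferior RV wall.  All
    regions are subendocardial (within ``subendo_depth_mm`` of the respective
    endocardium) and bounded by ``radius_mm`` around a seed voxel
    (``septal_radius_mm`` for S, whose stimulus layouts span farther).
    """
    if radius_mm <= 0 or septal_radius_mm <= 0:
        raise ParameterError("region radii must be positive")
    lbl = geom.label_volume
    L = geom.params.long_axis_mm
    sub = geom.subendo_depth_mm
    d_lv = geom.distance_to("LV_cavity")
    d_rv = geom.distance_to("RV_cavity")
    r_endo = geom.params.lv_cavity_radius_mm

    hosts = {
        "S": (lbl == SEPTUM) & (d_lv <= sub),
        "LASW": (lbl == LV_WALL) & (d_lv <= sub),
        "LPIW": (lbl == LV_WALL) & (d_lv <= sub),
        "RAIW": (lbl == RV_WALL) & (d_rv <= sub),
    }
    # RAIW sits centrally on the anterior RV free wall (the anterior
    # papillary muscle inserts mid free wall)
    th = np.deg2rad(135.0)
    rv_mid = np.array([
        geom.params.rv_center_x_mm + geom.params.rv_outer_x_mm * np.cos(th),
        geom.params.rv_outer_y_mm * np.sin(th), 0.50 * L])
    c_in = L - geom.params.lv_wall_thickness_mm

    def lv_endo_radius(z: float) -> float:
        # radius of the LV endocardial ellipse at height z
        return r_endo * float(np.sqrt(max(0.0, 1.0 - ((z - L) / c_in) ** 2)))

    def lv_target(azimuth_deg: float, z: float) -> np.ndarray:
        r = lv_endo_radius(z)
        a = np.deg2rad(azimuth_deg)
        return np.array([r * np.cos(a), r * np.sin(a), z])

    targets = {
        "S": np.array([-lv_endo_radius(0.55 * L), 0.0, 0.55 * L]),
        "LASW": lv_target(45.0, 0.80 * L),
        "LPIW": lv_target(240.0, L / 3.0),
        "RAIW": rv_mid,
    }

    host_labels = {"S": SEPTUM, "LASW": LV_WALL, "LPIW": LV_WALL, "RAIW": RV_WALL}
    masks: dict[str, np.ndarray] = {}
    seeds: dict[str, tuple[int, int, int]] = {}
    seed_positions: dict[str, np.ndarray] = {}
    frames: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name in IAR_NAMES:
        host = hosts[name]
        if not host.any():
            raise ResolutionError(f"no subendocardial voxels available for {name}")
        idx = np.argwhere(host)
        pos = geom.world_coords(idx)
        k = int(np.argmin(((pos - targets[name]) ** 2).sum(axis=1)))
        seed_ijk = tuple(int(v) for v in idx[k])
        seed_pos = pos[k]
        r = septal_radius_mm if name == "S" else radius_mm
        within = ((pos - seed_pos) ** 2).sum(axis=1) <= r ** 2
        mask = np.zeros(geom.shape, dtype=bool)
        mask[tuple(idx[within].T)] = True
        masks[name] = mask
        seeds[name] = seed_ijk
        seed_positions[name] = seed_pos
        frames[name] = local_wall_frame(geom, seed_ijk, septal=(name == "S"))

    for i, a in enumerate(IAR_NAMES):
        for b in IAR_NAMES[i + 1:]:
            if (masks[a] & masks[b]).any():
                raise ResolutionError(
                    f"IARs {a} and {b} overlap; geometry too small for "
                    f"radius {radius_mm} mm")
    return IARMap(masks=masks, seeds=seeds, seed_positions_mm=seed_positions,
                  frames=frames, host_labels=host_labels, host_subendo=hosts,
                  radius_mm=radius_mm, geometry=geom)


# ---------------------------------------------------------------------------
# Electrodes
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeSet:
    """Limb electrode positions (mm) in the frontal plane of the heart."""

    positions: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.positions)


def place_electrodes(geom: TissueGeometry,
                     torso_scale_mm: float = 250.0) -> ElectrodeSet:
    """Place LA/RA/LL electrodes on an Einthoven triangle around the heart.

    LA and RA sit symmetric about the sagittal midline at a superior level;
    LL sits inferior-left.  All three lie in the frontal (x-z) plane through
    the heart centroid, outside the tissue bounding box.
    """
    lo, hi = geom.tissue_bounding_box_mm()
    diag = float(np.linalg.norm(hi - lo))
    if torso_scale_mm <= diag:
        raise ParameterError(
            f"torso_scale_mm={torso_scale_mm} must exceed the heart "
            f"bounding-box diagonal ({diag:.0f} mm)")
    c = geom.centroid_mm()
    ts = torso_scale_mm
    positions = {
        "LA": c + np.array([0.50 * ts, 0.0, 0.35 * ts]),
        "RA": c + np.array([-0.50 * ts, 0.0, 0.35 * ts]),
        "LL": c + np.array([0.35 * ts, 0.0, -0.50 * ts]),
    }
    return ElectrodeSet(positions=positions)
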