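"""File output: NIfTI / legacy-VTK volumes, HDF5 simulation results, CSV."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .geometry import TissueGeometry
from .solver import SimulationResult


def _affine(geom: TissueGeometry) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = geom.spacing_mm
    a[:3, 3] = geom.origin_mm + geom.spacing_mm / 2.0
    return a


def write_nifti(volume: np.ndarray, geom: TissueGeometry, path) -> None:
    """Write a grid-shaped volume as NIfTI with the geometry's isotropic
    affine (voxel centers in mm)."""
    img = nib.Nifti1Image(np.asarray(volume), _affine(geom))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_vtk_structured_points(volume: np.ndarray, geom: TissueGeometry,
                                path, name: str = "values") -> None:
    """ASCII legacy-VTK STRUCTURED_POINTS export of a grid-shaped volume."""
    vol = np.asarray(volume)
    nx, ny, nz = vol.shape
    h = geom.spacing_mm
    o = geom.origin_mm + h / 2.0
    is_int = np.issubdtype(vol.dtype, np.integer)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {o[0]:g} {o[1]:g} {o[2]:g}\n")
        f.write(f"SPACING {h:g} {h:g} {h:g}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write(f"SCALARS {name} {'int' if is_int else 'float'} 1\n")
        f.write("LOOKUP_TABLE default\n")
        flat = vol.transpose(2, 1, 0).ravel()   # VTK is x-fastest
        fmt = "%d" if is_int else "%.6g"
        for start in range(0, flat.size, 9):
            f.write(" ".join(fmt % v for v in flat[start:start + 9]) + "\n")


def write_result_h5(result: SimulationResult, path) -> None:
    """HDF5 layout: /vm[t, voxel] (mV), /activation_time (grid, ms),
    /time_ms, /tissue_ijk, plus config/stimulus metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vm", data=result.vm_mv, compression="gzip")
        f.create_dataset("activation_time", data=result.activation_time_ms,
                         compression="gzip")
        f.create_dataset("time_ms", data=result.time_ms)
        f.create_dataset("tissue_ijk", data=result.tissue_ijk)
        f.attrs["config_name"] = result.config_name
        f.attrs["spacing_mm"] = result.geometry.spacing_mm
        f.attrs["stimulus_log"] = json.dumps(result.stimulus_log)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
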