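"""Configuration-driven pipeline: geometry -> simulation -> ECG -> features.

A YAML file selects geometry, solver, protocol and output options; the
pipeline writes, under the configured output directory: the label volume,
per-configuration ECG CSVs and activation-time maps, a tidy feature table,
DF/ASPS tables for sweeps, and a provenance manifest (config hash, package
version).  Everything is deterministic; two identical runs produce identical
CSV contents and manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ecg, io, qrs, sensitivity, solver, stimuli
from . import geometry as geo
from .errors import ValidationError

log = logging.getLogger("hearts")

SCHEMA_VERSION = 1

_SECTION_FIELDS = {
    "geometry": {f.name for f in dataclasses.fields(geo.GeometryParams)},
    "solver": {f.name for f in dataclasses.fields(solver.SolverParams)},
    "iars": {"radius_mm", "septal_radius_mm"},
    "fibers": {"alpha_endo_deg", "alpha_epi_deg"},
    "electrodes": {"torso_scale_mm"},
    "ecg": {"gain"},
}
_TOP_KEYS = set(_SECTION_FIELDS) | {
    "schema_version", "configurations", "output_dir", "log_level",
    "write_vm", "include_sparse",
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline settings (see the YAML schema in the README)."""

    geometry: geo.GeometryParams
    solver: solver.SolverParams
    iars: dict
    fibers: dict
    electrodes: dict
    gain: float | None
    configurations: list[str]
    output_dir: Path
    log_level: str = "INFO"
    write_vm: bool = False
    include_sparse: bool = False
    raw: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ValidationError("config root must be a mapping")
        unknown = sorted(set(data) - _TOP_KEYS)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        if data.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported schema_version {data['schema_version']}")
        for section, allowed in _SECTION_FIELDS.items():
            sub = data.get(section, {}) or {}
            bad = sorted(set(sub) - allowed)
            if bad:
                raise ValidationError(
                    f"unknown keys in section {section!r}: {bad}")
        configs = data.get("configurations", ["12S"])
        if not isinstance(configs, list) or not configs:
            raise ValidationError("configurations must be a non-empty list")
        return cls(
            geometry=geo.GeometryParams(**(data.get("geometry") or {})),
            solver=solver.SolverParams(**(data.get("solver") or {})),
            iars=data.get("iars") or {},
            fibers=data.get("fibers") or {},
            electrodes=data.get("electrodes") or {},
            gain=(data.get("ecg") or {}).get("gain"),
            configurations=[str(c) for c in configs],
            output_dir=Path(data.get("output_dir", "hearts_out")),
            log_level=str(data.get("log_level", "INFO")),
            write_vm=bool(data.get("write_vm", False)),
            include_sparse=bool(data.get("include_sparse", False)),
            raw=data,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _build_anatomy(cfg: PipelineConfig):
    geom = geo.build_ventricles(cfg.geometry)
    fibers = geo.assign_fibers(geom, **cfg.fibers)
    iars = geo.define_iars(geom, **cfg.iars)
    electrodes = geo.place_electrodes(geom, **cfg.electrodes)
    return geom, fibers, iars, electrodes


def run_pipeline(config_path) -> Path:
    """Run every configuration named in the YAML file; returns the output
    directory containing the report bundle."""
    cfg = PipelineConfig.from_yaml(config_path)
    logging.basicConfig(level=cfg.log_level)
    out = io.ensure_dir(cfg.output_dir)
    log.info("building anatomy (spacing %.2g mm)", cfg.geometry.spacing_mm)
    geom, fibers, iars, electrodes = _build_anatomy(cfg)
    io.write_nifti(geom.label_volume.astype(np.int16), geom,
                   out / "labels.nii.gz")

    gain = cfg.gain if cfg.gain is not None else ecg.DEFAULT_GAIN
    op = solver.build_diffusion_operator(geom, fibers, cfg.solver)
    rows = []
    for name in cfg.configurations:
        stim = stimuli.configuration_by_name(name, iars)
        log.info("configuration %s: %d stimuli", name, stim.total)
        res = solver.run_simulation(geom, fibers, stim, cfg.solver,
                                    operator=op)
        trace = ecg.compute_ecg(res, electrodes, gain)
        safe = name.replace("/", "-")
        ecg.write_ecg_csv(trace, out / f"ecg_{safe}.csv")
        io.write_nifti(res.activation_time_ms.astype(np.float32), geom,
                       out / f"at_{safe}.nii.gz")
        if cfg.write_vm:
            io.write_result_h5(res, out / f"result_{safe}.h5")
        feats = qrs.extract_features(trace)
        row = {"config_name": name, "n_stimuli": stim.total}
        row.update(feats.as_dict())
        for fname, (within, dist) in qrs.classify_physiological(feats).items():
            row[f"{fname}_within"] = within
        rows.append(row)
        log.info("configuration %s done (QRSd %.0f ms)", name,
                 feats.qrs_duration_ms)
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)

    manifest = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config_hash": cfg.config_hash(),
        "configurations": cfg.configurations,
        "n_tissue_voxels": int(geom.tissue_mask.sum()),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out


def run_sweep_pipeline(config_path) -> Path:
    """Full eleven-configuration sensitivity sweep with DF/ASPS tables."""
    cfg = PipelineConfig.from_yaml(config_path)
    logging.basicConfig(level=cfg.log_level)
    out = io.ensure_dir(cfg.output_dir)
    geom, fibers, iars, electrodes = _build_anatomy(cfg)
    sweep = sensitivity.run_sweep(
        geom, fibers, iars, electrodes, solver_params=cfg.solver,
        gain=cfg.gain, include_sparse=cfg.include_sparse,
        progress=lambda name, row: log.info(
            "config %s: QRSd %.0f ms", name, row["QRSd_ms"]))
    sweep.features.to_csv(out / "features.csv", index=False)
    sweep.df_frame().to_csv(out / "df.csv", index=False)
    sweep.asps_frame().to_csv(out / "asps.csv", index=False)
    if sweep.sparse_features is not None:
        sweep.sparse_features.to_csv(out / "features_sparse.csv", index=False)
        sensitivity.sparse_dense_differences(sweep).to_csv(
            out / "sparse_dense.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "kind": "sweep",
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out
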