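"""Sensitivity statistics of QRS features to stimulus number and location.

Two statistics summarize a feature's metric series over the eleven stimulus
configurations (N = 1, 2, 3, 4 seed; 12 ... 384 regional):

* the desensitization factor

      DF = range({metric_N : 1 <= N <= 4}) / range({metric_N : 4 <= N <= 384}),

  the ratio of the feature's statistical range over the seed-stimulus
  configurations to its range over the regional-stimulus configurations
  (N = 4 belongs to both categories); DF > 1 means the feature responds more
  to seed stimuli than to regional density;

* the average sensitivity per stimulus

      ASPS(M) = avg({ |Delta metric_N| : N <= M }) / M,

  where Delta metric_N is the change from the configuration with the next
  smallest N, and M is one of the configuration totals.  The N = 1
  configuration has no predecessor and contributes no Delta (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, GapError, InsufficientDataError,
                     ParameterError)

ALLOWED_N = (1, 2, 3, 4, 12, 20, 28, 84, 140, 196, 384)
ASPS_M_VALUES = (4, 12, 20, 28, 84, 140, 196, 384)


@dataclass
class MetricSeries:
    """One QRS feature's values indexed by total stimulus count N."""

    feature: str
    pairs: list[tuple[int, float]]

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.pairs]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ParameterError("N must be strictly increasing")
        bad = [n for n in ns if n not in ALLOWED_N]
        if bad:
            raise ParameterError(
                f"N values {bad} outside the configuration totals {ALLOWED_N}")

    @property
    def n_values(self) -> list[int]:
        return [n for n, _ in self.pairs]

    def value(self, n: int) -> float:
        for m, v in self.pairs:
            if m == n:
                return v
        raise GapError(f"series has no entry for N={n}")


@dataclass
class DFResult:
    """Desensitization factor of one feature (undefined iff the regional
    range is zero, mirroring an undetectable feature)."""

    feature: str
    df: float | None
    seed_range: float
    regional_range: float
    undefined: bool


@dataclass
class ASPSResult:
    """Average sensitivity per stimulus, tabulated over M."""

    feature: str
    table: list[tuple[int, float]]   # (M, ASPS) in feature units per stimulus


def desensitization_factor(series: MetricSeries) -> DFResult:
    """DF = seed-category range / regional-category range (range = max - min)."""
    seed = [v for n, v in series.pairs if 1 <= n <= 4]
    regional = [v for n, v in series.pairs if 4 <= n <= 384]
    if len(seed) < 2 or len(regional) < 2:
        raise InsufficientDataError(
            "need at least 2 seed and 2 regional points for DF")
    seed_range = max(seed) - min(seed)
    regional_range = max(regional) - min(regional)
    if regional_range == 0.0:
        return DFResult(feature=series.feature, df=None,
                        seed_range=seed_range, regional_range=0.0,
                        undefined=True)
    return DFResult(feature=series.feature,
                    df=seed_range / regional_range,
                    seed_range=seed_range, regional_range=regional_range,
                    undefined=False)


def average_sensitivity_per_stimulus(series: MetricSeries, m: int,
                                     include_first: bool = False) -> float:
    """ASPS for maximum stimulus count ``m``.

    ``include_first`` counts the N = 1 configuration as a zero Delta instead
    of excluding it from the average.
    """
    if m not in ASPS_M_VALUES:
        raise ParameterError(f"M={m} not one of {ASPS_M_VALUES}")
    ns = [n for n in series.n_values if n <= m]
    expected = [n for n in ALLOWED_N if n <= m]
    if ns != expected:
        missing = sorted(set(expected) - set(ns))
        raise GapError(f"series missing configurations {missing} below M={m}")
    deltas = [abs(series.value(b) - series.value(a))
              for a, b in zip(ns, ns[1:])]
    if include_first:
        deltas = [0.0] + deltas
    return float(np.mean(deltas) / m)


def asps_table(series: MetricSeries, include_first: bool = False) -> ASPSResult:
    rows = [(m, average_sensitivity_per_stimulus(series, m, include_first))
            for m in ASPS_M_VALUES if m <= max(series.n_values)]
    return ASPSResult(feature=series.feature, table=rows)


# ---------------------------------------------------------------------------
# Full sweep orchestration
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Feature table, metric series, DF and ASPS for the full sweep."""

    features: pd.DataFrame               # one row per configuration
    series: dict[str, MetricSeries]      # by feature name
    df: dict[str, DFResult]
    asps: dict[str, ASPSResult]
    sparse_features: pd.DataFrame | None = None
    ecg_traces: dict = field(default_factory=dict)

    def df_frame(self) -> pd.DataFrame:
        rows = [{"feature": r.feature,
                 "DF": np.nan if r.undefined else r.df,
                 "seed_range": r.seed_range,
                 "regional_range": r.regional_range,
                 "undefined": r.undefined}
                for r in self.df.values()]
        return pd.DataFrame(rows)

    def asps_frame(self) -> pd.DataFrame:
        rows = [{"feature": a.feature, "M": m, "ASPS": v}
                for a in self.asps.values() for (m, v) in a.table]
        return pd.DataFrame(rows)


def run_sweep(geom, fibers, iars, electrodes, solver_params=None,
              gain: float | None = None, include_sparse: bool = False,
              keep_traces: bool = False,
              progress=None) -> SweepResult:
    """Simulate all eleven stimulus configurations, extract QRS features and
    compute DF and ASPS per feature.  Fully deterministic.

    ``include_sparse`` additionally simulates the sparse counterparts
    (20S ... 384S; 12S is identical to 12) for the sparse-vs-dense
    comparison table.
    """
    from . import ecg as _ecg
    from . import qrs as _qrs
    from . import solver as _solver
    from . import stimuli as _stimuli

    params = solver_params or _solver.SolverParams()
    gain = _ecg.DEFAULT_GAIN if gain is None else gain
    op = _solver.build_diffusion_operator(geom, fibers, params)

    def one(name: str) -> dict:
        cfg = _stimuli.configuration_by_name(name, iars)
        res = _solver.run_simulation(geom, fibers, cfg, params, operator=op)
        trace = _ecg.compute_ecg(res, electrodes, gain)
        feats = _qrs.extract_features(trace)
        row = {"config_name": name, "n_stimuli": cfg.total}
        row.update(feats.as_dict())
        flags = _qrs.classify_physiological(feats)
        for fname, (within, _) in flags.items():
            row[f"{fname}_within"] = within
        if progress is not None:
            progress(name, row)
        return row, trace

    rows = []
    traces = {}
    for name in _stimuli.SWEEP_NAMES:
        row, trace = one(name)
        rows.append(row)
        if keep_traces:
            traces[name] = trace
    features = pd.DataFrame(rows)

    series = {}
    dfres = {}
    asps = {}
    for feat in _qrs.FEATURE_NAMES:
        s = MetricSeries(feature=feat, pairs=list(zip(
            features["n_stimuli"], features[feat])))
        series[feat] = s
        dfres[feat] = desensitization_factor(s)
        asps[feat] = asps_table(s)

    sparse_features = None
    if include_sparse:
        srows = []
        for name in _stimuli.SPARSE_NAMES:
            row, trace = one(name)
            srows.append(row)
            if keep_traces:
                traces[name] = trace
        sparse_features = pd.DataFrame(srows)

    return SweepResult(features=features, series=series, df=dfres,
                       asps=asps, sparse_features=sparse_features,
                       ecg_traces=traces)


def sparse_dense_differences(sweep: SweepResult) -> pd.DataFrame:
    """|sparse - dense| per feature and level for the sweep's sparse runs."""
    if sweep.sparse_features is None:
        raise ConfigurationError("sweep was run without sparse configurations")
    from .qrs import FEATURE_NAMES
    rows = []
    dense = sweep.features.set_index("config_name")
    sparse = sweep.sparse_features.set_index("config_name")
    for sname in sparse.index:
        dname = sname[:-1]
        if dname not in dense.index:
            continue
        for feat in FEATURE_NAMES:
            rows.append({
                "level": dname, "feature": feat,
                "dense": dense.loc[dname, feat],
                "sparse": sparse.loc[sname, feat],
                "abs_diff": abs(dense.loc[dname, feat]
                                - sparse.loc[sname, feat]),
            })
    return pd.DataFrame(rows)
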