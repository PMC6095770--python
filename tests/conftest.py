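"""Shared fixtures: anatomy at the desk-scale spacing and cached beats.

Full-heart simulations are expensive, so beats are simulated once per
session (keyed by configuration name) and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from hearts import ecg as ecg_mod
from hearts import geometry as geo
from hearts import solver as solver_mod
from hearts import stimuli as stimuli_mod

#: grid spacing used by the full-heart tests (desk-scale default)
TEST_SPACING_MM = 2.5


@pytest.fixture(scope="session")
def heart():
    return geo.build_ventricles(geo.GeometryParams(spacing_mm=TEST_SPACING_MM))


@pytest.fixture(scope="session")
def fibers(heart):
    return geo.assign_fibers(heart)


@pytest.fixture(scope="session")
def iars(heart):
    return geo.define_iars(heart)


@pytest.fixture(scope="session")
def electrodes(heart):
    return geo.place_electrodes(heart)


@pytest.fixture(scope="session")
def solver_params():
    return solver_mod.SolverParams(duration_ms=450.0)


@pytest.fixture(scope="session")
def operator(heart, fibers, solver_params):
    return solver_mod.build_diffusion_operator(heart, fibers, solver_params)


@pytest.fixture(scope="session")
def sweep_result(heart, fibers, iars, electrodes, solver_params):
    """The full eleven-configuration sensitivity sweep, run once per session."""
    from hearts import sensitivity
    return sensitivity.run_sweep(heart, fibers, iars, electrodes,
                                 solver_params=solver_params)


@pytest.fixture(scope="session")
def beat_runner(heart, fibers, iars, electrodes, solver_params, operator):
    """run(name) -> (SimulationResult, ECGTrace), cached per configuration."""
    cache: dict[str, tuple] = {}

    def run(name: str):
        if name not in cache:
            cfg = stimuli_mod.configuration_by_name(name, iars)
            res = solver_mod.run_simulation(heart, fibers, cfg, solver_params,
                                            operator=operator)
            trace = ecg_mod.compute_ecg(res, electrodes)
            cache[name] = (res, trace)
        return cache[name]

    return run
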