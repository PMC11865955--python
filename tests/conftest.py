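"""Shared fixtures.

The expensive end-to-end artefacts (synthetic twin patient, multistart
calibration) are session-scoped so the acceptance-surface tests and the
recovery tests share one run.
"""

import numpy as np
import pytest

from pulsetree.inference import CalibrationProblem, InferenceConfig, default_bounds, optimize
from pulsetree.solver import SolverConfig
from pulsetree.synthetic import NoiseConfig, generate, three_vessel_network
from pulsetree.waveforms import FlowWaveform


TWIN_SEED = 7
INFER_SEED = 3


def make_pulse_inflow(CO_ml_s=66.67, T=0.71, Tp=24, systolic_fraction=0.35):
    """Half-sine ejection waveform used by solver-level tests."""
    t = np.arange(Tp) * T / Tp
    ts = systolic_fraction * T
    q = np.where(t < ts, np.sin(np.pi * t / ts), 0.0)
    q = q * CO_ml_s / q.mean()
    return FlowWaveform(t, q, T)


@pytest.fixture(scope="session")
def twin_solver_config():
    # coarse desk-scale discretization for the 3-vessel twin
    return SolverConfig(points_per_cm=0.25, min_points=5)


@pytest.fixture(scope="session")
def twin_patient(twin_solver_config):
    """Seeded synthetic patient on the 3-vessel subnetwork (5% flow noise,
    non-conservative branches, Tp=20)."""
    net = three_vessel_network("DORV")
    return generate("DORV", seed=TWIN_SEED, network=net,
                    solver_config=twin_solver_config, Tp=20)


@pytest.fixture(scope="session")
def twin_calibration(twin_patient, twin_solver_config):
    """Full 12-start multistart calibration of the twin's final subset."""
    data = twin_patient.patient_data()
    prob = CalibrationProblem(twin_patient.network, twin_patient.inflow,
                              twin_patient.theta_true, data, twin_solver_config)
    result = prob.calibrate(twin_patient.inference_subset(),
                            InferenceConfig(seed=INFER_SEED))
    return twin_patient, prob, result


@pytest.fixture(scope="session")
def noisefree_recovery(twin_solver_config):
    """Single calibration against noise-free twin data from a perturbed start."""
    net = three_vessel_network("DORV")
    quiet = NoiseConfig(flow_noise=0.0, deconservation=(0.0, 0.0),
                        cuff_noise_mmhg=0.0, geometry_sigma=0.05)
    pat = generate("DORV", seed=TWIN_SEED, network=net, noise=quiet,
                   solver_config=twin_solver_config, Tp=20)
    prob = CalibrationProblem(pat.network, pat.inflow, pat.theta_true,
                              pat.patient_data(), twin_solver_config)
    truth = pat.inference_subset()
    start = {k: v * 1.15 for k, v in truth.items()}
    bounds = default_bounds(truth)
    bounds["tree_alpha"] = (0.45, 0.99)
    out = optimize(start, bounds, prob.rss, maxiter=60)
    return truth, out
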