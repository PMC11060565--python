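"""Shared fixtures.

Expensive forward runs and calibrations are session-scoped so that the
physics, conservation and recovery tests all read from the same handful of
simulations.
"""

from __future__ import annotations

import pytest

import pulsevol as pv
from pulsevol.cohort_tools import SubjectMeta, generate_cohort, \
    generate_synthetic_subject

REFERENCE_META = SubjectMeta(id="ref", height=175.0, SBP=120.0, DBP=80.0, T=0.8)
HEALTHY_PARAMS = pv.ParameterVector(E_max=2.56, t_m=0.55, S_R=2.02, S_C=11.89)


@pytest.fixture(scope="session")
def wall():
    return pv.WallModel()


@pytest.fixture(scope="session")
def toy_tree():
    return pv.toy_tree()


@pytest.fixture(scope="session")
def tree55():
    return pv.default_tree()


def _healthy_model(tree, solver):
    model = pv.build_subject_model(tree, REFERENCE_META, solver=solver)
    return pv.apply_parameters(model, HEALTHY_PARAMS)


@pytest.fixture(scope="session")
def toy_solution():
    """Tightly converged periodic run on the toy tree, production grid."""
    model = _healthy_model(pv.toy_tree(), pv.PRODUCTION)
    return pv.run_to_periodic(model, max_cycles=30, tol_mmHg=0.1)


@pytest.fixture(scope="session")
def tree55_solution():
    """Periodic run on the full 55-segment tree, production grid."""
    model = _healthy_model(pv.default_tree(), pv.PRODUCTION)
    return pv.run_to_periodic(model, max_cycles=20, tol_mmHg=0.1)


@pytest.fixture(scope="session")
def noiseless_recovery():
    """Calibration against a noise-free self-generated radial beat."""
    meta = SubjectMeta(id="s", height=178.0, SBP=125.0, DBP=78.0, T=0.85)
    true_p = pv.ParameterVector(E_max=2.8, t_m=0.56, S_R=1.9, S_C=10.5)
    w, meta2 = generate_synthetic_subject(true_p, meta, noise_sd=0.0, seed=7,
                                          tree=pv.toy_tree(), solver=pv.COARSE)
    res = pv.calibrate(w, meta2, tree=pv.toy_tree(), solver=pv.COARSE, seed=3)
    return true_p, meta2, res


@pytest.fixture(scope="session")
def noisy_cohort_recovery():
    """Five synthetic control subjects, 2% measurement noise, calibrated."""
    out = []
    for i, meta in enumerate(generate_cohort(5, "control", seed=42)):
        true_p = meta.true_params
        w, meta2 = generate_synthetic_subject(
            true_p, meta, noise_sd=0.02, seed=100 + i,
            tree=pv.toy_tree(), solver=pv.COARSE)
        res = pv.calibrate(w, meta2, tree=pv.toy_tree(), solver=pv.COARSE,
                           seed=200 + i)
        out.append((true_p, meta2, res))
    return out


def relative_errors_pct(true_p, est_p):
    return {k: 100.0 * abs(getattr(est_p, k) - getattr(true_p, k))
            / abs(getattr(true_p, k))
            for k in ("E_max", "t_m", "S_R", "S_C")}
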