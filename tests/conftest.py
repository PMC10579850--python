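"""Shared fixtures.

The fixed-step RK4 reference run at h=1e-3 over 120 days is the workhorse
oracle for several tests; it is computed once per session.
"""

import numpy as np
import pytest

import seirkit as sk

DAILY_GRID = np.arange(121.0)


@pytest.fixture(scope="session")
def code_default():
    return sk.get_parameter_set("code_default")


@pytest.fixture(scope="session")
def table1():
    return sk.get_parameter_set("table1")


@pytest.fixture(scope="session")
def seir_model():
    return sk.get_model("seir")


@pytest.fixture(scope="session")
def y0_seir():
    return np.array([1000.0, 0.0, 1.0, 0.0])


@pytest.fixture(scope="session")
def rk4_daily(seir_model, code_default, y0_seir):
    """Independent fixed-step oracle trajectory, sampled on the daily grid."""
    dense = sk.rk4_reference(
        seir_model, y0_seir, 0.0, 120.0, h=1e-3, params=code_default
    )
    return sk.sample(dense, DAILY_GRID)


@pytest.fixture(scope="session")
def dp45_daily(seir_model, code_default, y0_seir):
    """Adaptive run at the default tolerance, sampled on the daily grid."""
    dense = sk.integrate(seir_model, y0_seir, 0.0, 120.0, params=code_default)
    return sk.sample(dense, DAILY_GRID)


def scaled_max_deviation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column max |a-b| relative to the larger of 1 and b's magnitude."""
    scale = np.maximum(1.0, np.abs(b).max(axis=0))
    return np.abs(a - b).max(axis=0) / scale
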