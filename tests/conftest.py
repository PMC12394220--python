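"""Shared fixtures: toy vessels, fast solver settings, the packaged baseline."""

from __future__ import annotations

import numpy as np
import pytest

from cuffwave import (
    COARSE,
    HeartParameters,
    Probe,
    SolverSettings,
    baseline_patient,
    toy_tree,
)
from cuffwave.patient import VirtualPatient


@pytest.fixture(scope="session")
def baseline() -> VirtualPatient:
    return baseline_patient()


@pytest.fixture(scope="session")
def toy1() -> VirtualPatient:
    """Single vessel + Windkessel terminal."""
    return toy_tree(1)


@pytest.fixture(scope="session")
def toy3() -> VirtualPatient:
    """Symmetric bifurcation: one parent, two identical daughters."""
    return toy_tree(3)


@pytest.fixture(scope="session")
def fast_settings() -> SolverSettings:
    """Coarse, loose-tolerance settings for quick toy runs."""
    return SolverSettings(dx=5e-3, eps_ss=1e-3, max_cycles=30)


@pytest.fixture(scope="session")
def coarse() -> SolverSettings:
    return COARSE


def gaussian_inflow(period: float, t0: float, width: float, peak: float,
                    n: int = 512) -> tuple[float, np.ndarray]:
    """A single small Gaussian flow pulse per period (m^3/s)."""
    t = np.linspace(0.0, period, n, endpoint=False)
    return period, peak * np.exp(-0.5 * ((t - t0) / width) ** 2)
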