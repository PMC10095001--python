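"""Shared fixtures: model-eye conditions, presets and cached simulations.

The heavier through-focus sweeps are session-scoped so the metric tests and
the acceptance checks share one simulation each.
"""

import numpy as np
import pytest

from trifocal_bench import iol_designs, metrics, model_eye, optics_engine


@pytest.fixture(scope="session")
def eye1():
    return model_eye.condition("condition1")


@pytest.fixture(scope="session")
def eye2():
    return model_eye.condition("condition2")


@pytest.fixture(scope="session")
def at_lisa():
    return iol_designs.preset("at_lisa")


@pytest.fixture(scope="session")
def triumf():
    return iol_designs.preset("triumf")


@pytest.fixture(scope="session")
def trinova():
    return iol_designs.preset("trinova")


@pytest.fixture(scope="session")
def at_lisa_tf_c1(eye1, at_lisa):
    """AT Lisa through-focus record, 3 mm, condition 1, production grid."""
    return optics_engine.through_focus(eye1, at_lisa, 3.0, grid_size=1024)


@pytest.fixture(scope="session")
def at_lisa_tf_c2(eye2, at_lisa):
    """AT Lisa through-focus record, 3 mm, condition 2 (polychromatic + SA)."""
    return optics_engine.through_focus(eye2, at_lisa, 3.0, grid_size=1024)


@pytest.fixture(scope="session")
def at_lisa_mtfa_c1(at_lisa_tf_c1, eye1):
    return metrics.tf_mtfa(at_lisa_tf_c1, eye1)


@pytest.fixture(scope="session")
def at_lisa_mtfa_c2(at_lisa_tf_c2, eye2):
    return metrics.tf_mtfa(at_lisa_tf_c2, eye2)


@pytest.fixture(scope="session")
def small_truth():
    """A tiny, analytic through-focus record for fast synthetic-bench tests."""
    grid = np.round(np.arange(-3.0, 1.01, 0.5), 10)
    freqs = np.array([0.0, 10.0, 25.0, 50.0, 75.0, 100.0])
    env = np.exp(-freqs / 60.0)
    curves = np.array([env * np.exp(-(d / 1.5) ** 2) for d in grid])
    curves[:, 0] = 1.0
    return optics_engine.ThroughFocusMTF(
        defocus_grid=grid, frequencies=freqs,
        mtf_sagittal=curves, mtf_tangential=curves,
        condition="condition1", lens="synthetic", aperture=3.0)
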