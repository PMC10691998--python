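"""Shared fixtures: the calibrated model, its steady state and dose curves.

The expensive objects (dose-response curves: ~60 ODE solves each) are
session-scoped; population-scale fixtures live in the modules that use
them.
"""

import numpy as np
import pytest
from hypothesis import settings
from scipy.interpolate import PchipInterpolator

import nfkbcap as nc
from nfkbcap.signaling_model import DoseResponseCurve

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def params():
    return nc.build_default_parameters()


@pytest.fixture(scope="session")
def perturbed_params(params):
    return nc.apply_perturbation(params, "disable_ikkb_deactivation")


@pytest.fixture(scope="session")
def steady_state(params):
    return nc.pre_stimulation_steady_state(params)


@pytest.fixture(scope="session")
def dose_curve(params):
    return nc.dose_response(params)


@pytest.fixture(scope="session")
def perturbed_curve(perturbed_params):
    return nc.dose_response(perturbed_params)


@pytest.fixture(scope="session")
def saturating_trajectory(params, steady_state):
    return nc.simulate_response(params, steady_state, 100.0)


def make_synthetic_curve():
    """A model-free monotone dose-response curve (activation linear in
    log-antigen) for exercising probe construction and the capacity
    heuristic on toy channels."""
    grid = np.geomspace(1e-3, 1e2, 60)
    u = np.log10(grid)
    act = (u - u[0]) / (u[-1] - u[0])
    interp = PchipInterpolator(u, act + np.arange(len(act)) * 1e-12)
    from nfkbcap.signaling_model import _invert_on_interp

    return DoseResponseCurve(
        antigen_grid=grid, activation=act,
        anchor_low=_invert_on_interp(interp, grid, 0.055),
        anchor_high=_invert_on_interp(interp, grid, 0.96),
        _interp=interp,
    )


@pytest.fixture(scope="session")
def synthetic_curve():
    return make_synthetic_curve()


def gaussian_toy_channel(sigma, floor=0.0):
    """Toy channel on the activation scale: response = target + noise.

    ``floor`` optionally clips responses from below (keeps them usable
    with either KDE scale).
    """

    def channel(probe, n_per_level, rng):
        n = probe.n_levels
        labels = np.repeat(np.arange(n), n_per_level)
        y = probe.target_activations[labels] + rng.normal(0.0, sigma, len(labels))
        return labels, np.maximum(y, floor)

    return channel
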