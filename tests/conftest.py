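"""Shared fixtures: gradient schemes, phantoms and noiseless simulations.

Session-scoped where construction is expensive; every stochastic fixture is
seeded so the suite is fully reproducible.
"""

import numpy as np
import pytest

from ortrack import (
    DWIVolume,
    PhantomConfig,
    RunConfig,
    build_or_phantom,
    fit_dti,
    generate_gradient_scheme,
    simulate_dwi,
)
from ortrack.pipeline import MCMCConfig, SchemeConfig
from ortrack.tracking import TrackingParams

FIBER_EVALS = (1.7e-3, 0.3e-3)  # parallel, perpendicular (mm^2/s)


@pytest.fixture(scope="session")
def scheme30():
    return generate_gradient_scheme(30, 3000.0, n_b0=1, seed=1)


@pytest.fixture(scope="session")
def phantom():
    return build_or_phantom(seed=0)


@pytest.fixture(scope="session")
def dwi_noiseless(phantom, scheme30):
    return simulate_dwi(phantom, scheme30, s0=1000.0, snr=np.inf, seed=0)


@pytest.fixture(scope="session")
def tensor_noiseless(dwi_noiseless):
    return fit_dti(dwi_noiseless)


def make_voxel_dwi(scheme, dw_signal, s0=1000.0, snr=np.inf, seed=0):
    """Single-voxel DWIVolume from a normalized DW signal vector."""
    data = np.full((1, 1, 1, scheme.n_volumes), float(s0))
    # magnitude data: clip tiny negative ringing of synthesized signals
    data[0, 0, 0, scheme.dwi_indices] = s0 * np.clip(np.asarray(dw_signal, dtype=float), 0.0, None)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        data = np.hypot(data + rng.normal(0, sigma, data.shape),
                        rng.normal(0, sigma, data.shape))
    return DWIVolume(data, np.eye(4), scheme)


def tensor_signal(directions, b, fiber_dir, evals=FIBER_EVALS, f=1.0, d_iso=3.0e-3):
    """Normalized signal of an axially symmetric tensor plus isotropic water."""
    lam_par, lam_perp = evals
    dots2 = (np.asarray(directions) @ np.asarray(fiber_dir)) ** 2
    fiber = np.exp(-b * (lam_perp + (lam_par - lam_perp) * dots2))
    return (1 - f) * np.exp(-b * d_iso) + f * fiber


def stick_signal(directions, b, stick_dir, d, f):
    """Normalized ball-and-stick forward signal."""
    dots2 = (np.asarray(directions) @ np.asarray(stick_dir)) ** 2
    return (1 - f) * np.exp(-b * d) + f * np.exp(-b * d * dots2)


@pytest.fixture(scope="session")
def tiny_config():
    """A reduced-grid experiment configuration for fast end-to-end tests."""
    phantom_cfg = PhantomConfig(
        shape=(24, 40, 12),
        lgn_mm=(30.0, 55.0, 14.0),
        apex_mm=(20.0, 68.0, 14.0),
        v1_mm=(25.0, 7.5, 14.0),
        tp_mm=(20.0, 95.0, 14.0),
        op_mm=(25.0, 2.5, 14.0),
        fan_spread_mm=5.0,
        n_fan_curves=5,
        crossing_y_mm=35.0,
        crossing_z_mm=14.0,
        target_semiaxes_mm=(10.0, 7.0, 10.0),
    )
    return RunConfig(
        phantom=phantom_cfg,
        scheme=SchemeConfig(n_directions=30, b_value=3000.0, n_b0=1),
        tracking=TrackingParams(streamlines_per_seed_voxel=50),
        mcmc=MCMCConfig(burn_in=150, n_samples=50, thin=2),
        n_subjects=5,
        seed=3,
    )
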