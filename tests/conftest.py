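"""Shared fixtures: parameter sets and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from occpop import ModelParams, build_schedule, simulate_forward


@pytest.fixture(scope="session")
def params_full() -> ModelParams:
    """Full model with occurrences and partial removal."""
    return ModelParams(lam=1.0, mu=0.5, psi=0.3, omega=0.6, rho=0.5, r=0.2, t_or=2.0)


@pytest.fixture(scope="session")
def params_no_omega() -> ModelParams:
    """Tree-only sampling (omega = 0): the closed-form regime."""
    return ModelParams(lam=1.0, mu=0.5, psi=0.3, omega=0.0, rho=0.5, r=0.2, t_or=2.0)


def simulate_dataset(params: ModelParams, seed: int, grid=()):
    """A simulated dataset with its schedule and an adequate truncation."""
    sim = simulate_forward(params, seed=seed, require_observation=True)
    schedule = build_schedule(sim.tree, sim.occurrences, params, grid)
    N = int(4 * sim.traj_sizes.max()) + 20
    return sim, schedule, N


@pytest.fixture(scope="session")
def dataset_full(params_full):
    return simulate_dataset(params_full, seed=2)


def random_params(rng: np.random.Generator, t_or: float = 5.0) -> ModelParams:
    """A random subcritical-or-supercritical parameter draw with Delta bounded away from 0."""
    while True:
        lam = rng.uniform(0.2, 2.0)
        mu = rng.uniform(0.0, 1.5)
        psi = rng.uniform(0.0, 0.8)
        omega = rng.uniform(0.0, 0.8)
        p = ModelParams(
            lam=lam, mu=mu, psi=psi, omega=omega,
            rho=rng.uniform(0.05, 1.0), r=rng.uniform(0.0, 1.0), t_or=t_or,
        )
        if p.Delta > 0.05:
            return p
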