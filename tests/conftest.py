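"""Shared fixtures: random model factories and the parameter-recovery
experiment (expensive; computed once per session and shared)."""

from __future__ import annotations

import numpy as np
import pytest

from peakdyn import ModelParameters, RunConfig, fit
from peakdyn.block_finder import Block
from peakdyn.synthetic import sample_blocks

RECOVERY_SEEDS = (101, 202, 303)
RECOVERY_N_BLOCKS = 2000
RECOVERY_T = 4
RECOVERY_LEN_RANGE = (20, 60)


def recovery_truth(T: int = RECOVERY_T, ratio: float = 8.0) -> ModelParameters:
    """The generating parameters of the recovery study: background mean 1
    read/bin, peak/background ratio 8, moderately overdispersed emissions,
    jump NB means of 2 bins, dynamics priors (0.5, 0.3, 0.2)."""
    return ModelParameters(
        alpha=np.full(T, np.log(ratio)),
        beta=np.full(T, 0.0),
        gamma=np.zeros(T),
        delta=np.full(T, 2.0),
        pi=np.tile([0.5, 0.3, 0.2], (T - 1, 1)),
        jump_mu=np.full((T - 1, 2), 2.0),
        jump_delta=np.full((T - 1, 2), 2.0),
    )


def random_model(rng: np.random.Generator, T: int) -> ModelParameters:
    """A random valid parameter set for oracle-equivalence checks."""
    return ModelParameters(
        alpha=rng.normal(1.5, 0.5, T),
        beta=rng.normal(0.0, 0.3, T),
        gamma=rng.normal(0.0, 0.3, T),
        delta=np.exp(rng.normal(0.0, 0.5, T)),
        pi=np.array([rng.dirichlet([2.0, 2.0, 2.0]) for _ in range(T - 1)]).reshape(T - 1, 3),
        jump_mu=np.exp(rng.normal(0.5, 0.4, (T - 1, 2))),
        jump_delta=np.exp(rng.normal(0.0, 0.4, (T - 1, 2))),
    )


def random_block(rng: np.random.Generator, T: int, N: int, mean: float = 2.0) -> Block:
    """A block with Poisson counts and log-uniform rates (for exactness
    tests, where counts need not come from the model)."""
    return Block(
        chrom="chrT",
        start_bin=0,
        end_bin=N - 1,
        counts=rng.poisson(mean, (T, N)),
        rates=np.exp(rng.uniform(0.0, 1.5, (T, N))),
        intervals=[[] for _ in range(T)],
    )


@pytest.fixture(scope="session")
def narrow_config() -> RunConfig:
    return RunConfig(mode="narrow")


@pytest.fixture(scope="session")
def recovery_experiment(narrow_config):
    """Fit the model on 2000 blocks sampled from known parameters, for each
    of three seeds.  Blocks and truths are kept for the first seed only
    (used by the dynamics-classification test)."""
    true = recovery_truth()
    fits, traces = [], []
    first = None
    for seed in RECOVERY_SEEDS:
        blocks, truths = sample_blocks(true, RECOVERY_N_BLOCKS, RECOVERY_LEN_RANGE, seed)
        params, trace = fit(blocks, narrow_config, max_iter=60, tol=1e-6)
        fits.append(params)
        traces.append(trace)
        if first is None:
            first = (blocks, truths)
    return {
        "true": true,
        "fits": fits,
        "traces": traces,
        "blocks": first[0],
        "truths": first[1],
    }
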