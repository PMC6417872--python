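import numpy as np
import pandas as pd
import pytest

from pdxfidelity.simulate import (
    Clone,
    CloneArchitecture,
    SimulationConfig,
    simulate_paired_variants,
    observations_to_calls,
    observations_to_pileup,
)
from pdxfidelity.variants import build_paired_table


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_patients=4,
        genome={"chr1": 5_000_000, "chr2": 5_000_000},
        seed=11,
    )


@pytest.fixture
def three_clone_arch():
    return CloneArchitecture(
        clones=[
            Clone("founder", 1.0, None),
            Clone("sub1", 0.4, "founder"),
            Clone("sub2", 0.15, "sub1"),
        ],
        variants_per_clone=50,
    )


@pytest.fixture
def simulated_pair(three_clone_arch, small_config):
    """One simulated trio plus its re-interrogated paired table."""
    rng = np.random.default_rng(42)
    obs, truth = simulate_paired_variants(three_clone_arch, small_config, rng)
    table = build_paired_table(
        observations_to_calls(obs, "tumor", small_config),
        observations_to_calls(obs, "pdx", small_config),
        observations_to_pileup(obs, "tumor", "t"),
        observations_to_pileup(obs, "pdx", "x"),
    )
    return obs, truth, table


def brute_force_rank_sum(greater, lesser):
    """Enumeration oracle: P(rank sum of group 1 >= observed) over all
    rank assignments, mid-ranks for ties."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(greater, float), np.asarray(lesser, float)])
    ranks = rankdata(pooled)
    n1 = len(greater)
    observed = ranks[:n1].sum()
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total
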