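import numpy as np
import pytest

from adgreml.model_matrices import build_model_matrices, compute_grm
from adgreml.simulator import make_fixture_f1, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def f1():
    """Tiny deterministic dataset (6 individuals, 4 SNPs, 2-level batch)."""
    G, phen, truth = make_fixture_f1()
    return G, phen, truth


@pytest.fixture(scope="session")
def f1_model(f1):
    G, phen, _ = f1
    mm = build_model_matrices(G, phen, fixed_effects=["batch"], definition_id=1)
    grm = compute_grm(mm.T_alpha, mm.T_delta, 1)
    return mm, grm


def make_dataset(q, m, h2a=0.3, h2d=0.2, seed=0, n_validation=0, fixed=False):
    """Simulated dataset with model matrices and GRMs prebuilt."""
    import pandas as pd

    G = simulate_genotypes(q, m, seed=seed)
    phen, truth = simulate_phenotypes(G, h2a, h2d, seed=seed, n_validation=n_validation)
    fixed_effects = []
    if fixed:
        rng = np.random.default_rng(seed + 1)
        phen.covariates["group"] = rng.choice(["g1", "g2", "g3"], size=q)
        fixed_effects = ["group"]
    mm = build_model_matrices(G, phen, fixed_effects=fixed_effects)
    grm = compute_grm(mm.T_alpha, mm.T_delta, 1)
    return G, phen, truth, mm, grm


@pytest.fixture(scope="session")
def small_dataset():
    """q=12, m=6 dataset with a 3-level factor and 2 validation individuals."""
    return make_dataset(12, 6, seed=11, n_validation=2, fixed=True)
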