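"""Seeded simulation of genotypes and phenotypes with a known
additive + dominance architecture.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium with
allele frequencies sampled uniformly in a configurable MAF window
(default 0.05-0.5, unlinked markers).  Phenotypes place standard-normal
additive and dominance effects at a random QTL subset (default one SNP
in ten), map them through the additive and dominance coding of the
observed genotypes, and rescale the resulting genetic values so their
in-sample variances hit the target heritabilities exactly on a
phenotypic-variance scale of 1; the residual is Gaussian with variance
1 - h2a - h2d.  Exact in-sample scaling means the simulation truth is
known without Monte-Carlo error, which is what parameter-recovery tests
need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, PhenotypeTable
from .model_matrices import additive_codes, allele_frequencies, dominance_codes

__all__ = [
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_fixture_f1",
]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated phenotype set."""

    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    a: np.ndarray            # true breeding values per individual
    d: np.ndarray            # true dominance deviations per individual
    qtl_indices: np.ndarray
    seed: int

    @property
    def h2_alpha(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_d + self.sigma2_e)

    @property
    def h2_delta(self) -> float:
        return self.sigma2_d / (self.sigma2_a + self.sigma2_d + self.sigma2_e)


def simulate_genotypes(
    q: int,
    m: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """HWE genotypes for q individuals at m unlinked SNPs.

    Allele frequencies are Uniform(maf_low, maf_high); each genotype is
    the sum of two Bernoulli(p) allele draws, giving HWE frequencies
    (p^2, 2pq, q^2) for dosages (2, 1, 0).
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if q < 1 or m < 1:
        raise ValueError("q and m must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=m)
    codes = rng.binomial(2, p[None, :], size=(q, m)).astype(float)
    ids = [f"ind{i + 1:0{len(str(q))}d}" for i in range(q)]
    markers = [f"snp{j + 1:0{len(str(m))}d}" for j in range(m)]
    return GenotypeMatrix(ids, markers, codes, np.zeros_like(codes, dtype=bool))


def simulate_phenotypes(
    G: GenotypeMatrix,
    h2a: float,
    h2d: float,
    n_qtl: int | None = None,
    mu: float = 0.0,
    seed: int = 0,
    n_validation: int = 0,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Phenotypes with exact in-sample additive/dominance variance.

    QTL effects alpha*, delta* are standard normal at ``n_qtl``
    randomly chosen markers (default m // 10, at least 1); genetic
    values a* = W_qtl alpha*, d* = S_qtl delta* are rescaled so
    var(a*) = h2a and var(d*) = h2d on a phenotypic-variance scale of
    1, and e ~ N(0, 1 - h2a - h2d).  The last ``n_validation``
    individuals get a missing trait (genotyped, unphenotyped).
    """
    if h2a < 0 or h2d < 0 or h2a + h2d >= 1:
        raise ValueError("need h2a, h2d >= 0 with h2a + h2d < 1")
    import pandas as pd

    q, m = G.codes.shape
    if n_qtl is None:
        n_qtl = max(1, m // 10)
    if n_qtl > m:
        raise ValueError("n_qtl cannot exceed the marker count")
    rng = np.random.default_rng(seed)
    p, keep = allele_frequencies(G)
    candidates = np.flatnonzero(keep)   # QTLs must be polymorphic
    if len(candidates) < n_qtl:
        raise ValueError("fewer polymorphic markers than requested QTLs")
    qtl = np.sort(rng.choice(candidates, size=n_qtl, replace=False))
    W = additive_codes(G.codes, p)[:, qtl]
    S = dominance_codes(G.codes, p)[:, qtl]

    def scaled(M: np.ndarray, target_var: float) -> np.ndarray:
        if target_var == 0.0:
            return np.zeros(q)
        g = M @ rng.standard_normal(n_qtl)
        v = float(np.var(g))
        if v == 0.0:
            raise ValueError("degenerate genetic values: all QTLs monomorphic")
        return g * np.sqrt(target_var / v)

    a = scaled(W, h2a)
    d = scaled(S, h2d)
    sigma2_e = 1.0 - h2a - h2d
    e = rng.standard_normal(q) * np.sqrt(sigma2_e)
    y = mu + a + d + e
    trait = y.copy()
    if n_validation:
        trait[q - n_validation:] = np.nan
    phen = PhenotypeTable(
        individual_ids=list(G.individual_ids),
        trait=trait,
        covariates=pd.DataFrame(index=range(q)),
    )
    truth = SimulationTruth(
        sigma2_a=float(np.var(a)), sigma2_d=float(np.var(d)), sigma2_e=sigma2_e,
        a=a, d=d, qtl_indices=qtl, seed=seed,
    )
    return phen, truth


F1_SEED = 20140809


def make_fixture_f1() -> tuple[GenotypeMatrix, PhenotypeTable, SimulationTruth]:
    """Tiny deterministic dataset used by the dense-matrix oracle tests:
    6 individuals, 4 polymorphic SNPs, one 2-level fixed factor."""
    import pandas as pd

    rng = np.random.default_rng(F1_SEED)
    # redraw until every SNP is polymorphic so no marker is dropped by QC
    while True:
        p = rng.uniform(0.25, 0.5, size=4)
        codes = rng.binomial(2, p[None, :], size=(6, 4)).astype(float)
        freqs = codes.mean(axis=0) / 2.0
        if np.all((freqs > 0) & (freqs < 1)):
            break
    G = GenotypeMatrix(
        [f"f1_{i}" for i in range(1, 7)],
        [f"m{j}" for j in range(1, 5)],
        codes,
        np.zeros_like(codes, dtype=bool),
    )
    batch = ["A", "A", "A", "B", "B", "B"]
    p_obs, _ = allele_frequencies(G)
    W = additive_codes(G.codes, p_obs)
    S = dominance_codes(G.codes, p_obs)
    alpha = rng.standard_normal(4)
    delta = rng.standard_normal(4)
    a = W @ alpha
    d = S @ delta
    e = rng.standard_normal(6) * 0.5
    y = 10.0 + np.where(np.array(batch) == "B", 1.0, 0.0) + a + d + e
    phen = PhenotypeTable(
        individual_ids=list(G.individual_ids),
        trait=y,
        covariates=pd.DataFrame({"batch": batch}),
    )
    truth = SimulationTruth(
        sigma2_a=float(np.var(a)), sigma2_d=float(np.var(d)), sigma2_e=0.25,
        a=a, d=d, qtl_indices=np.arange(4), seed=F1_SEED,
    )
    return G, phen, truth
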