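"""Model-matrix construction for the additive + dominance genomic model.

From raw allele-dosage codes this module derives allele frequencies,
imputes missing calls, builds the additive (W) and dominance (S) code
matrices, normalizes them into T_alpha and T_delta under one of six
relationship definitions, forms the genomic relationship matrices
A_g = T_alpha T_alpha' and D_g = T_delta T_delta', and assembles the
fixed-effect design X, the incidence matrix Z and the training trait
vector y.

Coding convention: the dosage code counts copies of the A1 allele whose
frequency is p.  Per SNP with q = 1 - p,

    additive   A1A1/A1A2/A2A2 -> 2-2p, 1-2p, -2p        (W)
    dominance  A1A1/A1A2/A2A2 -> -2q^2, 2pq, -2p^2      (S)

Both codings have zero mean under Hardy-Weinberg equilibrium, and the
additive coding is orthogonal to the dominance coding in the HWE limit,
which is what makes sigma2_a the gene-substitution (breeding-value)
variance and sigma2_d the dominance-deviation variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PhenotypeTable, ValidationError

__all__ = [
    "ModelMatrices",
    "GrmPair",
    "allele_frequencies",
    "impute_missing",
    "additive_codes",
    "dominance_codes",
    "heterozygosity_codes",
    "build_T",
    "compute_grm",
    "build_design",
    "build_model_matrices",
]


@dataclass
class ModelMatrices:
    """Design and marker matrices for one analysis."""

    X: np.ndarray            # N x c fixed-effect design
    rank_X: int
    Z: np.ndarray            # N x q incidence (one 1 per row)
    train_idx: np.ndarray    # N integer positions into the genotype ordering
    y: np.ndarray            # N training trait values
    W: np.ndarray            # q x m additive codes
    S: np.ndarray            # q x m dominance codes
    T_alpha: np.ndarray      # q x m normalized additive matrix
    T_delta: np.ndarray      # q x m normalized dominance matrix
    k_alpha: float | np.ndarray
    k_delta: float | np.ndarray
    p: np.ndarray            # length-m allele frequencies
    definition_id: int
    individual_ids: list[str]
    marker_ids: list[str]

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.T_alpha.shape[0]

    @property
    def n_markers(self) -> int:
        return self.T_alpha.shape[1]


@dataclass
class GrmPair:
    """Additive and dominance genomic relationship matrices."""

    A_g: np.ndarray
    D_g: np.ndarray
    definition_id: int


def allele_frequencies(
    G: GenotypeMatrix,
    training_only: bool = False,
    training_ids: list[str] | None = None,
    maf_min: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed A1 allele frequencies and a keep-mask per marker.

    p_i = (sum of non-missing codes at marker i) / (2 * number of
    non-missing calls).  Markers that are monomorphic (p <= maf_min or
    p >= 1 - maf_min with maf_min defaulting to 0) or entirely missing
    are flagged for exclusion.
    """
    codes = G.codes
    mask = G.missing_mask
    if training_only:
        if not training_ids:
            raise ValidationError("training_only=True requires training_ids")
        rows = [i for i, ind in enumerate(G.individual_ids) if ind in set(training_ids)]
        codes, mask = codes[rows], mask[rows]
    observed = ~mask
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(np.where(observed, codes, 0.0), axis=0), np.nan)
        p = p / np.maximum(2 * n_obs, 1)
    keep = np.ones(G.n_markers, dtype=bool)
    all_missing = n_obs == 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} marker(s) with all calls missing excluded",
            stacklevel=2,
        )
        keep &= ~all_missing
    mono = (p <= maf_min) | (p >= 1.0 - maf_min)
    keep &= ~(mono & ~all_missing)
    return p, keep


def impute_missing(G: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    """Replace each missing call at marker i by its expected dosage 2*p_i."""
    dosages = G.codes.copy()
    rows, cols = np.where(G.missing_mask)
    dosages[rows, cols] = 2.0 * p[cols]
    return dosages


def additive_codes(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Centered additive codes w_ij = dosage_ij - 2 p_j."""
    return dosages - 2.0 * p[None, :]


def dominance_codes(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Dominance-deviation codes: -2q^2, 2pq, -2p^2 at dosages 2, 1, 0.

    Fractional (imputed) dosages are mapped by piecewise-linear
    interpolation between the three genotype values, so the map is
    continuous and exact at integer dosages.
    """
    q = 1.0 - p
    s0 = -2.0 * p**2           # A2A2, dosage 0
    s1 = 2.0 * p * q           # A1A2, dosage 1
    s2 = -2.0 * q**2           # A1A1, dosage 2
    d = np.asarray(dosages, dtype=float)
    lower = s0[None, :] + d * (s1 - s0)[None, :]
    upper = s1[None, :] + (d - 1.0) * (s2 - s1)[None, :]
    return np.where(d <= 1.0, lower, upper)


def heterozygosity_codes(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Centered heterozygosity codes h - 2pq with h in {0,1,0}.

    Used by the genotypic-dominance relationship definitions (3 and 4);
    fractional dosages interpolate linearly: h(d) = d for d <= 1,
    2 - d for d > 1.
    """
    d = np.asarray(dosages, dtype=float)
    h = np.where(d <= 1.0, d, 2.0 - d)
    return h - (2.0 * p * (1.0 - p))[None, :]


def build_T(
    W: np.ndarray,
    S: np.ndarray,
    p: np.ndarray,
    definition_id: int = 1,
    dosages: np.ndarray | None = None,
    user_freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float | np.ndarray, float | np.ndarray]:
    """Normalize W and S into T_alpha and T_delta.

    Definitions:
      1. global normalizers k_alpha = sum 2 p q, k_delta = sum (2 p q)^2
         (default; calibrates sigma2_a/sigma2_d to base-population
         additive/dominance variances under HWE).
      2. per-SNP standardized: column j of T_alpha = w_j / sqrt(m 2 p q);
         column j of T_delta = s_j / (sqrt(m) 2 p q).
      3. additive as 1; dominance from centered heterozygosity codes,
         global normalizer sqrt(sum 2 p q (1 - 2 p q)).
      4. additive as 2; dominance as 3 but per-SNP standardized.
      5. unscaled cross-products: W / sqrt(m), S / sqrt(m).
      6. as 1 with user-supplied (e.g. base-population) frequencies in
         the normalizers instead of the observed ones.

    Returns (T_alpha, T_delta, k_alpha, k_delta) where the k values are
    the squared normalizers (scalar for global, per-column vector for
    per-SNP definitions).
    """
    if not 1 <= definition_id <= 6:
        raise ValidationError(f"grm definition must be in 1..6, got {definition_id}")
    m = W.shape[1]
    pq = p * (1.0 - p)
    two_pq = 2.0 * pq

    if definition_id in (3, 4):
        if dosages is None:
            raise ValidationError("definitions 3 and 4 need the dosage matrix")
        H = heterozygosity_codes(dosages, p)

    if definition_id == 1 or definition_id == 3 or definition_id == 6:
        freqs = p if definition_id != 6 else user_freqs
        if definition_id == 6 and user_freqs is None:
            raise ValidationError("definition 6 needs user-supplied frequencies")
        f_pq = 2.0 * freqs * (1.0 - freqs)
        k_alpha = float(np.sum(f_pq))
        if k_alpha <= 0:
            raise ValidationError("k_alpha is zero: all markers monomorphic")
        T_alpha = W / np.sqrt(k_alpha)
        if definition_id == 3:
            k_delta = float(np.sum(two_pq * (1.0 - two_pq)))
            if k_delta <= 0:
                raise ValidationError("k_delta is zero under definition 3")
            T_delta = H / np.sqrt(k_delta)
        else:
            k_delta = float(np.sum(f_pq**2))
            if k_delta <= 0:
                raise ValidationError("k_delta is zero: all markers monomorphic")
            T_delta = S / np.sqrt(k_delta)
        return T_alpha, T_delta, k_alpha, k_delta

    if definition_id in (2, 4):
        if np.any(two_pq <= 0):
            raise ValidationError("per-SNP definitions need 0 < p < 1 at every marker")
        k_alpha = m * two_pq
        T_alpha = W / np.sqrt(k_alpha)[None, :]
        if definition_id == 2:
            k_delta = m * two_pq**2
            T_delta = S / (np.sqrt(m) * two_pq)[None, :]
        else:
            k_delta = m * two_pq * (1.0 - two_pq)
            if np.any(k_delta <= 0):
                raise ValidationError("definition 4 normalizer vanishes at a marker")
            T_delta = H / np.sqrt(k_delta)[None, :]
        return T_alpha, T_delta, k_alpha, k_delta

    # definition 5
    k_alpha = float(m)
    k_delta = float(m)
    return W / np.sqrt(m), S / np.sqrt(m), k_alpha, k_delta


def compute_grm(T_alpha: np.ndarray, T_delta: np.ndarray, definition_id: int = 1) -> GrmPair:
    """A_g = T_alpha T_alpha', D_g = T_delta T_delta' (symmetrized)."""
    A = T_alpha @ T_alpha.T
    D = T_delta @ T_delta.T
    return GrmPair(0.5 * (A + A.T), 0.5 * (D + D.T), definition_id)


def build_design(
    phenotypes: PhenotypeTable,
    G: GenotypeMatrix,
    fixed_effects: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """Assemble X, Z, y for the training records.

    X holds an intercept, dummy-coded categorical covariates (first
    level dropped) and mean-centered numeric covariates.  Z selects each
    training record's row in the genotype ordering (exactly one 1 per
    row).  Returns (X, Z, y, rank_X, train_idx).
    """
    fixed_effects = fixed_effects or []
    geno_index = {ind: i for i, ind in enumerate(G.individual_ids)}
    train_rows = [
        k for k, (ind, t) in enumerate(zip(phenotypes.individual_ids, phenotypes.trait))
        if np.isfinite(t)
    ]
    if not train_rows:
        raise ValidationError("no training records: every trait value is missing")
    missing = [
        phenotypes.individual_ids[k] for k in train_rows
        if phenotypes.individual_ids[k] not in geno_index
    ]
    if missing:
        raise ValidationError(
            f"training individual(s) without genotypes: {', '.join(missing[:5])}"
        )
    N = len(train_rows)
    y = phenotypes.trait[train_rows]
    train_idx = np.array(
        [geno_index[phenotypes.individual_ids[k]] for k in train_rows], dtype=int
    )
    Z = np.zeros((N, G.n_individuals))
    Z[np.arange(N), train_idx] = 1.0

    columns = [np.ones(N)]
    for cov in fixed_effects:
        col = phenotypes.covariates[cov].iloc[train_rows]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all() and col.dtype.kind in "ifub":
            v = numeric.to_numpy(dtype=float)
            columns.append(v - v.mean())
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                columns.append(dummies[c].to_numpy(dtype=float))
    X = np.column_stack(columns)
    rank_X = int(np.linalg.matrix_rank(X))
    if rank_X < X.shape[1]:
        warnings.warn(
            "fixed-effect design is rank deficient; a generalized inverse "
            "of X'V^-1 X is used downstream",
            stacklevel=2,
        )
    return X, Z, y, rank_X, train_idx


def build_model_matrices(
    G: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    fixed_effects: list[str] | None = None,
    definition_id: int = 1,
    training_only_freqs: bool = False,
    maf_min: float = 0.0,
    user_freqs: np.ndarray | None = None,
) -> ModelMatrices:
    """Full pipeline from raw genotypes and phenotypes to ModelMatrices.

    Monomorphic (and optionally low-MAF) markers are dropped before
    normalization; allele frequencies default to all genotyped
    individuals because the relationship matrices span the training and
    validation sets.
    """
    p_all, keep = allele_frequencies(
        G,
        training_only=training_only_freqs,
        training_ids=phenotypes.training_ids if training_only_freqs else None,
        maf_min=maf_min,
    )
    if not keep.any():
        raise ValidationError("no polymorphic markers remain after QC")
    G_kept = G.subset_markers(keep)
    p = p_all[keep]
    dosages = impute_missing(G_kept, p)
    W = additive_codes(dosages, p)
    S = dominance_codes(dosages, p)
    uf = user_freqs[keep] if user_freqs is not None else None
    T_alpha, T_delta, k_alpha, k_delta = build_T(
        W, S, p, definition_id, dosages=dosages, user_freqs=uf
    )
    X, Z, y, rank_X, train_idx = build_design(phenotypes, G_kept, fixed_effects)
    return ModelMatrices(
        X=X, rank_X=rank_X, Z=Z, train_idx=train_idx, y=y,
        W=W, S=S, T_alpha=T_alpha, T_delta=T_delta,
        k_alpha=k_alpha, k_delta=k_delta, p=p,
        definition_id=definition_id,
        individual_ids=list(G_kept.individual_ids),
        marker_ids=list(G_kept.marker_ids),
    )
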