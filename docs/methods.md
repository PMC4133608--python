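# Methods

## Model and parameterization

`adgreml` fits the additive + dominance genomic mixed model

    y = X b + Z a + Z d + e,
    a = T_α α,  d = T_δ δ,
    α ~ N(0, σ²_a I_m),  δ ~ N(0, σ²_d I_m),  e ~ N(0, σ²_e I_N),

assuming one phenotypic record per individual. `y` (length N) holds the
training records; `X` (N × c) the fixed effects (intercept, dummy-coded
factors with the first level dropped, centered numeric covariates); `Z`
(N × q) selects each record's genotyped individual. Individuals with
genotypes but no phenotype are carried through every per-individual output as
the validation set.

Marker codings (dosage = count of the allele with frequency p, per SNP):

| genotype | dosage | additive w | dominance s |
|----------|--------|------------|-------------|
| A1A1     | 2      | 2 − 2p     | −2q²        |
| A1A2     | 1      | 1 − 2p     | 2pq         |
| A2A2     | 0      | −2p        | −2p²        |

Both codings have zero mean under HWE, making σ²_a the variance of breeding
values (gene-substitution effects) and σ²_d the variance of dominance
deviations. Allele frequencies are computed from all genotyped individuals by
default (the relationship matrices span training and validation; a
training-only option exists). Missing calls (tokens `NA`, `-9`, `5`) are
imputed with the expected dosage 2p; fractional dosages map into the
dominance (and heterozygosity) codings by piecewise-linear interpolation
between the three genotype values, which is continuous and exact at integer
dosages. Monomorphic markers are always dropped; no further marker QC is
applied unless a MAF threshold is requested.

## Relationship-matrix definitions

`A_g = T_α T_α'` and `D_g = T_δ T_δ'` with six normalization menus
(definition 1 is the default used throughout estimation):

1. global: `T_α = W/√(Σ 2p_i q_i)`, `T_δ = S/√(Σ (2p_i q_i)²)` — calibrates
   σ²_a, σ²_d to base-population additive/dominance variances under HWE
   (mean diagonal → 1 as m grows);
2. per-SNP standardized columns: `w_j/√(m·2p_j q_j)` and `s_j/(√m·2p_j q_j)`;
3. additive as 1; dominance from centered heterozygosity codes
   `h − 2pq, h ∈ {0,1,0}`, global normalizer `√(Σ 2p_j q_j (1 − 2p_j q_j))`
   (a genotypic rather than breeding-value dominance parameterization);
4. additive as 2; dominance as 3, per-SNP standardized;
5. unscaled cross-products `W/√m`, `S/√m`;
6. definition 1 with user-supplied (e.g. base-population) frequencies in the
   normalizers.

This menu is this package's own concrete choice, spanning global-vs-per-SNP
weighting and breeding-value-vs-genotypic dominance; it is not claimed to
reproduce any other program's definitions byte for byte. The definition id is
recorded in every relationship-matrix output file.

## REML: two engines, one driver

Both engines return, for any θ = (σ²_a, σ²_d, σ²_e), the bundle
{y'P H_i P y, tr(P H_i), AI, logL} with H_a = Z A_g Z', H_d = Z D_g Z',
H_e = I, AI_ij = ½ (H_i P y)' P (H_j P y), and
logL = −½ [log|V| + log|X'V⁻¹X| + y'P y].

**CE engine.** Forms V = σ²_a H_a + σ²_d H_d + σ²_e I and
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻X'V⁻¹ densely (Cholesky for V and log|V|;
`pinvh` and an eigenvalue pseudo-determinant with cutoff 1e-10·λ_max for the
c × c inner matrix, honoring rank-deficient X). O(N³) per iteration.

**QM engine.** Absorbs fixed effects with M = I − X(X'X)⁻X' and solves the
2m × 2m system C u = (Z₁'My, Z₂'My), C = Z̃'MZ̃ + diag(λ_α I, λ_δ I),
λ = σ²_e/σ²-component, Z̃ = [Z T_α, Z T_δ]. The cross-product blocks are
formed once per dataset; only the ridge diagonal changes per iteration.
Quadratics follow from the standard MME identities
(P y = M(y − Z̃û)/σ²_e, α̂ = σ²_a Z₁'Py, tr(P H_a) = [mσ²_a − σ²_e tr(C^αα)]/σ⁴_a,
tr(P) from tr(PV) = N − rank X), the AI cross-terms from a matrix-free
apply-P (one extra solve per vector against the cached factorization), and the
likelihood from the Sylvester/Woodbury identities

    log|V| = (N − 2m) log σ²_e + m log σ²_a + m log σ²_d + log|C₀|,
    X'V⁻¹X = (X'X − X'Z̃ C₀⁻¹ Z̃'X) / σ²_e,   C₀ = Z̃'Z̃ + σ²_e G⁻¹,

evaluated with the same pseudo-determinant rule as CE, so the two engines
produce the *same* logL (including rank-deficient X) rather than values equal
up to a constant. tr(C^αα), tr(C^δδ) come from the explicit inverse of C;
selected-inversion shortcuts are deliberately out of scope.

**Updates.** With n_a = n_d = m (marker-effect space) and n_e = N,

    EM:  σ²_i ← σ²_i + (σ²_i)² (y'P H_i P y − tr(P H_i)) / n_i
    AI:  θ ← θ + AI⁻¹ s,   s_i = ½ (y'P H_i P y − tr(P H_i))

The divisor m for the genetic components is fixed by partition consistency:
it makes the per-SNP variance decomposition (below) sum exactly to the EM
update, hence to σ̂² at convergence. Both updates share the score s, so the
EM fixed point and the AI stationary point coincide.

**Hybrid scheme.** ≥2 EM warm-start iterations (default exactly 2), then AI.
An AI step is rejected — and replaced by an EM step for that iteration — when
the AI matrix is numerically singular (condition > 1e12) or any proposed
component is negative; after 5 consecutive rejections the run finishes
EM-only. All components are floored at 1e-10 × (current component total), so
V and C stay positive definite; estimates are therefore strictly positive
even at zero true heritability. Convergence: Σ(θ'−θ)² / Σθ'² < tolerance
(default 1e-8); default initial values var(y)/3 per component (AI can be
sensitive to starting values; EM warm-start plus this neutral start proved
robust across the test sweeps). Default iteration cap 200: moderate-signal
data converge in well under 20 hybrid iterations, while near-boundary optima
crawl along the EM path and are reported with a non-convergence flag if the
cap is hit.

Standard errors are √diag(AI⁻¹) at the converged point; heritability SEs
propagate AI⁻¹ through the ratios by the delta method (first order). When AI
is singular — typical for runs that stayed on the EM path at a boundary —
SEs are reported as missing rather than fabricated.

## Predictions and per-SNP partition

GBLUP (CE route; QM route by the block identities, equal to 1e-6 and in
practice to machine precision):

    â = σ²_a A_g Z'Py,  d̂ = σ²_d D_g Z'Py,  ĝ = â + d̂
    rel_a,i = σ²_a [A_g Z'PZ A_g]_ii / A_g,ii   (0 where A_g,ii = 0)
    rel_g,i = [var(â)+var(d̂)+2cov]_ii / (σ²_a A_g,ii + σ²_d D_g,ii)

Marker effects are back-solved as α̂ = σ²_a T_α' Z'Py (QM: directly from the
MME). Per-SNP variances take each marker's contribution to the EM update:

    σ²_{α,i} = [α̂_i² + σ²_a − σ⁴_a t_{α,i}'Z'PZ t_{α,i}] / m
             = [α̂_i² + σ²_e C^αα_ii] / m        (QM form, identical)

so Σ_i σ²_{α,i} equals the EM update of σ²_a, and the per-SNP heritabilities
σ²_{α,i}/σ²_p sum to ĥ²_α (to ~1e-6 at tolerance 1e-8 with AI convergence;
the quadratic terminal convergence of AI is what makes the residual this
small). Individual contributions are not sign-constrained; only the sum is.

## Synthetic data

The simulator draws allele frequencies ~ U(0.05, 0.5) and unlinked HWE
genotypes, places standard-normal additive and dominance effects at a random
QTL subset (default m/10 of the polymorphic markers), maps them through the
observed-frequency codings, and rescales the genetic-value vectors so their
**in-sample** variances equal the target heritabilities exactly on a
phenotypic-variance scale of 1 (residual ~ N(0, 1 − h²_α − h²_δ)). Exact
in-sample scaling removes Monte-Carlo error from the truth, which is what
recovery tests need. What it does not emulate: linkage disequilibrium,
minor-allele-frequency/effect-size coupling, population structure or
inbreeding, selection, pedigree, or multi-record/multi-trait designs — so
passing recovery tests demonstrate correctness of the estimator under the
model's own assumptions, not robustness to real-data violations of them.

The fixed fixture `make_fixture_f1` (6 individuals × 4 SNPs, one 2-level
factor, seed 20140809) is small enough for brute-force dense references to be
exact and is the anchor of the oracle tests.

## Numerical choices and problem sizes

- Pseudo-inverse/pseudo-determinant cutoff 1e-10·λ_max everywhere a
  generalized inverse appears, identically in both engines.
- AI singularity threshold: condition number 1e12.
- Positivity floor 1e-10 of the component total, referenced to the previous
  iterate so a wild step cannot poison the floor.
- Engine auto-choice: CE iff 2m > q, QM at the boundary q = 2m (QM does
  fewer large dense multiplications there).
- Test problem sizes were picked to make each scientific claim measurable on
  a single CPU: the engine-equivalence grid spans q ∈ {100, 300, 1000} ×
  m ∈ {50, 200, 1000} (20 datasets), recovery runs at q = 2000, m = 500 with
  10 seeds per condition, oracle comparisons at q ≤ 40 where explicit dense
  likelihood evaluation is trivial. Oracle-comparison fixtures require an
  interior REML optimum (all components well away from zero); seeds were
  screened for that validity condition, since at a boundary the
  unconstrained reference optimizer and the floored driver legitimately
  diverge in the tiny component.

## Known limitations

- Single trait, one record per individual, single pair of genomic random
  effects; no pedigree or epistatic terms.
- Dense linear algebra only: practical up to a few thousand individuals (CE)
  or a few thousand markers (QM) per run on one core.
- Delta-method heritability SEs are first-order and degrade when component
  SEs are comparable to the components themselves (small q).
- The six relationship definitions are a self-contained menu (see above),
  chosen for coverage of the common parameterizations rather than
  compatibility with any specific external tool.
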