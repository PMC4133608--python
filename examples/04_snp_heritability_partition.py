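"""Per-SNP effects and the heritability partition.

Each SNP's back-solved additive and dominance effects are combined
with its prediction-error variance into a per-SNP variance
contribution; dividing by the phenotypic variance gives per-SNP
heritabilities that sum exactly (to 1e-6) to the whole-genome
additive and dominance heritabilities.  With effects concentrated at
30 causal loci out of 300, the QTL markers should carry visibly more
of the heritability than the null markers.
"""

import numpy as np

from adgreml import run_greml, simulate_genotypes, simulate_phenotypes

G = simulate_genotypes(q=500, m=300, seed=5)
phenotypes, truth = simulate_phenotypes(G, h2a=0.4, h2d=0.2, n_qtl=30, seed=5)

run = run_greml(G, phenotypes, method="auto")
t, h = run.snp_table, run.heritabilities

print(f"sum_i h2_alpha_i = {t.h2_alpha_i.sum():.8f}  vs  h2_alpha = {h.h2_alpha:.8f}")
print(f"sum_i h2_delta_i = {t.h2_delta_i.sum():.8f}  vs  h2_delta = {h.h2_delta:.8f}")

is_qtl = np.zeros(len(t.marker_ids), dtype=bool)
is_qtl[truth.qtl_indices] = True
print(f"\nmean per-SNP additive h2 at QTLs:      {t.h2_alpha_i[is_qtl].mean():.2e}")
print(f"mean per-SNP additive h2 at null SNPs: {t.h2_alpha_i[~is_qtl].mean():.2e}")

top = np.argsort(t.h2_alpha_i)[::-1][:5]
print("\ntop SNPs by additive heritability:")
for i in top:
    flag = "QTL" if is_qtl[i] else "   "
    print(f"  {t.marker_ids[i]} {flag}  alpha_hat={t.alpha_hat[i]:+.4f}  "
          f"h2_alpha_i={t.h2_alpha_i[i]:.2e}")
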