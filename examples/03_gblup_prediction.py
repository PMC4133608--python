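"""GBLUP prediction for genotyped but unphenotyped individuals.

The last 60 of 600 individuals carry genotypes only (a validation
set).  After GREML, every individual — phenotyped or not — receives a
predicted breeding value (a_hat), dominance deviation (d_hat) and
genotypic value (g_hat = a_hat + d_hat), each with a reliability in
[0, 1] (the squared correlation between prediction and true value).
Validation reliabilities are lower than training ones because those
individuals contribute no records of their own.
"""

import numpy as np

from adgreml import run_greml, simulate_genotypes, simulate_phenotypes

G = simulate_genotypes(q=600, m=400, seed=11)
phenotypes, truth = simulate_phenotypes(G, h2a=0.35, h2d=0.15, seed=11,
                                        n_validation=60)

run = run_greml(G, phenotypes, method="auto")
g = run.gblup

train = np.array(g.sets) == "training"
print(f"training n={train.sum()}, validation n={(~train).sum()}")
print(f"mean rel_a training   = {np.mean(g.rel_a[train]):.3f}")
print(f"mean rel_a validation = {np.mean(g.rel_a[~train]):.3f}")
r = np.corrcoef(g.a_hat[~train], truth.a[~train])[0, 1]
print(f"cor(a_hat, true a) in validation = {r:.3f} "
      f"(~sqrt(mean reliability) = {np.sqrt(np.mean(g.rel_a[~train])):.3f})")
print("\nfirst validation individuals:")
for i in np.flatnonzero(~train)[:5]:
    print(f"  {g.individual_ids[i]}  a_hat={g.a_hat[i]:+.3f} (rel {g.rel_a[i]:.2f})  "
          f"d_hat={g.d_hat[i]:+.3f} (rel {g.rel_d[i]:.2f})  g_hat={g.g_hat[i]:+.3f}")
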