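"""Community-ecology statistics on a small cover table.

Six transects surveyed by two methods: Bray-Curtis dissimilarity, percent
similarity, ANOSIM with method as the grouping factor, a 2-D nMDS
ordination, and a one-way ANOVA + Tukey HSD on coral cover.
"""

import numpy as np

from reefspectra import ecostats as es

rng = np.random.default_rng(0)
true_profiles = rng.dirichlet([8, 4, 3, 2, 6], size=3)  # 3 transects
# each method measures each transect with its own sampling noise
rows, ids, method = [], [], []
for m in ("HS", "PQ"):
    for t, p in enumerate(true_profiles):
        rows.append(rng.dirichlet(400 * p))
        ids.append(f"{m}-T{t+1}")
        method.append(m)
cover = np.array(rows)

dist = es.bray_curtis(cover, ids=ids)
print("Bray-Curtis, matched transect pairs:",
      [round(dist.values[i, i + 3], 3) for i in range(3)])
print("percent similarity of first pair:",
      round(es.similarity_percent(dist.values[0, 3]), 1))

res = es.anosim(dist, method, n_permutations=999, seed=1)
print(f"ANOSIM: R = {res.R:.3f}, significance = {res.significance:.3f} "
      f"({res.method}, {res.n_permutations} relabelings)")
# R near 0 / significance >> 0.05: the methods measure the same communities

nm = es.nmds(dist, k=2, n_restarts=10, seed=2)
print(f"nMDS stress: {nm.stress:.4f} (converged: {nm.converged})")

coral = cover[:, 0]
av = es.anova_tukey(coral, method)
print(f"ANOVA on coral cover: F({av.df_between},{av.df_within}) = {av.F:.2f}, "
      f"p = {av.p:.3f}")
for pair, diff, p_adj in av.tukey:
    print(f"  Tukey {pair[0]} vs {pair[1]}: mean diff {diff:+.4f}, "
          f"adjusted p = {p_adj:.3f}")
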