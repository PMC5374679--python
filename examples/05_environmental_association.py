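"""Covariance-controlled gene-environment association.

Builds the composite climate axis env1 by PCA over elevation plus 19
bioclim covariates, estimates the neutral among-population covariance
Omega from a 10,000-SNP subsample, and scores every SNP's support Z (in
[0, 0.5]) and Bayes factor for a non-zero effect of env1.
"""

import numpy as np

import poolcline as pc

ds = pc.simulate_gradient_experiment(pc.SimulationConfig(seed=42, n_snps=20_000))
comp = pc.env_pca(ds.env)
print(f"env1 explains {100 * comp.variance_fraction:.1f}% of the "
      "environmental variance (altitude dominates the table)")

freqs, depths, idx = pc.pool_frequencies(ds.table)
model = pc.estimate_covariance(freqs, n_snps=10_000, seed=1)
print(f"Omega convergence between two subsamples: {model.convergence:.3f} "
      "(max |corr difference|; small = stable)")

scores = pc.env_score(freqs, depths, model, comp)
n_top = int(round(0.01 * len(scores)))
top = scores[scores["rank"] <= n_top]
print(f"top 1% = {n_top} SNPs; {int((top.z_support > 0.49).sum())} of them "
      "reach Z > 0.49 (0.5 is maximal support)")

sel = set(zip(ds.truth.scaffold[ds.truth.selected],
              ds.truth.position[ds.truth.selected]))
keys = np.array(list(zip(ds.table.scaffold[idx], ds.table.position[idx])),
                dtype=object)
is_sel = np.array([tuple(k) in sel for k in keys])
rec = (scores["rank"].to_numpy() <= n_top)[is_sel].mean()
print(f"{100 * rec:.0f}% of the truly selected loci rank in the top 1% -- "
      "the recovery rate under a strong (near-fixation) cline.")
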