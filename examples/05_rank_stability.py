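"""Rank genotypes across environments and quantify rank instability.

Ranks are taken on posterior-mean genotype effects within each
environment; each genotype's boxplot statistic is the multiset of its
pairwise absolute rank changes between environments.
"""

import numpy as np

from clonegxe import (
    MCMCOptions, ModelSpec, TrialDesign, VarianceComponents,
    generate_trial, gibbs_sample, rank_change_stats, rank_genotypes,
    standardize_phenotypes,
)
from clonegxe.ranking import effects_frame


def uniform_corr(n, r):
    m = np.full((n, n), r)
    np.fill_diagonal(m, 1.0)
    return m


vc = VarianceComponents(
    n_sites=3, sigma2_pop=0.3, sigma2_gen=0.4, sigma2_resid=0.6,
    corr_pop=uniform_corr(3, 0.95), corr_gen=uniform_corr(3, 0.6),
)
trial = generate_trial(TrialDesign(n_sites=3, n_populations=8, genotypes_per_population=3), vc, seed=9)
std, _ = standardize_phenotypes(trial)
chains = gibbs_sample(std, ModelSpec("DBH"),
                      MCMCOptions(iterations=3000, burn_in=500, thinning=5, seed=9))

rt = rank_genotypes(effects_frame(chains))
stats = rank_change_stats(rt)
print("genotype ranks per site (1 = best) and average clonal rank:")
table = rt.ranks.copy()
table["avg"] = rt.average
print(table.sort_values("avg").head(8))
per_geno = stats.drop_duplicates("genotype")[["genotype", "avg_rank", "min", "median", "max"]]
print("\npairwise rank-change dispersion (first genotypes by average rank):")
print(per_geno.head(8).to_string(index=False))
print("-> a genotype with median rank change near 0 performs consistently "
      "everywhere; large max changes mark environment-sensitive genotypes "
      "(with genotype-level cross-site correlation 0.6 some instability is expected).")
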