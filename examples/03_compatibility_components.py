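"""Compatibility Components from two replicate diallels.

Pollination profiles -> pairwise-complete Euclidean distances -> unscaled
PCA, then cross-replicate matching (component ORDER is not stable between
years) and Ward clustering.
"""

from sicomp.components import cluster_genotypes, diallel_components, match_components
from sicomp.simulate import SimConfig, simulate_diallel, simulate_population

cfg = SimConfig(seed=1)
pop = simulate_population(cfg)
r2013 = diallel_components(simulate_diallel(pop, cfg, "2013"), k=4)
r2015 = diallel_components(simulate_diallel(pop, cfg, "2015"), k=4)

for tag, r in (("2013", r2013), ("2015", r2015)):
    pct = ", ".join(f"{100 * v:.0f}%" for v in r.cumulative_variance)
    print(f"{tag}: cumulative variance of PC1-4 = {pct}")

match, cc2013, cc2015 = match_components(r2013, r2015)
print("component pairing 2013->2015:", match.mapping)
print("matched |correlation|:",
      {k: round(v, 2) for k, v in match.correlation.items()})
# a mapping like {1: 1, 2: 2, 3: 4, 4: 3} means the 3rd and 4th components
# swapped order between years — the same latent factor, different rank.

clusters = cluster_genotypes(cc2013.scores, n_clusters=4)
print("cluster sizes:", clusters.value_counts().sort_index().to_dict())
# genotypes with similar pollination behaviour (similar SI genotypes)
# land in the same cluster.
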