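"""Genome-wide single-marker association of a Compatibility Component.

MAF filter -> structure covariates -> per-marker OLS -> Bonferroni line;
the peak should sit near a true SI locus.
"""

from sicomp.components import diallel_components, match_components
from sicomp.gwas import GenotypeTable, maf_filter, manhattan_export, single_marker_scan, structure_covariates
from sicomp.simulate import SimConfig, simulate_diallel, simulate_population

cfg = SimConfig(seed=1)
pop = simulate_population(cfg)
r1 = diallel_components(simulate_diallel(pop, cfg, "2013"), k=4)
r2 = diallel_components(simulate_diallel(pop, cfg, "2015"), k=4)
_, cc1, _ = match_components(r1, r2)

gtable = GenotypeTable(
    dosages=pop.dosages(),
    marker_map=pop.marker_map.set_index("marker")[["linkage_group", "position_cM"]],
)
kept, report = maf_filter(gtable, threshold=0.05)
print(f"{len(gtable.markers)} markers, {len(kept.markers)} kept after MAF filter")

covs = structure_covariates(kept, n_axes=2)
res = single_marker_scan(cc1.scores["CC1"], kept, covariates=covs,
                         phenotype_label="2013/CC1")
print(f"Bonferroni threshold -log10(0.05/{res.m_tested}) = {res.threshold:.2f}")

manhattan = manhattan_export(res, kept.marker_map)
top = manhattan.nlargest(5, "neg_log10_p")
print(top.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("true loci: S on LG 1 at 20.0 cM, Z on LG 2 at 54.0 cM")
# markers above the threshold cluster on the linkage groups carrying the
# SI loci; their positions localize S and Z to within a few cM.
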