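"""Self-contained evaluation runs on simulated study populations.

These helpers wire the full method together for benchmarking on the
default study conditions: locus-localization trials (can the association
stage place S and Z within a map window from diallel scores alone?) and
null-calibration trials (is the scan's type-I error at its nominal level
when the phenotype carries no genetic signal?).
"""

from __future__ import annotations

import numpy as np

from sicomp import components as cc
from sicomp import gwas as gw
from sicomp import simulate as sim
from sicomp.pipeline import localization_summary


def _scans_for_population(pop, cfg, n_axes=2, k=4, replicates=("2013", "2015")):
    diallels = {t: sim.simulate_diallel(pop, cfg, t) for t in replicates}
    results = {t: cc.diallel_components(d, k=k) for t, d in diallels.items()}
    tags = list(replicates)
    _, m1, m2 = cc.match_components(results[tags[0]], results[tags[1]],
                                    n_components=k)
    matched = {tags[0]: m1, tags[1]: m2}
    gtable = gw.GenotypeTable(
        dosages=pop.dosages(),
        marker_map=pop.marker_map.set_index("marker")[
            ["linkage_group", "position_cM"]
        ],
    )
    kept, _ = gw.maf_filter(gtable)
    covs = gw.structure_covariates(kept, n_axes=n_axes)
    scans = {
        (t, comp): gw.single_marker_scan(
            r.scores[comp], kept, covariates=covs,
            phenotype_label=f"{t}/{comp}",
        )
        for t, r in matched.items()
        for comp in r.scores.columns
    }
    return matched, scans, kept


def localization_trial(seed: int, window_cM: float = 10.0,
                       n_axes: int = 2) -> dict:
    """One full simulate→CC→GWAS run under the default study conditions;
    returns the per-locus localization summary."""
    cfg = sim.SimConfig(seed=seed)
    pop = sim.simulate_population(cfg)
    matched, scans, _ = _scans_for_population(pop, cfg, n_axes=n_axes)
    return localization_summary(pop, matched, scans, window_cM=window_cM)


def localization_success(seeds, window_cM: float = 10.0) -> dict[str, int]:
    """Count, per SI locus, the seeds whose best-associated component's
    genome-wide top marker falls within the window of the true position."""
    hits: dict[str, int] = {}
    for seed in seeds:
        loc = localization_trial(seed, window_cM=window_cM)
        for name, entry in loc.items():
            hits[name] = hits.get(name, 0) + int(entry["hit"])
    return hits


def null_calibration_trial(seed: int, alpha: float = 0.05,
                           n_axes: int = 2) -> tuple[float, int]:
    """Scan a phenotype drawn independently of every marker on the default
    simulated population; returns (fraction of markers with p < alpha,
    number of markers tested)."""
    cfg = sim.SimConfig(seed=seed)
    pop = sim.simulate_population(cfg)
    gtable = gw.GenotypeTable(
        dosages=pop.dosages(),
        marker_map=pop.marker_map.set_index("marker")[
            ["linkage_group", "position_cM"]
        ],
    )
    kept, _ = gw.maf_filter(gtable)
    covs = gw.structure_covariates(kept, n_axes=n_axes)
    rng = np.random.default_rng(seed + 500_000)
    import pandas as pd

    pheno = pd.Series(
        rng.normal(size=len(kept.genotype_ids)), index=kept.genotype_ids
    )
    res = gw.single_marker_scan(pheno, kept, covariates=covs, alpha=alpha)
    tested = res.table[res.table["reason"].isin(["ok", "perfect fit (p capped)"])]
    frac = float((tested["p"] < alpha).mean())
    return frac, len(tested)
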