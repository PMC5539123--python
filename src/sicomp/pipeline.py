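"""End-to-end orchestration: simulate or ingest replicate diallels, run QC,
SI₅₀ tables, Compatibility-Component derivation with cross-replicate
matching, per-CC association scans, and (in simulation mode) a
truth-based locus-localization summary — all under one seeded config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sicomp import diallel as dm
from sicomp import components as cc
from sicomp import gwas as gw
from sicomp import si50 as si
from sicomp import simulate as sim
from sicomp.errors import ConfigError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class CCOptions:
    profile_mode: str = "both"
    k_components: int = 4
    n_clusters: int = 4
    center: bool = True


@dataclass
class GWASOptions:
    alpha: float = 0.05
    maf: float = 0.05
    structure_axes: int = 2


@dataclass
class RunConfig:
    """Validated configuration of a full run.

    Exactly one input mode: ``simulate`` (a :class:`sicomp.simulate.SimConfig`
    drives data generation) or ``files`` (paths of diallel matrices per
    replicate tag, a family metadata table and a genotype TSV).
    """

    seed: int
    outdir: str
    mode: str = "simulate"
    replicates: tuple[str, ...] = ("2013", "2015")
    sim: sim.SimConfig | None = None
    diallel_files: dict[str, str] = field(default_factory=dict)
    families_file: str | None = None
    genotypes_file: str | None = None
    cc: CCOptions = field(default_factory=CCOptions)
    gwas: GWASOptions = field(default_factory=GWASOptions)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed: field is required")
        if self.mode not in ("simulate", "files"):
            raise ConfigError(f"mode: must be 'simulate' or 'files', got {self.mode!r}")
        if not self.replicates:
            raise ConfigError("replicates: need at least one replicate tag")
        if self.mode == "simulate":
            if self.sim is None:
                self.sim = sim.SimConfig(seed=self.seed)
            self.sim.validate()
        else:
            if set(self.diallel_files) != set(self.replicates):
                raise ConfigError(
                    "files.diallels: one path per replicate tag is required"
                )
            if self.genotypes_file is None:
                raise ConfigError("files.genotypes: field is required")
        if self.cc.profile_mode not in cc.PROFILE_MODES:
            raise ConfigError(f"cc.profile_mode: must be one of {cc.PROFILE_MODES}")
        if self.cc.k_components < 1 or self.cc.n_clusters < 1:
            raise ConfigError("cc: k_components and n_clusters must be >= 1")
        if not 0 < self.gwas.alpha < 1:
            raise ConfigError("gwas.alpha: must be in (0, 1)")
        if not 0 <= self.gwas.maf <= 0.5:
            raise ConfigError("gwas.maf: must be in [0, 0.5]")
        if self.gwas.structure_axes < 0:
            raise ConfigError("gwas.structure_axes: must be >= 0")

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed, "mode": self.mode,
            "replicates": list(self.replicates),
            "sim": asdict(self.sim) if self.sim else None,
            "cc": asdict(self.cc), "gwas": asdict(self.gwas),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; defaults are filled and
    every range invariant enforced with a per-field message."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in raw:
        raise ConfigError("seed: field is required")
    sim_cfg = None
    if "simulate" in raw:
        s = dict(raw["simulate"])
        s.setdefault("seed", raw["seed"])
        if "family_sizes" in s:
            s["family_sizes"] = tuple(s["family_sizes"])
        if "loci" in s:
            s["loci"] = tuple(sim.SILocusSpec(**l) for l in s["loci"])
        try:
            sim_cfg = sim.SimConfig(**s)
        except TypeError as exc:
            raise ConfigError(f"simulate: {exc}") from exc
    files = raw.get("files", {})
    cfg = RunConfig(
        seed=raw["seed"],
        outdir=str(raw.get("outdir", "sicomp_out")),
        mode=raw.get("mode", "simulate"),
        replicates=tuple(str(t) for t in raw.get("replicates", ("2013", "2015"))),
        sim=sim_cfg,
        diallel_files={str(k): v for k, v in files.get("diallels", {}).items()},
        families_file=files.get("families"),
        genotypes_file=files.get("genotypes"),
        cc=CCOptions(**raw.get("cc", {})),
        gwas=GWASOptions(**raw.get("gwas", {})),
        log_level=raw.get("log_level", "INFO"),
    )
    cfg.validate()
    logger.info("resolved config: %s", cfg)
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    payload = {
        "seed": cfg.seed, "outdir": cfg.outdir, "mode": cfg.mode,
        "replicates": list(cfg.replicates),
        "cc": asdict(cfg.cc), "gwas": asdict(cfg.gwas),
        "log_level": cfg.log_level,
    }
    if cfg.mode == "simulate" and cfg.sim is not None:
        s = asdict(cfg.sim)
        s["family_sizes"] = list(s["family_sizes"])
        s["loci"] = [asdict(l) for l in cfg.sim.loci]
        s["epistatic_rejections"] = [list(e) for e in cfg.sim.epistatic_rejections]
        payload["simulate"] = s
    else:
        payload["files"] = {
            "diallels": dict(cfg.diallel_files),
            "families": cfg.families_file,
            "genotypes": cfg.genotypes_file,
        }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    seed: int
    config_hash: str
    qc: dict
    si50_tables: dict[str, pd.DataFrame]
    variance: dict[str, list[float]]
    match: dict | None
    clusters: dict[str, int]
    significant: dict[str, int]  # "<replicate>/<component>" -> count
    localization: dict | None

    def to_json(self) -> str:
        def _round(o):
            if isinstance(o, (float, np.floating)):
                return round(float(o), 6)
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, (bool, np.bool_)):
                return bool(o)
            if isinstance(o, dict):
                return {k: _round(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_round(v) for v in o]
            return o

        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "qc": _round(self.qc),
            "si50": {
                tag: _round(t.to_dict(orient="records"))
                for tag, t in self.si50_tables.items()
            },
            "variance_fraction": _round(self.variance),
            "component_match": _round(self.match),
            "cluster_sizes": _round(self.clusters),
            "significant_markers": _round(self.significant),
            "localization": _round(self.localization),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _header(cfg: RunConfig) -> str:
    from sicomp import __version__

    return (
        f"# sicomp {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)


def localization_summary(
    pop: sim.Population,
    matched: dict[str, cc.CCResult],
    scans: dict[tuple[str, str], gw.AssociationResult],
    window_cM: float = 10.0,
) -> dict:
    """For each SI locus, find the matched component best associated with
    it and ask whether that component's genome-wide top marker maps within
    ``window_cM`` of the locus.

    A locus's best-associated component is the (replicate, component) scan
    with the strongest −log₁₀p among markers within ``window_cM`` of the
    locus's true position — the same logic by which a study assigns
    components to loci from their association signal at known candidate
    regions.  The hit test is not circular: it asks whether that scan's
    GLOBAL maximum lies in the window, and a stronger peak anywhere else
    in the genome makes the locus a miss.
    """
    out = {}
    mmap = pop.marker_map.set_index("marker")
    for locus in pop.loci:
        lg_num = pd.to_numeric(mmap["linkage_group"], errors="coerce")
        near = (lg_num == locus.linkage_group) & (
            (mmap["position_cM"] - locus.position_cM).abs() <= window_cM
        )
        best = None
        for (tag, comp), scan in scans.items():
            t = scan.table[
                scan.table["reason"].isin(["ok", "perfect fit (p capped)"])
            ]
            near_t = t.loc[t.index.intersection(mmap.index[near])]
            peak = float(near_t["neg_log10_p"].max()) if len(near_t) else 0.0
            if best is None or peak > best[0]:
                best = (peak, tag, comp, t)
        near_peak, tag, comp, t = best
        top = t["neg_log10_p"].idxmax()
        top_lg = mmap.loc[top, "linkage_group"]
        top_cm = float(mmap.loc[top, "position_cM"])
        try:
            on_lg = int(top_lg) == locus.linkage_group
        except (TypeError, ValueError):
            on_lg = False  # unmapped marker
        dist = abs(top_cm - locus.position_cM) if on_lg else np.inf
        out[locus.name] = {
            "true_lg": locus.linkage_group,
            "true_cM": locus.position_cM,
            "best_component": f"{tag}/{comp}",
            "near_peak_neg_log10_p": near_peak,
            "top_marker": str(top),
            "top_lg": str(top_lg),
            "top_cM": top_cm,
            "top_neg_log10_p": float(t.loc[top, "neg_log10_p"]),
            "distance_cM": None if not np.isfinite(dist) else float(dist),
            "hit": bool(on_lg and dist <= window_cM),
        }
    return out


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and write all intermediate artifacts to
    ``cfg.outdir``.  Deterministic byte-for-byte under a fixed seed."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    # -- stage: inputs ---------------------------------------------------
    pop = None
    diallels: dict[str, dm.DiallelMatrix] = {}
    if cfg.mode == "simulate":
        pop = sim.simulate_population(cfg.sim)
        sim.write_genotypes(pop, outdir / "genotypes.tsv")
        sim.write_truth(pop, outdir / "truth.json")
        sim.write_families(pop, outdir / "families.tsv")
        for tag in cfg.replicates:
            d = sim.simulate_diallel(pop, cfg.sim, tag)
            diallels[tag] = d
            dm.write_diallel(d, outdir / f"diallel_{tag}.tsv")
        gtable = gw.GenotypeTable(
            dosages=pop.dosages(),
            marker_map=pop.marker_map.set_index("marker")[
                ["linkage_group", "position_cM"]
            ],
        )
    else:
        for tag in cfg.replicates:
            diallels[tag] = dm.read_diallel(
                cfg.diallel_files[tag], families=cfg.families_file,
                replicate_tag=tag,
            )
        gtable = gw.read_genotypes(cfg.genotypes_file)

    # -- stage: QC -------------------------------------------------------
    qc: dict = {"reciprocal_flags": {}, "replicate_correlation": {}}
    for tag, d in diallels.items():
        flags = dm.reciprocal_flags(d)
        qc["reciprocal_flags"][tag] = len(flags)
        _write_tsv(
            pd.DataFrame(
                [(f.pair[0], f.pair[1], f.score_fw, f.score_rev,
                  f.abs_difference) for f in flags],
                columns=["female_id", "male_id", "score_fw", "score_rev",
                         "abs_difference"],
            ),
            outdir / f"reciprocal_flags_{tag}.tsv", cfg,
        )
    tags = list(cfg.replicates)
    for i in range(len(tags)):
        for j in range(i + 1, len(tags)):
            r, n_shared = dm.replicate_correlation(diallels[tags[i]], diallels[tags[j]])
            qc["replicate_correlation"][f"{tags[i]}~{tags[j]}"] = {
                "r": r, "n_shared": n_shared,
            }
    logger.info("QC: %s", qc)

    # -- stage: SI50 -----------------------------------------------------
    si50_tables = {}
    for tag, d in diallels.items():
        table = si.group_si50(d)
        si50_tables[tag] = table
        _write_tsv(table, outdir / f"si50_{tag}.tsv", cfg)

    # -- stage: components ----------------------------------------------
    results = {
        tag: cc.diallel_components(
            d, k=cfg.cc.k_components, mode=cfg.cc.profile_mode,
            center=cfg.cc.center,
        )
        for tag, d in diallels.items()
    }
    variance = {
        tag: [float(v) for v in r.variance_fraction] for tag, r in results.items()
    }
    match_info = None
    if len(tags) >= 2:
        match, m1, m2 = cc.match_components(
            results[tags[0]], results[tags[1]],
            n_components=cfg.cc.k_components,
        )
        matched = {tags[0]: m1, tags[1]: m2}
        match_info = {
            "mapping": {str(k): v for k, v in match.mapping.items()},
            "abs_correlation": {str(k): v for k, v in match.correlation.items()},
            "sign": {str(k): v for k, v in match.sign.items()},
        }
    else:
        matched = {tags[0]: results[tags[0]]}
    for tag, r in matched.items():
        _write_tsv(r.scores, outdir / f"cc_scores_{tag}.tsv", cfg, index=True)
    _write_tsv(
        pd.DataFrame(variance).T.rename_axis("replicate"),
        outdir / "cc_variance.tsv", cfg, index=True,
    )

    clusters = cc.cluster_genotypes(
        matched[tags[0]].scores, n_clusters=cfg.cc.n_clusters
    )
    _write_tsv(clusters.rename_axis("genotype_id").reset_index(),
               outdir / "clusters.tsv", cfg)
    cluster_sizes = {
        str(k): int(v) for k, v in clusters.value_counts().sort_index().items()
    }

    # -- stage: association ---------------------------------------------
    kept, maf_report = gw.maf_filter(gtable, threshold=cfg.gwas.maf)
    _write_tsv(maf_report.rename_axis("marker").reset_index(),
               outdir / "maf_report.tsv", cfg)
    covs = gw.structure_covariates(kept, n_axes=cfg.gwas.structure_axes)
    scans: dict[tuple[str, str], gw.AssociationResult] = {}
    significant = {}
    for tag, r in matched.items():
        for comp in r.scores.columns:
            res = gw.single_marker_scan(
                r.scores[comp], kept, covariates=covs, alpha=cfg.gwas.alpha,
                phenotype_label=f"{tag}/{comp}",
            )
            scans[(tag, comp)] = res
            manhattan = gw.manhattan_export(res, kept.marker_map)
            _write_tsv(manhattan, outdir / f"gwas_{tag}_{comp}.tsv", cfg)
            sig = manhattan[manhattan["above_threshold"]]
            significant[f"{tag}/{comp}"] = int(len(sig))
            _write_tsv(sig, outdir / f"gwas_{tag}_{comp}_significant.tsv", cfg)
    logger.info("significant markers per scan: %s", significant)

    # -- stage: localization against truth (simulation mode only) -------
    localization = None
    if pop is not None:
        localization = localization_summary(pop, matched, scans)
        logger.info("localization: %s", localization)

    report = RunReport(
        seed=cfg.seed,
        config_hash=cfg.config_hash(),
        qc=qc,
        si50_tables=si50_tables,
        variance=variance,
        match=match_info,
        clusters=cluster_sizes,
        significant=significant,
        localization=localization,
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
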