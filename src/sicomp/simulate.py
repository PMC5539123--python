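"""Forward simulation of a multi-locus gametophytic SI population.

The simulator emulates a grass-type self-incompatibility (SI) study
population: half-sib families produced by pollinating a small set of
founder mothers with a shared pollen cloud, genotyped at biallelic SNP
markers spread over seven linkage groups, with the SI loci (by default the
complementary S and Z loci) embedded at known map positions.

The generative rule is the complementary gametophytic model: a pollen
gamete is rejected on a stigma if and only if, at EVERY SI locus, the
gamete's allele is present in the stigma's diploid genotype.  With two
heterozygous parents this yields cross compatibilities of exactly
0, 1/2, 3/4 or 1.  Gametes are produced by meiosis with recombination
under Haldane's map function (no interference), so markers close to an SI
locus co-segregate with its alleles — the signal the association stage is
designed to recover.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sicomp.diallel import DiallelMatrix, GenotypeLabel
from sicomp.errors import ConfigError, UnsatisfiableConfigError, ValidationError


@dataclass(frozen=True)
class SILocusSpec:
    """One self-incompatibility locus: a name, a map position and the size
    of its founder allelic series."""

    name: str
    linkage_group: int
    position_cM: float
    n_founder_alleles: int = 6

    def validate(self, n_lgs: int, lg_length: float) -> None:
        if not 1 <= self.linkage_group <= n_lgs:
            raise ConfigError(
                f"locus {self.name}: linkage_group must be in 1..{n_lgs}"
            )
        if not 0 <= self.position_cM <= lg_length:
            raise ConfigError(f"locus {self.name}: position_cM outside the map")
        if self.n_founder_alleles < 2:
            raise ConfigError(f"locus {self.name}: need at least 2 founder alleles")


@dataclass
class SIGenotypeRecord:
    """A diploid individual: SI alleles per locus on each haplotype, plus
    the two marker haplotypes (0/1 per marker, map order)."""

    id: str
    family: str
    si_hap: dict[str, tuple[int, int]]  # locus -> (allele on hap 0, allele on hap 1)
    haplotypes: tuple[np.ndarray, np.ndarray]

    def si_genotype(self, locus: str) -> frozenset[int]:
        """Unordered diploid allele pair at an SI locus."""
        if locus not in self.si_hap:
            raise ValidationError(f"record {self.id}: no alleles for locus {locus!r}")
        return frozenset(self.si_hap[locus])

    def is_heterozygous(self, locus: str) -> bool:
        a, b = self.si_hap[locus]
        return a != b

    def dosages(self) -> np.ndarray:
        return self.haplotypes[0].astype(np.int16) + self.haplotypes[1]


_DEFAULT_LOCI = (
    SILocusSpec("S", linkage_group=1, position_cM=20.0),
    SILocusSpec("Z", linkage_group=2, position_cM=54.0),
)


@dataclass
class SimConfig:
    """Study conditions for the simulated population.

    Defaults mirror the diallel study design the analysis targets: four
    half-sib families of 13 (52 plants) sharing a polycross pollen cloud,
    S on LG 1 at 20 cM and Z on LG 2 at 54 cM, ~2,100 biallelic markers
    over seven 100-cM linkage groups, ordinal scoring noise, year-replicate
    noise, ~8% missing cells and a small self-fertility leak.  Before the
    polycross, the founder base is expanded and recombined through
    ``burnin_generations`` of SI-respecting half-sib family mating (an
    advanced breeding population accumulates historical recombination this
    way; without it marker–locus LD would span whole linkage groups and no
    method could localize the loci to a few cM).

    The noise and diversity defaults are calibrated against the observable
    summaries such a study reports: a between-year replicate correlation
    near 0.68, within-family SI₅₀ well above between-family SI₅₀, and the
    possibility of family pairs that are almost fully cross-compatible
    (maternal parents sharing no SI alleles).
    """

    seed: int
    n_families: int = 4
    family_sizes: tuple[int, ...] = (13, 13, 13, 13)
    n_founders: int = 12
    burnin_generations: int = 10
    burnin_size: int = 80
    # mothers per burn-in generation; None = panmictic.  A small number
    # reproduces half-sib family selection (the breeding scheme behind
    # advanced forage populations), which narrows SI allele diversity and
    # builds the lineage structure seen in real diallels.
    burnin_mothers: int | None = 6
    loci: tuple[SILocusSpec, ...] = _DEFAULT_LOCI
    n_linkage_groups: int = 7
    lg_length_cM: float = 100.0
    markers_per_lg: int = 300
    score_noise_sd: float = 0.75
    replicate_noise_sd: float = 1.75
    missing_rate: float = 0.08
    self_fertility_leak: float = 0.02
    # optional epistatic pollen-lethality rule: gametes carrying any listed
    # (locus_a, allele_a, locus_b, allele_b) combination are rejected
    epistatic_rejections: tuple[tuple[str, int, str, int], ...] = ()
    max_attempts: int = 5000

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_families < 1 or len(self.family_sizes) != self.n_families:
            raise ConfigError("family_sizes length must equal n_families")
        if any(s < 1 for s in self.family_sizes):
            raise ConfigError("family sizes must be positive")
        if self.n_founders < self.n_families + 1:
            raise ConfigError("need more founders than families (mothers + cloud)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0 <= self.self_fertility_leak < 1:
            raise ConfigError("self_fertility_leak must be in [0, 1)")
        if self.score_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ConfigError("noise sds must be non-negative")
        if self.markers_per_lg < 0 or self.n_linkage_groups < 1:
            raise ConfigError("marker map spec out of range")
        if self.burnin_generations < 0:
            raise ConfigError("burnin_generations must be >= 0")
        if self.burnin_generations > 0 and self.burnin_size < self.n_families + 1:
            raise ConfigError("burnin_size must exceed n_families")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ConfigError("SI locus names must be unique")
        pos_seen = set()
        for locus in self.loci:
            locus.validate(self.n_linkage_groups, self.lg_length_cM)
            key = (locus.linkage_group, locus.position_cM)
            if key in pos_seen:
                raise ConfigError("distinct SI loci must have distinct positions")
            pos_seen.add(key)


# ---------------------------------------------------------------------------
# Compatibility rule
# ---------------------------------------------------------------------------

def compatible_fraction(
    pollen: SIGenotypeRecord,
    stigma: SIGenotypeRecord,
    loci: Sequence[SILocusSpec] | Sequence[str] | None = None,
    epistatic_rejections: Iterable[tuple[str, int, str, int]] = (),
) -> float:
    """Expected fraction of the pollen parent's gametes accepted by a stigma.

    Gametic SI-allele combinations of the pollen parent are enumerated as
    equiprobable (the SI loci are assumed unlinked).  A gamete is
    incompatible iff at every SI locus its allele occurs in the stigma's
    diploid genotype (complementary action); optional epistatic rejection
    pairs additionally kill gametes carrying a listed two-locus allele
    combination.  Note the rule is not symmetric in (pollen, stigma).
    """
    if loci is None:
        names = list(pollen.si_hap)
    else:
        names = [l.name if isinstance(l, SILocusSpec) else l for l in loci]
    for name in names:
        if name not in pollen.si_hap:
            raise ValidationError(f"pollen record lacks locus {name!r}")
        if name not in stigma.si_hap:
            raise ValidationError(f"stigma record lacks locus {name!r}")
    stigma_geno = {name: stigma.si_genotype(name) for name in names}
    n_incomp = 0
    combos = list(itertools.product(*[pollen.si_hap[name] for name in names]))
    for combo in combos:
        gamete = dict(zip(names, combo))
        if _gamete_rejected(gamete, stigma_geno, epistatic_rejections):
            n_incomp += 1
    return 1.0 - n_incomp / len(combos)


def _gamete_rejected(
    gamete: dict[str, int],
    stigma_geno: dict[str, frozenset[int]],
    epistatic_rejections: Iterable[tuple[str, int, str, int]],
) -> bool:
    for la, aa, lb, ab in epistatic_rejections:
        if gamete.get(la) == aa and gamete.get(lb) == ab:
            return True
    return all(gamete[name] in stigma_geno[name] for name in stigma_geno)


# ---------------------------------------------------------------------------
# Genome bookkeeping for meiosis
# ---------------------------------------------------------------------------

@dataclass
class _LGLayout:
    """Sites (markers + SI loci) of one linkage group in map order, with
    Haldane recombination fractions between adjacent sites."""

    marker_global_idx: np.ndarray  # global marker indices, map order
    is_marker: np.ndarray  # per site
    site_marker_idx: np.ndarray  # per marker site, global marker index
    si_site: dict[str, int]  # locus name -> site index
    recomb: np.ndarray  # len n_sites-1


def _haldane(d_cM: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


@dataclass
class _Genome:
    n_markers: int
    layouts: list[_LGLayout]


def _build_genome(marker_map: pd.DataFrame, loci: Sequence[SILocusSpec],
                  n_lgs: int) -> _Genome:
    layouts = []
    for lg in range(1, n_lgs + 1):
        sel = np.flatnonzero(marker_map["linkage_group"].to_numpy() == lg)
        mpos = marker_map["position_cM"].to_numpy()[sel]
        order = np.argsort(mpos, kind="stable")
        sel, mpos = sel[order], mpos[order]
        si_here = [l for l in loci if l.linkage_group == lg]
        pos = np.concatenate([mpos, [l.position_cM for l in si_here]])
        kind = np.concatenate(
            [np.ones(len(mpos), bool), np.zeros(len(si_here), bool)]
        )
        src = np.concatenate([sel, -np.ones(len(si_here), int)])
        si_names = [None] * len(mpos) + [l.name for l in si_here]
        o = np.argsort(pos, kind="stable")
        pos, kind, src = pos[o], kind[o], src[o]
        names = [si_names[k] for k in o]
        si_site = {nm: k for k, nm in enumerate(names) if nm is not None}
        layouts.append(
            _LGLayout(
                marker_global_idx=sel,
                is_marker=kind,
                site_marker_idx=src[kind],
                si_site=si_site,
                recomb=_haldane(np.diff(pos)),
            )
        )
    return _Genome(n_markers=len(marker_map), layouts=layouts)


@dataclass
class _Gamete:
    marker_alleles: np.ndarray
    si_alleles: dict[str, int]


def _meiosis(parent: SIGenotypeRecord, genome: _Genome,
             rng: np.random.Generator) -> _Gamete:
    """One recombinant gamete: a two-state path along each LG's sites,
    switching haplotype with the Haldane fraction between adjacent sites."""
    alleles = np.empty(genome.n_markers, dtype=np.int8)
    si: dict[str, int] = {}
    h0, h1 = parent.haplotypes
    for lay in genome.layouts:
        n_sites = len(lay.is_marker)
        if n_sites == 0:
            continue
        state = np.empty(n_sites, dtype=np.int64)
        state[0] = rng.integers(2)
        if n_sites > 1:
            switches = (rng.random(n_sites - 1) < lay.recomb).astype(np.int64)
            state[1:] = (state[0] + np.cumsum(switches)) % 2
        mstate = state[lay.is_marker]
        idx = lay.site_marker_idx
        alleles[idx] = np.where(mstate == 0, h0[idx], h1[idx])
        for name, k in lay.si_site.items():
            si[name] = parent.si_hap[name][state[k]]
    return _Gamete(alleles, si)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Simulated study population: offspring records, their founders, the
    marker map and the SI locus truth."""

    records: list[SIGenotypeRecord]
    founders: list[SIGenotypeRecord]
    marker_map: pd.DataFrame  # marker, linkage_group, position_cM, founder_freq
    loci: tuple[SILocusSpec, ...]
    config: SimConfig
    genome: _Genome = field(repr=False, default=None)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def families(self) -> dict[str, str]:
        return {r.id: r.family for r in self.records}

    def dosages(self) -> pd.DataFrame:
        """Marker × genotype dosage matrix (0/1/2)."""
        mat = np.column_stack([r.dosages() for r in self.records])
        return pd.DataFrame(
            mat, index=self.marker_map["marker"].tolist(), columns=self.ids
        )

    def si_allele_onehot(self, locus: str) -> pd.DataFrame:
        """Genotype × allele indicator-dosage matrix at one SI locus
        (how many copies of each founder allele an individual carries)."""
        alleles = sorted({a for r in self.records for a in r.si_hap[locus]})
        mat = np.zeros((len(self.records), len(alleles)), dtype=int)
        for i, r in enumerate(self.records):
            for a in r.si_hap[locus]:
                mat[i, alleles.index(a)] += 1
        return pd.DataFrame(mat, index=self.ids,
                            columns=[f"{locus}:{a}" for a in alleles])


def _founder_records(cfg: SimConfig, marker_map: pd.DataFrame,
                     rng: np.random.Generator) -> list[SIGenotypeRecord]:
    freqs = marker_map["founder_freq"].to_numpy()
    founders = []
    for f in range(cfg.n_founders):
        hap0 = (rng.random(len(freqs)) < freqs).astype(np.int8)
        hap1 = (rng.random(len(freqs)) < freqs).astype(np.int8)
        si_hap = {}
        for locus in cfg.loci:
            pair = rng.choice(locus.n_founder_alleles, size=2, replace=False)
            si_hap[locus.name] = (int(pair[0]), int(pair[1]))
        founders.append(
            SIGenotypeRecord(
                id=f"FND-{f + 1:02d}", family="founder",
                si_hap=si_hap, haplotypes=(hap0, hap1),
            )
        )
    return founders


def _mate(
    mother: SIGenotypeRecord,
    cloud: Sequence[SIGenotypeRecord],
    cfg: SimConfig,
    genome: _Genome,
    rng: np.random.Generator,
    child_id: str,
    family: str,
) -> SIGenotypeRecord:
    """One SI-constrained fertilisation: sample pollen gametes from the
    cloud until one is accepted by the mother's stigma (or slips through
    with probability ``self_fertility_leak``), then combine with one egg.

    Rejection sampling over uniformly chosen fathers weights each father
    by his compatible fraction with the mother.
    """
    stigma_geno = {l.name: mother.si_genotype(l.name) for l in cfg.loci}
    pollen = None
    for _ in range(cfg.max_attempts):
        father = cloud[rng.integers(len(cloud))]
        cand = _meiosis(father, genome, rng)
        rejected = _gamete_rejected(
            cand.si_alleles, stigma_geno, cfg.epistatic_rejections
        )
        if not rejected or rng.random() < cfg.self_fertility_leak:
            pollen = cand
            break
    if pollen is None:
        raise UnsatisfiableConfigError(
            f"mother {mother.id} received no compatible pollen in "
            f"{cfg.max_attempts} attempts (self_fertility_leak="
            f"{cfg.self_fertility_leak})"
        )
    egg = _meiosis(mother, genome, rng)
    si_hap = {
        l.name: (egg.si_alleles[l.name], pollen.si_alleles[l.name])
        for l in cfg.loci
    }
    return SIGenotypeRecord(
        id=child_id, family=family,
        si_hap=si_hap,
        haplotypes=(egg.marker_alleles, pollen.marker_alleles),
    )


def simulate_population(cfg: SimConfig) -> Population:
    """Simulate the study population.

    Founders are drawn at linkage equilibrium, then recombined through
    ``burnin_generations`` of SI-respecting panmictic mating at population
    size ``burnin_size`` (the historical-recombination phase that gives an
    advanced breeding population its mapping resolution).  Four mothers are
    then drawn from the final generation and each is pollinated by the
    cloud of all remaining plants to produce one half-sib family; pollen
    gametes fertilise only if compatible with the mother (or with
    probability ``self_fertility_leak`` despite incompatibility), so
    fathers are implicitly weighted by their compatible fraction.  SI
    alleles travel with the haplotype carrying them at their map position.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for lg in range(1, cfg.n_linkage_groups + 1):
        pos = np.sort(rng.uniform(0, cfg.lg_length_cM, size=cfg.markers_per_lg))
        for k, p in enumerate(pos):
            rows.append((f"LG{lg}_M{k + 1:04d}", lg, round(float(p), 3),
                         round(float(rng.uniform(0.1, 0.9)), 4)))
    marker_map = pd.DataFrame(
        rows, columns=["marker", "linkage_group", "position_cM", "founder_freq"]
    )
    genome = _build_genome(marker_map, cfg.loci, cfg.n_linkage_groups)
    founders = _founder_records(cfg, marker_map, rng)

    pool = founders
    for gen in range(cfg.burnin_generations):
        if cfg.burnin_mothers is None:
            mothers = pool
        else:
            m = min(cfg.burnin_mothers, len(pool))
            mothers = [pool[i] for i in rng.choice(len(pool), size=m, replace=False)]
        nxt = []
        for k in range(cfg.burnin_size):
            mother = mothers[k % len(mothers)]
            cloud = [p for p in pool if p.id != mother.id]
            nxt.append(
                _mate(mother, cloud, cfg, genome, rng,
                      child_id=f"G{gen + 1}-{k + 1:03d}", family="burnin")
            )
        pool = nxt

    mother_idx = rng.choice(len(pool), size=cfg.n_families, replace=False)
    records: list[SIGenotypeRecord] = []
    for fam, mi in enumerate(mother_idx):
        mother = pool[mi]
        cloud = [p for p in pool if p.id != mother.id]
        for k in range(cfg.family_sizes[fam]):
            records.append(
                _mate(mother, cloud, cfg, genome, rng,
                      child_id=f"HSF{fam + 1}-{k + 1:02d}",
                      family=f"HSF-{fam + 1}")
            )
    return Population(records, founders, marker_map, cfg.loci, cfg, genome)


def simulate_diallel(
    pop: Population,
    cfg: SimConfig,
    replicate_tag: str,
    rng: np.random.Generator | None = None,
) -> DiallelMatrix:
    """Score the full diallel of the population for one replicate (year).

    The latent score of cell (♀ i, ♂ j) is 10 × compatible_fraction of j's
    pollen on i's stigma; observed = latent + replicate noise + ordinal
    scoring noise, rounded and clipped to [0, 10]; cells drop out
    independently at ``missing_rate``.  The diagonal (selfs) is included.
    With the default rng, the replicate tag seeds the noise so different
    years differ while the whole run stays reproducible from ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, zlib.crc32(replicate_tag.encode())])
    n = len(pop.records)
    latent = np.empty((n, n))
    for i, stigma in enumerate(pop.records):
        for j, pollen in enumerate(pop.records):
            latent[i, j] = 10.0 * compatible_fraction(
                pollen, stigma, pop.loci,
                epistatic_rejections=cfg.epistatic_rejections,
            )
    noise = rng.normal(0.0, cfg.replicate_noise_sd, size=(n, n)) + rng.normal(
        0.0, cfg.score_noise_sd, size=(n, n)
    )
    observed = np.clip(np.round(latent + noise), 0, 10)
    observed[rng.random((n, n)) < cfg.missing_rate] = np.nan
    genos = [
        GenotypeLabel(r.id, r.family, frozenset({replicate_tag}))
        for r in pop.records
    ]
    return DiallelMatrix(genos, observed, replicate_tag=replicate_tag)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_genotypes(pop: Population, path: str | Path) -> None:
    """Genotype dosage TSV: marker, linkage_group, position_cM, then one
    0/1/2 dosage column per genotype."""
    out = pop.marker_map[["marker", "linkage_group", "position_cM"]].copy()
    out = pd.concat([out, pop.dosages().reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_truth(pop: Population, path: str | Path) -> None:
    """JSON truth file: SI locus positions and per-genotype SI alleles,
    for locus-recovery checks against simulation output."""
    payload = {
        "loci": [
            {
                "name": l.name,
                "linkage_group": l.linkage_group,
                "position_cM": l.position_cM,
            }
            for l in pop.loci
        ],
        "genotypes": {
            r.id: {name: sorted(pair) for name, pair in r.si_hap.items()}
            for r in pop.records
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_families(pop: Population, path: str | Path) -> None:
    """Companion metadata table (genotype_id, family) for the diallel reader."""
    pd.DataFrame(
        {"genotype_id": pop.ids, "family": [r.family for r in pop.records]}
    ).to_csv(path, sep="\t", index=False)
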