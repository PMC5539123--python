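# sicomp

Association mapping of multi-locus gametophytic self-incompatibility (SI)
from diallel pollination data.

Grasses carry a two-locus gametophytic SI system: a pollen grain is
rejected only when its alleles at **both** of the complementary loci *S*
(linkage group 1) and *Z* (linkage group 2) are present in the stigma's
diploid genotype. Between two heterozygous plants this yields cross
compatibilities of exactly 0, ½, ¾ or 1. Because every pollination score
depends on *both* parents, a diallel of scores is not directly usable as a
GWAS phenotype. `sicomp` implements the full analysis path that makes it
usable, plus a forward population simulator that provides a controlled
test surface:

1. **Diallel QC** (`sicomp.diallel`) — 0–10 ordinal score matrices
   (♀ rows × ♂ columns), reciprocal-difference flags (|Δ| > 3),
   between-replicate correlations, family-pair score subsets.
2. **SI₅₀ index** (`sicomp.si50`) — the quantile curve of a score set is
   sigmoid; a four-parameter logistic
   `Y = A + (B − A) / (1 + exp((D − x)/C))`
   is fitted to it after augmenting the series with asymptote anchors
   (x = −100…−1 at score 0, x = 101…200 at score 10, all scores +1).
   The inflection `D` is the SI₅₀ — the quantile at which half the
   reactions are half-compatible, by analogy with the LD₅₀.
3. **Compatibility Components** (`sicomp.components`) — each genotype's
   pollination profile (its ♀ row and ♂ column) enters a pairwise-complete
   Euclidean distance matrix; unscaled PCA of that matrix gives latent
   per-genotype phenotypes. Component *order* is not stable across
   replicate years, so components are matched across replicates by
   |Pearson correlation| and relabelled CC1…CCk; Ward clustering groups
   genotypes by pollination behaviour.
4. **Single-marker GWAS** (`sicomp.gwas`) — OLS of each CC on additive
   SNP dosage with PCA structure covariates, MAF < 0.05 exclusion, and a
   Bonferroni line −log₁₀(α/m).
5. **Simulator** (`sicomp.simulate`) — founders with a small SI allelic
   series are recombined through generations of SI-respecting half-sib
   mating (Haldane map function, no interference), then four half-sib
   families (52 plants) are produced by a shared pollen cloud; diallels are
   scored with ordinal and year-replicate noise and missing cells. SNP
   markers linked to the SI loci inherit alongside them, so the true map
   positions are recoverable — and known, enabling localization checks.
6. **Pipeline** (`sicomp.pipeline`, CLI `sicomp`) — the whole path under
   one seed with byte-reproducible outputs.

## Worked example

`examples/04_association_scan.py` simulates the default study, derives
matched Compatibility Components from two replicate years and scans CC1:

```
2100 markers, 1569 kept after MAF filter
Bonferroni threshold -log10(0.05/1569) = 4.50
   marker  linkage_group  position_cM  neg_log10_p  above_threshold
LG2_M0152              2        51.32         6.89             True
LG2_M0198              2        71.16         4.90             True
LG2_M0217              2        76.82         4.33            False
LG2_M0058              2        19.36         4.27            False
LG1_M0065              1        20.12         4.21            False
true loci: S on LG 1 at 20.0 cM, Z on LG 2 at 54.0 cM
```

The strongest association (−log₁₀p = 6.89) sits on LG 2 at 51.3 cM,
2.7 cM from the true *Z* locus: the component phenotype has localized an
SI locus from pollination scores alone. The other scripts in `examples/`
demonstrate the simulator, the SI₅₀ table (within-family SI₅₀ exceeds
between-family SI₅₀, as half sibs share maternal SI alleles), component
matching across years, and the end-to-end pipeline.

A shell entry point mirrors the library:

```sh
sicomp simulate --seed 1 --outdir demo
sicomp si50 demo/diallel_2013.tsv --families demo/families.tsv
sicomp run-all config.yaml
```

## Documentation

The model, its assumptions, parameter defaults and known limitations are
described in `docs/methods.md`.
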