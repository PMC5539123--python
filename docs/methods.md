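# Methods

## The measurement model

A diallel of semi-in-vivo pollinations scores every ordered pair of
plants, including selfs, on an ordinal 0–10 scale (0 fully incompatible,
4 half-compatible, 7 three-quarters compatible, 10 fully compatible).
The matrix convention is row = pollen recipient (♀), column = pollen
donor (♂). Reciprocal crosses may differ — the gametophytic rule is
genuinely asymmetric (the pollen parent contributes gametes, the stigma
parent a diploid genotype) — and cells may be missing. Missingness is a
mask throughout; no sentinel scores.

Quality control follows two rules: a reciprocal pair is flagged when both
directions are scored and their difference exceeds 3 (strictly: |Δ| ≥ 4),
and replicate agreement is summarised by Pearson correlation over cells
scored in both replicates (Spearman available; the choice matters little
on a 0–10 scale and Pearson is the default meaning of a reported R).

## The SI₅₀ index

Scores within a group of crosses are far from normal, so the group is
summarised by its quantile curve: scores sorted ascending at coordinates
x\_i = i/(n+1), which is sigmoid for SI-segregating material. A
four-parameter logistic

    Y = A + (B − A) / (1 + exp((D − x) / C))

is fitted by unweighted Levenberg–Marquardt least squares. Two
preprocessing steps make the fit stable and comparable across groups:
all scores are incremented by one, and 100 artificial points are appended
on each side (x = −100…−1 with y = 1, x = 101…200 with y = 11). The
anchors sit deep in the saturated tails, so they pin the asymptotes
(fitted A ∈ [0.8, 1.2], B ∈ [10.8, 11.2] in practice) without informing
C or D. D, reported as SI₅₀, lives on the real quantile axis (0, 1).

Start values: A₀ = min y, B₀ = max y, D₀ = the x of the real point whose
y is closest to the median, C₀ = (range of real x)/4. Non-convergence is
flagged on the result; a group whose real scores are all equal has no
inflection and is skipped in the group table (floor: 10 scores per group,
configurable).

The reported R² is computed over the real points only as
R² = 1 − Σr²/Σ(x − x̄)², where r are residuals from the fitted curve and
x are the observed scores. The denominator uses score deviations, which
makes this a nonstandard R² that can go negative for a fit worse than the
mean; it is implemented exactly in this form deliberately, because it is
the definition the index is specified with.

Parameter recovery on synthetic logistic series: noise-free series are
recovered to |D̂ − D| < 10⁻³; with ordinal noise (sd 0.75, rounded,
clipped) at n = 100 the mean error is ≈ 0.004.

## Compatibility Components

Each genotype's pollination profile is the concatenation of its matrix
row (behaviour as ♀) and column (as ♂), length 2n; this is the default
because reciprocal asymmetry is informative (row-only and column-only
modes exist). Profile distance is Euclidean over jointly observed
coordinates with proportional rescaling, d = √((p/m)·Σ(a−b)²) for m of p
coordinates shared — the pairwise-complete convention. A pair sharing no
coordinate is a hard error rather than an imputation.

The n×n distance matrix itself is the similarity structure that is
decomposed: each genotype's feature vector is its row of distances,
columns are centred (not variance-scaled) and the matrix is factored by
SVD. Scores are the projections; variance fractions come from squared
singular values. Centring is applied because the uncentred first
component merely reflects mean distance; an uncentred option is retained
for sensitivity checks. Signs are fixed so each component's
largest-magnitude score is positive, making output deterministic.

Components of replicate years describe the same latent factors but not in
the same order: neighbouring variance fractions let adjacent components
swap rank between years. Matching is greedy on descending |Pearson
correlation| between score vectors, yields a bijection on the leading
k = 4 components, flips signs so matched correlations are positive, and
relabels the pairs CC1…CC4 in the first replicate's variance order. With
four components greedy and optimal assignment coincide in practice.

Ward hierarchical clustering (on the Ward criterion proper, i.e. squared
Euclidean increments) of the first four component scores, cut at four
clusters, groups genotypes by pollination behaviour.

## Association scan

Markers with minor allele frequency below 0.05 (from non-missing dosages,
MAF = min(p̄, 1−p̄), p̄ = mean dosage/2) are excluded before testing.
Population structure is captured by the leading PCA axes of the centred
genotype×marker dosage matrix (2 axes by default; the study population is
a single closed breeding pool, so structure is modest). Each marker is
then tested by OLS: phenotype ~ intercept + dosage + axes, two-sided
t-test on the dosage coefficient. Missing dosages are marker-mean imputed
by default (keeping n constant lets the covariate block be residualised
once — Frisch–Waugh — and the scan vectorised; the per-marker
complete-case variant is available and agrees when nothing is missing).
Numerically perfect fits are reported at −log₁₀p = 15 with a flag;
markers collinear with the covariates are skipped with a reason. The
significance line is Bonferroni, −log₁₀(α/m) for the m markers actually
tested — with α = 0.05 and m = 2,261 that is 4.655. The threshold is
always computed from α and m, never hard-coded.

## The simulator

The generative core is the complementary gametophytic rule: a pollen
gamete is incompatible iff at every SI locus its allele occurs in the
stigma's genotype. Gamete enumeration over the pollen parent's allele
pairs (equiprobable; loci unlinked) gives the compatible fraction, which
for two heterozygous parents takes exactly {0, ½, ¾, 1}. The rule
generalises to L loci, and an optional epistatic table rejects gametes
carrying listed two-locus allele combinations (a pollen-lethality model
for modifier loci on other linkage groups). One subtlety worth noting:
strict SI forbids an individual homozygous at *all* SI loci
simultaneously, but single-locus homozygotes do arise, because a gamete
matching the stigma at only one locus is accepted.

A simulated genome has seven 100-cM linkage groups with 300 markers each
at uniform random positions and founder allele frequencies U(0.1, 0.9);
S sits on LG 1 at 20 cM and Z on LG 2 at 54 cM. Meiosis follows Haldane's
map function with no interference, implemented as a two-state path along
each linkage group's ordered sites (markers plus SI loci) switching with
the adjacent-interval recombination fraction; SI alleles travel with the
haplotype carrying them.

Population history matters. Twelve founders carry SI alleles drawn from a
six-allele series per locus. They are recombined through 10 burn-in
generations at population size 80 with six mothers per generation —
half-sib family mating, the scheme that produces advanced forage breeding
populations. The burn-in serves two purposes: historical recombination
shortens marker–locus LD from whole-chromosome scale to a few cM (a
single founder→offspring meiosis leaves r(30 cM) ≈ 0.23 of association —
no method could then localize anything to 10 cM), and the small maternal
bottleneck narrows and structures the allelic series the way a closed
breeding programme does. The study generation is then four half-sib
families of 13: four mothers drawn from the final pool, each pollinated
by the cloud of all other plants. Fathers are sampled by rejection — a
uniformly drawn pollen gamete fertilises only if compatible with the
mother, or despite incompatibility with probability
`self_fertility_leak` (default 0.02, per gamete; partial self-compatible
genotypes are a documented feature of real populations) — which weights
each father by his compatible fraction.

Observed scores are latent 10×(compatible fraction) plus per-cell
year-replicate noise (sd 1.75) plus ordinal scoring noise (sd 0.75),
rounded and clipped to [0, 10]; cells go missing independently at rate
0.08. Noise and diversity defaults were calibrated against the observable
summaries such a study reports, not tuned per run: the simulated
between-year correlation is R ≈ 0.66–0.70, within-family SI₅₀ exceeds
between-family SI₅₀, some family pairs approach full mutual
compatibility (maternal parents sharing no SI alleles), and per year
roughly 150–200 reciprocal pairs are flagged. A residual gap remains:
real within-family SI₅₀ values reach ≈ 0.5, higher than the simulator
produces without collapsing the allelic series so far that fully
compatible family pairs become impossible; the simulated population is
therefore somewhat *less* incompatible than a real one, which makes the
localization benchmark conservative rather than generous.

What the simulator does not emulate: scorer drift and systematic year
effects (noise is i.i.d. per cell), mutation, selection on agronomic
traits during burn-in, crossover interference, genotyping error, and
segregation-distorting modifier loci unless configured. Passing tests on
this surface show the analysis recovers what the two-locus model puts in;
they do not certify behaviour under model misspecification beyond the
leak and epistasis options.

## Localization benchmark

Simulation mode knows the truth, so the pipeline reports, per SI locus,
whether the method found it: among the eight scans (4 matched CCs × 2
replicates), the locus's best-associated component is the scan with the
strongest −log₁₀p within 10 cM of the true position — the same logic by
which real studies assign components to loci from their association
signal at known candidate regions. The hit criterion is then whether that
scan's *genome-wide* top marker lies within 10 cM: a stronger peak
anywhere else makes the locus a miss, so the selection is not circular.
An alternative truth-based selector (regressing each CC on the locus's
founder-allele indicator dosages and taking the highest R²) was
implemented first; it mis-assigns components that mix both loci and was
kept out of the default summary. Under the default conditions the hit
rate is ≈ 85–95% per locus over seeded runs, and the scan's empirical
type-I error on marker-independent phenotypes is ≈ 0.05 at nominal 0.05.

## Numerical and design notes

- Quantile grid i/(n+1): strictly inside (0, 1), keeping anchors strictly
  exterior; the augmentation x-values are taken literally as coordinates
  on the same axis.
- Logistic exponent clipped at ±700 to avoid overflow at the anchors.
- Optimizer tolerances 10⁻⁸ (xtol/ftol/gtol), LM, max ~200 iterations.
- Distance/PCA/clustering are fully deterministic; the only randomness in
  the package is in the simulator, which takes a mandatory seed, and every
  emitted file is byte-identical under a fixed seed.
- Problem sizes in tests and the acceptance script follow the default
  study conditions (52 genotypes, ~2,100 markers, 20-seed batches);
  unit tests use a structurally identical down-scaled configuration.
- Pipeline outputs carry a header with version, seed and a config hash;
  reports round floats to 6 decimals for stable serialisation.

## Known limitations

- The SI₅₀ R² definition is nonstandard (see above) and not comparable
  with a conventional coefficient of determination.
- OLS association assumes an additive biallelic tag of a multi-allelic
  causal series; power depends on how well any single marker splits the
  relevant alleles, so per-seed localization occasionally fails even with
  strong signal at the locus.
- No mixed-model (kinship) correction; with four half-sib families the
  PCA axes absorb most but not all relatedness.
- Confidence intervals on SI₅₀ are not provided.
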