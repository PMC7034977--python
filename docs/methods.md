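# Methods

This note documents the models implemented in `sexdim`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Forward simulation of sexually discordant selection

**Model.** A quantitative trait is controlled by additive biallelic loci
drawn from a founder haplotype panel.  Architectures are sex-symmetric with
exactly 50 contributing loci per sex:

* *specific* mode, asymmetry level *k*: 50 − k shared loci (identical
  effects in both sexes) + k male-specific + k female-specific loci (zero
  effect in the other sex); the population segregates 50 + k distinct loci.
* *biased* mode: 50 − 2k shared + k male-biased + k female-biased loci,
  all 50 contributing in both sexes with a two-fold effect difference at
  the biased loci.

Effect magnitudes are Gamma(shape 0.5, scale 2.5) with a random sign; the
(shape, rate) reading is available via `effect_scale=0.4`.  The intersex
genetic correlation and all acceptance-grade statistics are invariant to
this scale choice.  In biased mode the drawn magnitude is interpreted as
the *larger* of the two sex effects (the other sex receives half); the
alternative reading (the other sex receives double) is selectable via
`biased_reading="double"`.  The default was fixed by the generation-0
correlation oracle: under the 189-haplotype panel model it yields a mean
intersex correlation of ≈0.88 (SD ≈0.05) at k = 20, versus ≈0.86 for the
alternative; both are exposed because the locus accounting is a genuine
modeling choice.

**Founder panel.** Synthetic panels hold 189 haplotypes over independent
segregating loci.  Panel allele counts are drawn from {1, …, 188} with
probability ∝ 1/count — the neutral site-frequency-spectrum shape, which
concentrates mass on rare variants as in natural founder collections.
Sensitivity checks with heavier rare-variant weighting (∝ count^−1.5,
count^−2) move the k = 20 sex-specific mean correlation by < 0.05, so the
SFS choice is not critical for the reported statistics.  Loci are generated
at linkage equilibrium; real founder haplotypes carry linkage
disequilibrium, but the generation-0 correlation depends on frequencies and
effects, not LD structure, and responses over 100 generations with free
recombination are insensitive to initial LD at these locus numbers.

**Intersex genetic correlation r_mf.** The Pearson correlation between
male-trait and female-trait genotypic values of the same diploids.  The
default estimator samples 1000 individuals from random haplotype pairs; an
`exact` method returns the population value under random pairing, which
equals the haplotype-level correlation because a diploid value is the sum
of two independent haplotype draws.  The exact method matches brute-force
enumeration of all ordered diploid genotypes to machine precision (tested
up to 6 haplotypes × 4 loci).

**Selection and reproduction.** Phenotype = genotypic value + N(0, V_E,sex)
noise with V_E,sex = V_G0,sex (1 − h²)/h² fixed from generation 0, so
heritability is h² = 0.8 ancestrally *per sex* — with sex-asymmetric
architectures the two sexes have different genetic variances, and the
normalized response is reported per sex, so a per-sex h² contract is the
consistent reading.  Fitness is Gaussian, w(P) = exp(−(P − θ_sex)²/(2ω²)),
with θ_sex the ancestral sex mean plus that sex's optimum shift (defaults
+3 male, −3 female; the direction is a flag).  The fitness width defaults
to ω² = 4 V_P0 — moderate stabilizing selection that yields visible but
non-truncating 100-generation responses; the width is configurable because
the original analysis does not state it.  Both parents of each offspring
are drawn fitness-proportionally with replacement within sex (no
fecundity/viability split); transmission is Mendelian with free
recombination; population size (default N = 1000) and the balanced sex
ratio are constant.  Setting ω² = ∞ gives flat fitness: the simulator then
reproduces Wright–Fisher drift (per-generation allele-frequency variance
p(1 − p)/2N, verified in the test suite).

**Summary statistics.** Normalized response per sex = (mean phenotype at
the last generation − generation-0 mean) / realized generation-0 phenotypic
variance.  Decoupling = each sex moved toward its own optimum (a
direction-agnostic definition; the "male up, female down" convention is
recovered with the default shifts).  Scenario sweeps regenerate panel and
architecture per replicate, aggregate mean ± SD, and compare each
scenario's decoupling fraction to the k = 0 control with a one-sample
proportion score test, z = (p̂ − p₀)/√(p₀(1 − p₀)/n), Bonferroni-adjusted
over the non-control scenarios; an exact binomial test substitutes when the
control fraction is 0 or 1.

**Problem sizes.** The acceptance script uses 300 architecture replicates
per r_mf scenario (Monte-Carlo SE ≈ 0.012 for the widest-spread scenario)
and 50 forward replicates per decoupling scenario; the test suite uses 100
and 50.  These sizes put the Monte-Carlo error well inside the tolerances
of interest while keeping a full run around a minute.

## Gonad/carcass allometric correction

For gene *i*, condition means on the linear CPM scale satisfy
ȳ_wb = α ȳ_g + (1 − α) ȳ_c with α ∈ [0, 1]; the equations are linear, so
all arithmetic stays on the linear scale.  α is estimated per sex within
each group from replicate-mean CPM as α̂ = (ȳ_wb − ȳ_c)/(ȳ_g − ȳ_c),
clipped to [0, 1] with clipped fits retained but flagged `boundary`.

Genes expressed at similar levels in gonad and carcass are insensitive to
tissue scaling and ill-conditioned (denominator → 0); the default
non-correctability rule is |log2((ȳ_g + 0.5)/(ȳ_c + 0.5))| < 0.5,
configurable.  Non-correctable genes keep γ = 1 throughout.

Pseudo whole-body samples are α̂_evo ȳ_g,anc + (1 − α̂_evo) ȳ_c,anc per
replicate; γ̂ = pseudo mean / observed ancestral whole-body mean, applied
multiplicatively to ancestral whole-body samples only.  A correctable gene
with zero observed mean is demoted to γ = 1 with a logged warning.
Leave-one-replicate-out cross-validation estimates α from the remaining
replicates and predicts each held-out whole-body value from the held-out
dissected values; the summary correlation is computed on the log10 scale
(0.5-CPM pseudo-count) so genes contribute evenly across the dynamic
range.  Ancestral-vs-evolved α distributions are compared with the exact
two-sample KS statistic (asymptotic p), restricted to genes correctable in
both groups.

*Caveat.* A mixture of two CPM-normalized tissue profiles is not itself
exactly CPM-normalized; per-sample renormalization therefore leaves a
small compositional deviation (sub-percent at a few hundred genes) between
programmed and recovered α even without counting noise.  This mirrors real
data and is covered by the preregistered recovery tolerance (mean absolute
error < 0.2 at 6 replicates, set by Monte-Carlo during development).

## Differential expression

Counts are filtered (CPM > 0.1 in every sample), normalized by TMM, and
modeled per gene as NB with log link and offset log(library size × TMM
factor) under the single factor group ∈ {ancestral F, ancestral M, evolved
F, evolved M}.

**TMM.** Implemented from the published definition: reference = sample
whose 75th CPM percentile is closest to the mean of those percentiles;
per-sample gene-wise M and A values on genes positive in both members of
the pair; double trimming (30% of M, 5% of A, rank-based); factor = 2 to
the inverse-delta-method-variance weighted mean of surviving M values;
factors rescaled to geometric mean 1.

**Dispersion.** Per-gene method-of-moments (degrees-of-freedom corrected
against fitted group means), shrunk 50% on the log scale toward a
mean–dispersion trend fitted by lowess; genes with non-positive raw
estimates take the trend value.  This captures the empirical-Bayes
moderation used in standard count-model packages without reproducing any
package's internals.  At 6 replicates per group the resulting
likelihood-ratio test is mildly liberal (≈5.5–6% at nominal 5%), the known
finite-sample behavior of asymptotic NB LRTs; the null-calibration test
bounds the rejection rate with a 99% binomial interval around 5%.

**Testing.** Group means are fitted by per-group Fisher scoring (exact
Poisson limit below dispersion 1e-12, so the Poisson closed form is
reproduced to machine precision).  Each contrast is a 1-df linear
constraint c'η = 0 fitted by reparametrized batched Fisher scoring with
step halving; the LRT statistic is compared to χ²(1), and BH q-values are
computed across retained genes (non-convergent fits get p = NA and leave
the FDR denominator, with a logged count).  Corrected ancestral counts are
non-integer; the NB likelihood is evaluated through its gamma-function
form, which extends smoothly to continuous values.

**Classification.**  From the female- and male-evolution contrasts at
q < 0.05: both significant and same sign → concordant; exactly one →
sex-specific (direction from its LFC); both significant and opposite →
antagonistic; neither → unchanged.  The categories are exhaustive and
mutually exclusive by construction.  Sex-bias evolution compares the
within-group female-vs-male contrasts (ancestral vs evolved) on a
significance/sign lattice: gained, lost, reversed, strengthened, weakened,
unchanged; the reported direction is the sign of the change in the
female-vs-male log fold change.

## Enrichment and the TF screen

Tissue signatures use the strict rule expression(tissue) > 2 ×
expression(whole body).  Enrichment is the two-sided Fisher exact test
(point-probability definition) on the 2×2 membership table with BH
correction across sets; sample odds ratios use the Haldane +0.5 correction
when a cell is zero (flagged).  Degenerate tables (empty query or set)
report p = 1 and an undefined odds ratio rather than failing.

The TF screen requires (1) target enrichment among sex-biased genes,
(2) target enrichment among bias-evolving genes, and (3) a compatible
direction, operationalized as: the sign of the TF's own bias change equals
the sign of the *strict majority* of its significantly bias-evolving
targets (ties fail).  Because criteria 1–2 could also be read as mere
overlap with precomputed regulon hits, an `overlap` mode is provided; the
default is the enrichment reading.  TFs with empty target sets are
excluded and logged.

## Synthetic data

The generator emulates: a founder panel of segregating biallelic loci with
a rare-variant-heavy frequency spectrum; and gene × sample NB count
studies over sex × group × tissue × replicate designs in which whole-body
means obey the mixing model exactly (before noise), baselines are
log-normal around ~50 CPM with a sex-biased subset, evolved log2 fold
changes hit a configurable gene fraction independently per sex, the
evolved α can be shifted to emulate evolved allometry, and gene-wise NB
dispersions are log-normal (median 0.05 — typical bulk RNA-seq
overdispersion).  Baseline tissue profiles are rescaled to sum to 10⁶ so
the programmed CPM scale is compositionally coherent with per-sample CPM
recomputation.

It does **not** emulate: read-level error, mapping bias, batch effects,
isoform structure, correlated expression between genes, or linkage in the
founder panel.  Passing recovery tests therefore demonstrate correctness
of the estimators under the stated noise model, not robustness to
artifacts absent from that model.

All randomness flows from named substreams of a single seed
(`sexdim.data.substream`); identical configs reproduce outputs
bit-identically (timestamped log excepted).

## Known limitations

* The fitness width and the exact biased-mode locus accounting of the
  original simulation study are not published; both are configurable and
  the defaults are documented above.
* The group model has no batch or replicate random effect; ε is the NB
  sampling error only.
* α estimation is per sex within group on pooled replicate means; per-
  replicate α variation is visible only through the LOO diagnostics.
* The decoupling fraction for k = 0 reflects two drift coin-flips
  (≈0.25 in expectation under symmetric drift; smaller when weak
  stabilizing selection holds both sexes at the ancestral mean).
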