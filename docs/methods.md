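# Methods

## The experimental design being modelled

The package targets replicated evolve-and-resequence (E&R) experiments of
the following shape. A base population of outcrossing, self-incompatible
annual plants is split into eight treatment groups — a full factorial of two
soils (limestone, tuff), aphid herbivory (±), and pollination mode (bee vs
hand) — each with two replicate lines of 49 plants. Lines evolve
independently for eight generations under selection; two further
hand-pollinated generations without insects reduce maternal effects, so nine
transmission events separate the two sampled generations (labelled 1 and
10: the second wash-out generation is the sampled endpoint itself).
Generation-1 and generation-10 plants are genotyped; generation-10 (and
resurrected generation-1) lines are phenotyped in both soils in a reciprocal
transplant. The fitness-proxy trait is the number of open flowers on
pollination day.

## Synthetic data generator

`adaptscan.synthetic_experiment` is a forward-time Wright–Fisher-style
simulator of that design with known ground truth.

* **Founders.** Per replicate, diploid genotypes are independent
  Hardy–Weinberg draws at each locus's founder frequency (default 0.5 for
  the standard architecture). Loci are unlinked; linked variation is out of
  scope (window pruning is still exercised through assigned coordinates).
* **Fecundity selection.** A plant's expected seed set is multiplied by
  `exp(Σ_l dosage_l · s_l[soil])`. The exponential (log-additive) map is the
  standard choice that keeps fitness positive; selection coefficients are
  per allele copy.
* **Pollination and drift.** Under bee pollination only a visitation-limited
  random subset of plants — the treatment's configured effective number of
  seed parents, defaults 21–28 (LNHH 28, LHH 26, LNHB 22, LHB 22, TNHH 28,
  THH 27, TNHB 23, THB 21) — receives nonzero base seed set; this pollen
  limitation is the dominant drift source. Hand pollination assigns 28
  random mothers equal base seed set. Fathers are drawn per offspring
  proportionally to fitness, excluding the mother (self-incompatibility).
* **Reproduction quotas.** Each plant's contribution to the next generation
  is `seed_set / replicate seed total × 49`. Integer offspring counts come
  from largest-remainder rounding (ties to the lower index), which preserves
  the census of 49 exactly at every transmission; this is asserted
  programmatically each generation.
* **Wash-out.** During the neutral transmissions all selection coefficients
  are zero and mating is hand-style.
* **Trait model.** trait = intercept + soil main effect + Σ dosage×effect +
  `gxe_effect`·1[grown in the line's own soil] + Gaussian noise. The
  `gxe_effect` term is the built-in local advantage used for phenotype power
  studies (default scenario: 0.5 trait units at residual SD 1).
* **Architectures.** `standard_architecture()` plants AP loci (opposite-sign
  coefficients in the two soils), per-soil CN loci, and neutral loci 5 kb
  apart across 10 chromosomes. `strong_selection_architecture()` uses
  |s| = 0.8 per copy: with Ne ≈ 21–28 drift and the deliberately
  conservative drift-aware test, that is the regime in which most
  antagonistic loci reach significance, which is the scenario's purpose
  (ground-truth recovery).
* **Auxiliary generators.** `simulate_neutral_panel` produces pure-drift
  allele-count tables (founders sampled from a uniform 0.1–0.9 frequency
  pool, t binomial WF generations at Ne, endpoint sample of 49 diploids)
  for null calibration. `simulate_blup_panel` produces genotype/trait panels
  with a neutral-like 1/x minor-allele-frequency spectrum truncated at the
  0.01 maf filter and unit-effect causal loci drawn from the commonest
  markers — loci that respond visibly to selection (frequency changes of
  0.1–0.2) are necessarily at intermediate frequency, and a U-shaped SFS is
  what a filtered resequencing panel looks like.

What the generator does **not** emulate: linkage and LD decay, inbreeding
and family structure beyond replicate labels, sequencing/genotyping error and
depth variation, plastic responses other than an additive soil main effect,
aphid population dynamics and bee behaviour. Tests passing on synthetic data
therefore validate the statistical machinery, not robustness to those
real-data features.

## Drift-aware CMH test

For marker × treatment, each replicate contributes a 2×2 table (rows
generation 1/10, columns alt/ref allele counts). The classical CMH statistic

T = (Σ_k (a_k − E_k))² / Σ_k V_k,  a_k = generation-10 alt count,

uses the hypergeometric mean/variance of a_k (no continuity correction, so
allele-label swaps leave T exactly invariant); p-values from χ²₁. The
classical null models only the sampling of individuals, but after t
Wright–Fisher generations at effective size Ne the generation-10 frequency
has additionally drifted by

Var_drift = p(1−p) · [1 − (1 − 1/(2Ne))^t].

Writing the numerator cell as a_k − E_k = (n1_k a_k − n10_k b_k)/N_k shows a
unit of drift variance in the generation-10 frequency enters the statistic
scaled by (n1_k n10_k / N_k)²; the drift-aware denominator is therefore

V_k + (n1_k n10_k / N_k)² · p̂_k(1−p̂_k) · [1 − (1 − 1/(2Ne))^t],

with p̂_k the pooled stratum frequency. This coefficient is the one the
variance propagation gives — with the larger coefficient n10_k² the test
would be ~4× over-deflated for equal strata and essentially powerless at
realistic selection strengths; with the derived coefficient it is calibrated:
on neutral panels (Ne = 25, 49 diploids, t = 9) the empirical type-I rate at
α = 0.05 is ≈ 0.045, versus ≈ 0.53 for the classical test, and BH at 0.05
yields no discoveries. As Ne → ∞ the drift term vanishes and the classical
statistic is recovered. Defaults: t = 9 transmissions, per-treatment Ne from
the configuration.

Multiplicity and linkage: markers are assigned to non-overlapping half-open
2-kb windows anchored at coordinate 1; the minimum-p marker represents each
window (ties to the smaller position); BH FDR is applied to the
representatives (pruning first matches its purpose of removing redundant
linked tests before multiplicity control). A significant marker must also
have same-sign frequency change in both replicates — a change seen in one
replicate only is treated as drift.

## Ridge-BLUP marker effects

Model y = 1μ + Xg + e with g ~ N(0, σ²_g I), X coded −1/0/+1 (0 =
heterozygote), markers with > 50% missing data removed (exactly 50% is
kept), remaining missing entries imputed with the marker's mean coded value,
and the trait Z-transformed within each treatment × replicate data set.
Variance components are REML estimates obtained by eigen-decomposition of
S(K + I)S (K = XX', S the intercept projection; the +I offset keeps the
decomposition stable and is subtracted from the eigenvalues), profiling the
restricted likelihood over λ = σ²_e/σ²_g with bounded scalar minimisation on
log λ (bounds e±8·ln10, xatol 1e-10). Effects are the dual ridge solution
g = X'(K+λI)⁻¹(y − 1μ) with the GLS intercept; the primal identity
(X'X+λI)⁻¹X'(y−1μ) agrees to machine precision and is tested. Fits use a
60% uniform random training split (round(0.6·n), unstratified). Markers are
retained for classification only if they carry a finite nonzero effect in
both replicate models — a presence criterion, since ridge effects are
generically nonzero; sign agreement is deliberately not required.

## AP/CN classification

With per-replicate frequency changes (Δ) in the two soils, all inequalities
strict:

* **AP** — |Δ| > 0.1 in both soils and both replicates, directions
  consistent between replicates within each soil, and opposite between
  soils.
* **CN** — |Δ| > 0.2 in one soil (either direction) and |Δ| < 0.1 in the
  other, in both replicates, with one consistent large-change soil.
* **OTHER** — everything else. AP and CN are mutually exclusive by
  construction (AP needs |Δ| > 0.1 in both soils, CN needs < 0.1 in one);
  an exhaustive grid test proves equivalence with a literal restatement of
  the rules.

AP calls additionally require CMH significance in both soils (a marker
significant in one soil only is discarded from the AP path); CN calls
require significance in the large-change soil, with a `strict_cn` flag to
demand both — the discard-if-one-soil rule taken literally would contradict
CN's definition, so the permissive reading is the default and both tallies
are available. Genes are annotated within an inclusive ±1000 bp flank.
Class percentages are rounded half-up to one decimal. AP prevalence between
two treatments is compared by the 1-df likelihood-ratio statistic of the
binary (binomial) GLM with treatment as the only factor, computed in closed
form from the 2×2 binomial deviance so that complete separation stays
finite; a Pearson chi-square on the same table is reported alongside.

## Phenotypic local adaptation

`fit_gxe` fits trait ~ soil_line × soil_grown with a replicate random
intercept (REML; sum-to-zero coding so main effects are marginal); if the
mixed fit fails or the replicate variance is degenerate it falls back to the
boundary fit (OLS, replicate variance 0 — in practice near-zero generator
variance yields fitted values ≲ 1e-4, the numerical boundary tolerance).
Fixed terms get 1-df Wald chi-squares; contrasts use the fixed-effect
covariance with residual degrees of freedom (no Satterthwaite correction).
The verdict of local adaptation = significant G×E interaction AND
significant positive local-vs-foreign contrast, no multiplicity correction
across traits.

A structural point worth knowing: in a balanced 2×2 transplant the
local-vs-foreign and home-vs-away contrasts are the *same* linear
combination of the four cell means (½(LL+TT) − ½(LT+TL)), and both equal
twice the interaction coefficient. The conjunction verdict therefore behaves
like a one-sided interaction test, with a null rate near α/2 (≈ 0.025 at
α = 0.05), not the product of two independent tests. Both contrast labels
are still reported for interface completeness.

`trait_evolution` compares generations within treatment on local-soil plants
only (foreign-grown plants mix evolved change with plastic soil response and
are excluded, with a logged count), via a cell-means mixed model (one mean
per treatment × generation, replicate random intercept — algebraically the
generation × treatment interaction model). The zero-inflated seed set is
modelled in two parts (binary GLM on seeds/no-seeds; linear model on the
seed-producing subset — the "truncated" model is a plain linear fit on the
positive part, not a truncated-likelihood estimator); first choices get a
log-link Poisson GLM; the visits–seeds association is a Pearson correlation.
Perfect separation in the binary model is flagged as non-estimable rather
than reported.

## Problem sizes and determinism

All randomness flows from a single root seed through `numpy` SeedSequence
spawning (per treatment × replicate × stage via a CRC-based path hash), so
runs are bit-reproducible. Default analysis sizes: full design simulations
use 350 loci (20 AP / 30 CN / 300 neutral) and finish in well under a second;
null calibration uses 5,000-marker panels over 10 seeds; BLUP validation
uses 20 panels of n = 150, m = 200 at h² = 0.5; G×E power studies use 75
plants per cell over 25 seeded transplants. These sizes give stable
estimates of the rates being checked while keeping the whole suite fast.

## Known limitations

* The drift-aware variance treats the generation-1 sample as drift-free
  (founders are the sampled plants) and uses the pooled-frequency plug-in;
  both are small-order approximations, absorbed by the conservative margin
  in the calibration checks.
* Marker effects are in-sample BLUPs; no cross-validated predictive accuracy
  is reported, and effect retention is presence-based, not significance-based.
* CN calls inherit the usual caveat that weakly selected alleles can mimic
  neutrality in one environment; under strong selection a conditionally
  neutral locus can even drift past the AP thresholds in the other soil, so
  AP tallies on synthetic strong-selection runs slightly exceed the planted
  AP count.
* Real-data scale (millions of SNPs) is supported by the vectorized scan but
  I/O is plain-text oriented; BCF/compressed handling is out of scope.
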