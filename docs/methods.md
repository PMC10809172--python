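# Methods

## Diet-quality indices

All three indices are computed from one fixed food-group vocabulary
(servings/day; sodium in mg/day; MUFA/SFA in g/day; alcohol in g/day) so
that a single phenotype table supports every score.

Component scoring is rank-based: intakes are ranked with average ties, and
ranks are binned by right-closed empirical quantile boundaries. This makes
every score invariant to strictly monotone transforms of an intake (units,
log scales) and fully deterministic. A constant component has no quantiles;
all participants then receive the midpoint score, with a warning.

* **DASH** — fruits, vegetables, nuts+legumes, low-fat dairy and whole
  grains scored 1–5 by quintiles; sodium, sugar-sweetened beverages and
  red/processed meat reverse-scored 5–1. Range 8–40.
* **HPDI** — 7 healthy plant foods scored 1–5; 5 less-healthy plant foods
  and 6 animal foods reverse-scored. Range 18–90.
* **MMDS** — exact published computations of Mediterranean scores vary, so
  the point scale here is an explicit, configurable choice: 8 monotone
  components scored 0–3 by cohort quartiles (red/processed meat reversed),
  the MUFA:SFA ratio capped at its cohort 99th percentile before binning
  (guards against near-zero SFA), and 3 points for alcohol inside a
  sex-specific moderate window (default 5–25 g/day for women, 10–50 g/day
  for men; both configurable). Range 0–27; the defaults put simulated
  cohort means near 12–14, in line with published cohort descriptives.
* Sodium enters DASH as absolute mg/day quintiles (not energy-adjusted
  density), a deliberate simplification.

Scores are z-standardized within each cohort (n−1 denominator).
Participants with a missing component intake are excluded from that score
(no imputation) with a logged count; energy under-/over-reporters are
removed first using configurable sex-specific bounds (default 500–3500
kcal/day for women, 800–4200 for men).

## Per-cohort EWAS

Outcome: per-CpG standardized M-values (so coefficients are M-value SDs
per 1 SD of diet score); zero-variance CpGs are dropped. Model 1 adjusts
for age (years), total energy (kcal/day), sex (omitted in single-sex
cohorts), smoking (never/former/current dummies, never as reference), five
of the six blood-cell fractions (granulocytes dropped — the six sum to 1
and would be collinear with the intercept), an ethnicity dummy in
multi-ethnic cohorts, and k surrogate variables. Model 2 adds BMI (kg/m²).
Designs are checked for rank deficiency up front, with the collinear
columns named.

**Surrogate variables** are the top-k right singular vectors of the
residual methylation matrix after regressing each CpG on the Model-1
design ("SVA-lite"; the full iteratively reweighted SVA is not
implemented). k defaults to 2, the order of magnitude reported for such
analyses. For speed the decomposition may use an evenly spaced CpG subset
(deterministic); vectors are orthonormal with the first non-negligible
loading made positive.

**Clustering.** Family/chip clusters can be handled two ways. The pipeline
default is OLS point estimates with Liang–Zeger cluster-robust standard
errors (CR1 small-sample scaling, two-sided t on G−1 degrees of freedom):
deterministic, non-iterative, and — like the random-effects mixed models
such studies typically fit — it retains between-cluster information, which
matters because with family clusters of size ~2 and intra-class
correlation of a few percent, fixed-effects absorption would discard about
half of a family cohort's effective sample. Within-cluster demeaning
(absorption) remains available (`cluster_mode="absorb"`) for users who
want the fixed-effects estimand; its residual degrees of freedom are
reduced by the number of clusters.

**Inflation correction.** The genomic inflation factor is
λ = median(χ²)/0.455. When λ > 1.05 for a (cohort, score, model)
combination, z-scores are fitted with a three-component Gaussian mixture
(null + two flanking signal components): fixed initialization
π = (0.9, 0.05, 0.05), μ = (0, −3, 3), σ = (1, 2, 2); EM with tolerance
1e-6 on the log-likelihood and at most 2000 iterations; entirely
deterministic (no Gibbs sampling). Two identification devices stabilize
the fit: the null component is constrained to be the narrowest (the
constrained M-step pools variances when violated, preserving monotone
ascent), and when reading off the estimates any flanking component whose
mean lies within one null-SD of the null mean is pooled into it — on
weak-signal panels the likelihood cannot distinguish such a component from
the null. Corrected statistics are z′ = (z − μ₀)/σ₀, β′ = β − μ₀·se,
se′ = se·σ₀. The correction is **deflation-only**: when the fitted σ₀ ≤ 1
the elevated λ is attributed to sampling noise or tail signal and records
pass through unchanged, since "correcting" with σ₀ < 1 would inflate every
test statistic. Panels with fewer than 1000 tests also pass through (the
mixture is not stable below that).

## Meta-analysis

Per CpG and score: fixed-effect β = Σwβᵢ/Σw with w = 1/se²;
Q = Σw(βᵢ−β)², I² = max(0, (Q−(k−1))/Q), DerSimonian–Laird
τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)); random-effects weights 1/(se²+τ²). The
reported triplet is the fixed one unless I² > 0.50 or p(Q) < 0.05
(strictly), in which case the random one is reported; p-values come from
the normal approximation (no Hartung–Knapp adjustment; REML τ² not
implemented). CpGs present in a single cohort (EPIC-only probes in a
one-EPIC-cohort study) pass through with k = 1 recorded and keep their
cohort-level t-based p-value — recomputing it from a normal would be
anti-conservative in the tail.

Bonferroni counts the CpGs analysed in ≥ 2 cohorts; FDR
(Benjamini–Hochberg via statsmodels) is computed within each score.
Attenuation is the signed percent change (β₁−β₂)/β₁×100 between Models 1
and 2; values below 10 % (including negative values — a *stronger*
coefficient after BMI adjustment) classify the CpG as BMI-independent.
β₁ = 0 is flagged undefined.

**Null behaviour of the reported p-values.** Under a global null the
fixed-effect meta p-values are uniform, but the reported triplet is
intentionally conservative: the heterogeneity rule conditions on a large Q
and then inflates exactly those CpGs' standard errors, shrinking roughly a
tenth of null z-scores. The calibration tests therefore check uniformity
on the fixed-effect p-values and verify that the reported ones are never
anti-conservative.

## Mendelian randomization

Instruments per CpG: mQTL records with p < 1e-8 (the mQTL-database
significance cutoff is not standardized; configurable), greedily LD-pruned
best-p-first at r² < 0.8. Harmonization aligns outcome records to the
exposure effect allele (sign and frequency flips for swapped alleles;
allele-incompatible records dropped) and removes palindromic (A/T, C/G)
SNPs with exposure EAF in (0.42, 0.58) — "close to 0.5" made concrete and
configurable. Steiger filtering keeps a SNP only when it explains strictly
more exposure than outcome variance, with r² = F/(F+n−2) from the F
statistic and sample size.

Estimators: the multiplicative random-effects IVW (weighted regression of
outcome on exposure effects through the origin, weights 1/se_out²; SE
scaled by √max(1, Q/(J−1))), MR-Egger (weighted regression with intercept
after orienting exposure effects positive; Rücker's Q on J−2 df; the same
multiplicative dispersion; t-based p-values) and the weighted median of
Wald ratios (cumulative-weight interpolation at 0.5; SE by a seeded
parametric bootstrap, default 1000 replicates). Binary outcomes are
reported as OR = exp(β) with a 95 % CI.

The validity checklist: Egger intercept p ≥ 0.05; sign concordance of IVW,
Egger slope and weighted median (the qualitative "magnitude and direction"
criterion implemented as direction only); Cochran and Rücker Q p ≥ 0.05;
mean F strictly > 10. A result is valid only if all four hold; a missing
estimator (J < 3) voids validity. Note that the Q statistics weight by the
outcome SE only, so noisy instruments (exposure-side variance θ²·se_exp²)
legitimately register as heterogeneity — with weak instruments a
non-trivial share of perfectly clean simulations is flagged, which is the
checklist working as designed, not an error.

## Enrichment

One-sided hypergeometric tail tests of a foreground gene list against each
user-supplied gene set (universe = supplied background; BH FDR across
sets), and per-category 2×2 Fisher exact tests of hit CpGs versus the
tested background for island relation and positional class. One gene per
CpG, intergenic CpGs excluded from gene enrichment. No probe-number bias
correction is applied (genes covered by more CpGs are more likely hit);
users can mitigate by constructing the background accordingly. The default
background is the set of tested CpGs' genes.

## Synthetic-data generator

What it emulates: four to five cohorts of unequal size (defaults mirror a
published study's 1736/1843/573/269/853 split, including one all-female
multi-ethnic sample, one family-clustered sample and two EPIC samples); a
per-person latent healthy-eating factor loading on log-scale intakes
(exponentiated — nonnegative and right-skewed); BMI coupled negatively to
the factor (slope 1.2 kg/m² per SD, residual SD 4.4); smoking coupled on a
liability scale; Dirichlet blood-cell fractions; batch shifts (SD 0.15)
and family intercepts (SD 0.2); per-CpG bimodal baselines; planted diet
effects of 0.07 per SD of score on unit-noise M-values (≈ M-value SD
scale) at 20 CpGs by default, of which 30 % act only through BMI
(BMI effect 0.3 per BMI SD); 100 smoking and 100 BMI CpGs as realistic
non-diet structure; mQTL instruments (20 SNPs/CpG, |β| ∈ 0.05–0.15,
exposure n = 30 000, 2-SNP LD blocks, 10 % palindromic, 30 % of outcome
rows allele-swapped so harmonization has work to do) and outcome GWAS
under configurable causal θ per trait (outcome n = 200 000).

Latent loadings were calibrated once so the three scores come out
moderately correlated with SDs near published cohort descriptives. An
important structural fact: the indices share food groups, so scores
computed from the same table remain substantially correlated even with all
latent loadings zero; the latent factor adds the *health-behaviour*
correlation on top and is what couples scores to BMI and smoking.

Determinism: one global seed; every component draws from a substream
derived from (seed, component label, cohort name) via CRC-32 spawn keys,
so regenerating any piece in isolation reproduces it byte-for-byte.

What it does **not** emulate: probe-level intensity noise and array QC
artefacts, realistic LD from reference panels, genotype-level data,
non-Gaussian methylation error, cohort-specific dietary measurement
instruments, population stratification. Passing tests therefore show the
*statistical machinery* is correct and calibrated under a faithful
covariance structure, not that real cohort results would be numerically
reproduced.

## Problem sizes used in tests and the acceptance script

Unit tests run on 3-cohort studies of a few hundred participants and a few
hundred CpGs. Calibration and recovery checks use the study conditions the
package targets: global-null studies of 4 cohorts (n 250–500) × 2000 CpGs
over 20 seeds, and full-scale recovery/mediation runs at the default
cohort sizes (total n 5274) × 2000 CpGs over three seeds each; the Monte
Carlo MR checks use 100–500 draws. The acceptance script uses one
full-scale recovery run, two mediation runs and five null studies.

## Known limitations

* The MMDS point scale and alcohol windows are one reasonable convention,
  not the only one in use.
* bacon-style correction partially absorbs pervasive weak true signal into
  σ₀ (the usual bias/power trade-off of inflation correction); the
  deflation-only rule protects the null case but cannot recover power lost
  when λ is elevated by genuine signal.
* The heterogeneity-aware effect choice makes reported null p-values
  conservative (see above); consumers needing calibrated nulls should use
  the fixed-effect columns.
* No sample-overlap correction across cohorts, no meta-regression, no
  multivariable MR or colocalization.
* With small instrument panels the weighted-median bootstrap SE is noisy;
  its p-value should be read qualitatively.
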