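# Methods

This note records the models, numerical choices and design decisions behind
`methylaging`, and what the synthetic-cohort tests do and do not establish
about real data.

## Clocks and age acceleration

A clock is data, not code: a CSV of CpG weights with one `(Intercept)` row
plus calibration metadata. Two calibrations are implemented.

* **identity** — the linear predictor is already an age in years. This is
  the convention of causality-enriched clocks; their published coefficient
  files are user-supplied inputs, and the repository ships only synthetic
  stand-ins generated by `synthetic_data.make_adaptive_clock`.
* **log_linear_adult** — the pan-tissue convention. Training used
  `F(age) = log(age+1) − log(A+1)` for `age ≤ A` and `(age − A)/(A+1)`
  above, with adult age `A = 20` by default; the package inverts `F`
  exactly (`calibrate∘F = id` to < 1e-10 over (0, 120]). The constants live
  in the clock file so other calibrated clocks can differ.

EAA is the plain difference EA − chronological age. A residual-regression
EAA assumes a linear EA–age relation; in leukemic cohorts that relation
breaks down, so the difference method is the package-wide definition.

Missing clock CpGs: policy `error` (default) lists them; `mean_impute`
substitutes the cohort mean at that CpG (0.5 when the CpG is absent from
the matrix entirely) and reports the imputed count. Real studies rarely
state their policy; both are provided.

Normalization pairing: pan-tissue-style clocks consume BMIQ-normalized
betas, identity clocks consume raw betas. The CLI applies this pairing by
default from the clock file's `requires_normalization` flag.

## PCA outlier filter

Per iteration: probes are mean-centered (no scaling — betas share one
scale); samples are projected on PC1; `d²_i` is the squared distance from
the mean along PC1; `z_i = (d²_i − mean d²)/sd(d²)`; one-sided
`p_i = 1 − Φ(z_i)` (squared distance is one-sided by construction); BH
adjustment; samples with adjusted p < 0.2 are removed. Iteration stops
when nothing is removed, when all remaining z lie in ±20, or at the
iteration cap (20).

The stopping range is read as applying to the z-scores; the QC report
records `stopping_quantity: "z_score"` so the alternative reading (PC1
coordinates) can be audited. Degenerate inputs (identical samples, zero
PC1 variance) return unchanged with a `zero_variance` status.

A calibration caveat that shapes the tests: under a well-calibrated null,
BH at FDR 0.2 flags at least one sample in roughly 20% of cohorts, so
"no false removals" is only a meaningful expectation when the PC1
coordinate distribution is short-tailed — a homogeneous reference
population whose PC1 is dominated by a bounded covariate (age). The filter
tests therefore use control-style cohorts (no mutation-group structure, no
latent-age jitter) at the several-hundred-sample scale typical of control
arms; at small n (≲100) the empirical moments of d² fluctuate enough that
occasional boundary clusters are flagged even in clean data. On
heterogeneous disease cohorts the filter will — correctly, by its own
criterion — also remove genuine biological extremes.

## BMIQ-style normalization

`bmiq_normalize` maps one sample's beta vector onto a reference (default:
the probe-wise median sample — deterministic and cohort-internal). A
three-state beta mixture (unmethylated / hemimethylated / methylated) is
fitted to each vector by EM: states initialized by thresholds
(≤ 0.2 / 0.2–0.8 / ≥ 0.8), M-step by weighted method of moments,
convergence at 1e-4 on the mean log-likelihood, 100-iteration cap
(non-convergence raises an error carrying the likelihood trace).

The beta axis is partitioned at the sample mixture's state crossover
points; the unmethylated and methylated partitions are mapped onto the
corresponding reference partitions through truncated state-conditional
beta CDFs (boundaries map to boundaries), and the hemimethylated span is
bridged linearly between the anchors. The composite map is continuous and
monotone, so within-sample rank order is preserved and the identity input
returns itself to ~1e-6. This is a self-contained beta-mixture quantile
normalizer in the BMIQ family: it performs between-sample quantile
matching per methylation state; it does not model Infinium type I/II probe
chemistry (out of scope for the array model simulated here).

## M-values and moderated differential methylation

M = log2(β′/(1 − β′)) with β′ clipped to [ε, 1−ε], ε = 1e-3 by default.

The two-group moderated t follows the standard empirical-Bayes scheme:
per-probe pooled variance s²_g with d = n₁+n₂−2 (complete-case, per-probe
df), prior (d0, s0²) fitted by method of moments on
e_g = log s²_g − ψ(d/2) + log(d/2): solve ψ′(d0/2) = var(e) − ψ′(d/2)
(Newton on the trigamma with bisection safeguard) and
s0² = exp(mean e + ψ(d0/2) − log(d0/2)). When var(e) ≤ ψ′(d/2) the prior
df is infinite; in that branch the prior variance is the geometric mean of
the observed variances, so the degenerate all-equal-variances input
returns the common variance exactly. Posterior variance
s̃² = (d0·s0² + d·s²)/(d0 + d); t̃ = diff/(s̃·√(1/n₁+1/n₂)) on d0 + d df,
capped at 1e6 (the t distribution is used throughout, never a normal
substitution). DMCs are probes at BH-FDR < 0.05 (configurable). Zero-
variance probes are rescued by the moderation floor; zero-difference
probes report t̃ = 0, p = 1.

Covariates are not modeled (two-group contrast only); the group means and
per-probe df machinery leave the extension open.

## Regions, PRC2m, LMC stratification

All intervals are 0-based half-open; manifest positions are 1-based and
become `[pos−1, pos)` for overlap. Strand is ignored (CpG methylation is
strand-symmetric) except in promoter windows, where "+" gives
`[tss−3000, tss+200)` and "−" mirrors it. Intersection is a two-pointer
sweep per chromosome, validated against per-base brute-force oracles on
random universes; fragments are not merged.

PRC2 targets = EZH2 ∩ SUZ12 peaks. PRC2m = unweighted mean beta over CpGs
inside the target regions, per sample; TSS/non-TSS PRC2m comes from
running the same score on the two TSS-annotation partitions.

LMC stratification: regions whose cohort-reference (probe-median sample)
mean beta falls below 0.3 are ranked ascending by that reference value and
cut into equal-count bins; samples are cut into seven equal-size groups
(remainder to the oldest groups, ties broken by sample ID) by
chronological or epigenetic age; each cell is the mean beta over the
group's samples and the bin's CpGs. The 0.3 threshold, the reference-mean
ranking key and the equal-count binning are package choices — the
low-methylated-region definition is conventionally inherited from
embryonic-stem-cell studies without a universal parameterization — and all
three are exposed in `LmcStratConfig`.

## Enrichment

Hypergeometric upper tail with N = measured probes after QC (the
genome-wide background relative to what the array measured), K = universe
probes in the TF's regions, n = DMCs, k = their overlap. The
fewer-than-five-CpG exclusion is applied to K (universe overlap) — the
standard guard against tiny annotation sets; a k-based mode exists behind
`exclusion_basis="dmc"`. Excluded TFs never enter the BH family. The
EA-correlation ranking uses the per-TF mean binding-site methylation
(one score per sample per TF), partial Pearson against EA controlling
chronological age.

## Inferential toolbox

* Mann–Whitney U: exact two-sided p by enumerating all group assignments
  for pooled n ≤ 12 (enumeration handles ties without a separate
  correction); otherwise the normal approximation with midrank tie
  correction and 0.5 continuity correction. Exactness matters at the
  carrier-group sizes (≈ 18–50) that mutation screens produce.
* BH: `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1.
* Partial correlation: residuals from simple regressions on the control;
  equals the closed-form first-order formula to < 1e-10.
* Association outliers: |residual| > 2·SD(residuals) around the
  least-squares line; a near-zero residual SD (perfectly linear input)
  flags nothing.
* Median stratification: ties go to Low, deterministically.
* Survival: product-limit KM and the two-group log-rank
  (χ² = (ΣO−ΣE)²/ΣV with hypergeometric variance per event time,
  single-subject risk sets contribute zero variance), both cross-checked
  against lifelines in tests. Truncated-horizon contrasts (e.g. the first
  18 months of follow-up) are administrative censoring at the horizon
  before the test.
* Mutation screen: genes with ≥ 3 carriers tested carrier vs non-carrier;
  BH family = tested genes per score; screened-out genes reported. The
  multiple-testing family is configurable and logged because published
  analyses rarely state theirs.

## Synthetic cohorts: what they emulate

Defaults describe a mid-sized AML-like cohort: n = 200 samples, 5000
probes, ages uniform 20–90. Latent biological age = chronological age +
Normal(0, 5 y) jitter (`bioage_jitter_sd`); 200 age CpGs drift at 0.002
beta-units per latent-age year around a 0.4 baseline — the magnitude of
typical blood aging CpGs; 40 PRC2 regions × 8 probes with baselines
0.08–0.20 gain 0.002/year of latent age; DNMT3A-like carriers (25%) carry
a −0.08 PRC2-region shift and IDH2-like carriers (10%) +0.06 (signs from
the studied biology: the mutations' directions of PRC2-target
dysmethylation; magnitudes are free parameters chosen to be detectable at
n = 200 without being trivial — no published effect sizes exist to match);
remaining probes get bimodal Beta-mixture baselines constant across
samples; Gaussian noise sd 0.02; optional global +0.3 outlier samples.
Survival is exponential with the Low-adaptive group at a 24-month median
(AML-scale) and hazard ratio `survival_hazard_ratio_high_vs_low_adapt`
(default 2.5) for the High group, plus independent exponential censoring
matched to a 30% expected censoring fraction. The config value is the
literal hazard ratio High/Low; values < 1 encode the protective direction
of high adaptive age that motivates the stratification, and the log-rank
detection question is symmetric in HR ↔ 1/HR.

Two named condition sets recur in tests: *control-style* (no mutation
structure, zero jitter, n = 656 — a homogeneous reference population for
the outlier filter) and *latent-age-driven* (jitter 15 y, no mutation
shifts) for the LMC stratification contrast, where biological age must
genuinely decouple from chronological age for adaptive grouping to
out-resolve chronological grouping; at the default 5-y jitter the two
groupings are nearly equivalent by construction and the contrast is within
noise. Mutation-shift structure is likewise excluded there because
carrier-composition fluctuations between age groups perturb per-bin
monotonicity for reasons unrelated to the stratification logic.

What passing tests show: the pipeline recovers every planted effect —
linear in the generator — at the stated sizes, with calibrated error
rates. What they do not show: robustness to array chemistry (type I/II
probes), SNP-affected probes, cell-composition shifts, batch structure, or
non-linear age trajectories; none of these is simulated.

## Determinism

Every generator function takes a seed and uses one `numpy` Generator;
identical seeds give bit-identical matrices, files and downstream results.
CLI workflows write a run manifest (version, config, seed) sufficient to
reproduce the run; summaries are byte-identical across reruns.
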