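# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `cvrsearch`.

## Biomarker model

A candidate biomarker is a composite value ratio (CVR): two disjoint,
non-empty region sets (numerator, denominator) combined per scan by either a
simple mean of regional SUV (`mean_suv`) or a volume-weighted mean
(`volume_weighted`), then divided. Because every regional SUV of a scan
shares multiplicative confounds (dose/mass normalization, scanner bias,
global uptake level), such factors cancel exactly in the ratio; the package
asserts this cancellation to machine precision. Working from SUV or SUVR
inputs is therefore equivalent as long as the SUVR reference is common to
all regions of a scan.

In bilateral (`-B`) pipelines, left/right pairs are first collapsed to one
unit with volume `v_L + v_R` and SUV `(s_L v_L + s_R v_R)/(v_L + v_R)`.
The hemispheric average is volume-weighted — a deliberate choice, since it
makes the collapsed unit identical to the whole bilateral structure and
makes "collapse then compose" an exact algebraic no-op under volume
weighting (tested to 1e-12). In `mean_suv` pipelines each bilateral unit
then contributes one term to the unweighted mean, preserving
one-unit-one-vote semantics.

## Longitudinal model and metrics

Log biomarker trajectories are modelled per subject *j*, observation *i* as

    y_ij = β0 + β1 t_ij + β2 DX_j + β3 t_ij DX_j + b0j + b1j t_ij + ε_ij

with (b0j, b1j) ~ N(0, G) (unstructured 2×2, correlated) and
ε ~ N(0, σ_ε²). Time is centred at each subject's mean visit; together with
the correlated random effects this makes all reported metrics invariant to
shifting a subject's visit schedule (tested at 1e-6 relative, the precision
of the variance-component optimizer). DX = 1 for cognitively impaired (CI)
subjects.

Metrics:

* **Group separation** = β̂3 / SE(β̂3), a Wald ratio without finite-sample df
  correction — only its relative magnitude feeds the search objective.
* **Repeatability** = 100 × SD of the conditional residuals
  ε̂ = y − Xβ̂ − Zb̂ (sample SD, ddof = 1). The σ̂_ε parameter itself is also
  exposed (`use_sigma_eps=True`); the conditional-residual SD is the default
  because it is the literal "SD of the model residuals". With few visits per
  subject, BLUP shrinkage makes it slightly smaller than σ̂_ε.
* **Variance components** σ̂_b1², σ̂_ε² feed the trial power formula.

### Fitting

Fitting is restricted maximum likelihood (REML); maximum likelihood is used
only where nested models must be compared (the correlated-vs-independent
random-effects χ² test, df = 1, slightly conservative near the ρ = 0
boundary). The fitter is written in the package rather than delegated: the
genetic algorithm, the parametric bootstrap and the coverage simulations
refit the *same* design against thousands of response vectors, so the
likelihood is profiled onto per-subject sufficient statistics. With
Z_j = [1, t] and Ψ = G/σ², each subject contributes 2×2 blocks
(B_j = I + Ψ Z_j'Z_j) via the Woodbury identity; β and σ² are profiled out,
and the gradient of the profiled deviance follows from the envelope theorem
in closed form. Optimization is L-BFGS-B with analytic gradients on a
log-Cholesky parameterization (bounds keep variances in [e^-28, e^16] times
σ²), with two fixed starting points; convergence requires an optimizer
success at the best deviance or a vanishing gradient there. Variance
collapse at the boundary (σ_b1 → 0) is reported as a warning, not an error.
The implementation is validated against statsmodels `MixedLM` (REML and ML
log-likelihood to ~1e-8, fixed effects to ~1e-7 on fixtures) and against
simulation truth. Bootstrap replicates warm-start from the parent fit's
solution (falling back to the full multi-start sweep if that fails); search
evaluations always use the deterministic cold starts so a genome's fitness
never depends on evaluation order.

## Trial sample size

The sample size estimate (SSE) is the per-arm count for a two-arm, 1:1,
fixed-duration trial testing a reduction of the mean biomarker slope:

    n = 2 (z_{1−α/2} + z_{power})² (σ_b1² + σ_ε² / Σ_k (t_k − t̄)²) / Δ²

with Δ = pct_change × |group slope| (slope = β1 for CU trials, β1 + β3 for
CI trials), defaults power = 0.80, α = 0.05 two-sided, pct_change = 0.20.
This is the random-slope ("Edland-type") form appropriate for a fitted
random-intercept/slope model with a fixed visit schedule; the shipped
designs use two visits, {0, 4.5} years (preclinical/CU, `experiment1`) and
{0, 1.5} years (clinical/CI, `experiment2`), but any schedule is accepted
and enters through Σ(t_k − t̄)². Variance components come from the single
joint two-group fit (the printed model), the slope from the design's group.
Monte-Carlo two-arm trial simulations at the formula's own n give empirical
power within [0.75, 0.85] across σ_b1 ∈ {0, 0.01, 0.03} ×
σ_ε ∈ {0.01, 0.05} (2000 replicates per setting).

The SSE is an exact inverse-square function of the effect size before
ceiling; the ceiling is applied last, and the raw (pre-ceiling) value is
used inside the search fitness to avoid integer plateaus.

**Fitness** = separation / SSE^e with e = 2 by default (configurable):
squaring mildly prioritizes trial efficiency, and the signed separation
forces discovered biomarkers to rise faster in the impaired group. Failed
fits and zero-slope candidates map to a −∞ sentinel that ranks below every
valid candidate.

## Genetic algorithm

Genomes are vectors over searchable units (regions, or bilateral pairs plus
midline regions) with alleles 0 = numerator, 1 = excluded, 2 = denominator.
Two priors restrict the space: units containing Braak-stage-1–3 regions are
barred from the denominator, and units containing conventional SUVR
reference structures are barred from the numerator. Both lists live in the
region metadata (flags, not hard-coded names), so other atlases can redefine
them.

Operators, with design decisions where the operator family alone does not
pin down integer-alphabet semantics:

* **Selection**: tournament of 3, drawn with replacement, ties to the first
  drawn (exactly testable: P(best of 4 wins) = 37/64).
* **Crossover**: BLX-α (α = 0.5) with clamp to [0, 2] and round-half-up —
  the closest continuous-blend reading that yields valid alleles; per-gene
  allele probabilities follow from interval masses and are tested against
  them. Uniform crossover is available via `GAConfig(crossover="uniform")`.
* **Mutation**: each unpinned gene resamples to one of the other two alleles
  with probability `rate`; `rate` starts at 1/L and multiplies by
  `mutation_boost` (cap 0.5) every `stagnation_window` generations without
  improvement, resetting on improvement — the package's concrete reading of
  "adaptive" mutation.
* **Repair, not rejection**: after crossover/mutation, ineligible
  assignments are excluded, pinned genes restored, and an emptied side
  receives one uniformly chosen eligible unit. This keeps the population
  size fixed and every evaluated genome valid (asserted at the evaluation
  gate).
* **Elitism** (1 copy) makes the best-so-far trace monotone and testable.
* **Memoization** of fitness by genome key: with population 32 the search
  revisits genomes constantly; cache statistics are reported.

Restricted searches (fixing the numerator to a named composite, or the
denominator to a reference) are expressed as pinned gene values
(`frozen_assignments`), validated against the priors at construction.

A brute-force oracle enumerates all constraint-valid genomes for ≤ 8 units;
on ≤ 6-unit synthetic problems the GA reaches the enumerated optimum on
every tested cohort/seed combination.

## Baseline grid, ablation, bootstrap

The literature grid crosses 10 composite targets (Braak stages 1–6 as
stage-specific sets, meta-temporal, mesial-temporal, temporoparietal,
'rest') with 11 references (whole cerebellum, inferior cerebellar GM,
composite reference, eroded subcortical WM, cerebellum cortex, brainstem,
and five of their unions) under both composition methods: 220 biomarkers.
The meta-temporal and composite-reference memberships are fixed published
lists and ship as such in the default atlas metadata; mesial-temporal,
temporoparietal and 'rest' memberships are defined in cited literature we do
not reproduce verbatim, so the shipped lists are provisional and editable
(metadata is user-extensible; unknown composite labels are retained).
Combinations that do not resolve against a given metadata (empty membership,
overlapping sides) are kept in the catalog marked unusable with a reason, so
the count identity |targets|·|references|·2 always holds.

Ablation re-evaluates a spec with one region removed at a time, skipping
(with reason) removals that would empty a side.

Uncertainty comes from a model-based parametric bootstrap: holding X, Z and
β̂ fixed, each replicate draws b* ~ N(0, Ĝ) and ε* ~ N(0, σ̂_ε²), rebuilds
y*, refits, and recomputes the metrics; intervals are 2.5/97.5 percentiles
over B replicates (default B = 500 — the replicate count is a package
choice). Non-convergent replicates are dropped and counted; > 20% failures
flags the interval unreliable. Percentile (not normal-approximation)
intervals match the usual mixed-model bootstrap practice. As the variance
components go to zero, SSE and repeatability intervals collapse onto their
noise-free limits; the separation t-statistic instead diverges (its SE is
proportional to the vanishing noise), so it is not a collapse witness. In a
200-cohort outer simulation the 95% separation interval covers the
truth-derived Wald value ~94% of the time at B = 300.

## Amyloid screening

Fixed published cutoffs are boundary-inclusive (value ≥ cutoff is positive).
The data-driven cutoff fits a two-component univariate Gaussian mixture (EM
with 10 restarts, k-means++ initialization, tolerance 1e-8; components
sorted by mean) and places the threshold where the weighted component
densities are equal — the posterior-0.5 Bayes boundary — found by root
bracketing in (μ1, μ2) and equal to the closed-form quadratic root to 1e-8.
The published real-data cutoff value itself is not reproducible without the
corresponding cohort; only the mechanism is testable. Alternative rules
(density valley; μ1 + 2σ1) are available because the derivation rule behind
the published number is not stated.

## Synthetic cohorts

The generator emulates amyloid-positive longitudinal tau PET cohorts:

    log suv_jr(t) = m_r + a_j + (s_{r,g} + c_j)·t + log g_j(t) + e_jrt

with (a_j, c_j) bivariate normal (σ_b0 = 0.05, σ_b1 = 0.01, ρ = 0.5),
g_j(t) lognormal with σ_g = 0.05 shared by all regions of a scan (the
embodiment of the per-scan confounds that ratios cancel), regional noise
σ_noise = 0.02, and group-dependent planted slopes: signal regions
accumulate at 0.015 /y (CU) and 0.045 /y (CI) on the log scale — within the
range of reported annual tau PET change — while stable and reference
regions are flat. Volumes are region constants with 2% subject-level
lognormal jitter. Visit counts are 2–4 (probabilities 0.55/0.30/0.15) and
inter-visit intervals are drawn from the observed cohort mix over bins
≤1.5 / 1.5–2.5 / 2.5–3.5 / >3.5 years (0.61/0.22/0.06/0.11 for the CU-style
preset, 0.72/0.17/0.06/0.05 for the CI-style preset), uniform within bins,
first visit at 0. Presets: `experiment1_like` and `experiment2_like` use
76 CU + 122 CI subjects over a 17-unit panel (meta-temporal signal regions,
late-Braak stable cortex, the reference structures); `tiny_oracle` uses 6
lateral regions and 40 subjects for exhaustive-search tests.

**What the generator does and does not emulate.** Because the subject-level
random effects and the scan-scale factor are shared by all regions, *any*
ratio cancels them exactly: a fitted CVR retains only regional noise and the
planted slope structure. This makes the core claims sharply testable (ratio
repeatability ≈ 0 while single-region residual SD ≈ 100·σ_g; β̂3 recovers
the planted slope gap), but it also means synthetic separations (~40–60)
and sample sizes (~10 per arm) are far more favourable than real-cohort
values, where regional noise is correlated, confounds are only approximately
multiplicative, and between-subject progression heterogeneity survives the
ratio. Passing tests demonstrate correctness of the machinery, not expected
real-data effect sizes. Off-target binding and atrophy-driven partial-volume
effects are deliberately not modelled.

## Default atlas metadata

`data/dk_regions.csv` ships a Desikan–Killiany-style panel: 34 cortical
regions per hemisphere plus amygdala, hippocampus and ventral diencephalon,
the cerebellar and white-matter reference structures, brainstem, and five
corpus-callosum segments (87 regions). Braak-stage assignments follow the
standard stage-specific ROI mapping. Exact parity with any particular
cohort's available-region list is not claimed; the loaders accept arbitrary
metadata with the same schema.

## Problem sizes used by the test suite

The end-to-end suite runs on one CPU in roughly ten minutes by choosing
moderate sizes: discovery checks use the `experiment2_like` cohort with 35
GA generations × 10 seeds (the 300-generation default remains in
`GAConfig`); oracle-equivalence uses three ≤ 6-unit cohorts; mixed-model
recovery uses 100 replicates of 400 subjects × 3 visits; power calibration
uses 2000 trials per setting; bootstrap coverage uses 200 outer cohorts of
40 subjects at B = 300. Fitness on the discovery cohort converges to the
same optimum across all tested seeds (coefficient of variation ≈ 0).

## Known limitations

* No covariates (sex, APOE4, education) — excluded by design.
* Attrition, interim analyses and unequal allocation are out of scope; the
  power formula assumes complete two-visit follow-up per participant.
* The fitness is a single scalar; no Pareto front over (SSE, separation,
  repeatability).
* The mixed model assumes Gaussian errors on the log scale and a shared
  residual variance across groups.
* Search results are exchangeable JSON (`RatioSpec` + pipeline), but no
  brain-surface visualization is provided.
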