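# Methods

## Trajectory model

A biomarker quantity under treatment is modeled as two linear segments
joined at a patient-specific inflection time:

C(t) = α + S(t_inf − t)·β·t + S(t − t_inf)·(β·t_inf + γ·(t − t_inf)) + ε,
S(x) = 1 if x > 0 else 0.

The literal strict indicators leave C(t_inf) = α, a removable discontinuity
of the parameterisation; likelihood evaluation uses the left-limit
convention (α + β·t_inf at t = t_inf), which makes the trajectory
continuous. The literal form is retained behind the
`literal_indicators` flag of `piecewise_eval` for anyone who needs the
verbatim parameterisation.

The noise term is quantity-proportional technical variation: observations
are Gaussian with sd σ_ε·|C(t)|. A predicted mean of exactly zero makes
this noise scale degenerate and is reported as an error rather than being
regularised away — with positive concentrations and the generator's
positivity truncation (below) it does not occur in practice.

### Hierarchy and priors

Patient-level parameters are drawn from population distributions:

- log α ~ N(μ_α, σ_α²);
- β = α·(β₁ + s₁·E₁·β₂)/365 with β₁ ~ N(μ_β1, σ_β1²),
  log β₂ ~ N(μ_β2, σ_β2²), E₁ ~ Bernoulli(p₁);
- γ = α·(γ₁ + s₂·E₂·γ₂)/365, analogous, with probability p₂;
- t_inf ~ U(21, PFS − 21) days (censoring time substitutes for PFS in
  censored patients — the minimal extension that keeps the support proper).

The listed distributions are on the mixture *components*, not on β itself;
β is the deterministic product of α with the stochastic mixture. The
log-normal component is strictly positive, so a sign switch (s₁, default
−1) decides whether it deepens the decline or steepens a rise; the
post-inflection sign defaults to +1 (rebound component). The two-component
construction reflects the two empirically observed sub-populations of
trajectory shape.

Slope components are *relative rates per 365 days*. Units must be fixed by
convention because a per-day reading at the magnitudes used for the
hyperpriors would cross zero within days; on the per-year scale the default
values correspond to declines of roughly 15–40% per 100 days and rebounds
of similar magnitude, which matches the reported median biomarker dynamics
under bevacizumab (≈15–30% reduction within two weeks to two months,
partial rebound by progression).

Hyperpriors are normal on every location and scale (the second parameter is
a variance), uniform (0.2, 0.7) on p₁/p₂. Normal hyperpriors on scale
parameters admit negative values; all scales are truncated to (0, ∞), which
is required for a valid model. The default (vascular-marker) hyperprior set
is `TIE2_PRIOR`.

### Sampler

No closed-form full conditionals exist for t_inf, so the sampler is
adaptive Metropolis-within-Gibbs:

- vectorised random-walk updates per patient-level block (log α, β₁,
  log β₂, γ₁, log γ₂, t_inf), with t_inf proposals reflected into
  [21, PFS − 21]; proposal scales adapt during burn-in toward 20–50%
  acceptance and are frozen afterwards;
- exact Bernoulli full-conditional flips for E₁/E₂;
- two likelihood-free label-mixing moves, repeated three times per
  iteration because they are cheap: an exact Gibbs refresh of the inactive
  log-normal latent (its full conditional is its population prior when
  E = 0), and a *compensated flip* that toggles E while shifting the normal
  component to keep the total slope — and hence the likelihood — unchanged.
  Without these, chains stall in label-assignment modes and the slope
  hyperparameters mix poorly;
- conjugate normal draws for location hyperparameters, truncated-Beta
  inverse-CDF draws for p₁/p₂, random-walk updates (positive-reflected) for
  scale hyperparameters and σ_ε.

Chains are initialised over-dispersed around crude per-patient estimates
(first observed value for α, decline-to-minimum rate for β, rebound rate
for γ, time of the minimum for t_inf), with chain-indexed jitter.

Default chain protocol: 3 chains × (2,000 burn-in + 5,000 retained)
iterations — sized for synthetic desk problems of ~70 patients, where this
runs in under a minute and the monitored hyperparameters reach R-hat ≲ 1.2
(the weakly identified mixture hyperparameters mix slowest). Trial-scale
protocols (50,000 + 100,000) are available through `MCMCConfig`.

Convergence is summarised by the classic between/within-chain potential
scale reduction factor, clamped below at 1 (the pooled-variance estimate
can fall marginally under the within-chain variance by sampling noise);
effective sample sizes come from arviz. A parameter with zero within-chain
variance is reported as undefined rather than crashing.

### Pseudo-trials

`impute_pseudo_trial` draws, independently for each grid time, a posterior
parameter vector and emits a predictive value including the proportional
noise term; the default grid is monthly with ±5-day jitter up to the
patient's PFS. This interpolates the patient's own trajectory — no new
patients are created. Per-time independent draws propagate the full
posterior uncertainty into the imputed series; they also make the series
noisier than any single posterior trajectory, which matters when the nadir
rule is applied to them (see threshold optimization).

## Rules

**Response.** The minimal reduction distinguishable from technical noise is
derived from duplicate pre-treatment measurements: per-patient log2 ratios
are fitted by a zero-centred normal (sd = RMS of the ratios, symmetric
under replicate swap), the 95% half-width is 1.96·sd, and the implied
response fraction is 1 − 2^(−half-width), reported rounded to the nearest
5 percentage points. A response is called at the first on-treatment visit
whose value falls below baseline × (1 − threshold) within the window —
63 days (three 21-day cycles) by default, 42 for two-week cycles; an
optional flag requires two consecutive qualifying visits (confirmed
response).

**Progression.** Points are scanned in time order keeping the running nadir
of strictly earlier on-treatment values (the baseline is not part of the
nadir); progression is called at the first point ≥ nadir × (1 + threshold).

**Threshold optimization.** Repeated pseudo-trials are scanned at each
candidate threshold. A call counts as a correct prediction when the patient
progressed and the alarm fired at or before the recorded progression date
and within a configurable maximum lead window (default 180 days) of it;
the optimum maximises the fraction predicted, breaking ties toward the
smaller median absolute lead-time. The lead window operationalises
"reasonably close to the genuine progression date" without rewarding
alarms that fire a year early; note that with early inflections and a
finite window, smaller thresholds (earlier alarms) can be *penalised*,
so studies of the threshold's intrinsic discrimination should disable the
window (`max_lead_days=inf`), as the validation suite does.

**Combination.** Vascular and epithelial calls combine by OR with the
earliest call time. The OR rule dominates each single biomarker's
prediction fraction by construction.

**Lead-time.** Mean over co-called patients of (epithelial call time −
vascular call time); positive values mean the vascular alarm precedes.

## Correlation networks

Within a phase window (pre-treatment ≤ day 0; monotherapy days 1–14;
combination days 15–180) each patient contributes the median of their
in-window values per biomarker — the aggregation is not prescribed
anywhere authoritative, and the median is robust and consistent with the
package's other summaries. Pearson correlations are computed across
patients on pairwise-complete cases (circulating markers on the log2
scale; imaging fractions raw), with per-pair n recorded and pairs under 3
complete cases flagged undefined. Edges are classified by magnitude:
|r| ≥ 0.5 solid, 0.35 ≤ |r| < 0.5 dotted, otherwise hidden — sign is
retained in the export but the display rule is a magnitude rule. Phase
differences report Δr per pair and class transitions (hidden→displayed =
induced, displayed→hidden = lost).

## Trajectory clustering

Per-patient log2-ratio-to-baseline trajectories are linearly interpolated
onto the nominal visit grid (no extrapolation beyond each patient's
observed span), compared by correlation distance (1 − Pearson r,
pairwise-complete, with degenerate pairs treated as uncorrelated), and cut
into two cohorts by average-linkage agglomerative clustering — average
linkage being the standard companion of correlation distance; it is
configurable in the assignment record. Labels are content-defined (cluster
1 = deeper mean decline) so they are stable under patient reordering.
Cluster comparisons use each patient's mean log2 ratio over treatment as
the summary (the comparand is not prescribed; a per-patient summary keeps
the rank-sum test's independence assumptions intact) with a two-sided
Mann–Whitney U test, plus per-cluster median curves with standard errors
for plotting. Projection re-uses one biomarker's labels on another
biomarker unchanged.

## Survival screen

Cox machinery is lifelines' (Efron tie correction, the standard choice
when ties are present). The univariate screen fits each covariate alone
(continuous, or median-dichotomized on request), flags proportionality by
a Schoenfeld-residual trend test and nonlinearity by Martingale-residual
trends (linear and quadratic) at p < 0.05 — numeric stand-ins for what is
usually a visual check — applies a log2 re-fit to flagged positive
covariates, and marks covariates with Wald p < 0.05 for multivariate
entry. Backward-stepwise selection removes the largest p ≥ 0.05 until all
remaining covariates are significant, resolving exact collinearity by
dropping the later-listed member. Bootstrap validation refits on patient
resamples (zero-event or degenerate resamples skipped and tallied) and
retains covariates whose significance frequency strictly exceeds 66% —
significant in at least two cases out of three. The ratio covariate
divides two pre-treatment values (zero denominators flagged and excluded).
The percentile split cuts at the smallest observed value at or above the
requested percentile with the boundary order statistic in the low group —
the convention under which the 33rd percentile of 70 patients yields a
24/46 split — and compares groups by Kaplan–Meier estimates and a log-rank
test. Cluster-vs-covariate association uses Fisher's exact test, with
degenerate tables reported as p = 1 with a flag.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
70 patients by default; log-normal PFS calibrated to a 283-day median
(truncated below 42 days so the inflection support is proper) with 10%
independent censoring; per patient and biomarker a hierarchical draw of
(α, β₁, β₂, E₁, γ₁, γ₂, E₂, t_inf); dense early visits then ~4-weekly
follow-up; independent per-visit missingness (with at least three
on-treatment visits always retained so every patient stays modelable);
and two noisy pre-treatment replicates at days −7 and 0.

Two deliberate deviations from a naive hierarchical draw:

- **Positivity truncation.** A linear-in-t trajectory with unconstrained
  slopes and an independent uniform inflection eventually crosses zero.
  The continuous magnitudes and the inflection are redrawn until the
  noiseless trajectory stays above 5% of baseline through follow-up; the
  Bernoulli indicators are drawn once so the realized mixture fractions
  still follow p₁/p₂ exactly. At the default slope scales the truncation
  is mild (realized population means shift by well under one standard
  error at n = 5,000).
- **Inflection anchoring.** A spec may declare `inflection_lag_days`,
  anchoring its inflection at the first biomarker's inflection plus a
  fixed lag (clipped to the valid support) — modeling compartments that
  progress in sequence, as used for vascular→epithelial lead-time studies.

What the generator does *not* emulate: assay drift and batch effects,
informative missingness (drop-out correlated with progression), visit-time
measurement error, correlation between biomarkers beyond shared inflection
structure, and any link between trajectory shape and the PFS draw itself.
Passing tests therefore demonstrate that the analysis recovers the
structure it assumes, not that real trial data satisfy those assumptions.

## Validation scale and numerical choices

The validation suite exercises: the response-rule arithmetic on the printed
log2 half-widths (0.53 → 30%, 0.42 → 25%); piecewise evaluation against a
branch-based reference (1,000 random draws, 1e−12); full parameter
recovery on a 70-patient cohort at 3 × (2,000 + 5,000) iterations
(≥80% hyperparameter coverage at 95%, inflection median absolute error
≤ 30 days); R-hat separation of same-distribution vs 10-sd-offset chains;
the nadir rule against an exhaustive prefix-nadir scan with threshold
monotonicity; the pseudo-trial optimizer against an independent re-scan of
the identical pseudo-trials (200 repetitions, 24 patients); lead-time
recovery of a generative 50-day vascular→epithelial offset at n = 70
(low-noise cohorts, since running-nadir false alarms at 15% noise would
contaminate the estimand); block-correlation network recovery (within
r = 0.7 vs across 0, n = 70); two-shape clustering recovery (Rand ≥ 0.9)
with projection discrimination over 100 seeded cohorts; and the survival
screen's power (HR 3 at n = 70), null calibration, bootstrap retention,
exhaustive Fisher enumeration agreement, and the 24/46 percentile split.
Simulation counts are sized so the whole suite completes in a few minutes
on one CPU while leaving each check's Monte-Carlo error well inside its
assertion margin.

Known limitations: the mixture hyperparameters (μ_β2, σ_β2 and the γ
analogues) are weakly identified — only patients with the active indicator
inform them — so their effective sample sizes are low at desk-scale chain
lengths and their posteriors stay prior-influenced; the sampler targets the
untruncated hierarchy while the generator truncates to positive
trajectories, a mismatch kept negligible by the mild truncation; and the
progression rule's behaviour under heavy technical noise (running-nadir
false alarms) is a property of the rule itself that users should weigh
when choosing thresholds for noisy assays.
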