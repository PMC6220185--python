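# vegfmon

Monitoring tumor response to anti-angiogenic (VEGF-inhibitor) therapy
through longitudinal biomarkers. The package is aimed at biostatisticians
and translational researchers working with serial plasma markers (Tie2,
Ang2, CK18/M65, VEGFR2, ...) and per-visit DCE-MRI summaries (K-trans,
IAUC60, tumor volumes) from trials in which a VEGF inhibitor such as
bevacizumab is combined with cytotoxic chemotherapy.

## The model

Each patient's biomarker trajectory is treated as piecewise-linear in
treatment time with a single inflection:

    C(t) = α + S(t_inf − t)·β·t + S(t − t_inf)·(β·t_inf + γ·(t − t_inf)) + ε

where α is the pre-treatment quantity, β < 0 the on-treatment decline, γ the
post-inflection slope, S the indicator function (1 if x > 0), and ε technical
noise proportional to the biomarker quantity (sd = σ_ε·|C(t)|). The
inflection time t_inf — uniform on (21, PFS − 21) days — is read as the
earliest sign of progression in that biomarker's tissue compartment
(vascular for Tie2, epithelial for CK18).

The population level is hierarchical: log α ~ N(μ_α, σ_α²) and the slopes
are two-component Bernoulli mixtures, β = α·(β₁ − E₁·β₂)/365 with
β₁ ~ N(μ_β1, σ_β1²), log β₂ ~ N(μ_β2, σ_β2²), E₁ ~ Bernoulli(p₁) (and the
analogous γ construction), capturing the two observed sub-populations of
decline/rebound behaviour. Posteriors are drawn by an adaptive
Metropolis-within-Gibbs sampler (three over-dispersed chains, Gelman–Rubin
diagnostics), and posterior-predictive *pseudo-trials* re-sample each
patient's trajectory on a monthly (30 ± 5 day) schedule.

On top of the model sit the clinical rules and screens:

- **response rule** — a reduction beyond the 95% CI of replicate variation
  (1 − 2^(−1.96·sd_log2); ≈30% for Tie2, ≈25% for CK18) within three cycles;
- **progression rule** — a rise above the running nadir beyond an alarm
  threshold, optimized over pseudo-trials (≈40%/50%);
- **correlation networks** per treatment phase (|r| ≥ 0.5 solid,
  0.35 ≤ |r| < 0.5 dotted, else hidden) and their drug-induced changes;
- **trajectory clustering** (correlation distance, average linkage, k = 2)
  with projection of the cluster labels onto other biomarkers;
- **prognostic survival screen** — univariate Cox with Schoenfeld/Martingale
  checks, backward-stepwise selection, 1,000-resample bootstrap with the
  strict >66% retention rule, ratio covariates (e.g. VEGFR2:K-trans),
  33rd-percentile Kaplan–Meier split and Fisher's exact association.

Everything is exercisable on the bundled synthetic-cohort generator, which
emulates a 70-patient trial (log-normal baselines, mixture slopes, one
inflection per patient/biomarker, proportional noise, irregular visits with
missingness, duplicate pre-treatment replicates, censored PFS with median
≈283 days).

## Worked example

```python
import vegfmon as v
from vegfmon import trajectory_model as tm

ds = v.generate_cohort([v.TIE2_SPEC], n_patients=70, seed=11)
draws = v.run_mcmc(ds, "Tie2", tm.TIE2_PRIOR,
                   tm.MCMCConfig(n_chains=3, burn_in_iters=2000,
                                 sample_iters=5000, seed=5))
report = v.gelman_rubin(draws)
print(round(draws.patient_median("t_inflection").iloc[0], 1))
print(round(report.rhat["mu_alpha"], 3))

series = ds.patient_series("P01", "Tie2")
print(v.call_progression(series, threshold_fraction=0.40))
```

prints (seed 11 / 5):

```
174.7
1.0
ProgressionCall(patient_id='P01', biomarker='Tie2', called=True,
                call_time_days=210.0, nadir_value=19.83...,
                nadir_time_days=182.0, threshold_fraction=0.4)
```

— patient P01's vascular inflection is located at ~175 days, the population
baseline hyperparameter mixes cleanly (R-hat 1.0), and the 40%-above-nadir
rule raises the vascular-progression alarm at day 210 against the day-182
nadir.

The full pipeline (simulate → fit → rules → networks → cluster → survival)
is driven by one YAML config through the CLI:

```bash
vegfmon all --seed 4 --out out/       # complete bundle
vegfmon validate --config my.yaml     # report every config violation
```

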