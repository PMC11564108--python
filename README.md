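# adaptrial

Simulation and inference toolkit for an outcome-adaptive, ctDNA-biomarker-
driven platform trial in metastatic castration-resistant prostate cancer
(mCRPC).

## The problem

In mCRPC, randomized evidence comparing the two main therapy classes —
androgen receptor pathway inhibitors (ARPIs) and taxanes — and identifying
*which patients* benefit from which class is scarce. A biomarker-driven
platform trial addresses this by profiling circulating tumor DNA (ctDNA) at
entry, classifying each patient into one of 16 biomarker subgroup
combinations (AR SNV/GSR, clonal TP53 alteration, homologous recombination
deficiency, TMPRSS2–ERG fusion), and adapting randomization probabilities
toward the biomarker–treatment combinations that accumulate evidence of
benefit. Efficacy is evaluated within five overlapping biomarker
*signatures* (unions of subgroups), with early-termination rules for
graduation (success) and futility.

`adaptrial` implements this design end to end as a library for
biostatisticians: biomarker classification from variant tables, synthetic
cohort generation under configurable true-effect scenarios, the composite
"no longer clinically benefitting" (NLCB) endpoint on a discrete visit
schedule, Bayesian Weibull accelerated-failure-time (AFT) inference, the
adaptive randomization / stopping-rule engine, and Monte-Carlo operating
characteristics.

## The model

Treatment effects are **survival time ratios** (STR) under a Weibull AFT
model. For event time *T* with arm indicator *x*,

    log T = μ + β·x + σ·ε,      ε ~ Gumbel(min),

so *T* is Weibull with shape *k* = 1/σ and scale λ = exp(μ + β·x), and
**STR = exp(β)** multiplies every quantile of survival time: STR 1.2 means
20% longer survival, STR 0.8 means 20% shorter. The log STR carries a
Normal(0, 0.5) prior; posteriors are summarized by the median, a 90%
credible interval (CrI), and the posterior probability of superiority
**PPS = P(STR > 1)**.

The trial engine randomizes per subgroup with a control-arm floor (the
physician's-choice control probability is at least the highest experimental
probability in every subgroup), zeroes probabilities for non-permitted
sequences (no ARPI after prior ARPI exposure), and at biannual reviews
applies dual-level stopping rules: a (signature, arm) combination graduates
when its signature-level PPS exceeds 0.85 *and* every gated member subgroup
exceeds 0.70; it stops for futility below 0.15 / 0.50. Each combination
allows at most 150 randomized patients, decisions require a minimum number
of evaluated patients, and a termination recommendation must be confirmed
after a 4-month minimum follow-up. Patients reaching NLCB on an
investigational arm are re-randomized; control patients start a new
control-arm line. See `docs/methods.md` for the full specification.

## Worked example

`examples/fit_survival_model.py` simulates a two-arm comparison at a true
STR of 1.5 (censored at two years) and refits it:

```
records: 300 (252 events)
STR (arpi vs control): 1.59 (90% CrI 1.34, 1.90)
  -> +59% survival time
PPS = P(STR > 1): 1.000  (draw-based: 1.000)
median survival arpi    : 13.3 months (90% CrI 11.8, 15.1)
median survival control : 8.3 months (90% CrI 7.4, 9.4)
```

The credible interval covers the simulated truth (1.5); the posterior
median survival times correspond to the two arms' Weibull medians, and a
PPS of 1.000 means every posterior draw favors the investigational arm.

`examples/run_adaptive_trial.py` runs one complete 400-patient trial under
the default calibrated scenario (ARPI true STR 1.5, taxane 0.94 versus
control — the effect sizes that reproduce medians of 11.1, 6.9 and 7.4
months for ARPI, taxane and control):

```
randomizations: 788 (400 patients)
allocation: {'control': 539, 'arpi': 99, 'taxane': 150}
first graduation at month 40.0
final (signature, arm) statuses:
  all              taxane   capped
  ar_neg_tp53_wt   arpi     graduated
  terg_positive    taxane   stopped_futility
```

Here the ARPI arm graduated in the AR-negative/TP53-wild-type signature:
its signature-level PPS crossed 0.85 with both gated member subgroups above
0.70, and the decision was confirmed at the lock analysis four months
later. The other examples cover variant classification, cohort generation
and operating characteristics; each prints a short interpretation of its
output. A thin `adaptrial` command-line interface wraps the same functions
(`adaptrial --help`).

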