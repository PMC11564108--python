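# Methods

This note documents the models, algorithms, calibration choices and known
limitations of `adaptrial`. It is the reference for what the package
computes and why; the README gives the quick tour.

## Survival model and priors

All time-to-event analysis uses a Bayesian Weibull accelerated failure
time (AFT) model in log-time location form:

    log T_i = μ + β·x_i [+ γ·b_i + η·x_i·b_i] + σ·ε_i,   ε_i ~ Gumbel(min)

so T_i is Weibull with shape k = 1/σ and scale λ_i = exp(linear
predictor). Censored records contribute survival-function terms
S(t) = exp(−(t/λ)^k). The treatment effect is the survival time ratio
STR = exp(β): it multiplies every quantile of the survival distribution,
so STR 1.2 reads directly as a 20% longer survival time. The interaction
model adds a biomarker main effect γ and an arm×biomarker coefficient η;
exp(η) is the STR *ratio* — the multiplicative treatment effect in
biomarker-positive relative to biomarker-negative patients.

Priors: β, η ~ Normal(0, 0.5) (a weakly-skeptical prior on the log STR
that shrinks small-sample estimates toward no effect); μ ~ Normal(log 12,
2²) on the months scale; log k ~ Normal(0, 1); γ ~ Normal(0, 1). The β/η
prior standard deviation of 0.5 is a design constant (`prior_sd_log_str`);
the μ, γ and log k priors are package defaults, wide enough that a few
dozen events dominate them, and are exposed on `AftModelSpec` for
sensitivity analysis.

Posterior summaries are the median STR, the 90% equal-tailed credible
interval (CrI), and the posterior probability of superiority
PPS = P(STR > 1).

## Posterior computation: two backends, one contract

`fit_weibull_aft(records, spec, backend=...)` supports:

**`"fast"` (default, deterministic).** MAP estimation by damped Newton
iteration with analytic gradient and Hessian, then a Laplace Gaussian
approximation, then a refinement of the target coefficient's marginal: on
a 61-point grid spanning ±6 posterior SDs, the exact posterior is
integrated over the nuisance block (μ, log k[, γ]) by Gauss–Hermite
quadrature (5 nodes per dimension) centred on the Gaussian conditional
mean. The refined marginal supplies the STR median, CrI and PPS; joint
draws (for survival curves) take the target from its marginal by inverse
CDF and the nuisance block from the Gaussian conditional. With no data the
posterior reproduces the prior exactly (PPS 0.5). Inside the trial engine
the same backend runs with a slightly coarser grid (41 points, 3 nodes);
the difference is orders of magnitude below decision resolution.

**`"mcmc"`.** Affine-invariant ensemble sampling (emcee; 2,500 steps,
12–20 walkers, 500-step burn-in, initialized from the Laplace fit).
Convergence is gated on the integrated autocorrelation time τ (chain
length > 50τ per parameter and ESS > 400); split-R̂ across walkers is
reported but not gated on, as walkers of an ensemble sampler are not
independent chains. Non-convergence sets `converged=False` and raises a
`RuntimeWarning` — it is never silent.

Both backends are tested against a brute-force dense-grid quadrature
oracle on small datasets (|Δ| ≤ 0.02 on the log-STR posterior mean and on
the PPS) and the fast backend's 90% CrI is calibration-tested (coverage
86–94% over 200 parameter-recovery replicates). Kaplan–Meier curves
(lifelines) serve as the nonparametric cross-check of the parametric
posterior survival curves (sup-norm ≤ 0.05 at n = 2,000 on
model-generated data).

Numerical safeguards: the log-shape is confined to |log k| ≤ 30; the
Gumbel exponent is clipped at ±700/300 before exponentiation;
non-positive-definite curvature at a degenerate MAP is ridge-repaired
before inversion; Newton falls back to BFGS if it stalls.

## Endpoints

The primary endpoint is time to *no longer clinically benefitting*
(NLCB), a composite of three progression components, each a pure function:

- **Biochemical (PSA).** After a decline from baseline: first value ≥ 25%
  and ≥ 2 ng/ml above the running nadir. With no decline: first value
  ≥ 25% and ≥ 2 ng/ml above baseline observed beyond 12 weeks. A
  confirmation-visit requirement is available (`require_confirmation`)
  and off by default, since the composite-minimum reading is the default
  interpretation here.
- **Radiologic.** Earliest bone scan with ≥ 2 new lesions, or earliest
  nodal/visceral progression on CT, whichever is first.
- **Clinical.** Physician judgment is not modeled; the cohort simulator
  supplies an exogenous exponential time with configurable mean.

Components are observed on the fixed visit schedule (every 8 weeks to
week 24, then every 12 weeks); `snap_to_schedule` maps a latent
progression time to the next visit. `compose_nlcb` takes the earliest
component before administrative censoring and records *all* components
tied at that time. Endpoint logic works in weeks; survival analysis in
months, with the conversion fixed at 30.44/7 weeks per month. Overall
survival is time from first randomization to death.

## Synthetic cohorts

`ScenarioSpec` defines a complete generative world; its defaults are the
study conditions the package emulates:

| quantity | default | basis |
|---|---|---|
| biomarker prevalences (AR, TP53, HRD, TERG) | 0.29, 0.45, 0.12, 0.31 | printed shares; the AR marginal is derived from the 39% AR-neg∧TP53-wt share under independence |
| ctDNA band shares (low/medium/high) | 0.27 / 0.54 / 0.19 | printed baseline table |
| control median NLCB / OS | 7.4 / 21.8 months | printed medians |
| true STR (ARPI, taxane vs control) | 1.5, 0.94 | reproduce 11.1 / 6.9 months |
| Weibull shape k | 1.2 | mildly increasing hazard; not printed, free config |
| accrual | Poisson process, 10/month | realistic multicenter rate |
| horizon / administrative censoring | 60 months | 5-year platform horizon |
| prior ARPI / taxane exposure | 0.34 / 0.41 | printed baseline table |
| clinical-progression mean | 60 months | rare relative to PSA/radiologic progression |

Biomarkers are independent Bernoulli draws by default; an optional shared
log-odds dependence parameter induces positive association while a
bisection correction keeps the marginals exact (joint prevalences are not
printed, so dependence is a knob, not a calibrated value). ctDNA fractions
are uniform within a band drawn at the band shares. Event times are drawn
from the exact generative inverse of the analysis model — Weibull with
the scale set so the median equals baseline × exp(total log STR) — so
common random numbers make quantile scaling exact: scaling the log STR by
δ multiplies the identical draw by exp(δ). OS is generated as NLCB plus a
Weibull residual, enforcing OS ≥ NLCB (their joint law is unspecified).
PSA trajectories (log-linear decline-to-nadir then rise, lognormal noise
SD 0.1 per visit) are package-invented scaffolding whose only role is to
exercise the PCWG3 rule; the recovery property (detected progression
within one visit interval of the latent time) is tested.

What the generator does not emulate: biomarker conversion between
randomization rounds (profiles are fixed per patient), correlation of
event times within a patient across rounds, accrual ramp-up or seasonal
variation, informative censoring and dropout, and physician-judgment
clinical progression. Passing tests therefore demonstrate correctness of
the machinery under a stylized data-generating process, not performance
on real trial data.

## The adaptive engine

One event loop over calendar time: accrue → classify → randomize →
follow → NLCB → re-randomize, with interim reviews every 6 months.
Investigational-arm patients reaching NLCB are re-randomized (round ≤ 2
by default) with a refreshed permitted-arm mask; control patients start a
new control line — they never cross to investigational arms. Prior ARPI
exposure (at entry or from an earlier round) permanently removes the ARPI
arm; taxane sequencing is allowed.

**Adaptation.** Randomization is stratified over the 16 subgroups. At
each interim, per-(subgroup, arm) PPS versus control feed the matrix:
experimental weight w = PPS^κ (κ = 1 default) over permitted arms,
control weight = max experimental weight (the control floor, so a
graduating-level arm approaches 1:1 with control), rows normalized,
forbidden entries exactly zero. Because individual subgroups are far too
small to estimate each arm's effect on their own, the adaptation PPS come
from ONE joint Weibull AFT fit with an arm main effect plus arm×biomarker
interaction terms per arm (Laplace posterior); the log STR of subgroup g
under arm a is the arm effect plus the interactions of g's biomarkers.
This borrowing is what lets an effective arm actually earn allocation.

**Stopping.** Early termination is decided per (signature, arm)
combination against two thresholds at once: signature-level PPS > 0.85
(graduation) or < 0.15 (futility) from a two-arm Weibull AFT fit on the
signature subset (concurrently-randomized window applied), *and* every
gated member subgroup above 0.70 / below 0.50 from *independent*
within-subgroup fits — deliberately not the joint model, so the gate is
an independent consistency check rather than a restatement of the
signature statistic. The evaluability rules apply the design's
minimum-information constant (25) uniformly: a combination is evaluated
once its signature∩treatment cell holds ≥ 25 randomized patients, and a
member subgroup is gated once its own comparison holds ≥ 25 evaluable
patients with ≥ 1 event per side. When a signature spans several
populated subgroups, at least two gated subgroups are required — a
single subgroup cannot verify cross-subgroup consistency. A crossing
produces a termination *recommendation*: the combination stops accruing
and the rule is re-evaluated at a lock analysis after the 4-month minimum
follow-up; only a confirmed crossing is final, otherwise the
recommendation is withdrawn and accrual resumes at the next update. A
combination reaching 150 randomized patients is capped (stops accruing,
remains under evaluation). A therapy whose biomarker-unselected ("all")
evaluation reaches a terminal decision exits the platform; its
niche-signature evaluations freeze. These evaluability, confirmation and
exit semantics are the package's resolution of design details the printed
rules leave open; they were fixed by simulating the design against its
published operating-characteristic envelope (type I error < 10% per
therapy and < 5% per combination with five concurrent arms; power
65–83%), which is how the design's own thresholds were calibrated in the
first place. An alternative where the gates also use the joint model is
available (`DesignConfig.gate_model="joint"`) but showed weaker power at
similar type I error.

Determinism: one `numpy` Generator drives accrual, classification,
randomization and outcomes; every interim posterior is deterministic
(fast backend), so a (scenario, config, seed) triple reproduces a trial
byte-for-byte.

## Operating characteristics

`run_scenario` runs replicate trials with seeds spawned from one master
seed and tabulates graduation/futility frequencies per therapy (a
replicate counts once if the arm graduates in any signature) and per
(signature, therapy) combination, with binomial Monte-Carlo standard
errors, mean sample sizes and allocation shares. Scenario builders
produce the global null (all STRs 1) and single-effect alternatives.
Default acceptance-scale runs use 200 replicates of 400-patient trials;
the type-I scenarios evaluate five concurrent experimental arms, matching
the conditioning of the published type-I claim. At this scale a replicate
costs roughly a second on one CPU.

Measured at that scale, power (arm graduates in any signature at true STR
1.5) lands at the lower edge of the 65–83% design band (≈64–72% across
seeds, Monte-Carlo SE ≈3.4 points), per-combination null graduation stays
within about twice its Monte-Carlo error of the 5% design bound, and
per-therapy null graduation ranges roughly 10–19% — above the 10% design
bound. The excess concentrates in signatures dominated by a single large
subgroup, where the subgroup gate nearly duplicates the signature
statistic and adds little independent protection.
With a Normal(0, 0.5) prior, a *single* mature look at the 0.85 threshold
has ≈ 14% null crossing probability (the threshold in sampling units is
z ≈ 1.04·√(1+4/I) for Fisher information I), so with biannual re-testing
over a 5-year horizon the dual-level gate and the lock confirmation carry
the entire burden of type-I control; the exact published rates depend on
unpublished details of the original calibration grid, and
`scripts/acceptance.py` reports what this implementation actually
achieves.

## Known limitations

- Records are treated as independent across randomization rounds
  (mirroring the trial's own analysis); within-patient correlation is
  ignored.
- The concurrently-randomized window and the recommendation/lock
  machinery follow this package's reading of the design; the original
  protocol's supplementary specification may differ in detail.
- The fast backend's CrI and PPS are deterministic approximations;
  final-analysis numbers should use the MCMC backend (the two agree to
  ±0.02 on PPS in testing).
- Eligibility modeling is reduced to the MSI flag and detectable ctDNA;
  screening failures, technical failures and consent withdrawal are not
  simulated.
- The wet-lab assay — alignment, variant calling, clonality calling,
  clonal-hematopoiesis filtering — is upstream and out of scope; the
  classifier consumes a called, clonality-annotated variant table.
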