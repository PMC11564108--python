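"""Outcome-adaptive platform-trial engine.

The trial loop: patients accrue, are classified into one of 16 biomarker
subgroup combinations, and are randomized between a physician's-choice
control arm and the investigational arms with per-subgroup probabilities
that adapt to accumulating evidence.  At biannual interim reviews a
Bayesian Weibull AFT model is fitted for every populated (subgroup, arm)
comparison against control; the resulting posterior probabilities of
superiority (PPS) update the randomization matrix, subject to a control
floor (the control probability in each subgroup is at least the maximum
experimental probability) and to zeroed probabilities for non-permitted
sequences.  Dual-level stopping rules then declare a (signature, arm)
combination graduated (signature PPS > 0.85 and every gated member
subgroup > 0.70) or futile (signature PPS < 0.15 and every gated member
subgroup < 0.50), after a minimum number of evaluable randomizations;
a cap of 150 randomized patients per combination closes accrual.
Investigational-arm patients reaching the NLCB endpoint are re-randomized
with a refreshed permitted-arm mask (no ARPI rechallenge); control-arm
patients start a new line within the control arm.

Decision mechanics, in order of evaluation at each review:

- evaluability: stopping rules fire only once the signature-treatment cell
  holds at least ``min_evaluated`` randomized patients, and only member
  subgroups whose own comparison holds ``subgroup_min_evaluated`` patients
  with at least one event per side enter the gate (two gated subgroups are
  required when the signature spans several populated subgroups — a single
  subgroup cannot verify cross-subgroup consistency);
- recommendation and lock: a crossing yields a termination recommendation;
  the combination stops accruing and the same rule is re-evaluated after
  the mandated minimum follow-up — only a confirmed crossing is final,
  otherwise the recommendation is withdrawn and accrual resumes;
- platform exit: a therapy whose biomarker-unselected evaluation reaches a
  terminal decision leaves the platform; its niche-signature evaluations
  freeze.

The randomization-matrix update, in contrast to the stopping gates, pools
information across subgroups through one joint Weibull AFT fit with arm
main effects and arm-by-biomarker interactions (individual subgroups are
too small to learn per-arm effects on their own).
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from scipy.stats import norm

from .aft import (
    AftModelSpec,
    RandomizationRecord,
    _fit_fast,
    laplace_fit_design,
)
from .biomarkers import SIGNATURES, signature_subgroups
from .cohort import (
    PatientProfile,
    ScenarioSpec,
    generate_cohort,
    sample_event_time,
)
from .endpoints import (
    VisitSchedule,
    compose_nlcb,
    months_to_weeks,
    snap_to_schedule,
    weeks_to_months,
)

__all__ = [
    "DesignConfig",
    "RandomizationMatrix",
    "TrialState",
    "permitted_arms",
    "update_randomization_matrix",
    "randomize",
    "check_stopping",
    "run_trial",
]

Decision = Literal["graduate", "futility", "capped", "continue"]


@dataclass(frozen=True)
class DesignConfig:
    """All design constants of the adaptive platform.

    Defaults are the platform's operating values: graduation at signature
    PPS > 0.85 with every gated member subgroup > 0.70, futility at < 0.15
    with subgroups < 0.50, at most 150 randomized patients per (signature,
    arm) combination, at least 25 evaluable randomizations before stopping
    rules may fire, interim reviews every 6 months, a 4-month minimum
    follow-up after the decision lock, 90% credible intervals and a
    Normal(0, 0.5) prior on the log survival time ratio.
    """

    experimental_arms: tuple[str, ...] = ("arpi", "taxane")
    graduation_pps: float = 0.85
    futility_pps: float = 0.15
    subgroup_graduation_pps: float = 0.70
    subgroup_futility_pps: float = 0.50
    max_per_combination: int = 150
    min_evaluated: int = 25
    subgroup_min_evaluated: int = 25
    gate_model: str = "independent"  # or "joint": gates from the joint fit
    interim_interval: float = 6.0
    min_followup_after_lock: float = 4.0
    cri_level: float = 0.90
    prior_sd_log_str: float = 0.5
    adaptation_exponent: float = 1.0
    max_rounds: int = 2
    concurrent_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.futility_pps < self.graduation_pps < 1.0:
            raise ValueError("need 0 < futility < graduation < 1")
        if not 0.0 < self.subgroup_futility_pps < self.subgroup_graduation_pps < 1.0:
            raise ValueError("need 0 < subgroup futility < subgroup graduation < 1")
        if self.max_per_combination <= 0 or self.min_evaluated <= 0:
            raise ValueError("caps must be positive integers")
        if not 0.0 < self.cri_level < 1.0:
            raise ValueError("credible level must lie in (0, 1)")

    @property
    def arms(self) -> tuple[str, ...]:
        return ("control",) + self.experimental_arms


@dataclass
class RandomizationMatrix:
    """Per-(subgroup, arm) randomization probabilities.

    Rows sum to one over permitted arms, the control probability is at
    least the maximum experimental probability in every row, and forbidden
    entries are exactly zero.
    """

    arms: tuple[str, ...]
    probabilities: np.ndarray  # shape (16, len(arms)); column 0 is control

    def row(self, subgroup: int) -> np.ndarray:
        return self.probabilities[subgroup]

    def validate(self) -> None:
        p = self.probabilities
        if p.shape != (16, len(self.arms)):
            raise ValueError("matrix must be 16 x n_arms")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")
        control = p[:, 0]
        if p.shape[1] > 1 and np.any(control + 1e-12 < p[:, 1:].max(axis=1)):
            raise ValueError("control probability below an experimental arm")


def permitted_arms(
    patient: PatientProfile,
    config: DesignConfig,
    *,
    prior_arpi: bool | None = None,
) -> tuple[str, ...]:
    """Arms this patient may be randomized to given treatment history.

    ARPI sequencing/rechallenge is not allowed: any prior ARPI exposure
    removes the ARPI arm.  Taxane sequencing is allowed (e.g. cabazitaxel
    after docetaxel).  Control is always permitted.
    """
    had_arpi = patient.prior_arpi if prior_arpi is None else prior_arpi
    permitted = ["control"]
    for arm in config.experimental_arms:
        if arm == "arpi" and had_arpi:
            continue
        permitted.append(arm)
    return tuple(permitted)


def update_randomization_matrix(
    subgroup_pps: np.ndarray,
    forbidden: np.ndarray,
    config: DesignConfig,
) -> RandomizationMatrix:
    """Map per-(subgroup, experimental arm) PPS values to the matrix.

    Experimental weights are PPS ** adaptation_exponent over permitted
    arms; the control weight equals the maximum experimental weight (the
    control floor), so a graduating-level arm approaches 1:1 with control.
    Rows with no permitted experimental arm give control probability 1.
    """
    n_exp = len(config.experimental_arms)
    subgroup_pps = np.asarray(subgroup_pps, dtype=float)
    forbidden = np.asarray(forbidden, dtype=bool)
    if subgroup_pps.shape != (16, n_exp) or forbidden.shape != (16, n_exp):
        raise ValueError("expected (16, n_experimental_arms) inputs")
    if np.any((subgroup_pps < 0) | (subgroup_pps > 1)):
        raise ValueError("PPS values must lie in [0, 1]")
    w = np.where(forbidden, 0.0, subgroup_pps**config.adaptation_exponent)
    control = np.where(w.any(axis=1), w.max(axis=1), 1.0)
    probs = np.column_stack([control, w])
    probs /= probs.sum(axis=1, keepdims=True)
    matrix = RandomizationMatrix(arms=config.arms, probabilities=probs)
    matrix.validate()
    return matrix


def initial_matrix(config: DesignConfig) -> RandomizationMatrix:
    """Burn-in matrix: uniform over permitted arms subject to the control
    floor (equivalent to all PPS equal)."""
    return update_randomization_matrix(
        np.full((16, len(config.experimental_arms)), 0.5),
        np.zeros((16, len(config.experimental_arms)), dtype=bool),
        config,
    )


def randomize(
    patient: PatientProfile,
    matrix: RandomizationMatrix,
    rng: np.random.Generator,
    permitted: Sequence[str] | None = None,
) -> str:
    """Draw an arm for an eligible patient from their subgroup row,
    restricted to the patient's permitted arms (renormalized)."""
    if not patient.profile.eligible:
        raise ValueError(f"patient {patient.patient_id} is not eligible")
    row = matrix.row(patient.profile.subgroup_index).copy()
    if permitted is not None:
        mask = np.array([a in permitted for a in matrix.arms])
        row = np.where(mask, row, 0.0)
    total = row.sum()
    if total <= 0:
        return "control"
    return str(matrix.arms[rng.choice(len(row), p=row / total)])


def check_stopping(
    signature_pps: float,
    subgroup_pps: Sequence[float],
    n_evaluated: int,
    n_randomized: int,
    config: DesignConfig,
    n_populated_subgroups: int | None = None,
) -> Decision:
    """Dual-level stopping decision for one (signature, arm) combination.

    ``subgroup_pps`` holds the PPS of every *gated* member subgroup (those
    with enough evaluable data to inform the comparison); ``n_evaluated``
    counts evaluable randomizations in the signature-treatment cell and
    ``n_randomized`` counts patients randomized to the combination (cap).
    ``n_populated_subgroups`` is the number of member subgroups carrying
    any data; with several populated subgroups a single gated one cannot
    verify cross-subgroup consistency, so at least two are required.
    """
    if n_randomized >= config.max_per_combination:
        return "capped"
    required_gates = 1
    if n_populated_subgroups is not None and n_populated_subgroups >= 2:
        required_gates = 2
    if n_evaluated < config.min_evaluated or len(subgroup_pps) < required_gates:
        # The dual-level rule verifies that the signature-level effect is
        # consistent across member subgroups; with too few subgroups
        # informative enough to check, no early-termination decision is
        # possible.
        return "continue"
    if signature_pps > config.graduation_pps and all(
        p > config.subgroup_graduation_pps for p in subgroup_pps
    ):
        return "graduate"
    if signature_pps < config.futility_pps and all(
        p < config.subgroup_futility_pps for p in subgroup_pps
    ):
        return "futility"
    return "continue"


@dataclass
class TrialState:
    """Accumulated state of one simulated trial."""

    config: DesignConfig
    scenario: ScenarioSpec
    calendar_time: float = 0.0
    records: list[RandomizationRecord] = field(default_factory=list)
    matrix: RandomizationMatrix | None = None
    arm_status: dict[tuple[str, str], str] = field(default_factory=dict)
    decision_log: list[dict] = field(default_factory=list)
    matrix_history: list[tuple[float, np.ndarray]] = field(default_factory=list)
    n_randomized: dict[tuple[str, str], int] = field(default_factory=dict)
    pending: dict[tuple[str, str], tuple[str, float]] = field(default_factory=dict)
    first_graduation_time: float | None = None

    def graduated(self) -> set[tuple[str, str]]:
        return {k for k, v in self.arm_status.items() if v == "graduated"}

    def arm_graduated(self, arm: str) -> bool:
        return any(k[1] == arm for k in self.graduated())


# ---------------------------------------------------------------------------
# Internal interim machinery
# ---------------------------------------------------------------------------

_SIG_MEMBERS = {s: signature_subgroups(s) for s in SIGNATURES}


def _evaluable_arrays(
    records: list[RandomizationRecord], now: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(time, event, arm index placeholder, subgroup, start) censored at the
    interim date; records randomized at or after `now` are excluded."""
    t = np.empty(len(records))
    d = np.empty(len(records), dtype=bool)
    sub = np.empty(len(records), dtype=int)
    start = np.empty(len(records))
    arm = np.empty(len(records), dtype=object)
    m = 0
    for r in records:
        follow = now - r.start_time
        if follow <= 1e-9:
            continue
        t[m] = min(r.time, follow)
        d[m] = bool(r.event and r.time <= follow)
        sub[m] = r.subgroup_index
        start[m] = r.start_time
        arm[m] = r.arm
        m += 1
    return t[:m], d[:m], arm[:m], sub[:m], start[:m]


def _fit_pps(
    t: np.ndarray,
    d: np.ndarray,
    x: np.ndarray,
    spec: AftModelSpec,
) -> float:
    """Deterministic PPS of a focal-vs-control comparison from raw arrays.

    Interim decisions re-run thousands of times per simulated trial, so the
    marginal refinement uses a slightly coarser grid than the default
    public fit; the difference is far below decision resolution.
    """
    X = np.column_stack([np.ones_like(t), x])
    summary = _fit_fast(
        t, d, X, spec, n_draws=0, rng=np.random.default_rng(0), cri_level=0.90,
        grid_points=41, gh_nodes=3,
    )
    return summary.pps


def _adaptation_pps(
    t: np.ndarray,
    d: np.ndarray,
    arm: np.ndarray,
    sub: np.ndarray,
    config: DesignConfig,
) -> np.ndarray:
    """Per-(subgroup, arm) PPS vs control for the randomization update.

    Individual subgroups are too small to estimate each arm's effect on
    their own, so the adaptation model is ONE joint Weibull AFT fit with an
    arm main effect plus arm x biomarker interaction terms per arm
    (borrowing strength across the 16 subgroup combinations).  The log STR
    for subgroup g under arm a is the arm effect plus the interactions of
    the biomarkers present in g; its PPS is evaluated under the Laplace
    Gaussian posterior."""
    n_exp = len(config.experimental_arms)
    if t.size == 0 or not d.any():
        return np.full((16, n_exp), 0.5)
    bits = np.column_stack([(sub >> 3) & 1, (sub >> 2) & 1, (sub >> 1) & 1, sub & 1])
    cols = [np.ones_like(t)]
    for a in config.experimental_arms:
        ind = (arm == a).astype(float)
        cols.append(ind)
        for b in range(4):
            cols.append(ind * bits[:, b])
    X = np.column_stack(cols)
    p = X.shape[1] + 1  # + log shape
    prior_mean = np.zeros(p)
    prior_mean[0] = math.log(12.0)
    prior_sd = np.full(p, config.prior_sd_log_str)
    prior_sd[0] = 2.0
    prior_sd[-1] = 1.0
    theta, cov = laplace_fit_design(t, d, X, prior_mean, prior_sd)

    pps = np.full((16, n_exp), 0.5)
    for j in range(n_exp):
        base = 1 + 5 * j  # arm main effect column
        for g in range(16):
            idx = [base] + [base + 1 + b for b in range(4) if (g >> (3 - b)) & 1]
            c = np.zeros(p)
            c[idx] = 1.0
            mean = float(c @ theta)
            var = float(c @ cov @ c)
            pps[g, j] = float(norm.cdf(mean / math.sqrt(max(var, 1e-12))))
    return pps


def _interim(
    state: TrialState,
    now: float,
    *,
    lock_keys: set[tuple[str, str]] | None = None,
) -> None:
    """One interim review: refit comparisons, update stopping statuses and
    the randomization matrix.  With ``lock_keys`` given, this is a lock
    analysis: only those pending (signature, arm) combinations are
    re-evaluated and the randomization matrix is left untouched."""
    config = state.config
    n_exp = len(config.experimental_arms)
    t, d, arm, sub, start = _evaluable_arrays(state.records, now)
    spec_by_arm = {
        a: AftModelSpec(
            focal_arm=a, reference_arm="control",
            prior_sd_log_str=config.prior_sd_log_str,
        )
        for a in config.experimental_arms
    }
    arms_to_eval = (
        config.experimental_arms
        if lock_keys is None
        else tuple(a for a in config.experimental_arms if any(k[1] == a for k in lock_keys))
    )
    joint_pps = (
        _adaptation_pps(t, d, arm, sub, config)
        if (lock_keys is None or config.gate_model == "joint")
        else None
    )

    # Independent within-subgroup comparisons vs control; the prior PPS
    # (0.5) stands in where the comparison carries no information (a fit on
    # fewer evaluable patients than the gate threshold is itself
    # prior-dominated, so it is skipped rather than computed).
    subgroup_pps = np.full((16, n_exp), 0.5)
    subgroup_n = np.zeros((16, n_exp), dtype=int)
    subgroup_informed = np.zeros((16, n_exp), dtype=bool)
    is_control = arm == "control"
    for j, a in enumerate(config.experimental_arms):
        if a not in arms_to_eval:
            continue
        in_arm = arm == a
        if config.concurrent_only and in_arm.any():
            lo, hi = start[in_arm].min(), start[in_arm].max()
            window = (start >= lo - 1e-9) & (start <= hi + config.interim_interval)
        else:
            window = np.ones_like(is_control)
        use = (in_arm | is_control) & window
        for g in range(16):
            sel = use & (sub == g)
            n_g = int(sel.sum())
            subgroup_n[g, j] = n_g
            if n_g < config.subgroup_min_evaluated or config.gate_model == "joint":
                continue
            x = in_arm[sel].astype(float)
            # Informative comparison: an event on each side.
            subgroup_informed[g, j] = bool(
                d[sel][x == 1.0].any() and d[sel][x == 0.0].any()
            )
            if subgroup_informed[g, j]:
                subgroup_pps[g, j] = _fit_pps(t[sel], d[sel], x, spec_by_arm[a])

        # Signature-level comparisons drive the stopping rules.  Capped
        # combinations stop accruing but remain under evaluation and may
        # still graduate or stop for futility as follow-up matures.
        arm_exited = state.arm_status.get(("all", a)) in (
            "graduated",
            "stopped_futility",
        )
        for s in SIGNATURES:
            if lock_keys is not None and (s, a) not in lock_keys:
                continue
            status = state.arm_status.get((s, a), "active")
            if status in ("graduated", "stopped_futility"):
                continue
            # A therapy whose biomarker-unselected evaluation reached a
            # terminal decision has exited the platform: no further
            # recommendations are issued for its niche signatures (only an
            # already-pending lock analysis may still resolve).
            if arm_exited and s != "all" and (s, a) not in state.pending:
                continue
            members = _SIG_MEMBERS[s]
            in_sig = np.isin(sub, list(members))
            sel = use & in_sig
            # Evaluability is counted on the signature-treatment cell
            # itself: patients with the signature randomized to this arm.
            n_eval = int((sel & in_arm).sum())
            sig_pps = 0.5
            if n_eval and in_arm[sel].any() and is_control[sel].any():
                sig_pps = _fit_pps(
                    t[sel], d[sel], in_arm[sel].astype(float), spec_by_arm[a]
                )
            if config.gate_model == "joint":
                gated = [
                    float(joint_pps[g, j])
                    for g in members
                    if subgroup_n[g, j] > 0
                ]
            else:
                gated = [
                    float(subgroup_pps[g, j])
                    for g in members
                    if subgroup_n[g, j] >= config.subgroup_min_evaluated
                    and subgroup_informed[g, j]
                ]
            n_rand = 0 if status == "capped" else state.n_randomized.get((s, a), 0)
            n_populated = int(sum(subgroup_n[g, j] > 0 for g in members))
            decision = check_stopping(
                sig_pps, gated, n_eval, n_rand, config, n_populated
            )

            # A graduation/futility crossing is first a *recommendation*;
            # it becomes final only if the same rule is still met at the
            # lock analysis after the mandated minimum follow-up.
            pending = state.pending.get((s, a))
            stage = "interim"
            if pending is not None:
                rec_decision, rec_time = pending
                if now + 1e-9 < rec_time + config.min_followup_after_lock:
                    continue  # follow-up still maturing; no new decision
                stage = "lock"
                if decision == rec_decision:
                    final = {
                        "graduate": "graduated",
                        "futility": "stopped_futility",
                    }[decision]
                    state.arm_status[(s, a)] = final
                    if (
                        decision == "graduate"
                        and state.first_graduation_time is None
                    ):
                        state.first_graduation_time = now
                else:
                    decision = "withdrawn"
                del state.pending[(s, a)]
            elif decision in ("graduate", "futility"):
                state.pending[(s, a)] = (decision, now)
            elif decision == "capped":
                state.arm_status[(s, a)] = "capped"
            state.decision_log.append(
                {
                    "time": now, "signature": s, "arm": a, "stage": stage,
                    "signature_pps": sig_pps, "subgroup_pps": gated,
                    "n_evaluated": n_eval, "decision": decision,
                }
            )

    if lock_keys is not None:
        return  # lock analyses do not touch the randomization matrix

    # The randomization update pools information across subgroups through
    # the joint adaptation model.
    adaptation_pps = joint_pps

    # Forbidden mask: an arm accrues no new patients in any subgroup that
    # belongs to a signature where the (signature, arm) combination is no
    # longer active, or where a termination recommendation awaits its lock
    # analysis.
    forbidden = np.zeros((16, n_exp), dtype=bool)
    frozen = [k for k, v in state.arm_status.items() if v != "active"]
    frozen += list(state.pending.keys())
    for s, a in frozen:
        j = config.experimental_arms.index(a)
        for g in _SIG_MEMBERS[s]:
            forbidden[g, j] = True

    state.matrix = update_randomization_matrix(adaptation_pps, forbidden, config)
    state.matrix_history.append((now, state.matrix.probabilities.copy()))


def _observe_nlcb(
    patient: PatientProfile,
    arm: str,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    max_follow: float,
):
    """Latent NLCB outcome for one randomization: the latent progression
    time is observed at the next scheduled visit; an exogenous clinical
    progression time competes; administrative censoring applies."""
    latent = sample_event_time(patient, arm, spec, "nlcb", rng)
    observed_prog = weeks_to_months(
        snap_to_schedule(months_to_weeks(latent), spec.visit_schedule)
    )
    clinical = rng.exponential(spec.clinical_progression_mean)
    return compose_nlcb(
        psa_time=None,
        radiologic_time=observed_prog,
        clinical_time=clinical,
        censor_time=max_follow,
    )


def run_trial(
    scenario: ScenarioSpec,
    config: DesignConfig | None = None,
    seed: int | np.random.Generator = 0,
    *,
    n_patients: int = 400,
) -> TrialState:
    """Simulate one complete trial; deterministic for a fixed seed.

    Accrual, classification, adaptive randomization, follow-up, interim
    reviews and re-randomization run on a single event loop over calendar
    time up to the administrative horizon ``scenario.admin_censor_time``
    (months from trial start).
    """
    config = config or DesignConfig()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    state = TrialState(config=config, scenario=scenario)
    state.matrix = initial_matrix(config)
    state.matrix_history.append((0.0, state.matrix.probabilities.copy()))
    horizon = scenario.admin_censor_time

    patients = generate_cohort(scenario, n_patients, rng)
    counter = itertools.count()
    # Event heap: (time, tiebreak, kind, payload)
    heap: list[tuple[float, int, str, object]] = []
    for p in patients:
        if p.entry_time < horizon and p.profile.eligible:
            heapq.heappush(heap, (p.entry_time, next(counter), "entry", (p, 1)))
    t_interim = config.interim_interval
    while t_interim < horizon:
        heapq.heappush(heap, (t_interim, next(counter), "interim", None))
        t_interim += config.interim_interval

    history_arpi: dict[str, bool] = {p.patient_id: p.prior_arpi for p in patients}

    def do_randomization(
        patient: PatientProfile, round_no: int, now: float, prev_arm: str | None
    ) -> None:
        if prev_arm == "control":
            # Control patients never cross to the investigational arms:
            # they start a new line of physician's-choice therapy.
            arm = "control"
        else:
            permitted = permitted_arms(
                patient, config, prior_arpi=history_arpi[patient.patient_id]
            )
            arm = randomize(patient, state.matrix, rng, permitted)
        outcome = _observe_nlcb(patient, arm, scenario, rng, horizon - now)
        record = RandomizationRecord(
            patient_id=patient.patient_id,
            round=round_no,
            arm=arm,
            start_time=now,
            time=outcome.time,
            event=outcome.event,
            endpoint="nlcb",
            subgroup_index=patient.profile.subgroup_index,
            prior_arpi=history_arpi[patient.patient_id],
            prior_taxane=patient.prior_taxane,
            line=round_no,
            reason_components=outcome.reason_components,
        )
        state.records.append(record)
        if arm == "arpi":
            history_arpi[patient.patient_id] = True
        for s in SIGNATURES:
            if s in patient.profile.signatures and arm != "control":
                key = (s, arm)
                state.n_randomized[key] = state.n_randomized.get(key, 0) + 1
        if outcome.event and round_no < config.max_rounds:
            heapq.heappush(
                heap,
                (
                    now + outcome.time, next(counter), "rerandomize",
                    (patient, round_no + 1, arm),
                ),
            )

    locks_scheduled: set[tuple[tuple[str, str], float]] = set()
    while heap:
        now, _, kind, payload = heapq.heappop(heap)
        if now >= horizon:
            break
        state.calendar_time = now
        if kind == "interim":
            _interim(state, now)
            # Schedule the lock analysis for any fresh termination
            # recommendation after the mandated minimum follow-up.
            for key, (_, rec_time) in state.pending.items():
                if (key, rec_time) not in locks_scheduled:
                    locks_scheduled.add((key, rec_time))
                    t_lock = rec_time + config.min_followup_after_lock
                    if t_lock < horizon:
                        heapq.heappush(heap, (t_lock, next(counter), "lock", key))
        elif kind == "lock":
            if payload in state.pending:
                _interim(state, now, lock_keys={payload})  # type: ignore[arg-type]
        elif kind == "entry":
            patient, round_no = payload  # type: ignore[misc]
            do_randomization(patient, round_no, now, None)
        else:
            patient, round_no, prev_arm = payload  # type: ignore[misc]
            do_randomization(patient, round_no, now, prev_arm)

    state.calendar_time = horizon
    _interim(state, horizon)  # final analysis at the administrative horizon
    return state
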