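"""Monte-Carlo operating characteristics of the adaptive design.

The design's error rates are not analytic: type I error (the chance an
ineffective arm graduates), power (the chance a truly effective arm
graduates) and allocation behavior are estimated by running the complete
trial loop on many replicate synthetic cohorts.  Under the global null all
true survival time ratios are 1; alternatives set the focal arm's STR in a
chosen signature.  Replicates derive independent seeds from one master
seed, so every result is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .biomarkers import SIGNATURES
from .cohort import ScenarioSpec, default_scenario
from .engine import DesignConfig, TrialState, run_trial

__all__ = [
    "OcResult",
    "run_scenario",
    "build_null_scenario",
    "build_alternative_scenario",
]


@dataclass
class OcResult:
    """Replicate-level decision frequencies with Monte-Carlo SEs.

    Frequencies are proportions in [0, 1].  ``arm_graduation`` counts a
    replicate once if the arm graduated in *any* signature (the per-therapy
    frequency); ``combination_graduation`` is tabulated per (signature,
    arm).  MC SE = sqrt(p * (1 - p) / n_replicates).
    """

    scenario_label: str
    n_replicates: int
    arm_graduation: dict[str, float]
    arm_futility: dict[str, float]
    combination_graduation: dict[tuple[str, str], float]
    combination_futility: dict[tuple[str, str], float]
    mean_sample_size: float
    mean_randomizations: float
    allocation_shares: dict[str, float]
    config: DesignConfig = field(repr=False, default_factory=DesignConfig)

    def se(self, p: float) -> float:
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.n_replicates)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "n_replicates": self.n_replicates,
            "arm_graduation": self.arm_graduation,
            "arm_futility": self.arm_futility,
            "combination_graduation": {
                f"{s}:{a}": v for (s, a), v in self.combination_graduation.items()
            },
            "combination_futility": {
                f"{s}:{a}": v for (s, a), v in self.combination_futility.items()
            },
            "mean_sample_size": self.mean_sample_size,
            "mean_randomizations": self.mean_randomizations,
            "allocation_shares": self.allocation_shares,
        }


def build_null_scenario(config: DesignConfig | None = None, **overrides) -> ScenarioSpec:
    """Global null: every true survival time ratio equals 1."""
    return default_scenario(true_log_str={}, **overrides)


def build_alternative_scenario(
    target_str: float,
    signature: str = "all",
    arm: str = "arpi",
    config: DesignConfig | None = None,
    **overrides,
) -> ScenarioSpec:
    """Alternative: the focal (arm, signature) has true STR ``target_str``;
    every other effect is null."""
    if target_str <= 0:
        raise ValueError("target STR must be positive")
    if signature not in SIGNATURES:
        raise ValueError(f"unknown signature {signature!r}")
    effects = {} if target_str == 1.0 else {(arm, signature): math.log(target_str)}
    return default_scenario(true_log_str=effects, **overrides)


def run_scenario(
    scenario: ScenarioSpec,
    config: DesignConfig | None = None,
    n_replicates: int = 200,
    master_seed: int = 0,
    *,
    n_patients: int = 400,
    label: str = "scenario",
    backend: Literal["fast", "sampler"] = "fast",
) -> OcResult:
    """Run ``n_replicates`` complete trials and tabulate decision
    frequencies.  Deterministic for a fixed master seed."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if backend == "sampler" and n_replicates > 20:
        import warnings

        warnings.warn(
            "sampler backend across many replicates is expensive; interim "
            "decisions use the fast deterministic posterior either way",
            RuntimeWarning,
            stacklevel=2,
        )
    config = config or DesignConfig()
    seeds = np.random.SeedSequence(master_seed).spawn(n_replicates)

    arm_grad = {a: 0 for a in config.experimental_arms}
    arm_fut = {a: 0 for a in config.experimental_arms}
    combos = [(s, a) for s in SIGNATURES for a in config.experimental_arms]
    combo_grad = {c: 0 for c in combos}
    combo_fut = {c: 0 for c in combos}
    total_patients = 0
    total_randomizations = 0
    alloc = {a: 0 for a in config.arms}

    for ss in seeds:
        state = run_trial(
            scenario, config, np.random.default_rng(ss), n_patients=n_patients
        )
        for (s, a), status in state.arm_status.items():
            if status == "graduated":
                combo_grad[(s, a)] += 1
            elif status == "stopped_futility":
                combo_fut[(s, a)] += 1
        for a in config.experimental_arms:
            statuses = [
                state.arm_status.get((s, a), "active") for s in SIGNATURES
            ]
            if "graduated" in statuses:
                arm_grad[a] += 1
            if "stopped_futility" in statuses:
                arm_fut[a] += 1
        total_patients += len({r.patient_id for r in state.records})
        total_randomizations += len(state.records)
        for r in state.records:
            alloc[r.arm] += 1

    n = n_replicates
    total_alloc = max(sum(alloc.values()), 1)
    return OcResult(
        scenario_label=label,
        n_replicates=n,
        arm_graduation={a: c / n for a, c in arm_grad.items()},
        arm_futility={a: c / n for a, c in arm_fut.items()},
        combination_graduation={c: v / n for c, v in combo_grad.items()},
        combination_futility={c: v / n for c, v in combo_fut.items()},
        mean_sample_size=total_patients / n,
        mean_randomizations=total_randomizations / n,
        allocation_shares={a: c / total_alloc for a, c in alloc.items()},
        config=config,
    )
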