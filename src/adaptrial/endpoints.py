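"""Composite no-longer-clinically-benefitting (NLCB) endpoint logic.

The primary endpoint is the time until a therapy stops providing clinical
benefit, assessed from three components observed on a fixed visit schedule
(every 8 weeks for the first 24 weeks, then every 12 weeks):

- biochemical (PSA) progression: after a decline from baseline, the first
  PSA value that is >=25% AND >=2 ng/ml above the nadir; with no decline,
  a >=25% and >=2 ng/ml rise above baseline observed beyond 12 weeks;
- radiologic progression: >=2 new lesions on bone scintigraphy, or nodal /
  visceral progression on CT, whichever is first;
- clinical progression: physician judgment, supplied as an exogenous time.

The NLCB event time is the earliest component time, administratively
censored.  Endpoint logic works in weeks; survival analysis works in
months (weeks * 7 / 30.44).

All functions here are pure and operate on plain sequences, so they can be
driven equally by the synthetic cohort generator and by real visit tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "WEEKS_PER_MONTH",
    "weeks_to_months",
    "months_to_weeks",
    "VisitSchedule",
    "NlcbEvent",
    "detect_psa_progression",
    "detect_radiologic_progression",
    "compose_nlcb",
    "snap_to_schedule",
]

# 30.44 days per average month; fixed conversion used throughout the package.
WEEKS_PER_MONTH = 30.44 / 7.0


def weeks_to_months(weeks: float) -> float:
    return weeks / WEEKS_PER_MONTH


def months_to_weeks(months: float) -> float:
    return months * WEEKS_PER_MONTH


@dataclass(frozen=True)
class VisitSchedule:
    """Fixed evaluation visits: every ``early_interval`` weeks up to
    ``early_horizon``, then every ``late_interval`` weeks (8/24/12 default
    gives visits at 8, 16, 24, 36, 48, ... weeks)."""

    early_interval: float = 8.0
    early_horizon: float = 24.0
    late_interval: float = 12.0

    def __post_init__(self) -> None:
        if min(self.early_interval, self.early_horizon, self.late_interval) <= 0:
            raise ValueError("schedule intervals must be positive")

    def visits(self, horizon: float) -> list[float]:
        """All scheduled visit times (weeks) up to and including horizon."""
        times: list[float] = []
        t = self.early_interval
        while t <= min(self.early_horizon, horizon) + 1e-9:
            times.append(t)
            t += self.early_interval
        t = self.early_horizon + self.late_interval
        while t <= horizon + 1e-9:
            times.append(t)
            t += self.late_interval
        return times

    def next_visit(self, latent_time: float) -> float:
        """Smallest scheduled visit at or after ``latent_time`` (weeks)."""
        if latent_time <= self.early_horizon:
            n = -(-latent_time // self.early_interval)  # ceil division
            return max(1.0, n) * self.early_interval
        n = -(-(latent_time - self.early_horizon) // self.late_interval)
        return self.early_horizon + max(1.0, n) * self.late_interval


def snap_to_schedule(latent_time: float, schedule: VisitSchedule | None = None) -> float:
    """Observed time (weeks) of an event detected at the next scheduled visit."""
    if latent_time <= 0:
        raise ValueError("latent time must be positive")
    return (schedule or VisitSchedule()).next_visit(latent_time)


@dataclass(frozen=True)
class NlcbEvent:
    """Outcome of the NLCB composite: event time (months) with the
    progression components that fired, or a censoring time."""

    time: float
    event: bool
    reason_components: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.event and not self.reason_components:
            raise ValueError("an NLCB event must carry >=1 reason component")
        if not self.event and self.reason_components:
            raise ValueError("a censored record carries no reason components")


def detect_psa_progression(
    series: Sequence[tuple[float, float]],
    baseline_psa: float,
    *,
    min_weeks_no_decline: float = 12.0,
    require_confirmation: bool = False,
) -> float | None:
    """Time (weeks) of biochemical progression under the dual-threshold rule.

    With a post-baseline decline: first visit with PSA >= 1.25 * nadir and
    >= nadir + 2 ng/ml, where the nadir is the running minimum of all values
    observed so far (baseline included).  Without any decline: first visit
    beyond ``min_weeks_no_decline`` with PSA >= 1.25 * baseline and
    >= baseline + 2 ng/ml.  ``require_confirmation`` additionally demands
    that the next visit also satisfies the thresholds.

    Returns None when no visit qualifies.
    """
    if baseline_psa < 0:
        raise ValueError("baseline PSA must be non-negative")
    times = [t for t, _ in series]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("PSA series must be sorted by time")
    if any(v < 0 for _, v in series):
        raise ValueError("PSA values must be non-negative")

    def qualifies(i: int) -> bool:
        t, value = series[i]
        declined = any(v < baseline_psa for _, v in series[: i + 1])
        if declined:
            nadir = min(
                [baseline_psa] + [v for _, v in series[: i + 1]]
            )
            return value >= 1.25 * nadir and value >= nadir + 2.0
        return (
            t > min_weeks_no_decline
            and value >= 1.25 * baseline_psa
            and value >= baseline_psa + 2.0
        )

    for i, (t, _) in enumerate(series):
        if qualifies(i):
            if require_confirmation:
                if i + 1 < len(series) and qualifies(i + 1):
                    return t
                continue
            return t
    return None


def detect_radiologic_progression(
    new_bone_lesions_per_scan: Sequence[tuple[float, int]],
    nodal_visceral_progression: Sequence[tuple[float, bool]] = (),
) -> float | None:
    """Time of radiologic progression: earliest scan with >=2 new bone
    lesions, or earliest nodal/visceral progression, whichever is first."""
    for seq in (new_bone_lesions_per_scan, nodal_visceral_progression):
        times = [t for t, _ in seq]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("scan series must be sorted by time")
    bone = next(
        (t for t, n in new_bone_lesions_per_scan if n >= 2), None
    )
    soft = next((t for t, flag in nodal_visceral_progression if flag), None)
    candidates = [t for t in (bone, soft) if t is not None]
    return min(candidates) if candidates else None


def compose_nlcb(
    psa_time: float | None,
    radiologic_time: float | None,
    clinical_time: float | None,
    censor_time: float,
) -> NlcbEvent:
    """Compose component progression times (months) into the NLCB endpoint.

    The event occurs at the earliest component time strictly before the
    censoring time; components tied at that time are all recorded.
    """
    components = {
        "psa": psa_time,
        "radiologic": radiologic_time,
        "clinical": clinical_time,
    }
    observed = {k: t for k, t in components.items() if t is not None}
    if any(t < 0 for t in observed.values()) or censor_time < 0:
        raise ValueError("times must be non-negative")
    if observed:
        t_event = min(observed.values())
        if t_event < censor_time:
            reasons = frozenset(k for k, t in observed.items() if t == t_event)
            return NlcbEvent(time=t_event, event=True, reason_components=reasons)
    return NlcbEvent(time=censor_time, event=False)
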