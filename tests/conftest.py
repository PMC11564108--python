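import numpy as np
import pytest

from adaptrial.aft import RandomizationRecord
from adaptrial.cohort import weibull_scale_for_median


def make_weibull_records(
    n_per_arm: int,
    true_str: float = 1.0,
    *,
    baseline_median: float = 7.4,
    shape: float = 1.2,
    censor_frac: float = 0.0,
    seed: int = 0,
    focal_arm: str = "arpi",
) -> list[RandomizationRecord]:
    """Two-arm records drawn from the generative Weibull AFT model."""
    rng = np.random.default_rng(seed)
    records = []
    for arm, median in (
        ("control", baseline_median),
        (focal_arm, baseline_median * true_str),
    ):
        lam = weibull_scale_for_median(median, shape)
        times = lam * rng.weibull(shape, size=n_per_arm)
        events = rng.random(n_per_arm) >= censor_frac
        # censored records observed at a uniform fraction of the latent time
        obs = np.where(events, times, times * rng.uniform(0.2, 1.0, n_per_arm))
        for i in range(n_per_arm):
            records.append(
                RandomizationRecord(
                    patient_id=f"{arm}{i}",
                    round=1,
                    arm=arm,
                    start_time=0.0,
                    time=float(max(obs[i], 1e-6)),
                    event=bool(events[i]),
                )
            )
    return records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_oc_runs():
    """Paired null / strong-alternative OC runs on reduced-size trials
    (250 patients, 42-month horizon, 10 replicates, common master seed),
    shared across engine- and OC-level tests."""
    from adaptrial.engine import DesignConfig
    from adaptrial.oc import (
        build_alternative_scenario,
        build_null_scenario,
        run_scenario,
    )

    config = DesignConfig()
    kwargs = dict(admin_censor_time=42.0, prior_arpi_prob=0.0)
    null = run_scenario(
        build_null_scenario(**kwargs), config, 10, 5, n_patients=250, label="null"
    )
    alt = run_scenario(
        build_alternative_scenario(2.0, "all", "arpi", **kwargs),
        config, 10, 5, n_patients=250, label="alt",
    )
    return null, alt, config
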