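"""Bayesian Weibull AFT inference: oracle equivalence, prior recovery,
survival summaries, Kaplan-Meier agreement, interaction and analysis-set
selection."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from adaptrial.aft import (
    AftModelSpec,
    PosteriorSummary,
    RandomizationRecord,
    _design,
    _log_posterior_factory,
    fit_interaction,
    fit_weibull_aft,
    km_estimate,
    laplace_fit_design,
    median_survival,
    posterior_survival_curve,
    pps,
    records_to_frame,
    select_analysis_set,
    str_to_percent_change,
)
from adaptrial.cohort import weibull_scale_for_median

from conftest import make_weibull_records


def grid_quadrature_oracle(records, spec=None):
    """Brute-force posterior moments of the log STR by dense 3-d grid
    quadrature over (mu, beta, log k) -- independent of the fitting path."""
    spec = spec or AftModelSpec()
    t, d, X = _design(records_to_frame(records), spec)
    _, _, _, log_post_batch = _log_posterior_factory(t, d, X, spec)
    mu = np.linspace(math.log(12) - 8, math.log(12) + 8, 140)
    beta = np.linspace(-2.5, 2.5, 160)
    logk = np.linspace(-4, 4, 120)
    M, B, K = np.meshgrid(mu, beta, logk, indexing="ij")
    thetas = np.column_stack([M.ravel(), B.ravel(), K.ravel()])
    lp = log_post_batch(thetas).reshape(M.shape)
    w = np.exp(lp - lp.max())
    total = w.sum()
    return (w * B).sum() / total, w[B > 0].sum() / total


def random_toy_records(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    records = []
    for i in range(n):
        arm = "arpi" if i % 2 else "control"
        records.append(
            RandomizationRecord(
                patient_id=f"t{i}",
                round=1,
                arm=arm,
                start_time=0.0,
                time=float(6 * rng.weibull(1.0) + 0.3),
                event=bool(rng.random() < 0.7),
            )
        )
    return records


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [7, 11, 23, 42, 99])
    def test_fast_backend_matches_grid_quadrature(self, seed):
        records = random_toy_records(seed)
        mean_oracle, pps_oracle = grid_quadrature_oracle(records)
        summary = fit_weibull_aft(records, seed=0)
        mean_fast = float(np.mean(summary.draws["beta"]))
        assert abs(mean_fast - mean_oracle) <= 0.02
        assert abs(summary.pps - pps_oracle) <= 0.02

    def test_mcmc_backend_matches_grid_quadrature(self):
        records = random_toy_records(7)
        mean_oracle, pps_oracle = grid_quadrature_oracle(records)
        summary = fit_weibull_aft(records, backend="mcmc", seed=1, n_draws=8000)
        assert summary.converged
        assert abs(float(np.mean(summary.draws["beta"])) - mean_oracle) <= 0.02
        assert abs(summary.pps - pps_oracle) <= 0.02

    def test_laplace_fit_design_matches_map(self):
        records = random_toy_records(11)
        spec = AftModelSpec()
        t, d, X = _design(records_to_frame(records), spec)
        prior_mean, prior_sd = spec.prior_moments()
        theta, cov = laplace_fit_design(t, d, X, prior_mean, prior_sd)
        summary = fit_weibull_aft(records, seed=0)
        assert np.allclose(theta, summary.diagnostics["theta_map"], atol=1e-6)


class TestPriorAndNull:
    def test_no_data_recovers_prior(self):
        summary = fit_weibull_aft([], seed=0)
        assert summary.pps == pytest.approx(0.5, abs=0.01)
        assert summary.str_median == pytest.approx(1.0, abs=0.02)
        z = 1.6449  # 90% two-sided normal quantile
        assert summary.cri[0] == pytest.approx(math.exp(-z * 0.5), rel=0.02)
        assert summary.cri[1] == pytest.approx(math.exp(z * 0.5), rel=0.02)

    def test_two_identical_arms_estimate_near_one(self):
        records = make_weibull_records(1000, true_str=1.0, seed=4)
        summary = fit_weibull_aft(records, seed=0)
        assert 0.93 <= summary.str_median <= 1.08

    def test_effect_recovered_within_cri(self):
        records = make_weibull_records(1000, true_str=1.5, seed=8)
        summary = fit_weibull_aft(records, seed=0)
        assert summary.cri[0] <= 1.5 <= summary.cri[1]

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError):
            RandomizationRecord("p", 1, "arpi", 0.0, 0.0, True)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull_aft([], backend="vi")


class TestPps:
    def test_all_positive_draws(self):
        s = fit_weibull_aft([], seed=0)
        s.draws["beta"] = np.abs(s.draws["beta"]) + 1e-9
        assert pps(s) == 1.0

    def test_prior_draws_near_half(self):
        s = fit_weibull_aft([], seed=0, n_draws=4000)
        assert pps(s) == pytest.approx(0.5, abs=0.03)

    def test_matches_normal_tail(self):
        s = fit_weibull_aft([], seed=0)
        rng = np.random.default_rng(0)
        s.draws["beta"] = rng.normal(0.405, 0.1, size=100_000)
        from scipy.stats import norm

        assert pps(s) == pytest.approx(norm.cdf(4.05), abs=0.002)

    def test_empty_draws_rejected(self):
        s = fit_weibull_aft([], seed=0, n_draws=0)
        with pytest.raises(ValueError):
            pps(s)


def synthetic_summary(mu, logk, n=5000, spec=None):
    """A PosteriorSummary with point-mass draws, for closed-form checks."""
    spec = spec or AftModelSpec()
    draws = {
        "mu": np.full(n, mu),
        "beta": np.zeros(n),
        "logk": np.full(n, logk),
        "k": np.full(n, math.exp(logk)),
    }
    return PosteriorSummary(
        spec=spec, draws=draws, str_median=1.0, cri=(1.0, 1.0), pps=0.5,
        n_records=0, n_events=0, backend="fast",
    )


class TestSurvivalCurves:
    def test_exponential_median_closed_form(self):
        # k = 1, lambda = 10 -> median = 10 * ln 2
        s = synthetic_summary(mu=math.log(10.0), logk=0.0)
        med, _ = median_survival(s, "control")
        assert med == pytest.approx(10 * math.log(2), rel=1e-6)

    def test_survival_starts_at_one(self):
        records = make_weibull_records(100, 1.5, seed=3)
        summary = fit_weibull_aft(records, seed=0)
        for arm in ("arpi", "control"):
            curve = posterior_survival_curve(summary, arm, [0.0, 1.0, 5.0])
            assert curve["survival"].iloc[0] == 1.0
            assert curve["upper"].iloc[0] == 1.0
            assert (curve["survival"].diff().dropna() <= 0).all()

    def test_median_scales_with_str(self):
        records = make_weibull_records(2000, 1.5, seed=5)
        summary = fit_weibull_aft(records, seed=0)
        med_focal, _ = median_survival(summary, "arpi")
        med_ref, _ = median_survival(summary, "control")
        assert med_focal / med_ref == pytest.approx(1.5, rel=0.08)

    def test_scale_equivariance(self):
        """Multiplying all times by c multiplies survival medians by c and
        leaves the STR and shape posteriors (essentially) unchanged."""
        records = make_weibull_records(400, 1.5, censor_frac=0.2, seed=9)
        c = 2.0
        scaled = [
            RandomizationRecord(
                r.patient_id, r.round, r.arm, r.start_time, r.time * c, r.event
            )
            for r in records
        ]
        s1 = fit_weibull_aft(records, seed=0)
        s2 = fit_weibull_aft(scaled, seed=0)
        assert s2.str_median == pytest.approx(s1.str_median, rel=5e-3)
        assert s2.pps == pytest.approx(s1.pps, abs=5e-3)
        m1, _ = median_survival(s1, "control")
        m2, _ = median_survival(s2, "control")
        assert m2 == pytest.approx(c * m1, rel=0.02)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        records = [
            RandomizationRecord("a", 1, "control", 0.0, 1.0, True),
            RandomizationRecord("b", 1, "control", 0.0, 2.0, True),
        ]
        kmf = km_estimate(records)
        assert kmf.predict(1.0) == pytest.approx(0.5)
        assert kmf.predict(2.0) == pytest.approx(0.0)

    def test_censoring_between_events(self):
        # events at 1 and 2, censored at 1.5: S(2) = 0.5 * (1 - 1/1) = 0
        records = [
            RandomizationRecord("a", 1, "control", 0.0, 1.0, True),
            RandomizationRecord("b", 1, "control", 0.0, 1.5, False),
            RandomizationRecord("c", 1, "control", 0.0, 2.0, True),
        ]
        kmf = km_estimate(records)
        assert kmf.predict(1.0) == pytest.approx(2 / 3)
        assert kmf.predict(2.0) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        records = [
            RandomizationRecord(f"p{i}", 1, "control", 0.0, float(i + 1), False)
            for i in range(5)
        ]
        kmf = km_estimate(records)
        assert kmf.predict(5.0) == pytest.approx(1.0)

    def test_km_agrees_with_posterior_curve_at_large_n(self):
        """Sup-norm between the product-limit estimate and the posterior
        survival curve is below 0.05 when data are model-generated."""
        records = make_weibull_records(1000, 1.5, censor_frac=0.15, seed=12)
        summary = fit_weibull_aft(records, seed=0)
        for arm in ("arpi", "control"):
            kmf = km_estimate(records, arm=arm)
            grid = np.linspace(0.1, 25.0, 120)
            post = posterior_survival_curve(summary, arm, grid)
            km_vals = kmf.predict(grid).to_numpy()
            assert np.max(np.abs(post["survival"].to_numpy() - km_vals)) <= 0.05

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], arm="arpi")


class TestInteraction:
    @staticmethod
    def interaction_records(str_ratio, n_per_cell, seed=0, base_str=1.1):
        """Four-cell data: arm x biomarker with STR ratio exp(eta)."""
        rng = np.random.default_rng(seed)
        records = []
        shape = 1.2
        for arm in ("taxane", "arpi"):
            for bm in (0, 1):
                median = 7.4
                if arm == "arpi":
                    median *= base_str * (str_ratio if bm else 1.0)
                lam = weibull_scale_for_median(median, shape)
                for i in range(n_per_cell):
                    records.append(
                        RandomizationRecord(
                            f"{arm}{bm}{i}", 1, arm, 0.0,
                            float(max(lam * rng.weibull(shape), 1e-6)), True,
                            subgroup_index=4 if bm else 0,  # tp53 bit
                        )
                    )
        return records

    def test_str_ratio_recovery(self):
        records = self.interaction_records(1.44, 500, seed=2)
        summary = fit_interaction(records, "tp53", seed=0)
        assert 1.2 <= summary.str_median <= 1.7

    def test_reversed_flag_inverts_ratio(self):
        records = self.interaction_records(1.44, 300, seed=3)
        frame = records_to_frame(records)
        flipped = frame.assign(tp53=~frame["tp53"])
        s_fwd = fit_interaction(frame, "tp53", seed=0)
        s_rev = fit_interaction(flipped, "tp53", seed=0)
        assert s_rev.str_median == pytest.approx(1 / s_fwd.str_median, rel=0.06)

    def test_empty_stratum_warns_and_returns_wide_posterior(self):
        records = [
            r
            for r in self.interaction_records(1.0, 30, seed=4)
            if not (r.arm == "arpi" and r.subgroup_index == 4)
        ]
        with pytest.warns(RuntimeWarning, match="empty"):
            summary = fit_interaction(records, "tp53", seed=0)
        # eta posterior stays close to its prior spread
        assert np.std(summary.draws["eta"]) > 0.3


class TestAnalysisSets:
    @staticmethod
    def records_with_rounds():
        mk = lambda pid, rnd, arm, line, pa, pt: RandomizationRecord(
            pid, rnd, arm, 0.0, 5.0, True,
            line=line, prior_arpi=pa, prior_taxane=pt,
        )
        return [
            mk("p1", 1, "arpi", 1, False, False),
            mk("p1", 2, "taxane", 2, True, False),
            mk("p2", 1, "taxane", 1, False, True),
            mk("p3", 1, "control", 2, True, True),
        ]

    def test_os_uses_first_round_only(self):
        out = select_analysis_set(self.records_with_rounds(), "os")
        assert set(out["round"]) == {1} and len(out) == 3

    def test_nlcb_uses_all_rounds(self):
        out = select_analysis_set(self.records_with_rounds(), "nlcb")
        assert len(out) == 4

    def test_no_rechallenge_drops_prior_exposed(self):
        out = select_analysis_set(
            self.records_with_rounds(), "nlcb", "no_rechallenge"
        )
        # p2's taxane record carries prior taxane exposure -> dropped
        assert len(out) == 3
        assert not (
            ((out["arm"] == "taxane") & out["prior_taxane"]).any()
            or ((out["arm"] == "arpi") & out["prior_arpi"]).any()
        )

    def test_first_line_only(self):
        out = select_analysis_set(
            self.records_with_rounds(), "nlcb", "first_line_only"
        )
        assert set(out["line"]) == {1}

    def test_sensitivity_none_is_identity(self):
        out = select_analysis_set(self.records_with_rounds(), "nlcb", "none")
        assert len(out) == 4

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            select_analysis_set(self.records_with_rounds(), "nlcb", "whatever")


@pytest.mark.parametrize(
    "value,expected", [(1.2, 20.0), (0.8, -20.0), (1.0, 0.0), (2.0, 100.0)]
)
def test_str_to_percent_change(value, expected):
    assert str_to_percent_change(value) == pytest.approx(expected)


def test_str_to_percent_change_rejects_non_positive():
    with pytest.raises(ValueError):
        str_to_percent_change(0.0)
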