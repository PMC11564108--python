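"""Adaptive trial engine: permitted arms, randomization matrix, stopping
rules and full-trial invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptrial.biomarkers import BiomarkerProfile, signature_subgroups
from adaptrial.cohort import default_scenario
from adaptrial.engine import (
    DesignConfig,
    RandomizationMatrix,
    check_stopping,
    initial_matrix,
    permitted_arms,
    randomize,
    run_trial,
    update_randomization_matrix,
)
from test_cohort import make_patient

CONFIG = DesignConfig()
DECISION_RANK = {"futility": -1, "continue": 0, "graduate": 1}


class TestPermittedArms:
    def test_prior_arpi_blocks_arpi_arm(self):
        patient = make_patient(prior_arpi=True)
        assert permitted_arms(patient, CONFIG) == ("control", "taxane")

    def test_prior_taxane_keeps_all_arms(self):
        patient = make_patient(prior_taxane=True)
        assert permitted_arms(patient, CONFIG) == ("control", "arpi", "taxane")

    def test_treatment_naive_gets_all_arms(self):
        assert permitted_arms(make_patient(), CONFIG) == (
            "control", "arpi", "taxane",
        )


class TestRandomizationMatrix:
    def test_equal_pps_mimics_equal_randomization(self):
        pps = np.full((16, 2), 0.5)
        mat = update_randomization_matrix(pps, np.zeros((16, 2), bool), CONFIG)
        assert np.allclose(mat.probabilities, 1 / 3)

    def test_control_floor_tracks_best_arm(self):
        pps = np.tile([0.9, 0.1], (16, 1))
        mat = update_randomization_matrix(pps, np.zeros((16, 2), bool), CONFIG)
        control, a1, a2 = mat.probabilities[0]
        assert control == pytest.approx(a1)
        assert a1 > a2

    def test_forbidden_entries_are_exact_zero(self):
        pps = np.full((16, 2), 0.5)
        forbidden = np.zeros((16, 2), bool)
        forbidden[3, 1] = True
        mat = update_randomization_matrix(pps, forbidden, CONFIG)
        assert mat.probabilities[3, 2] == 0.0
        assert mat.probabilities[3].sum() == pytest.approx(1.0)

    def test_all_forbidden_row_goes_to_control(self):
        pps = np.full((16, 2), 0.5)
        forbidden = np.ones((16, 2), bool)
        mat = update_randomization_matrix(pps, forbidden, CONFIG)
        assert np.allclose(mat.probabilities[:, 0], 1.0)

    def test_burn_in_matrix_is_uniform_with_floor(self):
        mat = initial_matrix(CONFIG)
        assert np.allclose(mat.probabilities, 1 / 3)

    def test_invalid_pps_rejected(self):
        with pytest.raises(ValueError):
            update_randomization_matrix(
                np.full((16, 2), 1.5), np.zeros((16, 2), bool), CONFIG
            )

    @given(
        pps=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=16, max_size=16
        ),
        forbidden_bits=st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_matrix_invariants_hold_for_any_input(self, pps, forbidden_bits):
        pps = np.array(pps)
        forbidden = np.array(
            [[bool(forbidden_bits >> (2 * g + j) & 1) for j in range(2)]
             for g in range(16)]
        )
        mat = update_randomization_matrix(pps, forbidden, CONFIG)
        mat.validate()  # row sums, [0,1], control floor
        assert np.all(mat.probabilities[:, 1:][forbidden] == 0.0)


class TestRandomize:
    def test_degenerate_row_forces_control(self):
        probs = np.zeros((16, 3))
        probs[:, 0] = 1.0
        mat = RandomizationMatrix(arms=CONFIG.arms, probabilities=probs)
        assert randomize(make_patient(), mat, np.random.default_rng(0)) == "control"

    def test_seeded_reproducibility(self):
        mat = initial_matrix(CONFIG)
        draws1 = [
            randomize(make_patient(), mat, np.random.default_rng(7))
            for _ in range(1)
        ]
        draws2 = [
            randomize(make_patient(), mat, np.random.default_rng(7))
            for _ in range(1)
        ]
        assert draws1 == draws2

    def test_empirical_frequencies_match_row(self):
        probs = np.tile([0.4, 0.3, 0.3], (16, 1))
        mat = RandomizationMatrix(arms=CONFIG.arms, probabilities=probs)
        rng = np.random.default_rng(1)
        patient = make_patient()
        draws = [randomize(patient, mat, rng) for _ in range(10_000)]
        assert np.mean([a == "control" for a in draws]) == pytest.approx(
            0.4, abs=0.015
        )
        assert np.mean([a == "arpi" for a in draws]) == pytest.approx(0.3, abs=0.015)

    def test_ineligible_patient_rejected(self):
        patient = make_patient(BiomarkerProfile(False, False, False, False, 0.1, msi=True))
        with pytest.raises(ValueError, match="not eligible"):
            randomize(patient, initial_matrix(CONFIG), np.random.default_rng(0))


class TestCheckStopping:
    def test_graduation_example(self):
        assert (
            check_stopping(0.86, [0.72, 0.75], 60, 0, CONFIG) == "graduate"
        )

    def test_one_lagging_subgroup_blocks_graduation(self):
        assert (
            check_stopping(0.86, [0.72, 0.65], 60, 0, CONFIG) == "continue"
        )

    def test_cap_reached(self):
        assert check_stopping(0.5, [0.5, 0.5], 60, 150, CONFIG) == "capped"

    def test_below_minimum_evaluated_continues(self):
        assert check_stopping(0.99, [0.9, 0.9], 10, 0, CONFIG) == "continue"

    def test_futility_requires_all_gates_below_half(self):
        assert check_stopping(0.10, [0.4, 0.3], 60, 0, CONFIG) == "futility"
        assert check_stopping(0.10, [0.4, 0.6], 60, 0, CONFIG) == "continue"

    def test_no_gated_subgroup_blocks_decisions(self):
        assert check_stopping(0.99, [], 60, 0, CONFIG) == "continue"
        assert check_stopping(0.01, [], 60, 0, CONFIG) == "continue"

    def test_single_gate_insufficient_when_several_populated(self):
        assert (
            check_stopping(0.95, [0.9], 60, 0, CONFIG, n_populated_subgroups=4)
            == "continue"
        )
        assert (
            check_stopping(0.95, [0.9], 60, 0, CONFIG, n_populated_subgroups=1)
            == "graduate"
        )

    @given(
        sig=st.floats(0.0, 1.0),
        bump=st.floats(0.0, 0.3),
        gates=st.lists(st.floats(0.0, 0.7), min_size=1, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_pps_inputs(self, sig, bump, gates):
        """Raising every PPS input never moves the decision toward
        futility."""
        base = check_stopping(sig, gates, 60, 0, CONFIG)
        raised = check_stopping(
            min(sig + bump, 1.0), [min(g + bump, 1.0) for g in gates], 60, 0, CONFIG
        )
        assert DECISION_RANK[raised] >= DECISION_RANK[base]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(graduation_pps=0.1, futility_pps=0.5)


@pytest.fixture(scope="module")
def simulated_trial():
    scenario = default_scenario(admin_censor_time=42.0)
    return run_trial(scenario, DesignConfig(), seed=3, n_patients=250)


class TestRunTrial:
    def test_deterministic_under_fixed_seed(self):
        scenario = default_scenario(admin_censor_time=24.0)
        s1 = run_trial(scenario, DesignConfig(), seed=11, n_patients=80)
        s2 = run_trial(scenario, DesignConfig(), seed=11, n_patients=80)
        assert s1.records == s2.records
        assert s1.arm_status == s2.arm_status

    def test_matrix_invariants_at_every_interim(self, simulated_trial):
        config = simulated_trial.config
        for when, probs in simulated_trial.matrix_history:
            RandomizationMatrix(arms=config.arms, probabilities=probs).validate()

    def test_no_arpi_rechallenge_ever(self, simulated_trial):
        """Full-history audit: no patient is randomized to the ARPI arm
        after prior ARPI exposure (at entry or from an earlier round)."""
        seen_arpi = set()
        for record in sorted(simulated_trial.records, key=lambda r: r.start_time):
            if record.arm == "arpi":
                assert not record.prior_arpi
                assert record.patient_id not in seen_arpi
                seen_arpi.add(record.patient_id)

    def test_control_patients_never_cross_to_investigational(self, simulated_trial):
        first_arm = {}
        for record in sorted(simulated_trial.records, key=lambda r: r.round):
            first_arm.setdefault(record.patient_id, record.arm)
            if first_arm[record.patient_id] == "control":
                assert record.arm == "control"

    def test_rounds_bounded_and_times_positive(self, simulated_trial):
        for record in simulated_trial.records:
            assert 1 <= record.round <= simulated_trial.config.max_rounds
            assert record.time > 0

    def test_terminal_combinations_stop_accruing(self, simulated_trial):
        """Once a (signature, arm) combination is graduated or stopped, no
        further randomizations of that arm occur in the signature."""
        final = {}
        for entry in simulated_trial.decision_log:
            if entry["decision"] in ("graduate", "futility") and entry["stage"] == "lock":
                final[(entry["signature"], entry["arm"])] = entry["time"]
        for (signature, arm), when in final.items():
            members = signature_subgroups(signature)
            late = [
                r for r in simulated_trial.records
                if r.arm == arm
                and r.subgroup_index in members
                and r.start_time > when + 1e-9
            ]
            assert late == []

    def test_strong_effect_graduates_in_majority(self, small_oc_runs):
        _, alt, _ = small_oc_runs
        assert alt.arm_graduation["arpi"] >= 0.6
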