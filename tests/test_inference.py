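"""Forward-algorithm likelihood and maximum-likelihood fitting."""

import numpy as np
import pytest

from trapaware.data import DataError, EncounterData
from trapaware.inference import (
    ParameterDesign,
    compare_models,
    dataset_neg_log_likelihood,
    fit,
    history_log_likelihood,
)
from trapaware.model_core import ModelSpec, ParameterSet
from trapaware.simulator import SimulationScenario, simulate

from conftest import (
    all_single_patterns,
    brute_force_history_likelihood,
    random_single_params,
    random_two_state_params,
)


class TestHistoryLikelihood:
    def test_immediate_recapture(self):
        """(1,1): single path A->A with probability phi * p'."""
        params = ParameterSet(phi=0.8, p=0.5, p_prime=0.6)
        ll = history_log_likelihood([1, 1], params, ModelSpec(2))
        assert ll == pytest.approx(np.log(0.48), abs=1e-12)
        assert ll == pytest.approx(-0.7340, abs=5e-5)

    def test_skip_one_occasion(self):
        """(1,0,1): unique path A->U->A, phi(1-p') * phi p."""
        params = ParameterSet(phi=0.8, p=0.5, p_prime=0.6)
        ll = history_log_likelihood([1, 0, 1], params, ModelSpec(3))
        assert np.exp(ll) == pytest.approx(0.8 * 0.4 * 0.8 * 0.5, abs=1e-12)

    def test_removal_drops_tail(self):
        params = ParameterSet(phi=0.8, p=0.5, p_prime=0.6)
        spec = ModelSpec(4)
        kept = history_log_likelihood([1, 1, 0, 0], params, spec, removed=False)
        dropped = history_log_likelihood([1, 1, 0, 0], params, spec, removed=True)
        assert dropped > kept  # censoring removes a < 1 never-seen-again factor

    def test_no_capture_history_rejected(self):
        with pytest.raises(DataError):
            history_log_likelihood([0, 0, 0], ParameterSet(phi=0.8, p=0.5),
                                   ModelSpec(3))

    def test_code_two_rejected_single_state(self):
        with pytest.raises(DataError):
            history_log_likelihood([1, 2, 0], ParameterSet(phi=0.8, p=0.5),
                                   ModelSpec(3))

    @pytest.mark.parametrize("K", [3, 4, 5])
    @pytest.mark.parametrize("state_space", ["single", "two_state"])
    def test_forward_matches_path_enumeration(self, K, state_space, rng):
        """Exact agreement with brute-force hidden-path summation."""
        spec = ModelSpec(K, state_space=state_space)
        for rep in range(20):
            if state_space == "single":
                params = random_single_params(rng, K, time_varying=rep % 2 == 0)
                codes = rng.integers(0, 2, size=K)
            else:
                params = random_two_state_params(rng, K, time_varying=rep % 2 == 0)
                codes = rng.integers(0, 3, size=K)
            if not codes.any():
                codes[rng.integers(0, K)] = 1
            removed = bool(rng.integers(0, 2))
            ll = history_log_likelihood(codes, params, spec, removed=removed)
            oracle = brute_force_history_likelihood(codes, params, spec,
                                                    removed=removed)
            assert np.exp(ll) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("release", [1, 2])
    def test_pattern_probabilities_sum_to_one(self, release, rng):
        """All 2^(K-release) patterns after a release partition the sample space."""
        K = 5
        spec = ModelSpec(K)
        params = random_single_params(rng, K, time_varying=True)
        total = sum(
            np.exp(history_log_likelihood(pat, params, spec))
            for pat in all_single_patterns(K, release)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestDatasetLikelihood:
    def _toy(self):
        hist = np.array([[1, 0, 1], [1, 1, 0]], dtype=np.int8)
        return EncounterData(hist)

    def test_count_weighting(self):
        spec = ModelSpec(3, effects_p={"trap"})
        theta = np.array([0.3, -0.2, 0.5])
        d1 = EncounterData(np.array([[1, 0, 1]]), counts=[1])
        d3 = EncounterData(np.array([[1, 0, 1]]), counts=[3])
        assert dataset_neg_log_likelihood(d3, theta, spec) == pytest.approx(
            3 * dataset_neg_log_likelihood(d1, theta, spec), rel=1e-12
        )

    def test_duplicate_rows_equal_incremented_count(self):
        spec = ModelSpec(3, effects_p={"trap"})
        theta = np.array([0.1, 0.2, -0.1])
        dup = EncounterData(np.array([[1, 0, 1], [1, 0, 1], [1, 1, 0]]))
        cnt = EncounterData(np.array([[1, 0, 1], [1, 1, 0]]), counts=[2, 1])
        assert dataset_neg_log_likelihood(dup, theta, spec) == pytest.approx(
            dataset_neg_log_likelihood(cnt, theta, spec), rel=1e-12
        )

    def test_empty_dataset_rejected(self):
        with pytest.raises((DataError, ValueError)):
            EncounterData(np.zeros((0, 3), dtype=np.int8))

    def test_cjs_collapse_identical_values(self):
        """With p' = p the trap model and the naive CJS agree exactly."""
        data = self._toy()
        trap_spec = ModelSpec(3, effects_p={"trap"})
        cjs_spec = ModelSpec(3)
        theta_cjs = np.array([0.4, -0.3])
        theta_trap = np.array([0.4, -0.3, -0.3])  # pprime == p on link scale
        assert dataset_neg_log_likelihood(data, theta_trap, trap_spec) == \
            pytest.approx(dataset_neg_log_likelihood(data, theta_cjs, cjs_spec),
                          rel=1e-12)


class TestFit:
    def test_parameter_recovery_moderate_n(self):
        scn = SimulationScenario(
            n_occasions=8, n_released_per_cohort=150,
            params=ParameterSet(phi=0.8, p=0.4, p_prime=0.7), seed=5,
        )
        data, _ = simulate(scn)
        res = fit(data, ModelSpec(8, effects_p={"trap"}))
        assert res.converged
        # within a few Monte-Carlo standard errors of truth at n ~ 1000
        assert res.estimates_natural["phi"] == pytest.approx(0.8, abs=0.04)
        assert res.estimates_natural["p"] == pytest.approx(0.4, abs=0.07)
        assert res.estimates_natural["pprime"] == pytest.approx(0.7, abs=0.06)
        for name, ci in res.ci95.items():
            lo, hi = ci
            assert 0.0 <= lo <= res.estimates_natural[name] <= hi <= 1.0

    def test_refit_from_mle_is_fixed_point(self, trap_happy_data):
        spec = ModelSpec(8, effects_p={"trap"})
        first = fit(trap_happy_data, spec)
        again = fit(trap_happy_data, spec, start=first.estimates_link)
        assert again.loglik == pytest.approx(first.loglik, abs=1e-8)

    def test_terminal_cjs_confounding_flagged(self, trap_happy_data):
        """Fully time-dependent CJS: phi_{K-1} and p_K are confounded."""
        spec = ModelSpec(8, effects_phi={"time"}, effects_p={"time"})
        res = fit(trap_happy_data, spec)
        assert "phi_i7" in res.rank_deficient
        assert "p_t8" in res.rank_deficient

    def test_aic_definition(self, trap_happy_data):
        res = fit(trap_happy_data, ModelSpec(8, effects_p={"trap"}))
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.n_params)

    def test_additive_design_has_single_trap_parameter(self):
        spec = ModelSpec(5, effects_p={"time", "trap", "additive"})
        design = ParameterDesign(spec)
        assert design.names.count("m") == 1
        assert not any(n.startswith("pprime") for n in design.names)
        theta = np.zeros(design.n_params)
        theta[design.names.index("m")] = np.log(9.0)
        params = design.to_params(theta)
        assert params.p_at(3, aware=True) == pytest.approx(0.9, abs=1e-12)
        assert params.p_at(3, aware=False) == pytest.approx(0.5, abs=1e-12)


class TestCompareModels:
    def test_single_fit_zero_delta(self, trap_happy_data):
        res = fit(trap_happy_data, ModelSpec(8, effects_p={"trap"}))
        table = compare_models([res])
        assert table["dAIC"].iloc[0] == 0.0

    def test_nested_models_loglik_ordering(self, trap_happy_data):
        full = fit(trap_happy_data, ModelSpec(8, effects_p={"trap"}))
        constrained = fit(trap_happy_data, ModelSpec(8))
        assert constrained.loglik <= full.loglik + 1e-8
        table = compare_models([full, constrained])
        assert list(table["AIC"]) == sorted(table["AIC"])

    def test_different_data_rejected(self, trap_happy_data):
        other = EncounterData(np.array([[1, 1, 0, 0, 0, 0, 0, 0]]))
        f1 = fit(trap_happy_data, ModelSpec(8))
        f2 = fit(other, ModelSpec(8))
        with pytest.raises(ValueError):
            compare_models([f1, f2])


class TestTwoStateLikelihood:
    def test_release_state_sets_initial_vector(self, rng):
        K = 4
        spec = ModelSpec(K, state_space="two_state")
        params = random_two_state_params(rng, K)
        ll1 = history_log_likelihood([1, 0, 0, 0], params, spec)
        ll2 = history_log_likelihood([2, 0, 0, 0], params, spec)
        o1 = brute_force_history_likelihood([1, 0, 0, 0], params, spec)
        o2 = brute_force_history_likelihood([2, 0, 0, 0], params, spec)
        assert np.exp(ll1) == pytest.approx(o1, abs=1e-12)
        assert np.exp(ll2) == pytest.approx(o2, abs=1e-12)

    def test_free_pi1_adds_initial_state_term(self, rng):
        K = 3
        spec = ModelSpec(K, state_space="two_state")
        params = random_two_state_params(rng, K)
        base = history_log_likelihood([2, 0, 1], params, spec)
        with_pi = history_log_likelihood([2, 0, 1], params, spec, free_pi1=True)
        assert with_pi == pytest.approx(base + np.log(1 - params.pi1), abs=1e-10)
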