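"""Simulator: deterministic limits, reproducibility, exact frequencies."""

import numpy as np
import pytest
from scipy import stats

from trapaware.data import EncounterData
from trapaware.model_core import ModelSpec, ParameterSet, SpecificationError
from trapaware.simulator import (
    SimulationScenario,
    expected_history_frequencies,
    simulate,
)

from conftest import brute_force_history_likelihood


def test_immortal_always_caught_gives_all_ones():
    scn = SimulationScenario(4, 10, params=ParameterSet(phi=1.0, p=1.0), seed=0)
    data, _ = simulate(scn)
    for i in range(data.n_histories):
        f = data.first_capture()[i]
        assert np.all(data.histories[i, f - 1:] == 1)


def test_zero_survival_gives_release_only():
    scn = SimulationScenario(5, 20, params=ParameterSet(phi=0.0, p=0.9), seed=1)
    data, _ = simulate(scn)
    assert (data.histories != 0).sum() == data.n_histories  # only release captures


def test_seed_reproducibility_and_divergence():
    scn = SimulationScenario(6, 50, params=ParameterSet(phi=0.8, p=0.5,
                                                        p_prime=0.7), seed=3)
    d1, _ = simulate(scn)
    d2, _ = simulate(scn)
    np.testing.assert_array_equal(d1.histories, d2.histories)
    np.testing.assert_array_equal(d1.removed, d2.removed)
    d3, _ = simulate(SimulationScenario(6, 50,
                                        params=ParameterSet(phi=0.8, p=0.5,
                                                            p_prime=0.7), seed=4))
    assert not np.array_equal(d1.histories, d3.histories)


def test_immediate_reencounter_fraction_matches_closed_form():
    """P(seen at occasion 2 | released at 1) = phi * p' for aware animals."""
    n = 10000
    scn = SimulationScenario(
        3, [n, 0], params=ParameterSet(phi=0.8, p=0.4, p_prime=0.6), seed=11,
    )
    data, _ = simulate(scn)
    frac = (data.histories[:, 1] == 1).mean()
    se = np.sqrt(0.48 * 0.52 / n)
    assert abs(frac - 0.48) < 2.58 * se  # binomial 99% bound


def test_truth_record_stores_scenario():
    scn = SimulationScenario(4, 5, params=ParameterSet(phi=0.5, p=0.5), seed=9)
    _, truth = simulate(scn)
    assert truth["seed"] == 9
    assert truth["n_occasions"] == 4
    assert truth["n_released_per_cohort"] == [5, 5, 5]


class TestExpectedFrequencies:
    def test_immediate_recapture_probability(self):
        scn = SimulationScenario(2, 1, params=ParameterSet(phi=0.8, p=0.4,
                                                           p_prime=0.6))
        freqs = expected_history_frequencies(scn)
        assert freqs[(1, 1)] == pytest.approx(0.48, abs=1e-14)

    @pytest.mark.parametrize("release", [1, 2])
    def test_frequencies_sum_to_one(self, release):
        scn = SimulationScenario(
            5, 1, params=ParameterSet(phi=(0.7, 0.8, 0.6, 0.9), p=0.4,
                                      p_prime=0.65, phi1=0.5),
            transient_fraction=0.2,
        )
        freqs = expected_history_frequencies(scn, release_occasion=release)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_path_enumeration_oracle(self):
        scn = SimulationScenario(4, 1, params=ParameterSet(phi=0.75, p=0.35,
                                                           p_prime=0.55))
        spec = ModelSpec(4)
        freqs = expected_history_frequencies(scn)
        for pattern, prob in freqs.items():
            oracle = brute_force_history_likelihood(pattern, scn.params, spec)
            assert prob == pytest.approx(oracle, abs=1e-14)

    def test_no_trap_effect_matches_cjs_enumeration(self):
        """With p' = p the pattern law reduces to plain CJS probabilities."""
        scn_trap = SimulationScenario(4, 1, params=ParameterSet(phi=0.8, p=0.5,
                                                                p_prime=0.5))
        scn_cjs = SimulationScenario(4, 1, params=ParameterSet(phi=0.8, p=0.5))
        f_trap = expected_history_frequencies(scn_trap)
        f_cjs = expected_history_frequencies(scn_cjs)
        assert set(f_trap) == set(f_cjs)
        for k in f_trap:
            assert f_trap[k] == pytest.approx(f_cjs[k], abs=1e-14)

    def test_large_k_rejected(self):
        scn = SimulationScenario(9, 1, params=ParameterSet(phi=0.8, p=0.5))
        with pytest.raises(SpecificationError):
            expected_history_frequencies(scn)


def test_empirical_frequencies_match_exact_law():
    """Chi-square goodness of fit of simulated pattern counts at n = 100000."""
    n = 100000
    scn = SimulationScenario(
        4, [n, 0, 0], params=ParameterSet(phi=0.8, p=0.4, p_prime=0.65), seed=123,
    )
    data, _ = simulate(scn)
    freqs = expected_history_frequencies(scn, release_occasion=1)
    patterns = sorted(freqs)
    observed = np.zeros(len(patterns))
    lookup = {p: i for i, p in enumerate(patterns)}
    for row, cnt in zip(data.histories, data.counts):
        observed[lookup[tuple(int(c) for c in row)]] += cnt
    expected = np.array([freqs[p] for p in patterns]) * n
    stat = ((observed - expected) ** 2 / expected).sum()
    crit = stats.chi2.isf(0.001, df=len(patterns) - 1)
    assert stat < crit


def test_transients_depress_first_interval_survival():
    """Apparent first-interval survival equals (1 - f_transient) * phi."""
    n = 40000
    tf = 0.3
    scn = SimulationScenario(
        3, [n, 0], params=ParameterSet(phi=0.8, p=1.0, p_prime=1.0),
        transient_fraction=tf, seed=21,
    )
    data, _ = simulate(scn)
    # with certain detection, being seen at occasion 2 <=> surviving interval 1
    apparent = (data.histories[:, 1] == 1).mean()
    expected = (1 - tf) * 0.8
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(apparent - expected) < 3 * se


def test_removals_truncate_histories():
    scn = SimulationScenario(
        6, 500, params=ParameterSet(phi=0.9, p=0.6, p_prime=0.8),
        removal_prob=0.5, seed=33,
    )
    data, _ = simulate(scn)
    assert data.removed.any()
    data.validate_removals()
    # a removed animal records nothing after its removal occasion
    last = data.last_capture()
    for i in np.flatnonzero(data.removed):
        assert (data.histories[i, last[i]:] == 0).all()


def test_two_state_simulation_smoke():
    scn = SimulationScenario(
        5, 200, params=ParameterSet(phi=(0.85, 0.7), p=(0.5, 0.4),
                                    p_prime=(0.7, 0.6), psi12=0.2, psi21=0.3,
                                    pi1=0.6),
        state_space="two_state", seed=8,
    )
    data, _ = simulate(scn)
    assert data.max_code == 2
    # release states split roughly by pi1
    rel_codes = data.histories[np.arange(data.n_histories),
                               data.first_capture() - 1]
    assert 0.5 < (rel_codes == 1).mean() < 0.7


def test_invalid_cohort_sizes_rejected():
    with pytest.raises(SpecificationError):
        SimulationScenario(4, [10, 10], params=ParameterSet(phi=0.8, p=0.5)).releases()
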