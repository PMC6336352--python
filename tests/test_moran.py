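"""Constant-size Moran model: closed forms vs exact and stochastic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnclone.constants import DIVISIONS_PER_YEAR, N_ADULT
from scnclone.moran import (
    MoranModel,
    conditional_fixation_time,
    divisions_to_years,
    exact_fixation_oracle,
    fixation_probability,
    proof_of_principle_table,
    required_initial_mutants,
    simulate_moran,
    simulate_moran_many,
)

from conftest import PRINTED_TABLE


class TestFixationProbability:
    def test_boundaries(self):
        assert fixation_probability(100, 0.05, 0) == 0.0
        assert fixation_probability(100, 0.05, 100) == 1.0

    def test_neutral_limit_is_i_over_N(self):
        assert fixation_probability(50, 0.0, 10) == pytest.approx(0.2)

    def test_huge_N_advantageous_limit(self):
        # (1-s)^N underflows; the limit is 1 - (1-s)^i
        p = fixation_probability(N_ADULT, 0.005, 240.193)
        assert p == pytest.approx(0.7, rel=1e-3)

    def test_deleterious_huge_N_is_tiny_but_finite(self):
        p = fixation_probability(1e9, -0.01, 5)
        assert 0.0 < p < 1e-300 or p == 0.0  # log-space path, no overflow

    @pytest.mark.parametrize("N", [100, 500, 1000])
    @pytest.mark.parametrize("s", [0.01, 0.05, 0.1])
    def test_matches_absorbing_chain_oracle(self, N, s):
        """The closed form replaces the exact per-copy factor (1+s)^-1 by
        (1-s), which inflates the fixation probability by a relative factor
        of up to (1+s) (attained at i=1, where the closed numerator is s
        but the exact one is s/(1+s)).  The deviation is therefore bounded
        by ~s in relative terms and decays as i grows; 2% agreement only
        holds for s <= ~0.02."""
        for i in (1, 5, N // 4):
            p_exact, _ = exact_fixation_oracle(N, s, i)
            p_closed = fixation_probability(N, s, i)
            assert p_closed == pytest.approx(p_exact, rel=max(0.021, 1.05 * s))

    def test_closed_form_deviation_is_order_s(self):
        """Documented deviation of the closed form: largest at i=1 where it
        equals s exactly; well below s by i ~ 1/s."""
        for s in (0.02, 0.05, 0.1):
            p_exact, _ = exact_fixation_oracle(500, s, 1)
            rel = fixation_probability(500, s, 1) / p_exact - 1.0
            assert rel == pytest.approx(s, rel=0.02)
            p_exact_far, _ = exact_fixation_oracle(500, s, 100)
            rel_far = fixation_probability(500, s, 100) / p_exact_far - 1.0
            assert 0 <= rel_far < rel

    def test_monotone_in_i_and_s(self):
        N = 1000
        probs_i = [fixation_probability(N, 0.02, i) for i in (1, 10, 100, 500)]
        assert np.all(np.diff(probs_i) > 0)
        probs_s = [fixation_probability(N, s, 10) for s in (0.001, 0.01, 0.1)]
        assert np.all(np.diff(probs_s) > 0)


class TestRequiredInitialMutants:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        s=st.floats(0.001, 0.5),
        logN=st.floats(3, 12),
        p=st.floats(0.05, 0.95),
    )
    def test_is_exact_inverse_of_fixation_probability(self, s, logN, p):
        N = 10.0**logN
        i_real, _ = required_initial_mutants(N, s, p)
        assert fixation_probability(N, s, i_real) == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize(
        "s,expected", [(s, row[0]) for s, row in PRINTED_TABLE.items()]
    )
    def test_published_rounded_counts(self, s, expected):
        _, i_rounded = required_initial_mutants(N_ADULT, s, 0.7)
        assert i_rounded == expected

    def test_rejects_s_outside_unit_interval(self):
        with pytest.raises(ValueError):
            required_initial_mutants(1000, -0.1, 0.7)
        with pytest.raises(ValueError):
            required_initial_mutants(1000, 1.5, 0.7)


class TestConditionalFixationTime:
    def test_inverse_scaling_in_s(self):
        t1 = conditional_fixation_time(1e8, 0.02, 50).t_fix_divisions
        t2 = conditional_fixation_time(1e8, 0.04, 50).t_fix_divisions
        assert t1 == pytest.approx(2 * t2)

    @pytest.mark.parametrize(
        "s,i,years", [(0.02, 59.595, 23.4), (0.1, 11.427, 4.87)]
    )
    def test_published_rows(self, s, i, years):
        summ = conditional_fixation_time(N_ADULT, s, i, DIVISIONS_PER_YEAR)
        assert summ.t_fix_years == pytest.approx(years, rel=0.005)

    def test_rejects_absorbed_start(self):
        with pytest.raises(ValueError):
            conditional_fixation_time(100, 0.1, 0)
        with pytest.raises(ValueError):
            conditional_fixation_time(100, 0.1, 100)

    def test_matches_oracle_divisions_at_moderate_N(self):
        """The asymptotic (2 ln N - ln i)/s is within ~15% of the exact
        conditional absorption time (in divisions = steps/N) at N=1000."""
        N, s, i = 1000, 0.1, 10
        _, steps = exact_fixation_oracle(N, s, i)
        asym = conditional_fixation_time(N, s, i).t_fix_divisions
        assert asym == pytest.approx(steps / N, rel=0.15)


class TestOracle:
    def test_neutral_is_i_over_N(self):
        p, _ = exact_fixation_oracle(10, 0.0, 3)
        assert p == pytest.approx(0.3, abs=1e-12)

    def test_rejects_large_N(self):
        with pytest.raises(ValueError):
            exact_fixation_oracle(10_000, 0.05, 1)

    def test_conditional_time_agrees_with_simulation(self):
        """Mean conditional fixation time (Moran steps) from replicate
        trajectories lies within 3 standard errors of the linear solve."""
        N, s, i = 200, 0.1, 20
        _, t_oracle = exact_fixation_oracle(N, s, i)
        times = []
        for seed in range(1500):
            real = simulate_moran(N, s, i, rng_seed=seed)
            assert real.absorbed
            if real.fixed:
                times.append(real.steps)
        times = np.asarray(times, dtype=float)
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert abs(times.mean() - t_oracle) < 3 * se


class TestSimulator:
    def test_absorbed_starts(self):
        assert simulate_moran(50, 0.1, 0, rng_seed=1).steps == 0
        assert not simulate_moran(50, 0.1, 0, rng_seed=1).fixed
        assert simulate_moran(50, 0.1, 50, rng_seed=1).fixed

    def test_reproducible_under_seed(self):
        a = simulate_moran(100, 0.05, 5, rng_seed=7)
        b = simulate_moran(100, 0.05, 5, rng_seed=7)
        assert a == b

    def test_fixation_frequency_within_binomial_band(self):
        N, s, i, reps = 100, 0.05, 5, 10_000
        p_exact, _ = exact_fixation_oracle(N, s, i)
        fixed = simulate_moran_many(N, s, i, reps, rng_seed=11)
        se = math.sqrt(p_exact * (1 - p_exact) / reps)
        assert abs(fixed.mean() - p_exact) < 3 * se

    def test_max_steps_flagging(self):
        real = simulate_moran(1000, 0.0, 500, rng_seed=3, max_steps=10)
        assert not real.absorbed


class TestModelTypes:
    def test_relative_fitness(self):
        assert MoranModel(N=100, s=0.05, i=3).r == pytest.approx(1.05)

    def test_invariant_violations_raise(self):
        with pytest.raises(ValueError):
            MoranModel(N=10, s=0.1, i=11)
        with pytest.raises(ValueError):
            MoranModel(N=10, s=-1.5)


def test_divisions_to_years():
    assert divisions_to_years(91.25, 91.25) == pytest.approx(1.0)
    assert divisions_to_years(8273, 91.25) == pytest.approx(90.7, rel=0.01)


def test_table_regeneration_matches_publication():
    """One call regenerates the full proof-of-principle table: rounded
    counts exactly, fixation ages within 0.5%, mutation rates within 1%."""
    df = proof_of_principle_table()
    assert len(df) == len(PRINTED_TABLE)
    for _, row in df.iterrows():
        i_pub, mu_pub, e_pub = PRINTED_TABLE[row["s"]]
        assert row["i_rounded"] == i_pub
        assert row["E_years"] == pytest.approx(e_pub, rel=0.005)
        assert row["mu"] == pytest.approx(mu_pub, rel=0.01)
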