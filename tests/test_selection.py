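"""Cell-cycle selection inference, Hill fitting and rank testing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnclone.assays import MUTANT_HILL, REFERENCE_HILL
from scnclone.selection import (
    CellCycleObservation,
    DoseResponseData,
    HillCurve,
    crossing_concentration,
    delta_from_psi,
    estimate_selection,
    fit_hill,
    g1_fraction,
    growth_rate,
    psi_from_phi,
    split_rank_test,
)


class TestCellCycleChain:
    def test_worked_example_reproduces_printed_values(self):
        obs = CellCycleObservation(phi=0.70, psi_star=0.567, T=4.0)
        est = estimate_selection(obs)
        assert round(est.psi, 3) == 0.621
        assert round(est.Delta, 3) == 0.503
        assert round(est.lam, 3) == 0.173
        assert round(est.lam_star, 3) == 0.198
        assert round(est.s, 3) == 0.144

    def test_identical_populations_give_zero(self):
        obs = CellCycleObservation(phi=0.7, phi_star=0.7, T=4.0)
        assert estimate_selection(obs).s == 0.0

    def test_lower_mutant_division_efficiency_erases_advantage(self):
        obs = CellCycleObservation(phi=0.70, phi_star=0.66, alpha_star=0.93, T=4.0)
        assert estimate_selection(obs).s < 0.02

    def test_s_increases_with_psi_gap(self):
        gaps = [0.60, 0.57, 0.54]
        ss = [
            estimate_selection(
                CellCycleObservation(psi=0.62, psi_star=g, T=4.0)
            ).s
            for g in gaps
        ]
        assert np.all(np.diff(ss) > 0)

    def test_growth_rate_values(self):
        assert growth_rate(4.0, 1.0) == pytest.approx(0.173, abs=5e-4)
        assert growth_rate(1.0, 1.0) == pytest.approx(math.log(2))
        assert growth_rate(8.0, 1.0) == pytest.approx(growth_rate(4.0, 1.0) / 2)

    def test_growth_requires_supercritical_division(self):
        with pytest.raises(ValueError):
            growth_rate(4.0, 0.5)

    def test_g1_fraction_limits(self):
        lam = growth_rate(4.0, 1.0)
        assert g1_fraction(lam, 4.0, 4.0) == pytest.approx(1.0)
        assert g1_fraction(lam, 0.6215 * 4, 4.0) == pytest.approx(0.70, abs=5e-4)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(phi=st.floats(0.05, 0.95), alpha=st.floats(0.55, 1.0))
    def test_psi_phi_inversion(self, phi, alpha):
        """psi_from_phi is the exact inverse of the G1-fraction formula."""
        T = 4.0
        psi = psi_from_phi(phi, alpha)
        lam = growth_rate(T, alpha)
        assert g1_fraction(lam, psi * T, T) == pytest.approx(phi, abs=1e-12)

    def test_delta_edge_cases(self):
        assert delta_from_psi(0.6, 0.6, 4.0) == 0.0
        assert delta_from_psi(0.9, 0.1, 4.0) < 4.0
        assert delta_from_psi(0.6215, 0.567, 4.0) == pytest.approx(0.503, abs=5e-4)

    def test_invalid_observation_rejected(self):
        with pytest.raises(ValueError):
            CellCycleObservation(phi=1.2, psi_star=0.5)
        with pytest.raises(ValueError):
            CellCycleObservation(phi=0.7, psi_star=0.5, alpha=0.4)
        with pytest.raises(ValueError):
            CellCycleObservation(psi=0.6)  # mutant line missing entirely


class TestHillFit:
    @staticmethod
    def _synthetic(noise_sd, seed):
        from scnclone.assays import AssayGeneratorConfig, generate_dose_response

        return generate_dose_response(
            AssayGeneratorConfig(noise_sd=noise_sd, seed=seed)
        )

    def test_noiseless_parameter_recovery(self):
        ref, mut = self._synthetic(0.0, 0)
        cr, cm, rss = fit_hill(ref, mut)
        for fitted, truth in ((cr, REFERENCE_HILL), (cm, MUTANT_HILL)):
            assert fitted.y0 == pytest.approx(truth.y0, rel=0.01)
            assert fitted.a == pytest.approx(truth.a, rel=0.01)
            for par in ("b", "c", "n"):
                assert getattr(fitted, par) == pytest.approx(
                    getattr(truth, par), rel=0.05
                )
        assert rss < 1e-10

    def test_noisy_fit_is_stable(self):
        """1% absorbance noise moves the recovered curve little: fitted
        responses (not raw parameters, which trade off along the b/c ridge)
        stay within a few percent of the truth across the dose range."""
        ref, mut = self._synthetic(0.005, 1)
        cr, cm, _ = fit_hill(ref, mut)
        doses = np.geomspace(1e-3, 1e3, 50)
        assert np.allclose(cr(doses), REFERENCE_HILL(doses), rtol=0.05, atol=0.02)
        assert np.allclose(cm(doses), MUTANT_HILL(doses), rtol=0.05, atol=0.02)

    def test_shared_baseline(self):
        ref, mut = self._synthetic(0.01, 2)
        cr, cm, _ = fit_hill(ref, mut)
        assert cr.y0 == cm.y0

    def test_flat_data_gives_zero_amplitude(self):
        doses = np.geomspace(0.01, 100, 6)
        rng = np.random.default_rng(0)
        flat = 0.5 + 1e-4 * rng.standard_normal((6, 3))
        d = DoseResponseData(doses, flat)
        cr, cm, _ = fit_hill(d, DoseResponseData(doses, flat.copy()))
        assert cr.a < 0.01
        assert cr.y0 == pytest.approx(0.5, abs=0.01)

    def test_too_few_doses_rejected(self):
        d = DoseResponseData(np.array([1.0, 2.0, 4.0]), np.ones((3, 3)))
        with pytest.raises(ValueError):
            fit_hill(d, d)


class TestCrossing:
    def test_published_curves_cross_near_tenth_ng(self):
        x = crossing_concentration(REFERENCE_HILL, MUTANT_HILL)
        assert 0.05 < x < 0.3

    def test_identical_curves_raise(self):
        with pytest.raises(ValueError):
            crossing_concentration(REFERENCE_HILL, REFERENCE_HILL)

    def test_bracket_respected(self):
        with pytest.raises(ValueError):
            crossing_concentration(
                REFERENCE_HILL, MUTANT_HILL, bracket=(1.0, 10.0)
            )


class TestSplitRankTest:
    DOSES = np.array([0.01, 0.05, 0.1, 1.0, 10.0, 100.0])

    def test_identical_samples_give_half(self):
        vals = np.arange(6.0)[:, None] + np.array([0.0, 0.1])
        a = DoseResponseData(self.DOSES, vals)
        b = DoseResponseData(self.DOSES, vals.copy())
        assert split_rank_test(a, b) == (0.5, 0.5)

    def test_complete_separation_attains_exact_minimum(self):
        """3-vs-3 exact rank-sum: the smallest attainable one-sided p-value
        is 1/C(6,3) = 0.05."""
        low_r, low_m = [[4.0], [5.0], [6.0]], [[1.0], [2.0], [3.0]]
        high_r, high_m = [[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]]
        ref = DoseResponseData(self.DOSES, np.array(low_r + high_r))
        mut = DoseResponseData(self.DOSES, np.array(low_m + high_m))
        p_high, p_low = split_rank_test(ref, mut)
        assert p_high == pytest.approx(0.05)
        assert p_low == pytest.approx(0.05)

    def test_empty_stratum_error_names_it(self):
        d = DoseResponseData(np.array([1.0, 2.0, 4.0]), np.ones((3, 2)))
        with pytest.raises(ValueError, match="low"):
            split_rank_test(d, d, threshold=0.1)

    def test_detects_generated_effect_direction(self):
        """At generator defaults the mutant outgrows the reference above the
        crossing dose: p_high < 0.05 in at least 90% of seeds."""
        from scnclone.assays import AssayGeneratorConfig, generate_dose_response

        hits = 0
        for seed in range(30):
            ref, mut = generate_dose_response(AssayGeneratorConfig(seed=seed))
            p_high, _ = split_rank_test(ref, mut)
            hits += p_high < 0.05
        assert hits >= 27


def test_hill_curve_guards_log_domain():
    with pytest.raises(ValueError):
        HillCurve(0.3, 0.5, 20.0, 5.0, 10.0)(1.0)  # ln(1) = 0 <= c = 5
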