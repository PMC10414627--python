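"""Equation-level dose operations and the ensemble runner."""

import numpy as np
import pandas as pd
import pytest

from mc2dose.bundle import Individual, ResidenceRecord
from mc2dose.dose_engine import (
    RunOptions,
    chronic_cumulative,
    eurt_external_annual,
    eurt_intake,
    household_ratios,
    internal_cumulative_dose,
    run_ensemble,
    techa_external_annual,
    techa_external_cumulative,
    techa_intake,
    xi_scaling,
)
from conftest import make_hand_bundle


class TestTechaIntake:
    def test_identity_multipliers(self, hand_bundle):
        ind = hand_bundle.cohort[0]
        assert techa_intake(hand_bundle, ind, "Sr-90", 1951) == pytest.approx(1000.0)

    def test_zero_nuclide_ratio(self, hand_bundle):
        hand_bundle.intake.r_ratio[("Sr-90", "T000")] = 0.0
        ind = hand_bundle.cohort[0]
        assert techa_intake(hand_bundle, ind, "Sr-90", 1951) == 0.0

    def test_scalar_product_oracle(self, hand_bundle):
        """Randomized factors: engine product equals an independent product."""
        rng = np.random.default_rng(7)
        ind = hand_bundle.cohort[0]
        for _ in range(50):
            iref, f, alpha, xi, rr = rng.lognormal(0, 0.5, size=5)
            hand_bundle.intake.i_ref[:] = iref
            hand_bundle.settlements["T000"].f_ratio = f
            hand_bundle.intake.alpha[:] = alpha
            hand_bundle.intake.alpha[-1] = alpha
            hand_bundle.intake.r_ratio[("Sr-90", "T000")] = rr
            got = techa_intake(hand_bundle, ind, "Sr-90", 1953, xi=xi)
            assert got == pytest.approx(iref * f * alpha * xi * rr, rel=1e-12)

    def test_residence_weighting(self, hand_bundle):
        ind = Individual(
            id="M", birth_year=1930, household_id="H",
            residence_history=[
                ResidenceRecord("T000", 1950.0, 1953.25),
                ResidenceRecord("C000", 1953.25, 1960.0),
            ],
        )
        # only a quarter of 1953 is spent riverside
        assert techa_intake(hand_bundle, ind, "Sr-90", 1953) == pytest.approx(250.0)
        assert techa_intake(hand_bundle, ind, "Sr-90", 1954) == 0.0


class TestChronicKernel:
    def test_single_intake_constant_kernel(self, hand_bundle):
        series = {1950: 500.0}
        for y in (1950, 1953, 1959):
            got = internal_cumulative_dose(
                series, hand_bundle.dose_coeff, "stomach", "Sr-90", y, birth_year=1930
            )
            assert got == pytest.approx(500.0 * 1e-8)

    def test_zero_intake(self, hand_bundle):
        got = internal_cumulative_dose(
            {y: 0.0 for y in range(1950, 1955)},
            hand_bundle.dose_coeff, "stomach", "Sr-90", 1954, birth_year=1930,
        )
        assert got == 0.0

    def test_negative_intake_rejected(self, hand_bundle):
        with pytest.raises(ValueError):
            internal_cumulative_dose(
                {1950: -1.0}, hand_bundle.dose_coeff, "stomach", "Sr-90", 1950
            )

    def test_matches_double_loop_oracle(self):
        """Vectorized accumulation equals the brute-force (t, lag) double loop."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_years = rng.integers(2, 12)
            n_lag = rng.integers(1, 8)
            kernel = np.cumsum(rng.uniform(0, 1, size=(n_lag, 11)), axis=0)
            intakes = rng.uniform(0, 100, size=n_years)
            ages = rng.integers(0, 11, size=n_years)
            got = chronic_cumulative(intakes, kernel, ages)
            want = np.zeros(n_years)
            for y in range(n_years):
                for t in range(y + 1):
                    lag = min(y - t, n_lag - 1)
                    want[y] += intakes[t] * kernel[lag, ages[t]]
            np.testing.assert_allclose(got, want, rtol=1e-12)


class TestExternal:
    def test_bank_only_limit(self):
        b = make_hand_bundle(t1=1.0, t3=0.0)
        ind = b.cohort[0]
        assert techa_external_annual(b, ind, "stomach", 1951) == pytest.approx(0.005)

    def test_perfect_shielding_limit(self):
        b = make_hand_bundle(t1=0.0, t3=1.0, r_inout=0.0)
        ind = b.cohort[0]
        assert techa_external_annual(b, ind, "stomach", 1951) == 0.0

    def test_mixed_fraction_bracket(self):
        # T1=0.1, T2=0.5, T3=0.4; bracket = 0.1 + 0.03*0.5 + 0.5*0.4 = 0.315
        b = make_hand_bundle(t1=0.1, t3=0.4, r_inout=0.5)
        ind = b.cohort[0]
        got = techa_external_annual(b, ind, "stomach", 1951)
        assert got == pytest.approx(0.315 * 0.005, rel=1e-12)

    def test_cumulative_prefix_sum(self):
        assert techa_external_cumulative([0.002] * 5)[-1] == pytest.approx(0.01)
        rng = np.random.default_rng(2)
        series = rng.uniform(0, 1, 20)
        np.testing.assert_allclose(
            techa_external_cumulative(series), np.cumsum(series), rtol=1e-15
        )
        assert techa_external_cumulative([]).size == 0


class TestEurt:
    def _resident(self):
        return Individual(
            id="E", birth_year=1930, household_id="H",
            residence_history=[ResidenceRecord("E000", 1950.0, 1960.0)],
        )

    def test_zero_deposition(self, hand_bundle):
        hand_bundle.settlements["E000"].g_sr90 = 0.0
        assert eurt_intake(hand_bundle, self._resident(), "Sr-90", 1958) == 0.0

    def test_deposition_times_conversion(self, hand_bundle):
        # 56 kBq/m2 deposition at 0.001 Bq intake per Bq/m2 -> 56 Bq
        got = eurt_intake(hand_bundle, self._resident(), "Sr-90", 1958)
        assert got == pytest.approx(56.0, rel=1e-12)

    def test_randomized_product_oracle(self, hand_bundle):
        rng = np.random.default_rng(5)
        ind = self._resident()
        for _ in range(30):
            g = rng.uniform(1e3, 1e7)
            e = rng.uniform(1e-4, 1e-1)
            hand_bundle.settlements["E000"].g_sr90 = g
            hand_bundle.intake.e_conv["Sr-90"][:] = e
            assert eurt_intake(hand_bundle, ind, "Sr-90", 1959) == pytest.approx(
                g * e, rel=1e-12
            )

    def test_external_outdoor_limit(self):
        b = make_hand_bundle(t3=0.0)
        got = eurt_external_annual(b, self._resident(), "stomach", 1958)
        d_year = sum(d for _m, d in b.d_sr90_annual(1958))
        assert got == pytest.approx(56e3 * d_year, rel=1e-12)

    def test_external_shielding_free_limit(self):
        b = make_hand_bundle(t3=1.0, r_inout=1.0)
        got = eurt_external_annual(b, self._resident(), "stomach", 1958)
        d_year = sum(d for _m, d in b.d_sr90_annual(1958))
        assert got == pytest.approx(56e3 * d_year, rel=1e-12)

    def test_external_bracket_hand_value(self):
        # T3=0.6, R_in/out=0.3: bracket = 0.4 + 0.18 = 0.58
        b = make_hand_bundle(t3=0.6, r_inout=0.3)
        got = eurt_external_annual(b, self._resident(), "stomach", 1958)
        d_year = sum(d for _m, d in b.d_sr90_annual(1958))
        assert got == pytest.approx(0.58 * 56e3 * d_year, rel=1e-12)


class TestXiScaling:
    def test_none_mode(self):
        ind = Individual(id="a", birth_year=1930, household_id="H")
        assert xi_scaling(ind) == 1.0

    def test_single_member_household(self):
        a = Individual(id="a", birth_year=1930, household_id="H",
                       xi_mode="imr", imr=2.0, n_measurements=3)
        b = Individual(id="b", birth_year=1932, household_id="H", xi_mode="hsr")
        hh = household_ratios([a, b])
        assert hh["H"] == pytest.approx(2.0)
        assert xi_scaling(b, hh) == pytest.approx(0.5)

    def test_arithmetic_household_average(self):
        cohort = [
            Individual(id=str(i), birth_year=1930, household_id="H",
                       xi_mode="imr", imr=v, n_measurements=1)
            for i, v in enumerate([1.0, 2.0, 4.0])
        ]
        hh = household_ratios(cohort)
        assert hh["H"] == pytest.approx(7.0 / 3.0)

    def test_hsr_without_measured_household(self):
        b = Individual(id="b", birth_year=1932, household_id="H", xi_mode="hsr")
        with pytest.raises(ValueError):
            xi_scaling(b, {})


class TestRunEnsemble:
    def test_point_mass_mode_all_identical(self, hand_bundle):
        ens = run_ensemble(
            hand_bundle, 10, seed=3, options=RunOptions(shared=False, unshared=False)
        )
        assert np.allclose(ens.doses, ens.doses[..., :1], rtol=0, atol=0)

    def test_same_seed_bit_identical(self, small_bundle):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = run_ensemble(small_bundle, 6, seed=9)
            e2 = run_ensemble(small_bundle, 6, seed=9)
        assert np.array_equal(e1.doses, e2.doses)

    def test_nonnegative_and_monotone(self, small_bundle):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = run_ensemble(small_bundle, 6, seed=9)
        assert (ens.doses >= 0).all()
        assert (np.diff(ens.cumulative(), axis=1) >= -1e-18).all()

    def test_total_is_component_sum(self, small_bundle):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = run_ensemble(small_bundle, 4, seed=9)
        np.testing.assert_allclose(
            ens.total(), ens.doses.sum(axis=3), rtol=1e-15
        )

    def test_invalid_realization_count(self, hand_bundle):
        with pytest.raises(ValueError):
            run_ensemble(hand_bundle, 0, seed=1)


def test_ensemble_save_load_round_trip(tmp_path, hand_bundle):
    ens = run_ensemble(
        hand_bundle, 5, seed=3, options=RunOptions(shared=False, unshared=False)
    )
    ens.save(tmp_path / "ens")
    from mc2dose.dose_engine import DoseRealizationEnsemble

    back = DoseRealizationEnsemble.load(tmp_path / "ens")
    assert np.array_equal(back.doses, ens.doses)
    assert back.organs == ens.organs
    assert back.individual_ids == ens.individual_ids
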