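"""Per-person and population summary statistics over realizations."""

import math

import numpy as np
import pandas as pd
import pytest

from mc2dose.dose_engine import COMPONENTS, DoseRealizationEnsemble
from mc2dose.summaries import (
    cohort_records,
    cv_from_gsd,
    gsd_from_cv,
    individual_summary,
    internal_fraction,
    population_summary,
    realization_ratio_cdf,
    summarize_realizations,
)


def make_ensemble(final_doses: np.ndarray, split=None) -> DoseRealizationEnsemble:
    """Build a one-year, one-organ ensemble directly from final doses.

    ``final_doses`` has shape (n_individuals, n_realizations); ``split``
    optionally gives the fraction of each dose assigned to the riverside
    internal component (remainder goes to riverside external).
    """
    n_ind, n_real = final_doses.shape
    doses = np.zeros((n_ind, 1, 1, 4, n_real))
    frac = 1.0 if split is None else split
    doses[:, 0, 0, 0, :] = final_doses * frac
    doses[:, 0, 0, 1, :] = final_doses * (1.0 - frac)
    return DoseRealizationEnsemble(
        doses=doses,
        individual_ids=[f"I{i}" for i in range(n_ind)],
        years=np.array([1950]),
        organs=("stomach",),
        seed=0,
    )


class TestSummaryRecord:
    def test_constant_realizations(self):
        r = summarize_realizations(np.full(100, 0.1))
        assert r.am == pytest.approx(0.1)
        assert r.gm == pytest.approx(0.1)
        assert r.cv == pytest.approx(0.0, abs=1e-12)
        assert r.gsd == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_values(self):
        r = summarize_realizations(np.array([1.0, 4.0]))
        assert r.am == pytest.approx(2.5)
        assert r.gm == pytest.approx(2.0)
        assert r.cv == pytest.approx(0.6)
        assert r.gsd == pytest.approx(2.0)

    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(8)
        v = rng.lognormal(math.log(0.2), math.log(2.0), 1500)
        r = summarize_realizations(v)
        assert abs(r.gm - 0.2) / 0.2 < 0.05
        assert abs(r.gsd - 2.0) / 2.0 < 0.05

    def test_all_zero_flagged(self):
        r = summarize_realizations(np.zeros(50))
        assert r.gm == 0.0 and r.gsd == 1.0 and r.all_zero

    def test_zero_fraction_reported(self):
        v = np.array([0.0, 0.0, 1.0, 1.0])
        assert summarize_realizations(v).zero_fraction == pytest.approx(0.5)

    def test_am_ge_gm_always(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            v = rng.lognormal(0, rng.uniform(0.1, 1.5), 200)
            r = summarize_realizations(v)
            assert r.am >= r.gm - 1e-12

    def test_too_few_realizations(self):
        with pytest.raises(ValueError):
            summarize_realizations(np.array([1.0]))


class TestPopulationSummary:
    def test_identical_individuals(self):
        recs = cohort_records(make_ensemble(np.full((5, 10), 0.3)), "stomach")
        table = population_summary(recs)
        mean_row = table[table["statistic"] == "population_mean"].iloc[0]
        assert mean_row["mean"] == pytest.approx(0.3)
        assert mean_row["cv"] == pytest.approx(0.0)
        for p in (5, 25, 50, 75, 95):
            assert mean_row[f"p{p}"] == pytest.approx(0.3)

    def test_median_by_interpolation_rule(self):
        finals = np.repeat(np.arange(1.0, 101.0)[:, None], 2, axis=1)
        recs = cohort_records(make_ensemble(finals), "stomach")
        table = population_summary(recs)
        med = table[table["statistic"] == "population_mean"].iloc[0]["p50"]
        assert med == pytest.approx(50.5)

    def test_single_record_reproduced(self):
        finals = np.array([[1.0, 4.0]])
        recs = cohort_records(make_ensemble(finals), "stomach")
        table = population_summary(recs)
        gm_row = table[table["statistic"] == "population_geometric_mean"].iloc[0]
        assert gm_row["mean"] == pytest.approx(2.0)
        assert gm_row["p50"] == pytest.approx(2.0)
        assert gm_row["max"] == pytest.approx(2.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            population_summary(pd.DataFrame(columns=["am", "gm", "cv", "gsd"]))

    def test_csv_round_trip(self, tmp_path):
        finals = np.abs(np.random.default_rng(0).lognormal(0, 1, (8, 20)))
        table = population_summary(cohort_records(make_ensemble(finals), "stomach"))
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)


class TestLognormalConversions:
    def test_gsd_one(self):
        assert cv_from_gsd(1.0) == 0.0

    def test_closed_form_at_e(self):
        assert cv_from_gsd(math.e) == pytest.approx(math.sqrt(math.e - 1.0))

    def test_round_trip(self):
        assert gsd_from_cv(cv_from_gsd(2.5)) == pytest.approx(2.5, abs=1e-12)
        assert cv_from_gsd(gsd_from_cv(0.8)) == pytest.approx(0.8, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cv_from_gsd(0.9)
        with pytest.raises(ValueError):
            gsd_from_cv(-0.1)


class TestRealizationRatioCdf:
    def test_no_shared_error_curves_coincide(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.5, size=(4000, 1))
        finals = base * rng.lognormal(0, 0.3, size=(4000, 6))  # purely unshared
        ens = make_ensemble(finals)
        df = realization_ratio_cdf(ens, "stomach", [0, 3])
        med0 = df[df.realization == 0].query("cdf >= 0.5").ratio.iloc[0]
        med3 = df[df.realization == 3].query("cdf >= 0.5").ratio.iloc[0]
        assert abs(med0 - med3) < 0.05

    def test_global_shared_factor_translates_curve(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(0, 0.5, size=(2000, 1))
        shared = np.array([0.5, 1.0, 2.0, 1.5])
        finals = base * shared[None, :]
        ens = make_ensemble(finals)
        df = realization_ratio_cdf(ens, "stomach", list(range(4)))
        mean_shared = shared.mean()
        for rid in range(4):
            med = df[df.realization == rid].query("cdf >= 0.5").ratio.iloc[0]
            # the whole curve sits at the realization's shared factor
            assert med == pytest.approx(shared[rid] / mean_shared, rel=1e-9)

    def test_unknown_realization(self):
        ens = make_ensemble(np.ones((3, 4)))
        with pytest.raises(KeyError):
            realization_ratio_cdf(ens, "stomach", [99])


class TestInternalFraction:
    def test_all_internal(self):
        frac, n_ex = internal_fraction(make_ensemble(np.ones((5, 4)), split=1.0), "stomach")
        assert frac == 1.0 and n_ex == 0

    def test_all_external(self):
        frac, _ = internal_fraction(make_ensemble(np.ones((5, 4)), split=0.0), "stomach")
        assert frac == 0.0

    def test_fixed_ratio(self):
        frac, _ = internal_fraction(make_ensemble(np.ones((5, 4)), split=0.75), "stomach")
        assert frac == pytest.approx(0.75)

    def test_zero_dose_individuals_excluded(self):
        finals = np.ones((4, 6))
        finals[2] = 0.0
        frac, n_ex = internal_fraction(make_ensemble(finals, split=0.5), "stomach")
        assert n_ex == 1 and frac == pytest.approx(0.5)


def test_individual_summary_from_ensemble():
    finals = np.array([[1.0, 4.0], [2.0, 2.0]])
    ens = make_ensemble(finals)
    r = individual_summary(ens, "I0", "stomach")
    assert (r.am, r.gm) == (pytest.approx(2.5), pytest.approx(2.0))
    r1 = individual_summary(ens, "I1", "stomach")
    assert r1.cv == 0.0 and r1.gsd == 1.0
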