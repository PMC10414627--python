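"""Shared fixtures: a hand-computable mini scenario and synthetic bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mc2dose.bundle import (
    BehavioralFactors,
    DoseCoefficientTable,
    Individual,
    IntakeModel,
    N_AGE_BINS,
    ResidenceRecord,
    ScenarioBundle,
    Settlement,
)
from mc2dose.registry import Dimensioning, build_default_registry
from mc2dose.synthdata import ScenarioConfig, generate_scenario_bundle


def make_hand_bundle(
    *,
    years=(1950, 1959),
    df_const: float = 1.0e-8,
    t1: float = 0.1,
    t3: float = 0.5,
    r_inout: float = 0.5,
    cohort: list[Individual] | None = None,
) -> ScenarioBundle:
    """A one-nuclide, two-organ scenario with constant tables.

    Every mean value is a round number so equation-level results can be
    checked by hand: reference intake 1000 Bq/yr, settlement ratio 1,
    nuclide ratio 1, constant cumulative dose coefficient, constant
    shoreline dose rate 0.005 Gy/yr, fallout deposition 56 kBq/m2.
    """
    start, end = years
    n_years = end - start + 1
    yr = np.arange(start, end + 1)
    settlements = {
        "T000": Settlement(
            id="T000", kind="techa", distance_km=10.0, f_ratio=1.0,
            r_outriv_mean=0.03, r_outriv_min=0.01, r_outriv_max=0.09, index=0,
        ),
        "E000": Settlement(id="E000", kind="eurt", g_sr90=56e3, index=0),
        "C000": Settlement(id="C000", kind="clean", index=0),
    }
    intake = IntakeModel(
        i_ref=pd.Series(np.full(n_years, 1000.0), index=yr),
        alpha=np.ones(N_AGE_BINS),
        r_ratio={("Sr-90", "T000"): 1.0},
        e_conv={"Sr-90": np.full((15, N_AGE_BINS), 1.0e-3)},
    )
    organs = ("stomach", "marrow")
    kernels = {
        ("Sr-90", o): np.full((n_years + 5, N_AGE_BINS), df_const) for o in organs
    }
    behavior = BehavioralFactors(
        t1=np.full(N_AGE_BINS, t1),
        t3=np.full(N_AGE_BINS, t3),
        a_o={"stomach": 1.0, "marrow": 1.0},
        r_inout_mean=r_inout,
    )
    if cohort is None:
        cohort = [
            Individual(
                id="A", birth_year=1930, household_id="H1",
                residence_history=[ResidenceRecord("T000", float(start), float(end + 1))],
            )
        ]
    dim = Dimensioning(
        n_techa_settlements=1, n_eurt_villages=1, n_nuclides=1,
        n_eurt_nuclides=1, n_organs=len(organs), n_time_slices=n_years,
        n_age_groups=N_AGE_BINS, n_months=15, move_limit=20,
    )
    return ScenarioBundle(
        settlements=settlements,
        intake=intake,
        dose_coeff=DoseCoefficientTable(kernels),
        behavior=behavior,
        cohort=cohort,
        registry=build_default_registry(dim),
        nuclides=("Sr-90",),
        eurt_nuclides=("Sr-90",),
        organs=organs,
        start_year=start,
        end_year=end,
        accident_date=1957.75,
        d_riv={"T000": pd.Series(np.full(n_years, 0.005), index=yr)},
        d_sr90_monthly=np.full(15, 1.0e-9),
        d_sr90_tail=np.full(3, 1.0e-10),
        seed=0,
    )


@pytest.fixture
def hand_bundle() -> ScenarioBundle:
    return make_hand_bundle()


@pytest.fixture(scope="session")
def small_bundle() -> ScenarioBundle:
    return generate_scenario_bundle(ScenarioConfig(cohort_size=20, seed=11))


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return ScenarioConfig(cohort_size=20, seed=11)
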