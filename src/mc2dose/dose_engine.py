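"""Annual organ-dose evaluation over residence histories, per realization.

Four exposure components are evaluated for every person, year, organ and
Monte-Carlo realization:

* riverside internal — ingestion intake built from the reference-settlement
  intake series, the settlement ratio, the child-to-adult age ratio, an
  individual scaling factor and nuclide-to-90Sr ratios, convolved with
  cumulative dose-coefficient kernels;
* riverside external — shoreline dose rate in air modulated by behavioral
  time fractions and shielding ratios;
* fallout-trace internal — deposition times a deposition-to-intake
  conversion, through the same dose-coefficient kernels;
* fallout-trace external — deposition times a normalized outdoor dose rate
  with an indoor-shielding bracket.

The engine applies the shared factors of the active realization and the
person's unshared factors to every term, producing a
:class:`DoseRealizationEnsemble` of annual doses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bundle import (
    Individual,
    ScenarioBundle,
    age_bin,
    validate_bundle,
)
from .sampler import (
    SharedFactorTable,
    expand_autocorrelated,
    sample_shared,
    sample_unshared,
    unshared_generator,
)

__all__ = [
    "COMPONENTS",
    "RunOptions",
    "DoseRealizationEnsemble",
    "techa_intake",
    "internal_cumulative_dose",
    "chronic_cumulative",
    "techa_external_annual",
    "techa_external_cumulative",
    "eurt_intake",
    "eurt_external_annual",
    "household_ratios",
    "xi_scaling",
    "run_ensemble",
]

COMPONENTS = ("techa_internal", "techa_external", "eurt_internal", "eurt_external")

#: Baseline GSD of the unshared error on a measurement-based individual
#: intake ratio; reduced as 1/sqrt(number of body-burden measurements).
IMR_BASE_GSD = 1.5


@dataclass
class RunOptions:
    shared: bool = True
    unshared: bool = True
    imr_base_gsd: float = IMR_BASE_GSD
    validate: bool = True


# ----------------------------------------------------------------------
# Scalar equation-level operations (deterministic unless factors given)
# ----------------------------------------------------------------------

def techa_intake(
    bundle: ScenarioBundle,
    individual: Individual,
    nuclide: str,
    year: int,
    xi: float = 1.0,
    factors: Optional[dict] = None,
) -> float:
    """Annual riverside ingestion intake (Bq) of one nuclide.

    The product of the reference intake, the settlement ratio, the
    child-to-adult age ratio, the individual scaling factor and the
    nuclide-to-90Sr ratio, residence-weighted over in-year moves.  An
    optional ``factors`` mapping supplies multiplier overrides keyed by
    symbol (default 1 for each).
    """
    f = factors or {}
    iref = float(bundle.intake.i_ref.get(year, 0.0))
    if iref == 0.0:
        return 0.0
    tau = year - individual.birth_year
    if tau < 0:
        return 0.0
    ab = int(age_bin(tau))
    alpha = float(bundle.intake.alpha[ab])
    total = 0.0
    for sid, w, _m in individual.residence_weights(year):
        s = bundle.settlements[sid]
        if s.kind != "techa":
            continue
        rr = bundle.intake.r_ratio.get((nuclide, sid), 0.0)
        total += (
            w
            * iref * f.get("I_ref", 1.0)
            * s.f_ratio
            * alpha * f.get("alpha", 1.0)
            * xi
            * rr * f.get("R_ratio", 1.0)
        )
    return total


def chronic_cumulative(
    intakes: np.ndarray, kernel: np.ndarray, age_bins: np.ndarray
) -> np.ndarray:
    """Cumulative chronic-intake dose series.

    ``D[y] = sum_{t <= y} I[t] * K[y - t, age_bins[t]]`` where ``K`` is a
    cumulative kernel over (lag, age-at-intake bin).  ``intakes`` may carry
    trailing axes (e.g. realizations); the kernel column is broadcast.
    Lags beyond the kernel horizon hold the last value (no further accrual).
    """
    intakes = np.asarray(intakes, dtype=float)
    n_years = intakes.shape[0]
    out = np.zeros_like(intakes)
    n_lag = kernel.shape[0]
    for t in range(n_years):
        it = intakes[t]
        if np.all(it == 0):
            continue
        col = kernel[:, age_bins[t]]
        need = n_years - t
        if need > n_lag:
            col = np.concatenate([col, np.full(need - n_lag, col[-1])])
        else:
            col = col[:need]
        out[t:] += it * col.reshape((need,) + (1,) * (intakes.ndim - 1))
    return out


def internal_cumulative_dose(
    intake_series: dict[int, float] | pd.Series,
    dose_coeff,
    organ: str,
    nuclide: str,
    year: int,
    birth_year: int = 0,
) -> float:
    """Cumulative internal dose (Gy) at ``year`` from one nuclide's intakes.

    Sums single-intake contributions ``I(t) * DF(year - t, age(t))`` over
    all intake years up to ``year``.
    """
    if isinstance(intake_series, pd.Series):
        intake_series = {int(y): float(v) for y, v in intake_series.items()}
    total = 0.0
    for t, activity in sorted(intake_series.items()):
        if t > year:
            continue
        if activity < 0:
            raise ValueError("negative intake")
        ab = int(age_bin(t - birth_year))
        total += activity * float(dose_coeff.value(nuclide, organ, year - t, ab))
    return total


def techa_external_annual(
    bundle: ScenarioBundle,
    individual: Individual,
    organ: str,
    year: int,
    factors: Optional[dict] = None,
) -> float:
    """Annual riverside external organ dose (Gy), residence-weighted.

    ``A_o * D_riv * [T1 + R_outriv * T2 + R_inout * T3]`` with the
    behavioral fractions taken at the person's age in ``year``.
    """
    f = factors or {}
    tau = year - individual.birth_year
    if tau < 0:
        return 0.0
    ab = int(age_bin(tau))
    beh = bundle.behavior
    t1 = float(beh.t1[ab]) * f.get("T1", 1.0)
    t3 = float(beh.t3[ab]) * f.get("T3", 1.0)
    t1, t2, t3 = _adjust_fractions(t1, t3)
    a_o = beh.a_o[organ] * f.get("A_o", 1.0)
    total = 0.0
    for sid, w, _m in individual.residence_weights(year):
        s = bundle.settlements[sid]
        series = bundle.d_riv.get(sid)
        if s.kind != "techa" or series is None:
            continue
        d_riv = float(series.get(year, 0.0)) * f.get("D_riv", 1.0)
        bracket = (
            t1
            + s.r_outriv_mean * f.get("R_outriv", 1.0) * t2
            + beh.r_inout_mean * f.get("R_inout", 1.0) * t3
        )
        total += w * a_o * d_riv * bracket
    return total


def techa_external_cumulative(annual: Sequence[float]) -> np.ndarray:
    """Running sum of annual external doses (prefix sums)."""
    return np.cumsum(np.asarray(annual, dtype=float))


def eurt_intake(
    bundle: ScenarioBundle,
    individual: Individual,
    nuclide: str,
    year: int,
    factors: Optional[dict] = None,
) -> float:
    """Annual fallout-trace ingestion intake (Bq): deposition x conversion.

    Residence-weighted over fallout-trace villages; zero once the person
    has moved to clean territory.
    """
    f = factors or {}
    tau = year - individual.birth_year
    if tau < 0:
        return 0.0
    ab = int(age_bin(tau))
    ys = year - int(math.floor(bundle.accident_date))
    arr = bundle.intake.e_conv.get(nuclide)
    if arr is None or ys < 0 or ys >= arr.shape[0]:
        return 0.0
    e_r = float(arr[ys, ab]) * f.get("E_conv", 1.0)
    total = 0.0
    for sid, w, _m in individual.residence_weights(year):
        s = bundle.settlements[sid]
        if s.kind != "eurt" or s.g_sr90 <= 0:
            continue
        total += w * s.g_sr90 * f.get("G_sr90", 1.0) * e_r * f.get("I_E", 1.0)
    return total


def eurt_external_annual(
    bundle: ScenarioBundle,
    individual: Individual,
    organ: str,
    year: int,
    factors: Optional[dict] = None,
) -> float:
    """Annual fallout-trace external organ dose (Gy).

    ``G * A_o * D_norm(y) * [(1 - T3) + T3 * R_inout]`` with the monthly
    normalized dose-rate table aggregated to the calendar year.
    """
    f = factors or {}
    tau = year - individual.birth_year
    if tau < 0:
        return 0.0
    ab = int(age_bin(tau))
    beh = bundle.behavior
    t1 = float(beh.t1[ab]) * f.get("T1", 1.0)
    t3 = float(beh.t3[ab]) * f.get("T3", 1.0)
    _t1, _t2, t3 = _adjust_fractions(t1, t3)
    a_o = beh.a_o[organ] * f.get("A_o", 1.0)
    d_norm = sum(
        d * (f.get("D_sr90", 1.0) if m >= 0 else 1.0)
        for m, d in bundle.d_sr90_annual(year)
    )
    bracket = (1.0 - t3) + t3 * beh.r_inout_mean * f.get("R_inout", 1.0)
    total = 0.0
    for sid, w, _m in individual.residence_weights(year):
        s = bundle.settlements[sid]
        if s.kind != "eurt" or s.g_sr90 <= 0:
            continue
        total += w * s.g_sr90 * f.get("G_sr90", 1.0) * a_o * d_norm * bracket
    return total


def _adjust_fractions(t1: float | np.ndarray, t3: float | np.ndarray):
    """T2 = 1 - T1 - T3 after perturbation; rescale T1, T3 if they overrun."""
    t1 = np.asarray(t1, dtype=float)
    t3 = np.asarray(t3, dtype=float)
    s = t1 + t3
    over = s > 1.0
    scale = np.where(over, np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 1.0), 1.0)
    t1 = t1 * scale
    t3 = t3 * scale
    t2 = np.clip(1.0 - t1 - t3, 0.0, None)
    if t1.ndim == 0:
        return float(t1), float(t2), float(t3)
    return t1, t2, t3


# ----------------------------------------------------------------------
# Individualization
# ----------------------------------------------------------------------

def household_ratios(cohort: Sequence[Individual]) -> dict[str, float]:
    """Arithmetic mean of household members' measured-to-model ratios."""
    acc: dict[str, list[float]] = {}
    for ind in cohort:
        if ind.imr is not None and ind.imr > 0:
            acc.setdefault(ind.household_id, []).append(ind.imr)
    return {h: float(np.mean(v)) for h, v in acc.items()}


def xi_scaling(
    individual: Individual, household_imrs: Optional[dict[str, float]] = None
) -> float:
    """Deterministic individual intake scaling factor.

    ``imr`` mode inverts the person's own measured-to-model ratio; ``hsr``
    inverts the household average of member ratios; ``none`` leaves the
    village-average model prediction unscaled.
    """
    if individual.xi_mode == "none":
        return 1.0
    if individual.xi_mode == "imr":
        if individual.imr is None or individual.imr <= 0:
            raise ValueError(f"{individual.id}: imr mode without a measurement")
        return 1.0 / individual.imr
    if individual.xi_mode == "hsr":
        hh = (household_imrs or {}).get(individual.household_id)
        if hh is None:
            raise ValueError(
                f"{individual.id}: hsr mode but household "
                f"{individual.household_id} has no measured members"
            )
        return 1.0 / hh
    raise ValueError(f"unknown xi_mode {individual.xi_mode!r}")


# ----------------------------------------------------------------------
# Ensemble container
# ----------------------------------------------------------------------

@dataclass
class DoseRealizationEnsemble:
    """Annual organ doses (Gy): individuals x years x organs x 4 x realizations."""

    doses: np.ndarray
    individual_ids: list[str]
    years: np.ndarray
    organs: tuple[str, ...]
    seed: int
    components: tuple[str, ...] = COMPONENTS
    meta: dict = field(default_factory=dict)

    @property
    def n_realizations(self) -> int:
        return self.doses.shape[-1]

    def index_of(self, individual_id: str) -> int:
        return self.individual_ids.index(individual_id)

    def total(self) -> np.ndarray:
        """Annual total dose: sum over the four components."""
        return self.doses.sum(axis=3)

    def cumulative(self, component: Optional[str] = None) -> np.ndarray:
        if component is None:
            arr = self.total()
        else:
            arr = self.doses[:, :, :, self.components.index(component), :]
        return np.cumsum(arr, axis=1)

    def final_dose(self, organ: str, components: Optional[Sequence[str]] = None) -> np.ndarray:
        """Total dose at end of follow-up: (individuals, realizations)."""
        oi = self.organs.index(organ)
        if components is None:
            arr = self.total()[:, :, oi, :]
        else:
            idx = [self.components.index(c) for c in components]
            arr = self.doses[:, :, oi, idx, :].sum(axis=2)
        return arr.sum(axis=1)

    def to_long_dataframe(self) -> pd.DataFrame:
        ids, years, organs, comps, reals = np.meshgrid(
            np.arange(len(self.individual_ids)),
            self.years,
            np.arange(len(self.organs)),
            np.arange(len(self.components)),
            np.arange(self.n_realizations),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "individual_id": np.asarray(self.individual_ids)[ids.ravel()],
                "year": years.ravel(),
                "organ": np.asarray(self.organs)[organs.ravel()],
                "component": np.asarray(self.components)[comps.ravel()],
                "realization": reals.ravel(),
                "dose_gy": self.doses.ravel(),
            }
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(d / "doses.npz", doses=self.doses, years=self.years)
        with open(d / "ensemble.json", "w") as fh:
            json.dump(
                {
                    "individual_ids": self.individual_ids,
                    "organs": list(self.organs),
                    "components": list(self.components),
                    "seed": self.seed,
                    "meta": self.meta,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, directory) -> "DoseRealizationEnsemble":
        d = Path(directory)
        arrs = np.load(d / "doses.npz")
        with open(d / "ensemble.json") as fh:
            meta = json.load(fh)
        return cls(
            doses=arrs["doses"],
            individual_ids=list(meta["individual_ids"]),
            years=arrs["years"],
            organs=tuple(meta["organs"]),
            seed=meta["seed"],
            components=tuple(meta["components"]),
            meta=meta.get("meta", {}),
        )


# ----------------------------------------------------------------------
# The two-step Monte-Carlo runner
# ----------------------------------------------------------------------

def _check_dimensions(bundle: ScenarioBundle) -> None:
    dim = bundle.registry.dimensioning
    checks = [
        ("n_techa_settlements", dim.n_techa_settlements, len(bundle.techa_settlements())),
        ("n_eurt_villages", dim.n_eurt_villages, len(bundle.eurt_settlements())),
        ("n_nuclides", dim.n_nuclides, len(bundle.nuclides)),
        ("n_eurt_nuclides", dim.n_eurt_nuclides, len(bundle.eurt_nuclides)),
        ("n_organs", dim.n_organs, len(bundle.organs)),
        ("n_time_slices", dim.n_time_slices, len(bundle.intake.i_ref)),
        ("n_months", dim.n_months, len(bundle.d_sr90_monthly)),
    ]
    bad = [f"{name}: registry {a} != scenario {b}" for name, a, b in checks if a != b]
    if bad:
        raise ValueError("registry/scenario dimensioning mismatch: " + "; ".join(bad))


def _shared_arrays(
    bundle: ScenarioBundle, table: SharedFactorTable, n_years: int
) -> dict[str, np.ndarray]:
    """Resolve shared factor arrays, expanding AR(1)-scoped families."""
    reg = bundle.registry
    out: dict[str, np.ndarray] = {}
    for sym in ("I_ref", "alpha", "R_ratio", "I_E", "D_sr90", "G_sr90"):
        if reg.has(sym) and sym in table.factors:
            out[sym] = table.factors[sym]
    from .bundle import N_AGE_BINS

    if reg.has("DF") and "DF" in table.factors:
        out["DF"] = expand_autocorrelated(table, reg.get("DF"), N_AGE_BINS)
    if reg.has("A_o") and "A_o" in table.factors:
        out["A_o"] = expand_autocorrelated(table, reg.get("A_o"), N_AGE_BINS)
    if reg.has("D_riv") and "D_riv" in table.factors:
        out["D_riv"] = expand_autocorrelated(table, reg.get("D_riv"), n_years)
    return out


def _unshared_arrays(
    bundle: ScenarioBundle,
    individual: Individual,
    n_real: int,
    seed: int,
    options: RunOptions,
) -> dict[str, np.ndarray]:
    """Stack per-realization unshared factor maps into arrays (..., n_real)."""
    reg = bundle.registry
    if not options.unshared:
        ones: dict[str, np.ndarray] = {}
        for p in reg:
            if p.unshared is None:
                continue
            shape = list(p.unshared.shape or (1,))
            names = [n for n, _ in p.unshared.index_dims] or ["one"]
            if "moves" in names:
                shape[names.index("moves")] = individual.n_moves
            ones[p.symbol] = np.ones(tuple(shape) + (n_real,))
        ones["R_outriv_by_settlement"] = np.ones(
            (len(bundle.techa_settlements()) or 1, n_real)
        )
        return ones

    maps = [
        sample_unshared(reg, individual, k, seed, nuclide_names=bundle.nuclides)
        for k in range(n_real)
    ]
    out = {
        sym: np.stack([m[sym] for m in maps], axis=-1) for sym in maps[0]
    }
    # Residence-to-riverbank ratio: the multiplier range is village specific
    # (LogUniform between the village's min and max relative to its mean)
    techa = bundle.techa_settlements()
    rout = np.ones((len(techa) or 1, n_real))
    lived = {
        bundle.settlements[rec.settlement_id].index
        for rec in individual.residence_history
        if bundle.settlements[rec.settlement_id].kind == "techa"
    }
    for s in techa:
        if s.index not in lived or s.r_outriv_mean <= 0:
            continue
        lo = s.r_outriv_min / s.r_outriv_mean
        hi = s.r_outriv_max / s.r_outriv_mean
        if hi <= lo:
            continue
        for k in range(n_real):
            rng = unshared_generator(seed, individual.id, k, "R_outriv", extra=(s.index,))
            rout[s.index, k] = lo * (hi / lo) ** rng.uniform()
    out["R_outriv_by_settlement"] = rout
    return out


def _xi_vector(
    individual: Individual,
    household_imrs: dict[str, float],
    household_counts: dict[str, int],
    n_real: int,
    seed: int,
    options: RunOptions,
) -> np.ndarray:
    """Individual intake scaling factor per realization (with unshared error).

    The error on a measurement-based ratio shrinks as 1/sqrt(number of
    body-burden measurements); a household-average ratio carries an error
    shared within the household (same draw for every unmeasured member),
    shrinking with the number of measured members.
    """
    base = xi_scaling(individual, household_imrs)
    if individual.xi_mode == "none" or not options.unshared:
        return np.full(n_real, base)
    if individual.xi_mode == "imr":
        n = max(individual.n_measurements, 1)
        key = individual.id
    else:  # hsr: error shared within the household
        n = max(household_counts.get(individual.household_id, 1), 1)
        key = individual.household_id
    sigma = math.log(options.imr_base_gsd) / math.sqrt(n)
    out = np.empty(n_real)
    for k in range(n_real):
        z = unshared_generator(seed, key, k, "xi").standard_normal()
        out[k] = base * math.exp(sigma * z)
    return out


def run_ensemble(
    bundle: ScenarioBundle,
    n_realizations: int,
    seed: int,
    options: RunOptions | None = None,
) -> DoseRealizationEnsemble:
    """Two-step Monte-Carlo evaluation of the whole cohort.

    Step 1 draws the Latin-hypercube table of shared factors (one vector
    per realization); step 2 perturbs each person's evaluation with their
    unshared factors.  Deterministic under a fixed seed.
    """
    options = options or RunOptions()
    if options.validate:
        report = validate_bundle(bundle)
        if report:
            raise ValueError("invalid bundle: " + "; ".join(report[:10]))
    _check_dimensions(bundle)
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")

    years = bundle.years
    n_years = len(years)
    organs = bundle.organs
    n_org = len(organs)
    nuclides = bundle.nuclides
    eurt_nuclides = bundle.eurt_nuclides
    n_real = int(n_realizations)

    if options.shared:
        table = sample_shared(bundle.registry, n_real, seed)
    else:
        from .sampler import ones_shared

        table = ones_shared(bundle.registry, n_real, seed)
    sh = _shared_arrays(bundle, table, n_years)
    hh_imrs = household_ratios(bundle.cohort)
    hh_counts: dict[str, int] = {}
    for _ind in bundle.cohort:
        if _ind.imr is not None and _ind.imr > 0:
            hh_counts[_ind.household_id] = hh_counts.get(_ind.household_id, 0) + 1
    kernels = bundle.dose_coeff

    year0 = int(bundle.intake.i_ref.index[0])
    n_slices = len(bundle.intake.i_ref)
    iref_vals = np.array(
        [float(bundle.intake.i_ref.get(int(y), 0.0)) for y in years]
    )
    acc_year = int(math.floor(bundle.accident_date))

    doses = np.zeros((len(bundle.cohort), n_years, n_org, 4, n_real))
    ids = [ind.id for ind in bundle.cohort]

    for ii, ind in enumerate(bundle.cohort):
        un = _unshared_arrays(bundle, ind, n_real, seed, options)
        xi = _xi_vector(ind, hh_imrs, hh_counts, n_real, seed, options)
        ages = years - ind.birth_year
        alive = ages >= 0
        abins = age_bin(np.clip(ages, 0, None))

        res = [ind.residence_weights(int(y)) if alive[yi] else []
               for yi, y in enumerate(years)]

        # ---- behavioral fractions per year (vectorized over realizations)
        t1m = un["T1"][0] if "T1" in un else np.ones(n_real)
        t3m = un["T3"][0] if "T3" in un else np.ones(n_real)
        t1 = bundle.behavior.t1[abins][:, None] * t1m[None, :]
        t3 = bundle.behavior.t3[abins][:, None] * t3m[None, :]
        t1, t2, t3 = _adjust_fractions(t1, t3)

        ao_unsh = un["A_o"][0] if "A_o" in un else np.ones(n_real)

        # ---- riverside intake: (n_nuclides, n_years, n_real)
        techa_I = np.zeros((len(nuclides), n_years, n_real))
        for yi, y in enumerate(years):
            if not alive[yi] or iref_vals[yi] == 0.0:
                continue
            sl = min(max(int(y) - year0, 0), n_slices - 1)
            iref_m = un["I_ref"][sl] if "I_ref" in un else 1.0
            al_m_sh = sh["alpha"][abins[yi]] if "alpha" in sh else 1.0
            al_m_un = un["alpha"][abins[yi]] if "alpha" in un else 1.0
            base_y = (
                iref_vals[yi]
                * float(bundle.intake.alpha[abins[yi]])
                * al_m_sh * al_m_un * iref_m * xi
            )
            for sid, w, _m in res[yi]:
                s = bundle.settlements[sid]
                if s.kind != "techa":
                    continue
                iref_sh = sh["I_ref"][s.index] if "I_ref" in sh else 1.0
                for ri, nuc in enumerate(nuclides):
                    rr = bundle.intake.r_ratio.get((nuc, sid), 0.0)
                    if rr == 0.0:
                        continue
                    rr_sh = sh["R_ratio"][ri, s.index] if "R_ratio" in sh else 1.0
                    techa_I[ri, yi] += w * base_y * s.f_ratio * iref_sh * rr * rr_sh

        # ---- fallout-trace intake: (n_eurt_nuclides, n_years, n_real)
        eurt_I = np.zeros((len(eurt_nuclides), n_years, n_real))
        for yi, y in enumerate(years):
            if not alive[yi]:
                continue
            ys = int(y) - acc_year
            for sid, w, m in res[yi]:
                s = bundle.settlements[sid]
                if s.kind != "eurt" or s.g_sr90 <= 0:
                    continue
                g_sh = sh["G_sr90"][s.index] if "G_sr90" in sh else 1.0
                g_un = un["G_sr90"][min(m, un["G_sr90"].shape[0] - 1)] if "G_sr90" in un else 1.0
                ie_un = un["I_E"][min(m, un["I_E"].shape[0] - 1)] if "I_E" in un else 1.0
                for ri, nuc in enumerate(eurt_nuclides):
                    arr = bundle.intake.e_conv.get(nuc)
                    if arr is None or ys < 0 or ys >= arr.shape[0]:
                        continue
                    e_r = float(arr[ys, abins[yi]])
                    if e_r == 0.0:
                        continue
                    ie_sh = sh["I_E"][ri, s.index] if "I_E" in sh else 1.0
                    eurt_I[ri, yi] += w * s.g_sr90 * g_sh * g_un * e_r * ie_sh * ie_un

        # ---- internal doses via the chronic kernel, per organ
        df_sh = sh.get("DF")  # (n_nuc, n_org, n_age, n_real)
        df_un = un.get("DF")  # (n_nuc, n_org, n_real)
        for oi, organ in enumerate(organs):
            for comp_idx, (nuc_list, I) in enumerate(
                [(nuclides, techa_I), (eurt_nuclides, eurt_I)]
            ):
                dcum = np.zeros((n_years, n_real))
                for ri, nuc in enumerate(nuc_list):
                    gnuc = nuclides.index(nuc)
                    if np.all(I[ri] == 0):
                        continue
                    kern = kernels.kernels[(nuc, organ)]
                    msh = df_sh[gnuc, oi] if df_sh is not None else None
                    mun = df_un[gnuc, oi] if df_un is not None else 1.0
                    for t in range(n_years):
                        it = I[ri, t]
                        if np.all(it == 0):
                            continue
                        mult = (msh[abins[t]] if msh is not None else 1.0) * mun
                        col = kern[:, abins[t]]
                        need = n_years - t
                        if need > col.shape[0]:
                            col = np.concatenate(
                                [col, np.full(need - col.shape[0], col[-1])]
                            )
                        else:
                            col = col[:need]
                        dcum[t:] += (it * mult) * col[:, None]
                annual = np.diff(dcum, axis=0, prepend=0.0)
                doses[ii, :, oi, 0 if comp_idx == 0 else 2, :] = annual

        # ---- riverside external
        ao_sh = sh.get("A_o")  # (n_org, n_age, n_real)
        driv_sh = sh.get("D_riv")  # (n_set, n_years, n_real)
        rout_un = un.get("R_outriv_by_settlement")
        rin_un = un.get("R_inout")
        for yi, y in enumerate(years):
            if not alive[yi]:
                continue
            for sid, w, m in res[yi]:
                s = bundle.settlements[sid]
                series = bundle.d_riv.get(sid)
                if s.kind != "techa" or series is None:
                    continue
                driv = float(series.get(int(y), 0.0))
                if driv == 0.0:
                    continue
                driv_m = driv_sh[s.index, yi] if driv_sh is not None else 1.0
                rout = s.r_outriv_mean * (
                    rout_un[s.index] if rout_un is not None else 1.0
                )
                rin = bundle.behavior.r_inout_mean * (
                    rin_un[min(m, rin_un.shape[0] - 1)] if rin_un is not None else 1.0
                )
                bracket = t1[yi] + rout * t2[yi] + rin * t3[yi]
                for oi, organ in enumerate(organs):
                    ao = bundle.behavior.a_o[organ] * ao_unsh * (
                        ao_sh[oi, abins[yi]] if ao_sh is not None else 1.0
                    )
                    doses[ii, yi, oi, 1, :] += w * ao * driv * driv_m * bracket

        # ---- fallout-trace external
        d90_sh = sh.get("D_sr90")  # (n_months, n_real)
        for yi, y in enumerate(years):
            if not alive[yi]:
                continue
            entries = bundle.d_sr90_annual(int(y))
            if not entries:
                continue
            d_norm = np.zeros(n_real)
            for mth, dval in entries:
                if mth >= 0 and d90_sh is not None:
                    d_norm += dval * d90_sh[mth]
                else:
                    d_norm += dval
            for sid, w, m in res[yi]:
                s = bundle.settlements[sid]
                if s.kind != "eurt" or s.g_sr90 <= 0:
                    continue
                g_sh = sh["G_sr90"][s.index] if "G_sr90" in sh else 1.0
                rin = bundle.behavior.r_inout_mean * (
                    rin_un[min(m, rin_un.shape[0] - 1)] if rin_un is not None else 1.0
                )
                bracket = (1.0 - t3[yi]) + t3[yi] * rin
                for oi, organ in enumerate(organs):
                    ao = bundle.behavior.a_o[organ] * ao_unsh * (
                        ao_sh[oi, abins[yi]] if ao_sh is not None else 1.0
                    )
                    doses[ii, yi, oi, 3, :] += w * s.g_sr90 * g_sh * ao * d_norm * bracket

    return DoseRealizationEnsemble(
        doses=doses,
        individual_ids=ids,
        years=years,
        organs=tuple(organs),
        seed=int(seed),
        meta={
            "n_realizations": n_real,
            "shared": options.shared,
            "unshared": options.unshared,
        },
    )
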