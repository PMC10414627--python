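"""Input containers for the dose engine and their CSV/JSON round-trip.

A scenario bundle collects everything one run needs: the settlement table
(riverside and fallout-trace villages plus clean territories), the intake
model (reference intake series, age ratios, nuclide-to-90Sr ratios,
deposition-to-intake conversions), dose-coefficient kernels, behavioral
factors, the cohort with residence histories, and the parameter registry.
Bundles are written as a directory of plain CSV files with a JSON manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .registry import ParameterRegistry

__all__ = [
    "ResidenceRecord",
    "Individual",
    "Settlement",
    "IntakeModel",
    "DoseCoefficientTable",
    "BehavioralFactors",
    "ScenarioBundle",
    "validate_bundle",
    "N_AGE_BINS",
    "ORGANS_23",
]

#: Ages 0..9 have child-specific factors; ages >= 10 use the adult value.
N_AGE_BINS = 11

#: The full organ list for which annual doses can be computed.
ORGANS_23 = (
    "esophagus", "stomach", "small_intestine", "colon", "rectum", "lungs",
    "breast", "marrow", "bone_surface", "thyroid", "bladder", "liver",
    "spleen", "kidneys", "pancreas", "adrenals", "thymus", "uterus",
    "testes", "ovaries", "brain", "muscle", "skin",
)


def age_bin(age) -> np.ndarray:
    """Map integer age to the 0..10 age-group index (10 = adult)."""
    return np.clip(np.asarray(age, dtype=int), 0, N_AGE_BINS - 1)


@dataclass(frozen=True)
class ResidenceRecord:
    settlement_id: str
    start: float  # decimal year, inclusive
    end: float    # decimal year, exclusive

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"residence interval must satisfy start < end, got [{self.start}, {self.end})"
            )


@dataclass
class Individual:
    id: str
    birth_year: int
    household_id: str
    residence_history: list[ResidenceRecord] = field(default_factory=list)
    xi_mode: str = "none"  # "none" | "imr" | "hsr"
    imr: Optional[float] = None
    n_measurements: int = 0

    @property
    def n_moves(self) -> int:
        return len(self.residence_history)

    def violations(self, move_limit: int = 20) -> list[str]:
        out = []
        if self.n_moves > move_limit:
            out.append(f"{self.id}: {self.n_moves} residence records exceed move limit {move_limit}")
        hist = self.residence_history
        for a, b in zip(hist, hist[1:]):
            if b.start < a.end - 1e-9:
                out.append(
                    f"{self.id}: overlapping/non-chronological residence intervals "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if self.xi_mode not in ("none", "imr", "hsr"):
            out.append(f"{self.id}: unknown xi_mode {self.xi_mode!r}")
        if self.xi_mode == "imr" and (self.imr is None or self.imr <= 0):
            out.append(f"{self.id}: xi_mode=imr requires a positive IMR value")
        return out

    def residence_weights(self, year: int) -> list[tuple[str, float, int]]:
        """(settlement_id, fraction of year, move index) for a calendar year."""
        out = []
        for m, rec in enumerate(self.residence_history):
            frac = max(0.0, min(rec.end, year + 1.0) - max(rec.start, float(year)))
            if frac > 0:
                out.append((rec.settlement_id, frac, m))
        return out


@dataclass
class Settlement:
    id: str
    kind: str  # "techa" | "eurt" | "clean"
    distance_km: float = 0.0
    f_ratio: float = 0.0
    r_outriv_mean: float = 0.0
    r_outriv_min: float = 0.0
    r_outriv_max: float = 0.0
    g_sr90: float = 0.0  # Bq/m2 of 90Sr surface deposition
    evacuation_year: Optional[float] = None
    index: int = -1  # position within its region's registry dimension

    def violations(self) -> list[str]:
        out = []
        if self.kind not in ("techa", "eurt", "clean"):
            out.append(f"{self.id}: unknown kind {self.kind!r}")
        if self.g_sr90 < 0:
            out.append(f"{self.id}: negative deposition")
        if self.kind == "techa" and not (
            self.r_outriv_min <= self.r_outriv_mean <= self.r_outriv_max
        ):
            out.append(f"{self.id}: r_outriv range must satisfy min <= mean <= max")
        return out


@dataclass
class IntakeModel:
    """Mean-value intake tables for the riverside exposure pathway.

    * ``i_ref``: reference-settlement adult 90Sr intake (Bq/yr) by calendar
      year — the time-slice series.
    * ``alpha``: child-to-adult intake ratio for age bins 0..10 (1 at >= 10).
    * ``r_ratio``: nuclide-to-90Sr intake ratio per (nuclide, settlement).
    * ``e_conv``: fallout-trace intake conversion, Bq intake per Bq/m2 of
      deposition, per nuclide as an array over (year since deposition, age bin).
    """

    i_ref: pd.Series
    alpha: np.ndarray
    r_ratio: dict[tuple[str, str], float]
    e_conv: dict[str, np.ndarray]

    def violations(self) -> list[str]:
        out = []
        if (self.i_ref < 0).any():
            out.append("i_ref has negative entries")
        if (np.asarray(self.alpha) < 0).any():
            out.append("alpha has negative entries")
        if abs(float(self.alpha[-1]) - 1.0) > 1e-12:
            out.append("alpha must equal 1 for the adult age bin")
        if any(v < 0 for v in self.r_ratio.values()):
            out.append("r_ratio has negative entries")
        for nuc, arr in self.e_conv.items():
            if (np.asarray(arr) < 0).any():
                out.append(f"e_conv[{nuc}] has negative entries")
        return out


class DoseCoefficientTable:
    """Cumulative dose-coefficient kernels DF(lag, age at intake), Gy/Bq.

    ``kernels[(nuclide, organ)]`` is a 2-D array over (years since intake,
    age-at-intake bin).  Kernels are cumulative-to-date: nondecreasing in
    lag.  Lags beyond the table horizon extrapolate flat (no further
    accrual) with a warning.
    """

    def __init__(self, kernels: dict[tuple[str, str], np.ndarray]):
        self.kernels = {k: np.asarray(v, dtype=float) for k, v in kernels.items()}
        self._warned: set[tuple[str, str]] = set()

    @property
    def n_lags(self) -> int:
        return max(v.shape[0] for v in self.kernels.values())

    def value(self, nuclide: str, organ: str, lag, age_b) -> np.ndarray:
        kern = self.kernels[(nuclide, organ)]
        lag = np.asarray(lag, dtype=int)
        if np.any(lag >= kern.shape[0]) and (nuclide, organ) not in self._warned:
            warnings.warn(
                f"lag beyond dose-coefficient horizon for ({nuclide}, {organ}); "
                "extrapolating the cumulative value flat",
                stacklevel=2,
            )
            self._warned.add((nuclide, organ))
        lag = np.clip(lag, 0, kern.shape[0] - 1)
        return kern[lag, age_b]

    def column(self, nuclide: str, organ: str, age_b: int, n_lags: int) -> np.ndarray:
        """Cumulative kernel over lags 0..n_lags-1 at one age bin, flat beyond horizon."""
        kern = self.kernels[(nuclide, organ)]
        col = kern[:, age_b]
        if n_lags <= col.shape[0]:
            return col[:n_lags]
        return np.concatenate([col, np.full(n_lags - col.shape[0], col[-1])])

    def violations(self) -> list[str]:
        out = []
        for (nuc, org), kern in self.kernels.items():
            if (kern < 0).any():
                out.append(f"DF[{nuc},{org}] has negative entries")
            if (np.diff(kern, axis=0) < -1e-15).any():
                out.append(f"DF[{nuc},{org}] is not nondecreasing in lag")
        return out


@dataclass
class BehavioralFactors:
    """Age-dependent behavioral fractions and external conversion factors.

    ``t1``/``t3`` are mean fractions of the year on the riverbank / indoors
    per age bin; the outdoors-elsewhere fraction T2 is derived as
    1 - T1 - T3 after the error multipliers are applied.  ``a_o`` is the
    mean air-to-organ conversion factor per organ and ``r_inout_mean`` the
    mean indoor-to-outdoor dose-rate ratio.
    """

    t1: np.ndarray
    t3: np.ndarray
    a_o: dict[str, float]
    r_inout_mean: float = 1.0

    def violations(self) -> list[str]:
        out = []
        if (self.t1 < 0).any() or (self.t3 < 0).any():
            out.append("behavioral fractions must be nonnegative")
        if ((self.t1 + self.t3) > 1 + 1e-12).any():
            out.append("mean T1 + T3 exceeds 1 for some age bin")
        if any(v <= 0 for v in self.a_o.values()):
            out.append("a_o values must be positive")
        if self.r_inout_mean <= 0:
            out.append("r_inout_mean must be positive")
        return out


@dataclass
class ScenarioBundle:
    settlements: dict[str, Settlement]
    intake: IntakeModel
    dose_coeff: DoseCoefficientTable
    behavior: BehavioralFactors
    cohort: list[Individual]
    registry: ParameterRegistry
    nuclides: tuple[str, ...]
    eurt_nuclides: tuple[str, ...]
    organs: tuple[str, ...]
    start_year: int
    end_year: int
    accident_date: float  # decimal year of the fallout deposition event
    d_riv: dict[str, pd.Series]  # settlement -> Gy/yr by calendar year
    d_sr90_monthly: np.ndarray   # Gy per Bq/m2 delivered per month since deposition
    d_sr90_tail: np.ndarray      # Gy per Bq/m2 per year beyond the monthly table
    seed: Optional[int] = None

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def techa_settlements(self) -> list[Settlement]:
        return [s for s in self.settlements.values() if s.kind == "techa"]

    def eurt_settlements(self) -> list[Settlement]:
        return [s for s in self.settlements.values() if s.kind == "eurt"]

    # ------------------------------------------------------------------
    def d_sr90_annual(self, year: int) -> list[tuple[int, float]]:
        """(month index or -year_since, normalized dose) entries in a year.

        Entries with a nonnegative first element are monthly-table months
        (each carries its own shared multiplier); entries with index
        ``-year_since`` come from the deterministic annual tail.
        """
        out = []
        for m, d in enumerate(self.d_sr90_monthly):
            t0 = self.accident_date + m / 12.0
            if year <= t0 < year + 1:
                out.append((m, float(d)))
        tail_start = self.accident_date + len(self.d_sr90_monthly) / 12.0
        for ys, d in enumerate(self.d_sr90_tail):
            t0 = tail_start + ys
            if year <= t0 < year + 1:
                out.append((-(ys + 1), float(d)))
        return out

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "settlement_id": s.id, "kind": s.kind,
                "distance_km": s.distance_km, "f_ratio": s.f_ratio,
                "r_outriv_mean": s.r_outriv_mean, "r_outriv_min": s.r_outriv_min,
                "r_outriv_max": s.r_outriv_max, "g_sr90": s.g_sr90,
                "evacuation_year": "" if s.evacuation_year is None else s.evacuation_year,
                "index": s.index,
            }
            for s in self.settlements.values()
        ]
        pd.DataFrame(rows).to_csv(d / "settlements.csv", index=False)
        self.i_ref_frame().to_csv(d / "i_ref.csv", index=False)
        pd.DataFrame(
            {"age": np.arange(N_AGE_BINS), "ratio": self.intake.alpha}
        ).to_csv(d / "alpha.csv", index=False)
        pd.DataFrame(
            [
                {"nuclide": n, "settlement_id": s, "ratio": v}
                for (n, s), v in self.intake.r_ratio.items()
            ]
        ).to_csv(d / "r_ratio.csv", index=False)
        econv_rows = []
        for nuc, arr in self.intake.e_conv.items():
            for ys in range(arr.shape[0]):
                for a in range(arr.shape[1]):
                    econv_rows.append(
                        {"nuclide": nuc, "year_since": ys, "age": a, "bq_per_bq_m2": arr[ys, a]}
                    )
        pd.DataFrame(econv_rows).to_csv(d / "e_conv.csv", index=False)
        df_rows = []
        for (nuc, org), kern in self.dose_coeff.kernels.items():
            for lag in range(kern.shape[0]):
                for a in range(kern.shape[1]):
                    df_rows.append(
                        {"nuclide": nuc, "organ": org, "lag": lag, "age": a,
                         "gy_per_bq": kern[lag, a]}
                    )
        pd.DataFrame(df_rows).to_csv(d / "dose_coeff.csv", index=False)
        pd.DataFrame(
            {"age": np.arange(N_AGE_BINS), "t1": self.behavior.t1, "t3": self.behavior.t3}
        ).to_csv(d / "behavior.csv", index=False)
        pd.DataFrame(
            [{"organ": o, "a_o": v} for o, v in self.behavior.a_o.items()]
        ).to_csv(d / "a_o.csv", index=False)
        driv_rows = [
            {"settlement_id": sid, "year": int(y), "gy_per_yr": v}
            for sid, series in self.d_riv.items()
            for y, v in series.items()
        ]
        pd.DataFrame(driv_rows).to_csv(d / "d_riv.csv", index=False)
        pd.DataFrame(
            {"month": np.arange(len(self.d_sr90_monthly)),
             "gy_per_bq_m2": self.d_sr90_monthly}
        ).to_csv(d / "d_sr90.csv", index=False)
        pd.DataFrame(
            {"year_since": np.arange(len(self.d_sr90_tail)),
             "gy_per_bq_m2": self.d_sr90_tail}
        ).to_csv(d / "d_sr90_tail.csv", index=False)
        cohort_rows = []
        for ind in self.cohort:
            for rec in ind.residence_history:
                cohort_rows.append(
                    {
                        "individual_id": ind.id, "birth_year": ind.birth_year,
                        "household_id": ind.household_id, "xi_mode": ind.xi_mode,
                        "imr": "" if ind.imr is None else ind.imr,
                        "n_measurements": ind.n_measurements,
                        "settlement_id": rec.settlement_id,
                        "start": rec.start, "end": rec.end,
                    }
                )
        pd.DataFrame(cohort_rows).to_csv(d / "cohort.csv", index=False)
        self.registry.to_json(d / "registry.json")
        manifest = {
            "schema_version": 1,
            "seed": self.seed,
            "nuclides": list(self.nuclides),
            "eurt_nuclides": list(self.eurt_nuclides),
            "organs": list(self.organs),
            "start_year": self.start_year,
            "end_year": self.end_year,
            "accident_date": self.accident_date,
            "r_inout_mean": self.behavior.r_inout_mean,
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    def i_ref_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.intake.i_ref.index.astype(int),
             "intake_bq": self.intake.i_ref.values}
        )

    @classmethod
    def load(cls, directory) -> "ScenarioBundle":
        d = Path(directory)
        with open(d / "manifest.json") as fh:
            man = json.load(fh)
        st = pd.read_csv(d / "settlements.csv")
        settlements = {}
        for _, r in st.iterrows():
            ev = r["evacuation_year"]
            settlements[str(r["settlement_id"])] = Settlement(
                id=str(r["settlement_id"]), kind=r["kind"],
                distance_km=float(r["distance_km"]), f_ratio=float(r["f_ratio"]),
                r_outriv_mean=float(r["r_outriv_mean"]),
                r_outriv_min=float(r["r_outriv_min"]),
                r_outriv_max=float(r["r_outriv_max"]),
                g_sr90=float(r["g_sr90"]),
                evacuation_year=None if pd.isna(ev) or ev == "" else float(ev),
                index=int(r["index"]),
            )
        iref = pd.read_csv(d / "i_ref.csv")
        i_ref = pd.Series(iref["intake_bq"].values, index=iref["year"].values)
        alpha = pd.read_csv(d / "alpha.csv").sort_values("age")["ratio"].to_numpy()
        rr = pd.read_csv(d / "r_ratio.csv")
        r_ratio = {
            (r["nuclide"], str(r["settlement_id"])): float(r["ratio"])
            for _, r in rr.iterrows()
        }
        ec = pd.read_csv(d / "e_conv.csv")
        e_conv = {}
        for nuc, grp in ec.groupby("nuclide"):
            n_ys = grp["year_since"].max() + 1
            arr = np.zeros((n_ys, N_AGE_BINS))
            arr[grp["year_since"].to_numpy(), grp["age"].to_numpy()] = grp[
                "bq_per_bq_m2"
            ].to_numpy()
            e_conv[nuc] = arr
        dfk = pd.read_csv(d / "dose_coeff.csv")
        kernels = {}
        for (nuc, org), grp in dfk.groupby(["nuclide", "organ"]):
            n_lag = grp["lag"].max() + 1
            arr = np.zeros((n_lag, N_AGE_BINS))
            arr[grp["lag"].to_numpy(), grp["age"].to_numpy()] = grp["gy_per_bq"].to_numpy()
            kernels[(nuc, org)] = arr
        beh = pd.read_csv(d / "behavior.csv").sort_values("age")
        ao = pd.read_csv(d / "a_o.csv")
        behavior = BehavioralFactors(
            t1=beh["t1"].to_numpy(), t3=beh["t3"].to_numpy(),
            a_o={r["organ"]: float(r["a_o"]) for _, r in ao.iterrows()},
            r_inout_mean=float(man["r_inout_mean"]),
        )
        driv = pd.read_csv(d / "d_riv.csv")
        d_riv = {
            str(sid): pd.Series(grp["gy_per_yr"].values, index=grp["year"].values)
            for sid, grp in driv.groupby("settlement_id")
        }
        d90 = pd.read_csv(d / "d_sr90.csv").sort_values("month")
        d90t = pd.read_csv(d / "d_sr90_tail.csv").sort_values("year_since")
        co = pd.read_csv(d / "cohort.csv")
        cohort = []
        for iid, grp in co.groupby("individual_id", sort=False):
            first = grp.iloc[0]
            imr = first["imr"]
            cohort.append(
                Individual(
                    id=str(iid), birth_year=int(first["birth_year"]),
                    household_id=str(first["household_id"]),
                    xi_mode=str(first["xi_mode"]),
                    imr=None if pd.isna(imr) or imr == "" else float(imr),
                    n_measurements=int(first["n_measurements"]),
                    residence_history=[
                        ResidenceRecord(str(r["settlement_id"]), float(r["start"]), float(r["end"]))
                        for _, r in grp.iterrows()
                    ],
                )
            )
        registry = ParameterRegistry.from_json(d / "registry.json")
        return cls(
            settlements=settlements,
            intake=IntakeModel(i_ref=i_ref, alpha=alpha, r_ratio=r_ratio, e_conv=e_conv),
            dose_coeff=DoseCoefficientTable(kernels),
            behavior=behavior,
            cohort=cohort,
            registry=registry,
            nuclides=tuple(man["nuclides"]),
            eurt_nuclides=tuple(man["eurt_nuclides"]),
            organs=tuple(man["organs"]),
            start_year=int(man["start_year"]),
            end_year=int(man["end_year"]),
            accident_date=float(man["accident_date"]),
            d_riv=d_riv,
            d_sr90_monthly=d90["gy_per_bq_m2"].to_numpy(),
            d_sr90_tail=d90t["gy_per_bq_m2"].to_numpy(),
            seed=man.get("seed"),
        )


def validate_bundle(bundle: ScenarioBundle) -> list[str]:
    """Invariant violations across all bundle components (empty = valid)."""
    from .registry import validate_registry

    report: list[str] = []
    for s in bundle.settlements.values():
        report.extend(s.violations())
    report.extend(bundle.intake.violations())
    report.extend(bundle.dose_coeff.violations())
    report.extend(bundle.behavior.violations())
    move_limit = bundle.registry.dimensioning.move_limit
    for ind in bundle.cohort:
        report.extend(ind.violations(move_limit))
        for rec in ind.residence_history:
            if rec.settlement_id not in bundle.settlements:
                report.append(f"{ind.id}: unknown settlement {rec.settlement_id}")
    report.extend(validate_registry(bundle.registry))
    for sid, series in bundle.d_riv.items():
        if (series < 0).any():
            report.append(f"d_riv[{sid}] has negative entries")
    if (bundle.d_sr90_monthly < 0).any() or (bundle.d_sr90_tail < 0).any():
        report.append("normalized fallout dose-rate tables must be nonnegative")
    return report
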