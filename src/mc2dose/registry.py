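"""Registry of uncertain dosimetry-system parameters with sharing scopes.

The dose reconstruction model is driven by a set of mean-value tables
(intake functions, dose coefficients, dose rates in air, behavioral
fractions) whose uncertainty is expressed as multiplicative error factors.
Each factor is either *shared* — a systematic, lack-of-knowledge error
common to a group of people (a village, a household, an age group) within
one Monte-Carlo realization — or *unshared* — a stochastic error drawn
independently per person.  The registry encodes, for every model parameter
family, the multiplier distribution and the sharing scope of each error
component, together with the index dimensions that determine how many
scalar parameters the family contributes to the sampling problem.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional

import numpy as np
from scipy import special, stats

__all__ = [
    "Family",
    "ScopeLevel",
    "Correlation",
    "DistributionSpec",
    "SharingScope",
    "UncertaintyComponent",
    "UncertainParameter",
    "Dimensioning",
    "ParameterRegistry",
    "build_default_registry",
    "count_parameters",
    "validate_registry",
    "point_mass",
]


class Family(str, Enum):
    """Distribution families available for multiplier errors."""

    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    UNIFORM = "uniform"
    LOGUNIFORM = "loguniform"
    EMPIRICAL = "empirical"


class ScopeLevel(str, Enum):
    GLOBAL = "global"
    VILLAGE = "village"
    HOUSEHOLD = "household"
    AGE_GROUP = "age_group"
    NUCLIDE_ORGAN = "nuclide_organ"
    TIME_SLICE = "time_slice"
    MONTH = "month"
    MOVE = "move"
    CLUSTER = "cluster"
    INDIVIDUAL = "individual"


class Correlation(str, Enum):
    NONE = "none"
    AR1 = "ar1"


@dataclass(frozen=True)
class DistributionSpec:
    """A multiplier distribution (multiplicative error on a mean of 1).

    Parameters are family specific:

    * ``normal``:     params = (mean, sd), mean normally 1
    * ``lognormal``:  params = (GM, GSD), GM normally 1
    * ``uniform``:    params = (lo, hi) as multiples of the mean
    * ``loguniform``: params = (lo, hi) as multiples of the mean
    * ``empirical``:  quantile grid: probs (strictly increasing on [0, 1])
                      and values (nondecreasing)

    ``trunc_lower`` bounds the sampled multiplier from below (doses must be
    nonnegative, so the default is 0; a slightly negative-mass normal such
    as Norm[1, 0.25] is truncated there).
    """

    family: Family
    params: tuple[float, ...] = ()
    probs: Optional[tuple[float, ...]] = None
    values: Optional[tuple[float, ...]] = None
    trunc_lower: float = 0.0
    trunc_upper: float = math.inf

    # -- validation ----------------------------------------------------
    def violations(self) -> list[str]:
        out: list[str] = []
        fam = Family(self.family)
        if fam is Family.NORMAL:
            if len(self.params) != 2:
                out.append("normal requires (mean, sd)")
            elif self.params[1] < 0:
                out.append(f"normal sd must be >= 0, got {self.params[1]}")
        elif fam is Family.LOGNORMAL:
            if len(self.params) != 2:
                out.append("lognormal requires (GM, GSD)")
            elif self.params[1] < 1:
                out.append(f"lognormal GSD must be >= 1, got {self.params[1]}")
            elif self.params[0] <= 0:
                out.append("lognormal GM must be > 0")
        elif fam in (Family.UNIFORM, Family.LOGUNIFORM):
            if len(self.params) != 2:
                out.append(f"{fam.value} requires (lo, hi)")
            elif self.params[0] > self.params[1]:
                out.append(f"{fam.value} requires lo <= hi")
            elif fam is Family.LOGUNIFORM and self.params[0] <= 0:
                out.append("loguniform requires lo > 0")
        elif fam is Family.EMPIRICAL:
            if self.probs is None or self.values is None:
                out.append("empirical requires probs and values grids")
            else:
                p = np.asarray(self.probs, dtype=float)
                v = np.asarray(self.values, dtype=float)
                if p.size != v.size or p.size < 2:
                    out.append("empirical grids must align and have >= 2 points")
                elif not np.all(np.diff(p) > 0):
                    out.append("empirical probs must be strictly increasing")
                elif not np.all(np.diff(v) >= 0):
                    out.append("empirical values must be nondecreasing")
                elif p[0] < 0 or p[-1] > 1:
                    out.append("empirical probs must lie in [0, 1]")
        if self.trunc_lower >= self.trunc_upper:
            out.append("truncation bounds out of order")
        return out

    def validate(self) -> None:
        bad = self.violations()
        if bad:
            raise ValueError("; ".join(bad))

    # -- quantile machinery (closed forms; hot path, so no scipy freezing)
    def ppf(self, u):
        """Inverse CDF of the (truncation-respecting) multiplier distribution."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("probability deviates must lie in [0, 1]")
        fam = Family(self.family)
        if fam is Family.EMPIRICAL:
            return np.interp(u, self.probs, self.values)
        if self.is_point_mass():
            return np.full_like(u, float(self.params[0]), dtype=float)
        if fam is Family.NORMAL:
            mean, sd = self.params
            f_lo = special.ndtr((self.trunc_lower - mean) / sd)
            f_hi = (
                special.ndtr((self.trunc_upper - mean) / sd)
                if math.isfinite(self.trunc_upper)
                else 1.0
            )
            return mean + sd * special.ndtri(f_lo + u * (f_hi - f_lo))
        if fam is Family.LOGNORMAL:
            gm, gsd = self.params
            with np.errstate(divide="ignore"):
                return gm * np.exp(math.log(gsd) * special.ndtri(u))
        if fam is Family.UNIFORM:
            lo, hi = self.params
            return lo + u * (hi - lo)
        # loguniform
        lo, hi = self.params
        return np.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        fam = Family(self.family)
        if fam is Family.EMPIRICAL:
            return np.interp(x, self.values, self.probs)
        if self.is_point_mass():
            return (x >= self.params[0]).astype(float)
        if fam is Family.NORMAL:
            mean, sd = self.params
            f_lo = special.ndtr((self.trunc_lower - mean) / sd)
            f_hi = (
                special.ndtr((self.trunc_upper - mean) / sd)
                if math.isfinite(self.trunc_upper)
                else 1.0
            )
            f = special.ndtr((x - mean) / sd)
            return np.clip((f - f_lo) / (f_hi - f_lo), 0.0, 1.0)
        if fam is Family.LOGNORMAL:
            gm, gsd = self.params
            out = np.zeros_like(x, dtype=float)
            pos = x > 0
            out[pos] = special.ndtr(np.log(x[pos] / gm) / math.log(gsd))
            return out
        if fam is Family.UNIFORM:
            lo, hi = self.params
            return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        lo, hi = self.params
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (np.log(x) - math.log(lo)) / (math.log(hi) - math.log(lo))
        return np.clip(np.nan_to_num(out, nan=0.0, neginf=0.0), 0.0, 1.0)

    def is_point_mass(self) -> bool:
        fam = Family(self.family)
        if fam is Family.NORMAL:
            return self.params[1] == 0
        if fam is Family.LOGNORMAL:
            return self.params[1] == 1
        if fam in (Family.UNIFORM, Family.LOGUNIFORM):
            return self.params[0] == self.params[1]
        return False

    def mean(self) -> float:
        fam = Family(self.family)
        if fam is Family.EMPIRICAL:
            # mean of the piecewise-linear inverse CDF
            u = np.linspace(0, 1, 2001)
            return float(np.trapezoid(np.interp(u, self.probs, self.values), u))
        if self.is_point_mass():
            return float(self.params[0])
        if fam is Family.NORMAL:
            m, sd = self.params
            a = (self.trunc_lower - m) / sd
            b = (self.trunc_upper - m) / sd if math.isfinite(self.trunc_upper) else np.inf
            num = stats.norm.pdf(a) - (stats.norm.pdf(b) if np.isfinite(b) else 0.0)
            den = special.ndtr(b) - special.ndtr(a) if np.isfinite(b) else 1.0 - special.ndtr(a)
            return float(m + sd * num / den)
        if fam is Family.LOGNORMAL:
            gm, gsd = self.params
            return float(gm * math.exp(0.5 * math.log(gsd) ** 2))
        if fam is Family.UNIFORM:
            lo, hi = self.params
            return (lo + hi) / 2.0
        lo, hi = self.params
        return float((hi - lo) / (math.log(hi) - math.log(lo)))


def point_mass(value: float = 1.0) -> DistributionSpec:
    """A degenerate multiplier distribution (uncertainty disabled)."""
    return DistributionSpec(Family.NORMAL, (value, 0.0))


@dataclass(frozen=True)
class SharingScope:
    """How an error component is shared across people and indices."""

    level: ScopeLevel
    correlation: Correlation = Correlation.NONE
    rho: float = 0.0
    correlated_index: str = "none"  # "age" | "year" | "none"

    def violations(self) -> list[str]:
        out: list[str] = []
        if Correlation(self.correlation) is Correlation.AR1:
            if not (0.0 <= self.rho < 1.0):
                out.append(f"AR(1) rho must be in [0, 1), got {self.rho}")
            if self.correlated_index == "none":
                out.append("AR(1) scope requires a correlated index (age or year)")
        return out


@dataclass(frozen=True)
class UncertaintyComponent:
    """One error component: distribution, scope and index dimensions.

    ``index_dims`` is a tuple of (dimension name, cardinality) pairs; the
    number of scalar parameters the component contributes is the product of
    the cardinalities.
    """

    spec: DistributionSpec
    scope: SharingScope
    index_dims: tuple[tuple[str, int], ...] = ()

    @property
    def n_scalars(self) -> int:
        n = 1
        for _, card in self.index_dims:
            n *= int(card)
        return n

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(int(c) for _, c in self.index_dims)


@dataclass(frozen=True)
class UncertainParameter:
    """One model-parameter family with its shared/unshared error structure."""

    symbol: str
    description: str = ""
    shared: Optional[UncertaintyComponent] = None
    unshared: Optional[UncertaintyComponent] = None
    alt_shared_spec: Optional[DistributionSpec] = None
    nuclide_specific_unshared: dict[str, DistributionSpec] = field(default_factory=dict)

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.shared is None and self.unshared is None:
            out.append(f"{self.symbol}: neither shared nor unshared component present")
        for label, comp in (("shared", self.shared), ("unshared", self.unshared)):
            if comp is None:
                continue
            for msg in comp.spec.violations():
                out.append(f"{self.symbol}.{label}: {msg}")
            for msg in comp.scope.violations():
                out.append(f"{self.symbol}.{label}: {msg}")
            for name, card in comp.index_dims:
                if card <= 0:
                    out.append(f"{self.symbol}.{label}: dimension {name} has nonpositive cardinality {card}")
        return out


#: Symbols recognised by the default registry builder.
SYMBOLS = (
    "G_sr90", "I_ref", "f_ratio", "xi", "alpha", "R_ratio", "I_E", "E_conv",
    "DF", "A_o", "D_riv", "D_sr90", "R_outriv", "R_inout", "T1", "T3",
)


@dataclass(frozen=True)
class Dimensioning:
    """Named cardinalities of the dosimetry system's index sets."""

    n_techa_settlements: int = 42
    n_eurt_villages: int = 84
    n_nuclides: int = 11
    n_eurt_nuclides: int = 6
    n_organs: int = 23
    n_time_slices: int = 53
    n_age_groups: int = 11
    n_months: int = 15
    move_limit: int = 20

    def violations(self) -> list[str]:
        return [
            f"dimension {name} must be positive, got {value}"
            for name, value in asdict(self).items()
            if int(value) <= 0
        ]

    def validate(self) -> None:
        bad = self.violations()
        if bad:
            raise ValueError("; ".join(bad))


@dataclass
class ParameterRegistry:
    parameters: list[UncertainParameter]
    dimensioning: Dimensioning = field(default_factory=Dimensioning)

    def __iter__(self):
        return iter(self.parameters)

    def get(self, symbol: str) -> UncertainParameter:
        for p in self.parameters:
            if p.symbol == symbol:
                return p
        raise KeyError(symbol)

    def has(self, symbol: str) -> bool:
        return any(p.symbol == symbol for p in self.parameters)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def spec_d(s: Optional[DistributionSpec]):
            if s is None:
                return None
            d = {"family": Family(s.family).value, "params": list(s.params)}
            if s.probs is not None:
                d["probs"] = list(s.probs)
                d["values"] = list(s.values)
            if s.trunc_lower != 0.0:
                d["trunc_lower"] = s.trunc_lower
            if math.isfinite(s.trunc_upper):
                d["trunc_upper"] = s.trunc_upper
            return d

        def comp_d(c: Optional[UncertaintyComponent]):
            if c is None:
                return None
            return {
                "spec": spec_d(c.spec),
                "scope": {
                    "level": ScopeLevel(c.scope.level).value,
                    "correlation": Correlation(c.scope.correlation).value,
                    "rho": c.scope.rho,
                    "correlated_index": c.scope.correlated_index,
                },
                "dims": [[name, card] for name, card in c.index_dims],
            }

        return {
            "dimensioning": asdict(self.dimensioning),
            "parameters": [
                {
                    "symbol": p.symbol,
                    "description": p.description,
                    "shared": comp_d(p.shared),
                    "unshared": comp_d(p.unshared),
                    "alt_shared_spec": spec_d(p.alt_shared_spec),
                    "nuclide_specific_unshared": {
                        k: spec_d(v) for k, v in p.nuclide_specific_unshared.items()
                    },
                }
                for p in self.parameters
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterRegistry":
        def spec_f(s):
            if s is None:
                return None
            return DistributionSpec(
                family=Family(s["family"]),
                params=tuple(s.get("params", ())),
                probs=tuple(s["probs"]) if "probs" in s else None,
                values=tuple(s["values"]) if "values" in s else None,
                trunc_lower=s.get("trunc_lower", 0.0),
                trunc_upper=s.get("trunc_upper", math.inf),
            )

        def comp_f(c):
            if c is None:
                return None
            sc = c["scope"]
            return UncertaintyComponent(
                spec=spec_f(c["spec"]),
                scope=SharingScope(
                    level=ScopeLevel(sc["level"]),
                    correlation=Correlation(sc.get("correlation", "none")),
                    rho=sc.get("rho", 0.0),
                    correlated_index=sc.get("correlated_index", "none"),
                ),
                index_dims=tuple((name, int(card)) for name, card in c.get("dims", [])),
            )

        params = [
            UncertainParameter(
                symbol=p["symbol"],
                description=p.get("description", ""),
                shared=comp_f(p.get("shared")),
                unshared=comp_f(p.get("unshared")),
                alt_shared_spec=spec_f(p.get("alt_shared_spec")),
                nuclide_specific_unshared={
                    k: spec_f(v) for k, v in p.get("nuclide_specific_unshared", {}).items()
                },
            )
            for p in d["parameters"]
        ]
        dim = Dimensioning(**d["dimensioning"])
        return cls(parameters=params, dimensioning=dim)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterRegistry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Default empirical ("custom") multiplier grid for the shared error of the
# reference-intake function: a right-skewed tabulated inverse CDF spanning
# roughly a factor of 2.8 between the 5th and 95th percentiles, in line with
# the spread of village-mean intake estimates.  The synthetic-data generator
# may emit its own grid; this one is the registry default.
_P = np.linspace(0.0, 1.0, 21)
_V = np.exp(stats.norm.ppf(np.clip(_P, 0.005, 0.995)) * math.log(1.45))
DEFAULT_IREF_GRID = (tuple(_P.tolist()), tuple(np.round(_V, 6).tolist()))
del _P, _V


def build_default_registry(dimensioning: Dimensioning | None = None) -> ParameterRegistry:
    """Build the default parameter/uncertainty registry.

    One :class:`UncertainParameter` per model-parameter family, each with
    the multiplier distributions and index cardinalities of the standard
    uncertainty structure.  With the default dimensioning the registry
    totals 1,436 shared and 422 unshared scalar parameters.
    """
    dim = dimensioning or Dimensioning()
    dim.validate()

    probs, values = DEFAULT_IREF_GRID
    norm = lambda sd: DistributionSpec(Family.NORMAL, (1.0, sd))
    logn = lambda gsd: DistributionSpec(Family.LOGNORMAL, (1.0, gsd))
    unif = lambda lo, hi: DistributionSpec(Family.UNIFORM, (lo, hi))

    params = [
        UncertainParameter(
            symbol="G_sr90",
            description="Surface deposition of 90Sr (Bq/m2) from the 1957 fallout trace",
            shared=UncertaintyComponent(
                norm(0.05), SharingScope(ScopeLevel.VILLAGE),
                (("eurt_villages", dim.n_eurt_villages),),
            ),
            unshared=UncertaintyComponent(
                norm(0.2), SharingScope(ScopeLevel.MOVE),
                (("moves", dim.move_limit),),
            ),
        ),
        UncertainParameter(
            symbol="I_ref",
            description="Annual reference-settlement adult 90Sr intake",
            shared=UncertaintyComponent(
                DistributionSpec(Family.EMPIRICAL, probs=probs, values=values),
                SharingScope(ScopeLevel.VILLAGE),  # household-level when an HSR exists
                (("techa_settlements", dim.n_techa_settlements),),
            ),
            unshared=UncertaintyComponent(
                norm(0.25), SharingScope(ScopeLevel.TIME_SLICE),
                (("time_slices", dim.n_time_slices),),
            ),
        ),
        UncertainParameter(
            symbol="alpha",
            description="Child-to-adult 90Sr intake ratio (age < 10)",
            shared=UncertaintyComponent(
                norm(0.1), SharingScope(ScopeLevel.AGE_GROUP),
                (("age_groups", dim.n_age_groups),),
            ),
            unshared=UncertaintyComponent(
                norm(0.2), SharingScope(ScopeLevel.AGE_GROUP),
                (("age_groups", dim.n_age_groups),),
            ),
        ),
        UncertainParameter(
            symbol="R_ratio",
            description="Nuclide-to-90Sr intake ratio by settlement (river transport)",
            shared=UncertaintyComponent(
                logn(2.0), SharingScope(ScopeLevel.VILLAGE),
                (("nuclides", dim.n_nuclides), ("techa_settlements", dim.n_techa_settlements)),
            ),
            alt_shared_spec=unif(0.5, 1.0),
        ),
        UncertainParameter(
            symbol="I_E",
            description="Radionuclide intake per unit 90Sr surface deposition (fallout trace)",
            shared=UncertaintyComponent(
                logn(3.0), SharingScope(ScopeLevel.VILLAGE),
                (("eurt_nuclides", dim.n_eurt_nuclides), ("eurt_villages", dim.n_eurt_villages)),
            ),
            unshared=UncertaintyComponent(
                logn(2.0), SharingScope(ScopeLevel.MOVE),
                (("moves", dim.move_limit),),
            ),
        ),
        UncertainParameter(
            symbol="DF",
            description="Dose coefficient: cumulative organ dose (Gy) per Bq ingested",
            shared=UncertaintyComponent(
                norm(0.1),
                SharingScope(ScopeLevel.NUCLIDE_ORGAN, Correlation.AR1, 0.8, "age"),
                (("nuclides", dim.n_nuclides), ("organs", dim.n_organs)),
            ),
            unshared=UncertaintyComponent(
                logn(2.0), SharingScope(ScopeLevel.INDIVIDUAL),
                (("nuclides", dim.n_nuclides), ("organs", dim.n_organs)),
            ),
            nuclide_specific_unshared={"Sr-90": logn(1.25)},
        ),
        UncertainParameter(
            symbol="A_o",
            description="Absorbed dose in air to organ dose conversion factor",
            shared=UncertaintyComponent(
                unif(0.9, 1.1),
                SharingScope(ScopeLevel.AGE_GROUP, Correlation.AR1, 0.8, "age"),
                (("organs", dim.n_organs),),
            ),
            unshared=UncertaintyComponent(
                unif(0.9, 1.1), SharingScope(ScopeLevel.INDIVIDUAL),
                (("one", 1),),
            ),
        ),
        UncertainParameter(
            symbol="D_riv",
            description="Annual absorbed dose in air on the river shoreline (Gy/yr)",
            shared=UncertaintyComponent(
                norm(0.1),
                SharingScope(ScopeLevel.VILLAGE, Correlation.AR1, 0.8, "year"),
                (("techa_settlements", dim.n_techa_settlements),),
            ),
        ),
        UncertainParameter(
            symbol="D_sr90",
            description="Normalized outdoor dose rate in air from fallout deposition",
            shared=UncertaintyComponent(
                unif(0.9, 1.1), SharingScope(ScopeLevel.MONTH),
                (("months", dim.n_months),),
            ),
        ),
        UncertainParameter(
            symbol="R_outriv",
            description="Residence-to-riverbank dose-rate ratio (village specific range)",
            unshared=UncertaintyComponent(
                DistributionSpec(Family.LOGUNIFORM, (0.5, 2.0)),  # range overridden per village
                SharingScope(ScopeLevel.VILLAGE),
                (("techa_settlements", dim.n_techa_settlements),),
            ),
        ),
        UncertainParameter(
            symbol="R_inout",
            description="Indoor-to-outdoor dose-rate ratio (building type)",
            unshared=UncertaintyComponent(
                unif(0.28, 1.72), SharingScope(ScopeLevel.MOVE),
                (("moves", dim.move_limit),),
            ),
        ),
        UncertainParameter(
            symbol="T1",
            description="Fraction of the year spent on the riverbank",
            unshared=UncertaintyComponent(
                logn(2.7), SharingScope(ScopeLevel.INDIVIDUAL),
                (("one", 1),),
            ),
        ),
        UncertainParameter(
            symbol="T3",
            description="Fraction of the year spent indoors",
            unshared=UncertaintyComponent(
                logn(2.7), SharingScope(ScopeLevel.INDIVIDUAL),
                (("one", 1),),
            ),
        ),
    ]
    reg = ParameterRegistry(parameters=params, dimensioning=dim)
    report = validate_registry(reg)
    if report:
        raise ValueError("default registry failed validation: " + "; ".join(report))
    return reg


def count_parameters(registry: ParameterRegistry) -> tuple[int, int]:
    """Total (shared, unshared) scalar parameter counts over all families."""
    n_shared = sum(p.shared.n_scalars for p in registry if p.shared is not None)
    n_unshared = sum(p.unshared.n_scalars for p in registry if p.unshared is not None)
    return n_shared, n_unshared


#: Index-dimension names that must agree with the dimensioning block.
_DIM_NAMES = {
    "techa_settlements": "n_techa_settlements",
    "eurt_villages": "n_eurt_villages",
    "nuclides": "n_nuclides",
    "eurt_nuclides": "n_eurt_nuclides",
    "organs": "n_organs",
    "time_slices": "n_time_slices",
    "age_groups": "n_age_groups",
    "months": "n_months",
    "moves": "move_limit",
}


def validate_registry(registry: ParameterRegistry) -> list[str]:
    """Collect invariant violations; an empty report means the registry is valid."""
    report: list[str] = []
    report.extend(registry.dimensioning.violations())
    seen: set[str] = set()
    for p in registry:
        if p.symbol in seen:
            report.append(f"duplicate symbol {p.symbol}")
        seen.add(p.symbol)
        report.extend(p.violations())
        for label, comp in (("shared", p.shared), ("unshared", p.unshared)):
            if comp is None:
                continue
            for name, card in comp.index_dims:
                attr = _DIM_NAMES.get(name)
                if attr is None:
                    continue
                expected = getattr(registry.dimensioning, attr)
                if card != expected:
                    report.append(
                        f"{p.symbol}.{label}: dimension {name} has cardinality "
                        f"{card} but dimensioning declares {expected}"
                    )
    return report
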