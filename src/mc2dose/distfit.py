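"""Best-fitting distribution classification for dose-realization samples.

Each person's total-dose realizations are tested against six candidate
families — lognormal, three-parameter (scaled) beta, generalized extreme
value, gamma, generalized logistic (type I) and Weibull — with a one-sample
Kolmogorov-Smirnov test against the maximum-likelihood fit.  The best fit
is the candidate with the largest p-value among those exceeding 0.05; if
every candidate falls below 0.05 the sample is labelled ``none``.

Because the candidate parameters are estimated from the same sample, the
asymptotic K-S p-value is anti-conservative; the default p-value is a
parametric bootstrap (fit, simulate, refit), with the asymptotic value
available for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose_engine import DoseRealizationEnsemble

__all__ = [
    "CANDIDATES",
    "FitResult",
    "ks_best_fit",
    "classify_cohort",
]

CANDIDATES = (
    "lognormal",
    "scaled_beta",
    "gev",
    "gamma",
    "generalized_logistic",
    "weibull",
)

P_THRESHOLD = 0.05


@dataclass
class FitResult:
    p_values: dict[str, float]
    parameters: dict[str, tuple]
    best_label: str
    failed: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {f"p_{k}": v for k, v in self.p_values.items()}
        row["best_label"] = self.best_label
        return row


# ----------------------------------------------------------------------
# Per-family fitting.  Each fitter returns (frozen distribution, params).
# ----------------------------------------------------------------------

def _fit_lognormal(x: np.ndarray):
    logs = np.log(x)
    mu = logs.mean()
    sigma = logs.std(ddof=0)
    sigma = max(sigma, 1e-12)
    return stats.lognorm(s=sigma, scale=np.exp(mu)), (sigma, float(np.exp(mu)))


def _fit_scaled_beta(x: np.ndarray):
    # three-parameter beta on (0, c): the scale is pinned just above the
    # sample maximum so the MLE of the shape parameters is well defined
    c = float(x.max()) * (1.0 + 1.0 / x.size)
    a, b, loc, scale = stats.beta.fit(x, floc=0.0, fscale=c)
    return stats.beta(a, b, loc=0.0, scale=c), (a, b, c)


def _fit_gev(x: np.ndarray):
    params = stats.genextreme.fit(x)
    return stats.genextreme(*params), params


def _fit_gamma(x: np.ndarray):
    params = stats.gamma.fit(x, floc=0.0)
    return stats.gamma(*params), params


def _fit_genlogistic(x: np.ndarray):
    params = stats.genlogistic.fit(x)
    return stats.genlogistic(*params), params


def _fit_weibull(x: np.ndarray):
    params = stats.weibull_min.fit(x, floc=0.0)
    return stats.weibull_min(*params), params


_FITTERS = {
    "lognormal": _fit_lognormal,
    "scaled_beta": _fit_scaled_beta,
    "gev": _fit_gev,
    "gamma": _fit_gamma,
    "generalized_logistic": _fit_genlogistic,
    "weibull": _fit_weibull,
}


def _ks_stat(x: np.ndarray, frozen) -> float:
    return float(stats.kstest(x, frozen.cdf).statistic)


def _bootstrap_p(
    x: np.ndarray, family: str, d_obs: float, n_boot: int, rng: np.random.Generator
) -> float:
    """Parametric-bootstrap p-value: refit each simulated sample."""
    fitter = _FITTERS[family]
    frozen, _ = fitter(x)
    count = 0
    n = x.size
    for _ in range(n_boot):
        sim = frozen.rvs(size=n, random_state=rng)
        sim = np.abs(sim) + 1e-300  # guard: candidates may emit <= 0
        try:
            refit, _ = fitter(sim)
            d_b = _ks_stat(sim, refit)
        except Exception:
            continue
        if d_b >= d_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_boot)


def ks_best_fit(
    sample: np.ndarray,
    candidates: Sequence[str] = CANDIDATES,
    *,
    method: str = "bootstrap",
    n_boot: int = 199,
    seed: Optional[int] = None,
) -> FitResult:
    """Fit each candidate family and pick the best by the K-S rule.

    The label is the candidate with the largest p-value above 0.05, or
    ``"none"`` when every candidate's p-value is below 0.05.  A family
    whose fit fails to converge is recorded with p = 0 and flagged rather
    than aborting the classification.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 realizations to classify")
    if (x <= 0).any():
        raise ValueError("sample values must be positive")
    if method not in ("bootstrap", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    parameters: dict[str, tuple] = {}
    failed: list[str] = []
    for family in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frozen, params = _FITTERS[family](x)
                d_obs = _ks_stat(x, frozen)
                if method == "asymptotic":
                    p = float(stats.kstest(x, frozen.cdf).pvalue)
                else:
                    p = _bootstrap_p(x, family, d_obs, n_boot, rng)
            if not np.isfinite(p):
                raise FloatingPointError("non-finite p-value")
            p_values[family] = p
            parameters[family] = tuple(np.atleast_1d(params).tolist())
        except Exception:
            p_values[family] = 0.0
            parameters[family] = ()
            failed.append(family)
    passing = {k: v for k, v in p_values.items() if v > P_THRESHOLD}
    best = max(passing, key=passing.get) if passing else "none"
    return FitResult(p_values=p_values, parameters=parameters, best_label=best, failed=failed)


def classify_cohort(
    ensemble: DoseRealizationEnsemble,
    organ: str,
    components: Optional[Sequence[str]] = None,
    *,
    method: str = "bootstrap",
    n_boot: int = 199,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-person best-fit labels and the cohort label percentages.

    Returns a per-person table (id, per-family p-values, label) and a
    Series of label percentages (summing to 100 over the labels present).
    People with non-positive realizations are skipped with label
    ``"excluded"`` and do not enter the percentages.
    """
    if organ not in ensemble.organs:
        raise ValueError(f"organ {organ!r} not in ensemble")
    final = ensemble.final_dose(organ, components)
    rows = []
    for ii, iid in enumerate(ensemble.individual_ids):
        x = final[ii]
        if (x <= 0).any():
            rows.append({"individual_id": iid, "best_label": "excluded"})
            continue
        res = ks_best_fit(
            x, method=method, n_boot=n_boot,
            seed=None if seed is None else seed + ii,
        )
        row = {"individual_id": iid}
        row.update(res.as_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    labelled = table[table["best_label"] != "excluded"]
    if len(labelled) == 0:
        raise ValueError("no classifiable individuals")
    counts = labelled["best_label"].value_counts()
    percentages = 100.0 * counts / counts.sum()
    return table, percentages
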