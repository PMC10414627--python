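"""Per-person and population summaries over dose realizations.

For each person the arithmetic mean and CV (arithmetic scale) and the
geometric mean and GSD (log scale) are computed over realizations; the
population tables then summarise the distribution of those per-person
statistics with mean, CV and selected percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_engine import DoseRealizationEnsemble

__all__ = [
    "SummaryRecord",
    "individual_summary",
    "summarize_realizations",
    "population_summary",
    "cv_from_gsd",
    "gsd_from_cv",
    "realization_ratio_cdf",
    "internal_fraction",
]

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class SummaryRecord:
    am: float
    gm: float
    cv: float
    gsd: float
    n_realizations: int
    zero_fraction: float = 0.0
    all_zero: bool = False


def summarize_realizations(values: np.ndarray) -> SummaryRecord:
    """AM/CV on the arithmetic scale, GM/GSD on the log scale.

    Zero realizations are excluded from the log-scale statistics (doses
    are products of positive factors, so zeros only arise from a zero base
    dose); an all-zero vector reports GM = 0, GSD = 1 with a flag.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 realizations")
    if (v < 0).any():
        raise ValueError("doses must be nonnegative")
    am = float(v.mean())
    sd = float(v.std())  # population moment over the realization ensemble
    cv = sd / am if am > 0 else 0.0
    pos = v[v > 0]
    zero_fraction = 1.0 - pos.size / v.size
    if pos.size == 0:
        return SummaryRecord(am, 0.0, cv, 1.0, v.size, 1.0, all_zero=True)
    logs = np.log(pos)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std())) if pos.size > 1 else 1.0
    return SummaryRecord(am, gm, cv, gsd, v.size, zero_fraction)


def individual_summary(
    ensemble: DoseRealizationEnsemble,
    individual_id: str,
    organ: str,
    components: Optional[Sequence[str]] = None,
) -> SummaryRecord:
    """Summary of one person's end-of-follow-up dose over realizations."""
    ii = ensemble.index_of(individual_id)
    final = ensemble.final_dose(organ, components)[ii]
    return summarize_realizations(final)


def cohort_records(
    ensemble: DoseRealizationEnsemble,
    organ: str,
    components: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-person summary table for one organ (one row per individual)."""
    final = ensemble.final_dose(organ, components)
    rows = []
    for ii, iid in enumerate(ensemble.individual_ids):
        r = summarize_realizations(final[ii])
        rows.append(
            {"individual_id": iid, "am": r.am, "gm": r.gm, "cv": r.cv,
             "gsd": r.gsd, "zero_fraction": r.zero_fraction}
        )
    return pd.DataFrame(rows)


def population_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Population distribution of the per-person statistics.

    Rows: the per-person AM, GM, CV and GSD; columns: population mean, CV,
    the 5/25/50/75/95 percentiles and the maximum.  Percentiles use linear
    interpolation between order statistics.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    out = []
    for col, label in (
        ("am", "population_mean"),
        ("gm", "population_geometric_mean"),
        ("cv", "individual_cv"),
        ("gsd", "individual_gsd"),
    ):
        v = records[col].to_numpy(dtype=float)
        mean = float(v.mean())
        cv = float(v.std() / mean) if (len(v) > 1 and mean > 0) else 0.0
        row = {"statistic": label, "mean": mean, "cv": cv}
        for p in PERCENTILES:
            row[f"p{p}"] = float(np.percentile(v, p))
        row["max"] = float(v.max())
        out.append(row)
    return pd.DataFrame(out)


def cv_from_gsd(gsd: float) -> float:
    """CV implied by a GSD under lognormality: sqrt(exp(ln^2 GSD) - 1)."""
    if gsd < 1:
        raise ValueError("gsd must be >= 1")
    s2 = math.log(gsd) ** 2
    return math.sqrt(math.expm1(s2))


def gsd_from_cv(cv: float) -> float:
    """Inverse of :func:`cv_from_gsd`."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return math.exp(math.sqrt(math.log1p(cv * cv)))


def realization_ratio_cdf(
    ensemble: DoseRealizationEnsemble,
    organ: str,
    realization_ids: Sequence[int],
    components: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Empirical CDFs of dose-to-individual-mean ratios per realization.

    For each selected realization, the distribution over people of
    (dose in that realization) / (person's mean dose over realizations).
    Systematic horizontal offsets between the curves are the visible
    signature of shared error: some realizations sit high for everyone.
    """
    final = ensemble.final_dose(organ, components)  # (n_ind, n_real)
    means = final.mean(axis=1)
    keep = means > 0
    if not np.any(keep):
        raise ValueError("no individual with positive mean dose")
    rows = []
    for rid in realization_ids:
        if not (0 <= rid < ensemble.n_realizations):
            raise KeyError(f"unknown realization id {rid}")
        ratios = np.sort(final[keep, rid] / means[keep])
        n = ratios.size
        cdf = (np.arange(1, n + 1)) / n
        for x, p in zip(ratios, cdf):
            rows.append({"realization": rid, "ratio": x, "cdf": p})
    return pd.DataFrame(rows)


def internal_fraction(ensemble: DoseRealizationEnsemble, organ: str) -> tuple[float, int]:
    """Cohort-average fraction of the mean total dose that is internal.

    Returns (fraction in [0, 1], number of zero-total-dose people excluded).
    """
    internal = ensemble.final_dose(organ, ["techa_internal", "eurt_internal"])
    total = ensemble.final_dose(organ)
    mi = internal.mean(axis=1)
    mt = total.mean(axis=1)
    keep = mt > 0
    n_excluded = int((~keep).sum())
    if not np.any(keep):
        raise ValueError("all individuals have zero total dose")
    return float(np.mean(mi[keep] / mt[keep])), n_excluded
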