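"""Cohort-level summaries and method-agreement statistics.

Descriptives are mean +/- sample SD (n-1) with min/max/range; agreement
between dose-estimation methods uses Bland-Altman statistics (mean paired
difference and 1.96-SD limits of agreement); correlations are tie-corrected
Spearman rank coefficients; matched patient pairs are compared metric by
metric as percent differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummary",
    "AgreementResult",
    "summarize",
    "bland_altman",
    "spearman",
    "matched_pair_compare",
    "bmi_class",
    "age_class",
]


from dataclasses import dataclass


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive summary of one variable across the cohort."""

    variable: str
    n: int
    mean: float
    sd: float
    min: float
    max: float

    @property
    def range(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement between two paired dose series (a - b)."""

    mean_difference: float
    sd_difference: float
    pairs_n: int

    @property
    def limits_of_agreement(self) -> tuple[float, float]:
        lo = self.mean_difference - 1.96 * self.sd_difference
        hi = self.mean_difference + 1.96 * self.sd_difference
        return (lo, hi)


def summarize(cohort: pd.DataFrame, variable: str) -> CohortSummary:
    """Mean, sample SD, min, max and range of one cohort column."""
    if variable not in cohort.columns:
        raise KeyError(f"unknown variable {variable!r}")
    x = cohort[variable].dropna().to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("summaries need at least two records")
    return CohortSummary(
        variable=variable,
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        min=float(x.min()),
        max=float(x.max()),
    )


def bland_altman(a, b) -> AgreementResult:
    """Agreement statistics for paired series: differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("agreement analysis needs at least two pairs")
    d = a - b
    return AgreementResult(
        mean_difference=float(d.mean()),
        sd_difference=float(d.std(ddof=1)),
        pairs_n=int(d.size),
    )


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and two-sided p-value
    (t-approximation, as reported descriptively)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("correlation needs paired series of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


_PAIR_METRICS = (
    "dlp_mGycm",
    "ed_dlp_mSv",
    "ed_nci_mSv",
    "ed_mc_mSv",
    "lar_per_100k",
    "err_pct",
)


def matched_pair_compare(p1, p2, metrics=_PAIR_METRICS) -> dict[str, float]:
    """Percent difference 100 * (p2 - p1) / p1 per metric for a matched pair.

    ``p1`` and ``p2`` are mappings (e.g. cohort table rows).  Metrics missing
    from either patient are skipped; zero denominators are rejected."""
    out = {}
    for m in metrics:
        if m not in p1 or m not in p2:
            continue
        v1, v2 = float(p1[m]), float(p2[m])
        if not (np.isfinite(v1) and np.isfinite(v2)):
            continue
        if v1 == 0:
            raise ValueError(f"zero denominator for metric {m!r}")
        out[m] = 100.0 * (v2 - v1) / v1
    return out


def bmi_class(bmi: float) -> str:
    """Cohort BMI bins (>30 nested within >25, as in the reference tables)."""
    if bmi < 20:
        return "<20"
    if bmi <= 25:
        return "20-25"
    if bmi <= 30:
        return ">25"
    return ">30"


def age_class(age: float) -> str:
    if age < 40:
        return "<40"
    if age <= 55:
        return "40-55"
    if age <= 70:
        return "55-70"
    return ">70"
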