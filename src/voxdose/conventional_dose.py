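"""Conventional DLP-based effective dose and method comparison.

The conventional estimate is ED_DLP = DLP x k_body with the population
conversion factor k_body = 0.015 mSv/(mGy cm) for whole-body acquisitions.
The per-patient conversion factor implied by the Monte Carlo estimate is
k_MC = ED_MC / DLP, and method deviations are expressed as percent of the
conventional reference.  Rounding happens in the reporting layer only
(doses and deviations at 1 decimal, k at 3 decimals).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_report

__all__ = [
    "K_BODY",
    "ed_dlp",
    "k_mc",
    "relative_deviation",
    "k_within_band",
    "build_dose_report",
]

#: population whole-body DLP-to-ED conversion factor [mSv/(mGy cm)]
K_BODY = 0.015


def ed_dlp(dlp: float, k_body: float = K_BODY) -> float:
    """Conventional effective dose (mSv) = DLP x k_body."""
    dlp = np.asarray(dlp, dtype=float)
    if np.any(dlp < 0):
        raise ValueError("DLP must be non-negative")
    out = dlp * k_body
    return float(out) if out.ndim == 0 else out


def k_mc(ed_mc: float, dlp: float) -> float:
    """Individual conversion factor k_MC = ED_MC / DLP [mSv/(mGy cm)]."""
    dlp = np.asarray(dlp, dtype=float)
    if np.any(dlp <= 0):
        raise ValueError("k_MC undefined for DLP <= 0")
    out = np.asarray(ed_mc, dtype=float) / dlp
    return float(out) if out.ndim == 0 else out


def relative_deviation(alternative: float, reference: float) -> float:
    """Percent deviation of an alternative estimate from a reference:
    100 * (alternative - reference) / reference."""
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference dose must be positive")
    out = 100.0 * (np.asarray(alternative, dtype=float) - reference) / reference
    return float(out) if out.ndim == 0 else out


def k_within_band(
    k_values: Sequence[float], center: float = K_BODY, band: float = 0.10
) -> int:
    """Count of conversion factors within +-band of the population value
    (closed interval, e.g. [0.0135, 0.0165] for the default 10% band)."""
    k = np.asarray(list(k_values), dtype=float)
    if k.size == 0:
        raise ValueError("empty list of conversion factors")
    lo, hi = center * (1.0 - band), center * (1.0 + band)
    return int(np.sum((k >= lo) & (k <= hi)))


def build_dose_report(
    cohort: pd.DataFrame, k_body: float = K_BODY, rounded: bool = False
) -> pd.DataFrame:
    """Per-patient dose report from a cohort table.

    Requires a ``dlp_mGycm`` column; ``ed_mc_mSv`` and ``ed_nci_mSv`` enable
    the k_MC and deviation columns (the phantom-based reference ED_NCI is an
    ingested input, never computed here).  With ``rounded`` the derived
    columns carry report rounding (1 dp for mSv and %, 3 dp for k)."""
    out = pd.DataFrame(index=cohort.index)
    for col in ("id", "age_y", "sex", "bmi"):
        if col in cohort.columns:
            out[col] = cohort[col]
    out["dlp_mGycm"] = cohort["dlp_mGycm"]
    ed = ed_dlp(cohort["dlp_mGycm"].to_numpy(), k_body)
    out["ed_dlp_mSv"] = round_report(ed, 1) if rounded else ed
    ref = out["ed_dlp_mSv"].to_numpy()
    if "ed_mc_mSv" in cohort.columns:
        out["ed_mc_mSv"] = cohort["ed_mc_mSv"]
        k = k_mc(cohort["ed_mc_mSv"].to_numpy(), cohort["dlp_mGycm"].to_numpy())
        dev = relative_deviation(cohort["ed_mc_mSv"].to_numpy(), ref)
        out["k_mc"] = round_report(k, 3) if rounded else k
        out["dev_mc_pct"] = round_report(dev, 1) if rounded else dev
    if "ed_nci_mSv" in cohort.columns:
        out["ed_nci_mSv"] = cohort["ed_nci_mSv"]
        dev = relative_deviation(cohort["ed_nci_mSv"].to_numpy(), ref)
        out["dev_nci_pct"] = round_report(dev, 1) if rounded else dev
    return out
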