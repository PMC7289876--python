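"""Lifetime attributable risk (LAR) and excess relative risk (ERR).

BEIR VII tabulates the lifetime attributable risk of cancer mortality per
100,000 persons exposed to 100 mGy, by sex and age at exposure on a
decennial grid.  For a patient of age A_p between the anchor cohorts A_y
(younger, coefficient N_y) and A_y + 10 (older, N_o):

    LAR = (N_y - (N_y - N_o) * (A_p - A_y) / 10 y) * D / 100 mGy

i.e. linear interpolation in age and linear scaling in dose D.  Doses are
accepted in mSv, numerically equal to mGy for photons (W_R = 1).  The
whole-body estimate uses the all-solid-cancer mortality coefficients by
default and the whole-body effective dose ED_MC; per-site estimates use the
site's coefficients and, by default, the organ's equivalent dose (both
choices switchable).  ERR is LAR divided by the sex-specific baseline
lifetime solid-cancer mortality (female 17,500 / male 22,100 per 100,000),
reported as a percentage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._rounding import round_report
from .organ_dosimetry import OrganDoseTable

log = logging.getLogger("voxdose.risk_model")

__all__ = [
    "RiskCoefficientTable",
    "BaselineRates",
    "RiskEstimate",
    "lar",
    "err",
    "organ_lar",
    "whole_body_risk",
    "lar_report",
    "err_report",
    "ORGAN_TO_SITE",
    "DEFAULT_WHOLE_BODY_SITE",
]

#: BEIR VII site used for the whole-body estimate (see the methods note)
DEFAULT_WHOLE_BODY_SITE = "all_solid"

#: organ vocabulary -> BEIR VII cancer site; organs without a site yield no
#: per-site estimate (mirroring the blank cells of the reference tables)
ORGAN_TO_SITE: dict[str, str] = {
    "colon": "colon",
    "lung": "lung",
    "stomach": "stomach",
    "breast": "breast",
    "liver": "liver",
    "bladder": "bladder",
    "prostate": "prostate",
    "uterus": "uterus",
    "gonads": "ovary",  # female gonads; male testes have no BEIR VII site
    "red_bone_marrow": "leukemia",
}


@dataclass(frozen=True)
class BaselineRates:
    """Baseline lifetime solid-cancer mortality per 100,000 (US)."""

    female: float = 17500.0
    male: float = 22100.0

    def for_sex(self, sex: str) -> float:
        if sex not in ("female", "male"):
            raise ValueError(f"unknown sex {sex!r}")
        return self.female if sex == "female" else self.male


@dataclass
class RiskCoefficientTable:
    """LAR coefficients N (per 100,000 per 100 mGy) by sex, anchor age, site.

    ``reference_dose`` is the exposure the coefficients refer to (100 mGy).
    Ages outside the anchor span are clamped to the nearest anchor with a
    warning (configurable policy: "clamp" or "raise")."""

    data: pd.DataFrame
    reference_dose: float = 100.0
    age_policy: str = "clamp"

    def __post_init__(self):
        need = {"sex", "age_anchor", "site", "n_per_100k_at_100mGy"}
        if not need <= set(self.data.columns):
            raise ValueError(f"coefficient table must have columns {sorted(need)}")
        if (self.data["n_per_100k_at_100mGy"] < 0).any():
            raise ValueError("LAR coefficients must be non-negative")
        if self.age_policy not in ("clamp", "raise"):
            raise ValueError("age_policy must be 'clamp' or 'raise'")

    @classmethod
    def beir7(cls, age_policy: str = "clamp") -> "RiskCoefficientTable":
        """Packaged BEIR VII cancer-mortality coefficients (20-80 y anchors)."""
        with resources.as_file(
            resources.files("voxdose.data").joinpath("beir7_mortality.csv")
        ) as p:
            return cls(data=pd.read_csv(p), age_policy=age_policy)

    @classmethod
    def from_csv(cls, path, **kw) -> "RiskCoefficientTable":
        return cls(data=pd.read_csv(path), **kw)

    def sites(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["site"].unique()))

    def anchors(self, sex: str, site: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.data[(self.data["sex"] == sex) & (self.data["site"] == site)]
        if sel.empty:
            raise KeyError(f"no coefficients for site {site!r}, sex {sex!r}")
        sel = sel.sort_values("age_anchor")
        ages = sel["age_anchor"].to_numpy(dtype=float)
        if not np.all(np.diff(ages) > 0):
            raise ValueError("anchor ages must be strictly increasing")
        return ages, sel["n_per_100k_at_100mGy"].to_numpy(dtype=float)

    def coefficient(self, sex: str, site: str, age: float) -> float:
        """N at an arbitrary age: piecewise-linear between anchor cohorts."""
        ages, ns = self.anchors(sex, site)
        if age < ages[0] or age > ages[-1]:
            if self.age_policy == "raise":
                raise ValueError(
                    f"age {age} outside the coefficient span [{ages[0]}, {ages[-1]}]"
                )
            warnings.warn(
                f"age {age} outside anchor span [{ages[0]}, {ages[-1]}]; clamped",
                stacklevel=2,
            )
        return float(np.interp(age, ages, ns))


@dataclass(frozen=True)
class RiskEstimate:
    """Whole-body risk for one patient."""

    lar_mc: float  # per 100,000
    err_mc: float  # percent
    per_site: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lar_mc < 0 or self.err_mc < 0:
            raise ValueError("risk estimates must be non-negative")


def lar(
    age: float,
    sex: str,
    dose_mSv: float,
    site: str = DEFAULT_WHOLE_BODY_SITE,
    table: RiskCoefficientTable | None = None,
) -> float:
    """Lifetime attributable risk per 100,000: age-interpolated coefficient
    scaled linearly by dose / 100 mGy.  Exact at anchor ages; exactly linear
    in dose."""
    if dose_mSv < 0:
        raise ValueError("dose must be non-negative")
    table = table or _default_table()
    n = table.coefficient(sex, site, age)
    return n * dose_mSv / table.reference_dose


def err(
    lar_value: float, sex: str, baselines: BaselineRates | None = None
) -> float:
    """Excess relative risk (percent) = LAR / baseline lifetime mortality."""
    if lar_value < 0:
        raise ValueError("LAR must be non-negative")
    baselines = baselines or BaselineRates()
    return 100.0 * lar_value / baselines.for_sex(sex)


def organ_lar(
    organ_doses: OrganDoseTable,
    age: float,
    sex: str,
    table: RiskCoefficientTable | None = None,
    dose_quantity: str = "equivalent",
) -> dict[str, float]:
    """Per-site LAR for every organ with a BEIR VII site.

    ``dose_quantity`` selects the organ dose entering the risk formula:
    "equivalent" (default) or "effective".  Unmapped organs are skipped with
    a log notice."""
    col = {"equivalent": "equivalent_mSv", "effective": "effective_mSv"}.get(
        dose_quantity
    )
    if col is None:
        raise ValueError("dose_quantity must be 'equivalent' or 'effective'")
    table = table or _default_table()
    out: dict[str, float] = {}
    for organ, row in organ_doses.data.iterrows():
        site = ORGAN_TO_SITE.get(organ)
        if site is None:
            log.debug("organ %s has no cancer site mapping; skipped", organ)
            continue
        try:
            out[site] = lar(age, sex, float(row[col]), site=site, table=table)
        except KeyError:
            log.info("no %s coefficients for sex %s; organ %s skipped", site, sex, organ)
    return out


def whole_body_risk(
    organ_doses: OrganDoseTable,
    age: float,
    sex: str,
    table: RiskCoefficientTable | None = None,
    baselines: BaselineRates | None = None,
    whole_body_dose: str = "ed_mc",
) -> RiskEstimate:
    """LAR and ERR for one patient from an organ dose table.

    ``whole_body_dose`` selects the dose entering the whole-body formula:
    "ed_mc" (the effective-dose sum, default) or "mean_equivalent"."""
    if whole_body_dose == "ed_mc":
        dose = organ_doses.ed_mc
    elif whole_body_dose == "mean_equivalent":
        dose = float(organ_doses.data["equivalent_mSv"].mean())
    else:
        raise ValueError("whole_body_dose must be 'ed_mc' or 'mean_equivalent'")
    lar_v = lar(age, sex, dose, table=table)
    return RiskEstimate(
        lar_mc=lar_v,
        err_mc=err(lar_v, sex, baselines),
        per_site=organ_lar(organ_doses, age, sex, table=table),
    )


def lar_report(lar_value: float) -> int:
    """LAR rounded to whole persons per 100,000 (report convention)."""
    return int(round_report(lar_value, 0))


def err_report(err_value: float) -> float:
    """ERR as a 2-decimal percentage (report convention)."""
    return float(round_report(err_value, 2))


_TABLE_CACHE: RiskCoefficientTable | None = None


def _default_table() -> RiskCoefficientTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = RiskCoefficientTable.beir7()
    return _TABLE_CACHE
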