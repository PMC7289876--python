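"""Organ-level dose aggregation.

Takes a per-voxel absorbed-dose grid and an organ label map and produces, per
organ: mean absorbed dose (mGy), equivalent dose (mSv, radiation weighting
factor W_R = 1 for photons), effective organ dose (mSv, ICRP-103 tissue
weighting factor W_T) and the fractional contribution of each organ to the
whole-body effective dose.  The whole-body effective dose ED_MC is the sum of
the effective organ doses over the organs actually present in the label map:
missing organs (aplasia, resection, sex) contribute nothing and are reported
as absent rather than imputed.

The tissue weighting factors follow the per-organ convention of the source
dose tables: each of the 13 remainder tissues carries its own W_T of 0.0092
instead of a collective remainder term, and thymus is not part of the
vocabulary.  Breast and uterus are female-only, prostate male-only; testes
and ovaries are both subsumed under a single "gonads" entry (W_T = 0.08).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._rounding import round_report

__all__ = [
    "OrganMissingError",
    "WeightingTables",
    "OrganDoseTable",
    "ORGAN_SEX",
    "ORGANS",
    "organ_mean_dose",
    "equivalent_dose",
    "effective_organ_dose",
    "total_effective_dose",
    "organ_contribution",
    "build_organ_dose_table",
    "organs_for_sex",
    "load_organ_reference",
    "write_table_csv",
    "write_table_json",
]


class OrganMissingError(KeyError):
    """Raised when an organ is requested that has no voxels in the label map.

    Absence is a meaningful anatomical state (aplasia, resection, wrong sex),
    so it is signalled explicitly instead of being treated as zero dose."""


def _data_path(name: str):
    return resources.files("voxdose.data").joinpath(name)


def _load_weights() -> pd.DataFrame:
    with resources.as_file(_data_path("tissue_weights.csv")) as p:
        return pd.read_csv(p)


_WEIGHTS = _load_weights()

#: organ name -> sex restriction ("both", "female", "male")
ORGAN_SEX: dict[str, str] = dict(zip(_WEIGHTS["organ"], _WEIGHTS["sex"]))

#: full organ vocabulary (27 classes)
ORGANS: tuple[str, ...] = tuple(_WEIGHTS["organ"])


def organs_for_sex(sex: str) -> tuple[str, ...]:
    """Organ vocabulary applicable to one sex (26 female / 25 male)."""
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex {sex!r}")
    return tuple(o for o, s in ORGAN_SEX.items() if s in ("both", sex))


@dataclass(frozen=True)
class WeightingTables:
    """Radiation (W_R) and tissue (W_T) weighting factors.

    W_R is 1 for photons.  ``w_t`` maps organ name to its ICRP-103 tissue
    weighting factor, restricted to the organs applicable to ``sex`` when a
    sex is given."""

    w_r: float = 1.0
    w_t: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.w_r != 1.0:
            raise ValueError("radiation weighting factor for photons is 1")

    @classmethod
    def icrp103(cls, sex: str | None = None) -> "WeightingTables":
        df = _WEIGHTS
        if sex is not None:
            if sex not in ("female", "male"):
                raise ValueError(f"unknown sex {sex!r}")
            df = df[df["sex"].isin(["both", sex])]
        return cls(w_r=1.0, w_t=dict(zip(df["organ"], df["w_t"])))


@dataclass
class OrganDoseTable:
    """Per-organ dose table plus whole-body effective dose.

    ``data`` has one row per present organ with columns ``absorbed_mGy``,
    ``equivalent_mSv``, ``effective_mSv`` and ``contribution``; ``ed_mc`` is
    the whole-body effective dose (mSv); ``missing`` lists vocabulary organs
    absent from the label map."""

    data: pd.DataFrame
    ed_mc: float
    missing: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(self.data.index)


def _dose_grid(dose_map) -> np.ndarray:
    """Accept a DoseMap (uses absorbed dose) or a plain ndarray."""
    grid = getattr(dose_map, "absorbed_dose", dose_map)
    if grid is None:
        raise ValueError("dose map has no absorbed dose; scale it first")
    return np.asarray(grid, dtype=float)


def organ_mean_dose(dose_map, labels: np.ndarray, organ, label_map=None) -> float:
    """Mean absorbed dose (mGy) over the voxels of one organ.

    ``organ`` is either an integer label or an organ name, in which case
    ``label_map`` (name -> integer label) is required.  Raises
    :class:`OrganMissingError` if the organ has no voxels."""
    grid = _dose_grid(dose_map)
    labels = np.asarray(labels)
    if grid.shape != labels.shape:
        raise ValueError("dose grid and label map differ in shape")
    if isinstance(organ, str):
        if label_map is None or organ not in label_map:
            raise OrganMissingError(organ)
        lab = label_map[organ]
    else:
        lab = int(organ)
    mask = labels == lab
    n = int(mask.sum())
    if n == 0:
        raise OrganMissingError(f"organ {organ!r} has no voxels in the label map")
    return float(grid[mask].sum() / n)


def equivalent_dose(absorbed: float, w_r: float = 1.0) -> float:
    """Equivalent dose (mSv) = absorbed dose (mGy) x W_R; identity for photons."""
    absorbed = np.asarray(absorbed, dtype=float)
    if np.any(absorbed < 0):
        raise ValueError("absorbed dose must be non-negative")
    out = absorbed * w_r
    return float(out) if out.ndim == 0 else out


def effective_organ_dose(equivalent: float, organ: str, tables: WeightingTables) -> float:
    """Effective organ dose (mSv) = equivalent dose x W_T(organ)."""
    if organ not in tables.w_t:
        raise KeyError(f"organ {organ!r} not in weighting tables")
    return float(equivalent) * tables.w_t[organ]


def total_effective_dose(table: OrganDoseTable) -> float:
    """Whole-body effective dose ED_MC: sum of effective organ doses."""
    if len(table) == 0:
        raise ValueError("empty organ dose table")
    return float(table.data["effective_mSv"].sum())


def organ_contribution(table: OrganDoseTable) -> pd.Series:
    """Fraction C of ED_MC contributed by each organ (sums to 1)."""
    ed = total_effective_dose(table)
    if ed <= 0:
        raise ValueError("organ contributions undefined for ED_MC = 0")
    return table.data["effective_mSv"] / ed


def build_organ_dose_table(
    dose_map,
    labels: np.ndarray,
    label_map: Mapping[str, int],
    sex: str,
    tables: WeightingTables | None = None,
) -> OrganDoseTable:
    """Aggregate a dose map into an :class:`OrganDoseTable` for one patient.

    Organs in the sex-appropriate vocabulary that are absent from the label
    map are recorded in ``missing``; ED_MC sums over present organs only."""
    if tables is None:
        tables = WeightingTables.icrp103(sex)
    rows, missing = {}, []
    for organ in organs_for_sex(sex):
        if organ not in tables.w_t:
            continue
        try:
            absorbed = organ_mean_dose(dose_map, labels, organ, label_map)
        except OrganMissingError:
            missing.append(organ)
            continue
        eq = equivalent_dose(absorbed, tables.w_r)
        rows[organ] = (absorbed, eq, effective_organ_dose(eq, organ, tables))
    if not rows:
        raise ValueError("no vocabulary organ present in the label map")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["absorbed_mGy", "equivalent_mSv", "effective_mSv"]
    )
    table = OrganDoseTable(data=df, ed_mc=float(df["effective_mSv"].sum()), missing=tuple(missing))
    df["contribution"] = organ_contribution(table)
    return table


def load_organ_reference() -> pd.DataFrame:
    """Packaged cohort-mean organ dose reference table (printed values)."""
    with resources.as_file(_data_path("organ_dose_reference.csv")) as p:
        return pd.read_csv(p, index_col="organ")


def write_table_csv(table: OrganDoseTable, path) -> None:
    """Report CSV: doses at 1 decimal, contributions at 3 decimals."""
    out = pd.DataFrame(
        {
            "absorbed_mGy": round_report(table.data["absorbed_mGy"].to_numpy(), 1),
            "equivalent_mSv": round_report(table.data["equivalent_mSv"].to_numpy(), 1),
            "effective_mSv": round_report(table.data["effective_mSv"].to_numpy(), 2),
            "contribution": round_report(table.data["contribution"].to_numpy(), 3),
        },
        index=table.data.index,
    )
    out.index.name = "organ"
    out.to_csv(path)


def write_table_json(table: OrganDoseTable, path) -> None:
    """Full-precision JSON variant of the organ dose table."""
    payload = {
        "ed_mc_mSv": table.ed_mc,
        "missing_organs": list(table.missing),
        "organs": {
            o: {k: float(v) for k, v in row.items()}
            for o, row in table.data.to_dict(orient="index").items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
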