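"""Synthetic study cohort: patients, voxel phantoms and scanner reports.

No imaging data is deposited with the source study, so this module emulates
its inputs with the statistical structure the downstream analysis assumes:

* patient demographics drawn from the study collective's distributions
  (female fraction 0.227, age 57.3 +/- 14.3 y, sex-specific BMI);
* stylized voxel phantoms - geometric organs (ellipsoids, tubes, shells)
  positioned inside a body ellipse, with plausible Hounsfield units per
  tissue class, hollow organs labelled on wall voxels only, sex-conditional
  anatomy, and support for omitting named organs (aplasia / resection);
* a tube-current-modulation emulator: effective mAs grows exponentially with
  BMI between the calibration anchors (86 mAs at BMI 21.6, 165 mAs at
  BMI 40.0), CTDIvol is proportional to effective mAs, and
  DLP = CTDIvol x scan length with scan length a fixed fraction of height
  (head to mid-femur).

The printed 22-patient cohort table ships as package data and is loaded with
:func:`load_cohort_table` / :func:`load_packaged_cohort`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("voxdose.synthetic_cohort")

__all__ = [
    "PatientRecord",
    "ScanParameters",
    "ScannerReport",
    "CohortSpec",
    "VoxelPhantom",
    "PhantomError",
    "CohortValidationError",
    "generate_patient",
    "generate_cohort",
    "generate_phantom",
    "emulate_scanner_report",
    "scan_parameters_for",
    "load_cohort_table",
    "load_packaged_cohort",
    "save_phantom",
    "load_phantom",
]

# ---------------------------------------------------------------------------
# calibration constants (anchored to the packaged cohort table)
# ---------------------------------------------------------------------------

#: effective mAs at the BMI reference point (cohort row: 86 mAs at BMI 21.6)
MAS_ANCHOR = 86.0
MAS_BMI0 = 21.6
#: exponential slope, from the two anchor rows (165 mAs at BMI 40.0)
MAS_SLOPE = float(np.log(165.0 / 86.0) / (40.0 - 21.6))
#: CTDIvol per effective mAs at 120 kV, least squares through the origin on
#: the packaged cohort table (residual SD 1.28 mGy; the table's ratio is not
#: constant, see the methods note)
CTDI_PER_MAS = 0.0713
#: head-to-mid-femur scan length as a fraction of body height, fit from the
#: packaged table via DLP/CTDIvol against height implied by weight and BMI
SCAN_FRACTION = 0.64
#: free-in-air kerma at the isocenter for the reference technique
AIR_KERMA_REF = 18.3  # mGy
#: effective mAs the reference air kerma corresponds to (cohort mean)
AIR_KERMA_REF_MAS = 112.6
#: multiplicative log-normal noise on the tube-current modulation
MAS_NOISE_SIGMA = 0.05


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, demographics and body habitus."""

    id: str
    age: float  # years
    sex: str  # "female" | "male"
    weight: float  # kg
    bmi: float  # kg/m^2
    height: float | None = None  # cm

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.weight <= 0 or self.bmi <= 0:
            raise ValueError("weight and BMI must be positive")
        if self.height is not None:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.5:
                raise ValueError(
                    f"BMI {self.bmi} inconsistent with weight/height (implies {implied:.1f})"
                )

    @property
    def height_cm(self) -> float:
        """Height in cm; reconstructed from weight and BMI when not recorded."""
        if self.height is not None:
            return self.height
        return 100.0 * float(np.sqrt(self.weight / self.bmi))


@dataclass(frozen=True)
class ScanParameters:
    """Helical CT acquisition parameters (protocol defaults of the study)."""

    tube_voltage: float = 120.0  # kV
    reference_mAs: float = 170.0
    effective_mAs: float = 112.6
    pitch: float = 0.8
    rotation_time: float = 0.5  # s
    collimation: float = 19.2  # mm (32 x 0.6 mm)
    scan_length: float = 110.0  # cm
    air_kerma: float = AIR_KERMA_REF  # mGy, free in air at the isocenter

    def __post_init__(self):
        for name in (
            "tube_voltage",
            "reference_mAs",
            "effective_mAs",
            "pitch",
            "rotation_time",
            "collimation",
            "scan_length",
            "air_kerma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ScannerReport:
    """Dose quantities the scanner console reports for one examination."""

    ctdi_vol: float  # mGy
    dlp: float  # mGy cm
    effective_mAs: float

    def __post_init__(self):
        if min(self.ctdi_vol, self.dlp, self.effective_mAs) <= 0:
            raise ValueError("scanner report quantities must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters of the emulated study collective."""

    female_fraction: float = 0.227
    age_mean: float = 57.3
    age_sd: float = 14.3
    age_range: tuple[float, float] = (18.0, 90.0)
    bmi_female: tuple[float, float] = (21.2, 2.5)  # mean, sd
    bmi_male: tuple[float, float] = (27.4, 5.88)
    bmi_range: tuple[float, float] = (15.0, 45.0)
    height_female: tuple[float, float] = (163.0, 6.0)  # cm
    height_male: tuple[float, float] = (176.0, 7.0)

    def __post_init__(self):
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.age_sd <= 0 or self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("invalid age specification")
        for lo_hi in (self.bmi_female, self.bmi_male, self.height_female, self.height_male):
            if min(lo_hi) <= 0:
                raise ValueError("distribution parameters must be positive")
        if self.bmi_range[0] <= 0 or self.bmi_range[1] <= self.bmi_range[0]:
            raise ValueError("invalid BMI range")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kw)


class PhantomError(ValueError):
    """Phantom construction failed (e.g. resolution too small for anatomy)."""


class CohortValidationError(ValueError):
    """A cohort table row violates the schema (reported with its row index)."""


@dataclass
class VoxelPhantom:
    """Voxelized patient: HU grid, organ label map and geometry.

    Axis order is (x, y, z) with z the table-feed (cranio-caudal) axis;
    ``spacing`` is mm per axis, ``origin`` the world position (mm) of the
    voxel (0,0,0) center.  ``label_map`` maps organ names to the integer
    labels used in ``labels``; label 0 is background / unlabelled tissue."""

    hu: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[str, int] = field(default_factory=dict)
    sex: str = "male"
    patient_id: str = ""

    def __post_init__(self):
        if self.hu.shape != self.labels.shape:
            raise ValueError("hu and labels grids must be congruent")
        if np.any(self.hu < -1000):
            raise ValueError("HU below -1000 are not physical")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.label_map.values())
        if not present <= known:
            raise ValueError(f"labels outside the organ vocabulary: {present - known}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def organ_mask(self, organ: str) -> np.ndarray:
        return self.labels == self.label_map[organ]

    def present_organs(self) -> tuple[str, ...]:
        counts = np.bincount(self.labels.ravel())
        return tuple(
            name
            for name, lab in self.label_map.items()
            if lab < len(counts) and counts[lab] > 0
        )


# ---------------------------------------------------------------------------
# patient generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_patient(seed: int, spec: CohortSpec | None = None) -> PatientRecord:
    """Draw one patient from the cohort distribution; deterministic in seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    sex = "female" if rng.random() < spec.female_fraction else "male"
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range)
    h_mean, h_sd = spec.height_female if sex == "female" else spec.height_male
    height = _truncated_normal(rng, h_mean, h_sd, h_mean - 3 * h_sd, h_mean + 3 * h_sd)
    b_mean, b_sd = spec.bmi_female if sex == "female" else spec.bmi_male
    bmi = _truncated_normal(rng, b_mean, b_sd, *spec.bmi_range)
    weight = round(bmi * (height / 100.0) ** 2, 1)
    bmi = weight / (height / 100.0) ** 2
    return PatientRecord(
        id=f"SYN{seed % 10**8:08d}",
        age=round(age, 1),
        sex=sex,
        weight=weight,
        bmi=bmi,
        height=round(height, 1),
    )


def generate_cohort(n: int, seed: int, spec: CohortSpec | None = None) -> list[PatientRecord]:
    """Generate ``n`` patients with independent per-patient sub-seeds."""
    root = np.random.default_rng(seed)
    subs = root.integers(0, 2**31 - 1, size=n)
    return [
        replace(generate_patient(int(s), spec), id=f"SYN{i:04d}")
        for i, s in enumerate(subs)
    ]


# ---------------------------------------------------------------------------
# scanner-report emulation
# ---------------------------------------------------------------------------


def expected_effective_mas(bmi: float) -> float:
    """Noise-free tube-current modulation curve (monotone increasing in BMI)."""
    return MAS_ANCHOR * float(np.exp(MAS_SLOPE * (bmi - MAS_BMI0)))


def emulate_scanner_report(
    patient: PatientRecord,
    scan: ScanParameters | None = None,
    seed: int = 0,
) -> ScannerReport:
    """Emulate the console dose report for one patient.

    Effective mAs follows the BMI modulation curve with multiplicative
    log-normal noise; CTDIvol is proportional to effective mAs at fixed kV;
    DLP = CTDIvol x scan length with scan length derived from height."""
    scan = scan or ScanParameters()
    rng = np.random.default_rng(seed)
    noise = float(np.exp(rng.normal(0.0, MAS_NOISE_SIGMA)))
    eff_mas = expected_effective_mas(patient.bmi) * noise
    kv_factor = (scan.tube_voltage / 120.0) ** 2.5
    ctdi = CTDI_PER_MAS * eff_mas * kv_factor
    scan_length = SCAN_FRACTION * patient.height_cm
    return ScannerReport(
        ctdi_vol=round(ctdi, 2),
        dlp=round(ctdi * scan_length, 0),
        effective_mAs=round(eff_mas, 0),
    )


def scan_parameters_for(
    patient: PatientRecord,
    report: ScannerReport,
    base: ScanParameters | None = None,
) -> ScanParameters:
    """Scan parameters for one examination, with the free-in-air kerma scaled
    in proportion to the effective mAs of the report (kerma is linear in tube
    output at fixed kV)."""
    base = base or ScanParameters()
    return replace(
        base,
        effective_mAs=report.effective_mAs,
        scan_length=report.dlp / report.ctdi_vol,
        air_kerma=AIR_KERMA_REF * report.effective_mAs / AIR_KERMA_REF_MAS,
    )


# ---------------------------------------------------------------------------
# stylized phantom geometry
# ---------------------------------------------------------------------------

# (name, kind, params, nominal HU); centers as (dx_cm, dy_cm, fz) with dx/dy
# lateral/anterior offsets from the body axis in cm at reference BMI 26 and
# fz the fraction of the scanned length (0 = mid-femur, 1 = vertex).
# kind: "ellipsoid", "shell" (hollow: wall voxels only), "pair" (mirrored),
# "pair_shell".  Sizes are semi-axes in cm at reference BMI 26.
_ORGAN_SHAPES: list[tuple] = [
    # trunk bulk structures first; later entries overwrite earlier ones
    ("lung", "pair", (8.0, 0.5, 0.705, 5.2, 7.0, 10.5), -700.0),
    ("liver", "ellipsoid", (6.5, 1.5, 0.575, 8.0, 6.0, 6.5), 95.0),
    ("colon", "shell", (0.0, 1.0, 0.41, 9.5, 5.5, 6.5, 0.72), 30.0),
    ("small_intestine", "shell", (0.0, 0.5, 0.405, 6.2, 3.6, 4.4, 0.55), 30.0),
    ("stomach", "shell", (-5.0, 3.5, 0.595, 5.0, 4.0, 4.5, 0.6), 35.0),
    ("heart", "ellipsoid", (1.5, 2.8, 0.69, 5.2, 4.8, 4.8), 45.0),
    ("brain", "ellipsoid", (0.0, 0.0, 0.945, 6.5, 7.5, 5.2), 38.0),
    ("spleen", "ellipsoid", (-8.5, -2.0, 0.57, 3.5, 3.0, 4.0), 90.0),
    ("kidney", "pair", (6.0, -3.4, 0.50, 3.0, 2.6, 4.8), 180.0),
    ("bladder", "shell", (0.0, 1.5, 0.265, 3.5, 3.2, 3.0, 0.55), 20.0),
    ("pancreas", "ellipsoid", (-1.5, 1.0, 0.52, 6.0, 1.8, 1.8), 50.0),
    ("salivary_glands", "ellipsoid", (0.0, 1.5, 0.875, 4.5, 2.0, 1.6), 55.0),
    ("thyroid", "ellipsoid", (0.0, 2.5, 0.815, 2.4, 1.2, 1.6), 200.0),
    ("esophagus", "ellipsoid", (0.0, -3.0, 0.70, 1.0, 1.0, 8.5), 40.0),
    ("gall_bladder", "shell", (4.0, 4.5, 0.545, 2.2, 2.0, 2.4, 0.5), 25.0),
    ("adrenal_gland", "pair", (5.5, -3.0, 0.545, 1.7, 1.3, 1.5), 35.0),
    ("oral_mucosa", "ellipsoid", (0.0, 4.0, 0.885, 2.6, 1.6, 1.3), 45.0),
    ("et_region", "ellipsoid", (0.0, 2.0, 0.845, 1.6, 1.6, 3.2), 80.0),
    ("lymph_nodes", "pair", (4.5, 1.5, 0.44, 1.4, 1.2, 1.6), 45.0),
]

# sex-conditional shapes
_FEMALE_SHAPES: list[tuple] = [
    ("breast", "pair", (7.2, None, 0.705, 4.4, 3.0, 4.0), -40.0),  # dy set to front wall
    ("uterus", "ellipsoid", (0.0, -0.5, 0.285, 3.0, 2.5, 3.5), 50.0),
    ("gonads", "pair", (3.5, 0.5, 0.30, 1.5, 1.2, 1.5), 45.0),  # ovaries
]
_MALE_SHAPES: list[tuple] = [
    ("prostate", "ellipsoid", (0.0, 0.2, 0.225, 2.2, 2.0, 2.0), 45.0),
    ("gonads", "ellipsoid", (0.0, 2.0, 0.195, 2.2, 1.6, 2.0), 40.0),  # testes
]

_HU_SOFT = -70.0  # unlabelled body tissue (adipose / connective)
_HU_SKIN = 30.0
_HU_MUSCLE = 50.0
_HU_CORTICAL = 1100.0
_HU_MARROW = 140.0

MIN_RESOLUTION = 16


def _erode(mask: np.ndarray, n: int = 1) -> np.ndarray:
    """Binary erosion with a 6-neighbour cross, applied ``n`` times."""
    out = mask
    for _ in range(n):
        m = out
        out = m.copy()
        out[1:, :, :] &= m[:-1, :, :]
        out[:-1, :, :] &= m[1:, :, :]
        out[:, 1:, :] &= m[:, :-1, :]
        out[:, :-1, :] &= m[:, 1:, :]
        out[:, :, 1:] &= m[:, :, :-1]
        out[:, :, :-1] &= m[:, :, 1:]
    return out


def generate_phantom(
    patient: PatientRecord,
    resolution: int = 64,
    seed: int = 0,
    omit: Sequence[str] = (),
) -> VoxelPhantom:
    """Build a stylized voxel phantom for one patient.

    ``resolution`` is the voxel count per axis (>= 16).  ``omit`` names
    organs to leave out (emulating aplasia or surgical resection).  Geometry
    and HU are jittered per seed; the organ class inventory is seed-invariant.
    Raises :class:`PhantomError` if the grid is too coarse to place every
    expected organ."""
    from .organ_dosimetry import ORGANS, organs_for_sex  # local: avoid cycle at import

    if resolution < MIN_RESOLUTION:
        raise PhantomError(f"resolution {resolution} < minimum {MIN_RESOLUTION}")
    unknown = set(omit) - set(ORGANS)
    if unknown:
        raise PhantomError(f"cannot omit unknown organs: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = int(resolution)

    height = patient.height_cm
    length = SCAN_FRACTION * height  # cm, scanned extent
    ax = 3.6 * float(np.sqrt(patient.bmi))  # trunk lateral half-axis, cm
    ay = 0.72 * ax
    size_scale = (patient.bmi / 26.0) ** (1.0 / 3.0)

    fov_x, fov_y = 2.4 * ax, 2.6 * ay
    dx, dy, dz = fov_x / n, fov_y / n, length / n
    xs = (np.arange(n) + 0.5) * dx - fov_x / 2.0
    ys = (np.arange(n) + 0.5) * dy - fov_y / 2.0
    zs = (np.arange(n) + 0.5) * dz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    FZ = Z / length

    # --- body envelope -----------------------------------------------------
    head_a, head_b = 7.8 * size_scale**0.3, 9.5 * size_scale**0.3
    neck_r = 5.5 * size_scale**0.5
    thigh_r = 0.36 * ax
    body = np.zeros((n, n, n), dtype=bool)
    trunk = (FZ >= 0.18) & (FZ < 0.80) & ((X / ax) ** 2 + (Y / ay) ** 2 <= 1.0)
    neck = (FZ >= 0.80) & (FZ < 0.87) & (X**2 + Y**2 <= neck_r**2)
    head = (
        (FZ >= 0.87)
        & ((X / head_a) ** 2 + (Y / head_b) ** 2
           + ((FZ - 0.935) * length / (0.075 * length)) ** 2 <= 1.0)
    )
    thighs = (FZ < 0.18) & (
        ((X - 0.45 * ax) ** 2 + Y**2 <= thigh_r**2)
        | ((X + 0.45 * ax) ** 2 + Y**2 <= thigh_r**2)
    )
    body = trunk | neck | head | thighs
    if not body.any():
        raise PhantomError("degenerate anatomy: empty body mask")

    hu = np.full((n, n, n), -1000.0, dtype=np.float32)
    labels = np.zeros((n, n, n), dtype=np.uint8)
    hu[body] = _HU_SOFT

    label_map = {name: i + 1 for i, name in enumerate(ORGANS)}
    expected = [o for o in organs_for_sex(patient.sex) if o not in omit]

    def jhu(nominal: float) -> float:
        return float(nominal * rng.uniform(0.9, 1.1))

    # skin: outer rind; muscle: next rind inside it
    core1 = _erode(body, 1)
    core2 = _erode(body, 2)
    if "skin" in expected:
        skin = body & ~core1
        labels[skin] = label_map["skin"]
        hu[skin] = jhu(_HU_SKIN)
    if "muscle" in expected:
        muscle = core1 & ~core2
        labels[muscle] = label_map["muscle"]
        hu[muscle] = jhu(_HU_MUSCLE)

    # spine: posterior cylinder through the trunk; cortical shell = bone
    # surface, core = red bone marrow
    spine_y = -0.62 * ay
    r_out, r_in = 2.3 * size_scale, 1.45 * size_scale
    in_spine_z = (FZ >= 0.30) & (FZ < 0.80)
    r2 = X**2 + (Y - spine_y) ** 2
    if "bone_surface" in expected:
        shell = in_spine_z & (r2 <= r_out**2) & (r2 > r_in**2) & body
        labels[shell] = label_map["bone_surface"]
        hu[shell] = jhu(_HU_CORTICAL)
    if "red_bone_marrow" in expected:
        core = in_spine_z & (r2 <= r_in**2) & body
        labels[core] = label_map["red_bone_marrow"]
        hu[core] = jhu(_HU_MARROW)

    shapes = list(_ORGAN_SHAPES) + (
        list(_FEMALE_SHAPES) if patient.sex == "female" else list(_MALE_SHAPES)
    )

    centers: dict[str, tuple[int, int, int]] = {}
    organ_hu: dict[str, float] = {}

    def paint(name, kind, params, nominal_hu):
        if name not in expected:
            return
        cx, cy, fz0, a, b, c = params[:6]
        mirror = [1] if kind in ("ellipsoid", "shell") else [1, -1]
        inner = params[6] if len(params) > 6 else None
        if cy is None:  # anterior wall attachment (breast)
            cy = 0.82 * ay
        a, b, c = (s * size_scale * rng.uniform(0.95, 1.05) for s in (a, b, c))
        val = jhu(nominal_hu)
        organ_hu[name] = val
        lab = label_map[name]
        for m in mirror:
            jx = rng.uniform(-0.02, 0.02) * ax
            jy = rng.uniform(-0.02, 0.02) * ay
            jz = rng.uniform(-0.01, 0.01)
            cxm = m * cx * size_scale + jx
            cym = cy * size_scale**0.5 + jy
            cz = (fz0 + jz) * length
            q = ((X - cxm) / a) ** 2 + ((Y - cym) / b) ** 2 + ((Z - cz) / c) ** 2
            mask = (q <= 1.0) & body
            if inner is not None and kind in ("shell", "pair_shell"):
                mask &= q > inner**2
            labels[mask] = lab
            hu[mask] = val
            if m == 1:
                centers[name] = (
                    int(np.clip((cxm + fov_x / 2) / dx, 0, n - 1)),
                    int(np.clip((cym + fov_y / 2) / dy, 0, n - 1)),
                    int(np.clip(cz / dz, 0, n - 1)),
                )

    for entry in shapes:
        paint(*entry)

    # repair pass: on coarse grids a small organ's analytic shape (or its
    # single fallback voxel) may have been swallowed by a neighbour; give
    # every expected organ at least its center voxel back, stealing only
    # from background or from organs that keep other voxels
    counts = np.bincount(labels.ravel(), minlength=len(ORGANS) + 1)
    for name in expected:
        lab = label_map[name]
        if counts[lab] > 0 or name not in centers:
            continue
        ci, cj, ck = centers[name]
        placed = False
        for di, dj, dk in sorted(
            np.ndindex(3, 3, 3), key=lambda t: abs(t[0] - 1) + abs(t[1] - 1) + abs(t[2] - 1)
        ):
            i, j, k = ci + di - 1, cj + dj - 1, ck + dk - 1
            if not (0 <= i < n and 0 <= j < n and 0 <= k < n) or not body[i, j, k]:
                continue
            occ = int(labels[i, j, k])
            if occ == 0 or counts[occ] > 1:
                if occ:
                    counts[occ] -= 1
                labels[i, j, k] = lab
                hu[i, j, k] = organ_hu.get(name, _HU_SOFT)
                counts[lab] += 1
                placed = True
                break
        if not placed:
            break  # reported by the final inventory check below

    # mild CT noise inside the body; air stays exactly -1000
    hu[body] += rng.normal(0.0, 10.0, size=int(body.sum())).astype(np.float32)
    np.clip(hu, -1000.0, None, out=hu)

    phantom = VoxelPhantom(
        hu=hu,
        labels=labels,
        spacing=(dx * 10.0, dy * 10.0, dz * 10.0),
        label_map=label_map,
        sex=patient.sex,
        patient_id=patient.id,
    )
    present = set(phantom.present_organs())
    missing = [o for o in expected if o not in present]
    if missing:
        raise PhantomError(
            f"resolution {resolution} too small to place organs: {missing}"
        )
    return phantom


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["id", "age_y", "sex", "weight_kg", "bmi", "dlp_mGycm"]
_DOSE_COLUMNS = ["ed_dlp_mSv", "ed_nci_mSv", "ed_mc_mSv"]


def load_cohort_table(path) -> pd.DataFrame:
    """Read a cohort CSV and validate it row by row.

    Returns a DataFrame with one row per patient.  Missing optional columns
    are tolerated; malformed rows raise :class:`CohortValidationError` naming
    the row index; non-positive DLP and negative doses are rejected."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_REQUIRED_COLUMNS + _DOSE_COLUMNS)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    for idx, row in df.iterrows():
        if row["sex"] not in ("female", "male"):
            raise CohortValidationError(f"row {idx}: unknown sex {row['sex']!r}")
        for col in ("age_y", "weight_kg", "bmi", "dlp_mGycm"):
            v = row[col]
            if not np.isfinite(v) or v <= 0:
                raise CohortValidationError(f"row {idx}: {col} must be positive, got {v}")
        for col in _DOSE_COLUMNS + ["ctdi_vol_mGy", "eff_mas", "k_mc", "lar_per_100k"]:
            if col in df.columns:
                v = row[col]
                if pd.notna(v) and v < 0:
                    raise CohortValidationError(f"row {idx}: negative {col} = {v}")
    return df


def load_packaged_cohort() -> pd.DataFrame:
    """The printed 22-patient cohort table shipped with the package."""
    with resources.as_file(
        resources.files("voxdose.data").joinpath("cohort_table.csv")
    ) as p:
        return load_cohort_table(p)


def cohort_records(df: pd.DataFrame) -> list[tuple[PatientRecord, ScannerReport, dict]]:
    """Split a cohort table into typed records: (patient, report, dose columns)."""
    out = []
    for _, row in df.iterrows():
        patient = PatientRecord(
            id=str(row["id"]),
            age=float(row["age_y"]),
            sex=str(row["sex"]),
            weight=float(row["weight_kg"]),
            bmi=float(row["bmi"]),
        )
        report = ScannerReport(
            ctdi_vol=float(row.get("ctdi_vol_mGy", np.nan))
            if pd.notna(row.get("ctdi_vol_mGy", np.nan))
            else row["dlp_mGycm"] / 100.0,
            dlp=float(row["dlp_mGycm"]),
            effective_mAs=float(row.get("eff_mas", np.nan))
            if pd.notna(row.get("eff_mas", np.nan))
            else 100.0,
        )
        doses = {
            c: float(row[c])
            for c in df.columns
            if c not in _REQUIRED_COLUMNS and pd.notna(row[c])
        }
        out.append((patient, report, doses))
    return out


# ---------------------------------------------------------------------------
# phantom file I/O (NIfTI + sidecar organ vocabulary)
# ---------------------------------------------------------------------------


def save_phantom(phantom: VoxelPhantom, prefix: str) -> None:
    """Write ``<prefix>_hu.nii.gz``, ``<prefix>_labels.nii.gz`` and a JSON
    sidecar with the organ vocabulary and patient metadata."""
    import nibabel as nib

    affine = np.diag(list(phantom.spacing) + [1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(phantom.hu.astype(np.float32), affine), f"{prefix}_hu.nii.gz")
    nib.save(
        nib.Nifti1Image(phantom.labels.astype(np.uint16), affine),
        f"{prefix}_labels.nii.gz",
    )
    with open(f"{prefix}_organs.json", "w") as fh:
        json.dump(
            {
                "label_map": phantom.label_map,
                "sex": phantom.sex,
                "patient_id": phantom.patient_id,
            },
            fh,
            indent=2,
        )


def load_phantom(prefix: str) -> VoxelPhantom:
    import nibabel as nib

    img_hu = nib.load(f"{prefix}_hu.nii.gz")
    img_lab = nib.load(f"{prefix}_labels.nii.gz")
    with open(f"{prefix}_organs.json") as fh:
        meta = json.load(fh)
    spacing = tuple(float(v) for v in img_hu.header.get_zooms()[:3])
    return VoxelPhantom(
        hu=np.asarray(img_hu.dataobj, dtype=np.float32),
        labels=np.asarray(img_lab.dataobj, dtype=np.uint8),
        spacing=spacing,
        origin=tuple(float(v) for v in img_hu.affine[:3, 3]),
        label_map={k: int(v) for k, v in meta["label_map"].items()},
        sex=meta["sex"],
        patient_id=meta["patient_id"],
    )
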