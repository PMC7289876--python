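"""Simplified helical-CT Monte Carlo photon transport on a voxel grid.

This is a deliberately simple, verifiable transport model, not a clinical
dose engine.  Physics scope:

* photons only, kerma approximation: energy is deposited at the interaction
  site, secondary electrons are not transported;
* photoelectric absorption and incoherent (Klein-Nishina) scatter; no
  coherent scatter, no bowtie filter, no heel effect;
* monoenergetic effective beam (64 keV standing in for a 120 kVp spectrum)
  by default, optionally a 3-bin spectrum;
* point source on a helix around the table-feed axis, fan confined to the
  phantom; overranging is not modelled (a single spiral covering the whole
  imaged volume makes it negligible).

Attenuation is derived from Hounsfield units via a two-segment material
model: below HU = 100 the voxel is water-like with density 1 + HU/1000;
above, density and composition ramp linearly toward cortical bone
(HU 1800, density 1.92 g/cm3).  Mass attenuation coefficients for water and
cortical bone and mass energy-absorption coefficients for air are tabulated
from the NIST XCOM/X-ray tables at 10-150 keV and interpolated log-log.

Relative dose is normalized so that the free-in-air air-kerma reference at
the isocenter equals 1; multiplying by the scanner's air kerma (mGy) yields
absorbed dose per voxel.  Per-voxel statistical uncertainty is estimated by
the batch method over 10 batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .synthetic_cohort import ScanParameters, VoxelPhantom

log = logging.getLogger("voxdose.mc_dose")

__all__ = [
    "TransportConfig",
    "InteractionFlags",
    "DoseMap",
    "hu_to_attenuation",
    "hu_to_density",
    "simulate_dose",
    "scale_to_absorbed",
    "make_cylinder_phantom",
    "primary_dose_oracle",
    "klein_nishina_cross_section",
    "mass_attenuation_water",
    "mass_attenuation_bone",
    "mass_energy_absorption_air",
]

# ---------------------------------------------------------------------------
# tabulated photon data (NIST), 10-150 keV
# ---------------------------------------------------------------------------

_E_TAB = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])
# mass attenuation mu/rho [cm^2/g]
_MU_WATER = np.array(
    [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505]
)
_MU_BONE = np.array(  # cortical bone, ICRU-44
    [28.51, 9.032, 4.001, 1.331, 0.6655, 0.4242, 0.3148, 0.2229, 0.1855, 0.1480]
)
# mass energy-absorption mu_en/rho [cm^2/g]
_MUEN_AIR = np.array(
    [4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098, 0.03041, 0.02407, 0.02325, 0.02496]
)

E_MIN, E_MAX = float(_E_TAB[0]), float(_E_TAB[-1])

_ELECTRON_REST_KEV = 511.0
_RE2 = 7.94079e-26  # classical electron radius squared, cm^2
_NE_WATER = 3.343e23  # electrons per gram
_NE_BONE = 3.192e23

# HU material model anchors
_HU_SOFT_MAX = 100.0  # top of the water-like segment
_HU_BONE = 1800.0  # cortical bone anchor
_RHO_SOFT_MAX = 1.1
_RHO_BONE = 1.92


def _loglog_interp(energy, table):
    e = np.asarray(energy, dtype=float)
    if np.any(e < E_MIN) or np.any(e > E_MAX):
        raise ValueError(f"energy outside supported range [{E_MIN}, {E_MAX}] keV")
    out = np.exp(np.interp(np.log(e), np.log(_E_TAB), np.log(table)))
    return float(out) if out.ndim == 0 else out


def mass_attenuation_water(energy_keV):
    """mu/rho of water [cm^2/g], log-log interpolated from the NIST table."""
    return _loglog_interp(energy_keV, _MU_WATER)


def mass_attenuation_bone(energy_keV):
    """mu/rho of cortical bone [cm^2/g]."""
    return _loglog_interp(energy_keV, _MU_BONE)


def mass_energy_absorption_air(energy_keV):
    """mu_en/rho of air [cm^2/g] (free-in-air kerma reference)."""
    return _loglog_interp(energy_keV, _MUEN_AIR)


def hu_to_density(hu):
    """Mass density [g/cm^3] from HU: 1 + HU/1000 up to HU 100, then a linear
    ramp to cortical bone (HU 1800 -> 1.92); rho(-1000) = 0."""
    hu = np.asarray(hu, dtype=float)
    soft = 1.0 + hu / 1000.0
    ramp = _RHO_SOFT_MAX + (hu - _HU_SOFT_MAX) * (_RHO_BONE - _RHO_SOFT_MAX) / (
        _HU_BONE - _HU_SOFT_MAX
    )
    rho = np.where(hu <= _HU_SOFT_MAX, soft, ramp)
    out = np.clip(rho, 0.0, None)
    return float(out) if out.ndim == 0 else out


def _bone_fraction(hu):
    hu = np.asarray(hu, dtype=float)
    f = (hu - _HU_SOFT_MAX) / (_HU_BONE - _HU_SOFT_MAX)
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def hu_to_attenuation(hu, energy_keV):
    """Linear attenuation coefficient [1/cm] of a voxel with the given HU.

    Below HU = 100 the voxel is water of density 1 + HU/1000, so
    mu = mu_water(E) * (1 + HU/1000); above, the material blends linearly
    toward cortical bone (documented two-segment ramp).  mu(-1000) = 0 and
    mu(0) = mu_water(E) exactly."""
    hu = np.asarray(hu, dtype=float)
    if np.any(hu < -1000):
        raise ValueError("HU below -1000 are not physical")
    rho = hu_to_density(hu)
    f = _bone_fraction(hu)
    mu_rho = (1.0 - f) * mass_attenuation_water(energy_keV) + f * mass_attenuation_bone(
        energy_keV
    )
    out = rho * mu_rho
    return float(out) if np.ndim(out) == 0 else out


def klein_nishina_cross_section(energy_keV):
    """Total Klein-Nishina cross-section per electron [cm^2]."""
    a = np.asarray(energy_keV, dtype=float) / _ELECTRON_REST_KEV
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log(1.0 + 2.0 * a) / a)
    t2 = np.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    out = 2.0 * np.pi * _RE2 * (t1 + t2 - t3)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionFlags:
    """Which interactions the transport simulates.

    With ``compton`` off every real collision absorbs the photon at the
    total cross-section (the primary-only mode used against the analytic
    attenuation oracle).  With ``compton`` on but ``follow_scatter`` off the
    Compton recoil energy is still deposited at the collision site but the
    scattered photon is discarded, so enabling scatter transport can only
    add deposition."""

    photoelectric: bool = True
    compton: bool = True
    follow_scatter: bool = True


@dataclass(frozen=True)
class TransportConfig:
    """Parameters of the simplified transport model."""

    n_histories: int = 100_000
    photon_energy_model: str = "monoenergetic_effective"
    energies_keV: tuple[float, ...] = (64.0,)
    spectrum_weights: tuple[float, ...] = (1.0,)
    helix: tuple[float, float, float, float] | None = None  # start_z, end_z, pitch, source_radius (cm)
    interactions: InteractionFlags = field(default_factory=InteractionFlags)
    rng_seed: int = 0
    batches: int = 10
    fan_halfwidth_cm: float | None = None  # default: covers the phantom
    energy_cutoff_keV: float = E_MIN

    def __post_init__(self):
        if self.n_histories <= 0:
            raise ValueError("n_histories must be positive")
        if self.photon_energy_model not in ("monoenergetic_effective", "binned_spectrum"):
            raise ValueError(f"unknown energy model {self.photon_energy_model!r}")
        for e in self.energies_keV:
            if not E_MIN <= e <= E_MAX:
                raise ValueError(f"photon energy {e} keV outside [{E_MIN}, {E_MAX}]")
        if len(self.spectrum_weights) != len(self.energies_keV):
            raise ValueError("spectrum_weights must match energies_keV")
        if self.batches < 2:
            raise ValueError("batch variance estimation needs >= 2 batches")

    @classmethod
    def spectrum_3bin(cls, **kw) -> "TransportConfig":
        """3-bin stand-in spectrum for a 120 kVp beam."""
        kw.setdefault("photon_energy_model", "binned_spectrum")
        kw.setdefault("energies_keV", (45.0, 64.0, 90.0))
        kw.setdefault("spectrum_weights", (0.25, 0.5, 0.25))
        return cls(**kw)


@dataclass
class DoseMap:
    """Per-voxel dose grids on the phantom geometry.

    ``relative_dose`` is dimensionless (free-in-air reference at the
    isocenter = 1); ``absorbed_dose`` (mGy) is populated by
    :func:`scale_to_absorbed`; ``uncertainty`` is the per-voxel relative
    standard error from the batch method."""

    relative_dose: np.ndarray
    uncertainty: np.ndarray
    spacing: tuple[float, float, float]  # mm
    absorbed_dose: np.ndarray | None = None
    emitted_keV: float = 0.0
    deposited_keV: float = 0.0
    n_histories: int = 0


def scale_to_absorbed(dose_map: DoseMap, air_kerma: float) -> DoseMap:
    """Absorbed dose per voxel = relative dose x air kerma (mGy).  The
    relative grid is left unchanged."""
    if air_kerma <= 0:
        raise ValueError("air kerma must be positive")
    return replace(dose_map, absorbed_dose=dose_map.relative_dose * air_kerma)


# ---------------------------------------------------------------------------
# transport kernel
# ---------------------------------------------------------------------------


def _kahn_sample(rng, alpha):
    """Vectorized Klein-Nishina sampling of eps = E'/E and cos(theta)."""
    n = alpha.size
    eps = np.empty(n)
    cos = np.empty(n)
    todo = np.arange(n)
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    while todo.size:
        a = alpha[todo]
        e0 = eps0[todo]
        u1, u2, u3 = rng.random((3, todo.size))
        use_log = u1 < a1[todo] / (a1[todo] + a2[todo])
        e = np.where(use_log, e0 ** u2, np.sqrt(e0**2 + u2 * (1.0 - e0**2)))
        t = (1.0 - e) / (a * e)
        sin2 = t * (2.0 - t)
        g = 1.0 - e * sin2 / (1.0 + e**2)
        ok = u3 <= g
        idx = todo[ok]
        eps[idx] = e[ok]
        cos[idx] = 1.0 - t[ok]
        todo = todo[~ok]
    return eps, cos


def _rotate(d, cos_t, rng):
    """Rotate unit vectors ``d`` by polar angle with cosine ``cos_t`` and a
    uniform azimuth."""
    n = d.shape[0]
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    # orthonormal frame around d
    small = np.abs(d[:, 2]) < 0.99
    a = np.where(small[:, None], np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        d * cos_t[:, None]
        + u * (sin_t * np.cos(phi))[:, None]
        + v * (sin_t * np.sin(phi))[:, None]
    )
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _ray_box(pos, d, lo, hi):
    """Distance to entry of the axis-aligned box, inf if the ray misses; 0 if
    already inside."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - pos) / d
        t2 = (hi - pos) / d
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    enter = np.where((tmax >= np.maximum(tmin, 0.0)), np.maximum(tmin, 0.0), np.inf)
    return enter


def simulate_dose(
    phantom: VoxelPhantom,
    scan: ScanParameters | None = None,
    cfg: TransportConfig | None = None,
) -> DoseMap:
    """Run the transport and return the relative dose map.

    Deterministic for a fixed ``cfg.rng_seed``.  Energy bookkeeping is
    exposed on the returned map (total deposited <= total emitted)."""
    scan = scan or ScanParameters()
    cfg = cfg or TransportConfig()
    hu = np.asarray(phantom.hu, dtype=float)
    if hu.size == 0 or min(hu.shape) < 2:
        raise ValueError("degenerate phantom (zero extent)")
    nx, ny, nz = hu.shape
    sx, sy, sz = (s / 10.0 for s in phantom.spacing)  # mm -> cm
    lo = np.array([-nx * sx / 2.0, -ny * sy / 2.0, 0.0])
    hi = np.array([nx * sx / 2.0, ny * sy / 2.0, nz * sz])
    spacing = np.array([sx, sy, sz])
    voxel_volume = sx * sy * sz

    # energy-independent material grids
    rho = hu_to_density(hu)
    f = _bone_fraction(hu)
    wa = (rho * (1.0 - f)).astype(np.float64)  # water-equivalent mass density
    wb = (rho * f).astype(np.float64)  # bone mass density
    ne = rho * ((1.0 - f) * _NE_WATER + f * _NE_BONE)  # electrons / cm^3
    mass = rho * voxel_volume  # g per voxel

    # majorant attenuation per keV (upper bound: sum of componentwise maxima)
    e_grid = np.arange(np.floor(E_MIN), np.ceil(E_MAX) + 1.0)
    maj_grid = wa.max() * mass_attenuation_water(e_grid) + wb.max() * mass_attenuation_bone(
        e_grid
    )

    if cfg.helix is not None:
        z0, z1, pitch, src_r = cfg.helix
        if z0 > lo[2] + 1e-9 or z1 < hi[2] - 1e-9:
            raise ValueError("helix does not cover the phantom z-extent")
    else:
        z0, z1, pitch, src_r = lo[2], hi[2], scan.pitch, 60.0
    coll = scan.collimation / 10.0  # cm
    feed = pitch * coll  # table feed per rotation
    halfwidth = cfg.fan_halfwidth_cm or 0.55 * max(hi[0] - lo[0], hi[1] - lo[1])
    z_range = z1 - z0

    energies = np.asarray(cfg.energies_keV, dtype=float)
    weights = np.asarray(cfg.spectrum_weights, dtype=float)
    weights = weights / weights.sum()
    if cfg.photon_energy_model == "monoenergetic_effective":
        energies, weights = energies[:1], np.array([1.0])

    rng = np.random.default_rng(cfg.rng_seed)
    flat_shape = hu.size
    batch_dep = np.zeros((cfg.batches, flat_shape), dtype=np.float64)
    emitted = 0.0
    per_batch = [cfg.n_histories // cfg.batches] * cfg.batches
    per_batch[-1] += cfg.n_histories - sum(per_batch)
    muen_ref = 0.0  # accumulates E * muen_air(E) over histories

    mu_c_enabled = cfg.interactions.compton
    mu_pe_enabled = cfg.interactions.photoelectric

    for b, n_b in enumerate(per_batch):
        if n_b == 0:
            continue
        # --- source sampling -------------------------------------------------
        z_src = rng.uniform(z0, z1, n_b)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        theta = 2.0 * np.pi * (z_src - z0) / feed + phi0
        src = np.stack(
            [src_r * np.cos(theta), src_r * np.sin(theta), z_src], axis=1
        )
        tangent = np.stack([-np.sin(theta), np.cos(theta)], axis=1)
        u = rng.uniform(-halfwidth, halfwidth, n_b)
        v = rng.uniform(-coll / 2.0, coll / 2.0, n_b)
        target = np.stack(
            [u * tangent[:, 0], u * tangent[:, 1], z_src + v], axis=1
        )
        d = target - src
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        E = rng.choice(energies, size=n_b, p=weights)
        emitted += E.sum()
        muen_ref += (E * mass_energy_absorption_air(E)).sum()

        # advance to the phantom bounding box
        t_in = _ray_box(src, d, lo, hi)
        inside = np.isfinite(t_in)
        pos = src[inside] + d[inside] * (t_in[inside] + 1e-9)[:, None]
        d = d[inside]
        E = E[inside]
        dep = batch_dep[b]

        while pos.shape[0]:
            maj = np.interp(E, e_grid, maj_grid)
            maj = np.maximum(maj, 1e-12)
            step = -np.log(rng.random(pos.shape[0])) / maj
            pos = pos + d * step[:, None]
            in_box = np.all((pos > lo) & (pos < hi), axis=1)
            pos, d, E, maj = pos[in_box], d[in_box], E[in_box], maj[in_box]
            if not pos.shape[0]:
                break
            idx = ((pos - lo) / spacing).astype(np.int64)
            idx[:, 0] = np.clip(idx[:, 0], 0, nx - 1)
            idx[:, 1] = np.clip(idx[:, 1], 0, ny - 1)
            idx[:, 2] = np.clip(idx[:, 2], 0, nz - 1)
            flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), hu.shape)
            mu = wa.ravel()[flat] * mass_attenuation_water(E) + wb.ravel()[
                flat
            ] * mass_attenuation_bone(E)
            real = rng.random(pos.shape[0]) < mu / maj
            if not real.any():
                continue
            r_flat = flat[real]
            r_E = E[real]
            r_mu = mu[real]
            if mu_c_enabled:
                mu_c = np.minimum(
                    klein_nishina_cross_section(r_E) * ne.ravel()[r_flat], r_mu
                )
                p_c = np.where(r_mu > 0, mu_c / r_mu, 0.0)
                if not mu_pe_enabled:
                    p_c = np.ones_like(p_c)
                is_c = rng.random(r_E.size) < p_c
            else:
                is_c = np.zeros(r_E.size, dtype=bool)

            # photoelectric (or forced absorption): deposit everything
            pe_flat = r_flat[~is_c]
            np.add.at(dep, pe_flat, r_E[~is_c])

            # Compton: deposit the recoil energy, continue with E'
            if is_c.any():
                c_sel = np.flatnonzero(real)[is_c]
                alpha = r_E[is_c] / _ELECTRON_REST_KEV
                eps, cos_t = _kahn_sample(rng, alpha)
                e_new = r_E[is_c] * eps
                np.add.at(dep, r_flat[is_c], r_E[is_c] - e_new)
                if cfg.interactions.follow_scatter:
                    low = e_new < cfg.energy_cutoff_keV
                    if low.any():  # below the table floor: deposit locally
                        np.add.at(dep, r_flat[is_c][low], e_new[low])
                else:  # scattered photon discarded; its energy escapes
                    low = np.ones_like(e_new, dtype=bool)
                keep_c = c_sel[~low]
                d[keep_c] = _rotate(d[keep_c], cos_t[~low], rng)
                E[keep_c] = e_new[~low]

            # drop absorbed / terminated photons
            killed = np.zeros(pos.shape[0], dtype=bool)
            kill_idx = np.flatnonzero(real)[~is_c]
            killed[kill_idx] = True
            if is_c.any():
                killed[c_sel[low]] = True
            alive = ~killed
            pos, d, E = pos[alive], d[alive], E[alive]

    # --- normalization: free-in-air kerma at the isocenter -------------------
    # helical source, targets uniform over the fan: planar fluence at the
    # isocenter = N / (2 * halfwidth * z_range); kerma = sum E*muen_air / area
    ref_area = 2.0 * halfwidth * z_range
    d_ref = muen_ref / ref_area  # keV/g equivalent reference
    dep_total = batch_dep.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dose = dep_total.reshape(hu.shape) / np.where(mass > 0, mass, np.inf)
    relative = dose / d_ref

    # batch-method relative standard error
    with np.errstate(divide="ignore", invalid="ignore"):
        b_dose = batch_dep.reshape(cfg.batches, *hu.shape) / np.where(
            mass > 0, mass, np.inf
        )
    b_mean = b_dose.mean(axis=0)
    b_se = b_dose.std(axis=0, ddof=1) / np.sqrt(cfg.batches)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_se = np.where(b_mean > 0, b_se / b_mean, 0.0)

    deposited = float(dep_total.sum())
    if deposited > emitted + 1e-6:
        raise AssertionError("energy conservation violated")
    return DoseMap(
        relative_dose=relative,
        uncertainty=rel_se,
        spacing=phantom.spacing,
        emitted_keV=float(emitted),
        deposited_keV=deposited,
        n_histories=cfg.n_histories,
    )


# ---------------------------------------------------------------------------
# benchmark geometry and analytic oracle
# ---------------------------------------------------------------------------


def make_cylinder_phantom(
    radius_cm: float = 8.0,
    length_cm: float = 20.0,
    n: int = 33,
    hu_inside: float = 0.0,
) -> VoxelPhantom:
    """Homogeneous cylinder (water by default) on an air background, axis on
    the table-feed axis - the convergence benchmark geometry."""
    fov = 2.5 * radius_cm
    d_t = fov / n
    d_z = length_cm / n
    xs = (np.arange(n) + 0.5) * d_t - fov / 2.0
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    disk = (X**2 + Y**2) <= radius_cm**2
    hu = np.full((n, n, n), -1000.0, dtype=np.float32)
    hu[disk] = hu_inside
    return VoxelPhantom(
        hu=hu,
        labels=np.zeros((n, n, n), dtype=np.uint8),
        spacing=(d_t * 10.0, d_t * 10.0, d_z * 10.0),
        label_map={},
    )


def primary_dose_oracle(
    radius_cm: float,
    energy_keV: float = 64.0,
    x_cm: float = 0.0,
    y_cm: float = 0.0,
    source_radius_cm: float = 60.0,
    hu_inside: float = 0.0,
    n_angles: int = 4096,
) -> float:
    """Analytic primary-only relative dose inside a homogeneous cylinder.

    Angular average over source positions of exp(-mu * pathlength) times the
    inverse-square fluence factor, converted to dose with the medium's total
    mass attenuation (absorption-only deposition) and normalized by the
    free-in-air air-kerma reference.  Independent line-integral oracle for
    the transport kernel."""
    mu = hu_to_attenuation(hu_inside, energy_keV)
    rho = hu_to_density(hu_inside)
    r2 = x_cm**2 + y_cm**2
    if r2 > radius_cm**2:
        raise ValueError("oracle point must lie inside the cylinder")
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    c = x_cm * np.cos(theta) + y_cm * np.sin(theta)
    b2 = r2 - c**2
    path = np.sqrt(radius_cm**2 - b2) - c  # entry point to (x, y)
    invsq = (source_radius_cm / (source_radius_cm - c)) ** 2
    fluence = float(np.mean(np.exp(-mu * path) * invsq))
    return fluence * (mu / rho) / mass_energy_absorption_air(energy_keV)
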