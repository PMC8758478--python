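"""Hydrodynamics of sedimentation velocity experiments.

Svedberg/Stokes relations between sedimentation coefficient, frictional
ratio, molar mass and diffusion coefficient; a conservative finite-volume
Lamm-equation solver for sector-shaped cells; regularised non-negative
c(S) deconvolution of radial boundary scans; and weight-average s_w
integration of c(S) distributions.

Units are CGS throughout the internals: radius in cm, time in s,
sedimentation coefficients in Svedberg (1 S = 1e-13 s), viscosity taken
in mPa*s (= centipoise) and converted to poise internally, density in
g/mL, partial specific volume in mL/g, molar mass in g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.optimize import brentq, nnls

__all__ = [
    "SVEDBERG",
    "AVOGADRO",
    "BOLTZMANN",
    "GAS_CONSTANT",
    "SolutionConditions",
    "WATER_20C",
    "HydroSpecies",
    "CellGeometry",
    "RadialScan",
    "CSDistribution",
    "mass_from_hydro",
    "s_from_mass",
    "implied_vbar",
    "diffusion_coefficient",
    "lamm_simulate",
    "fit_cs",
    "integrate_sw",
    "scans_to_frame",
    "frame_to_scans",
]

SVEDBERG = 1e-13            # s
AVOGADRO = 6.02214076e23    # 1/mol
BOLTZMANN = 1.380649e-16    # erg/K (CGS)
GAS_CONSTANT = 8.31446261815324e7  # erg/(mol K) (CGS)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolutionConditions:
    """Solvent conditions entering the Svedberg and Stokes relations.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.
    density : float
        Solvent density rho in g/mL.
    viscosity : float
        Solvent viscosity eta in mPa*s (water at 20 C: 1.002).
    partial_specific_volume : float
        Protein partial specific volume vbar in mL/g (default 0.73,
        the canonical unmodified-protein value).
    """

    temperature: float = 293.15
    density: float = 0.99823
    viscosity: float = 1.002
    partial_specific_volume: float = 0.73

    def __post_init__(self) -> None:
        for name in ("temperature", "density", "viscosity", "partial_specific_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.buoyancy <= 0:
            raise ValueError("buoyancy factor (1 - vbar*rho) must be positive")

    @property
    def buoyancy(self) -> float:
        return 1.0 - self.partial_specific_volume * self.density

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity * 1e-2  # mPa*s -> g/(cm s)


WATER_20C = SolutionConditions()


def _stokes_radius_coeff(cond: SolutionConditions) -> float:
    """Radius of the anhydrous sphere per M^(1/3): r0 = coeff * M^(1/3) [cm]."""
    return (3.0 * cond.partial_specific_volume / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)


def mass_from_hydro(s: float, ff0: float, cond: SolutionConditions = WATER_20C) -> float:
    """Molar mass (g/mol) from sedimentation coefficient and frictional ratio.

    Solves the Svedberg relation s = M(1 - vbar rho) / (N_A f) with
    f = (f/f0) * 6 pi eta r0 and r0 the anhydrous-sphere radius, giving
    the closed form

        M = [ s N_A (f/f0) 6 pi eta (3 vbar / 4 pi N_A)^(1/3) / (1 - vbar rho) ]^(3/2)

    Parameters
    ----------
    s : float
        Sedimentation coefficient in Svedberg.
    ff0 : float
        Frictional ratio f/f0 (>= 1).
    cond : SolutionConditions
        Solvent conditions.
    """
    if s <= 0:
        raise ValueError("sedimentation coefficient must be positive")
    if ff0 < 1:
        raise ValueError("frictional ratio f/f0 must be >= 1")
    s_sec = s * SVEDBERG
    m_23 = (
        s_sec * AVOGADRO * ff0 * 6.0 * np.pi * cond.viscosity_poise
        * _stokes_radius_coeff(cond) / cond.buoyancy
    )
    return float(m_23 ** 1.5)


def s_from_mass(molar_mass: float, ff0: float, cond: SolutionConditions = WATER_20C) -> float:
    """Sedimentation coefficient (Svedberg) of a species of given molar mass.

    Inverse of :func:`mass_from_hydro`; strictly increasing in M (s ~ M^(2/3))
    at fixed frictional ratio.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if ff0 < 1:
        raise ValueError("frictional ratio f/f0 must be >= 1")
    friction = ff0 * 6.0 * np.pi * cond.viscosity_poise * _stokes_radius_coeff(cond) * molar_mass ** (1.0 / 3.0)
    s_sec = molar_mass * cond.buoyancy / (AVOGADRO * friction)
    return float(s_sec / SVEDBERG)


def implied_vbar(s: float, ff0: float, target_mass: float,
                 cond: SolutionConditions = WATER_20C) -> float:
    """Partial specific volume (mL/g) that makes (s, f/f0) imply `target_mass`.

    Root-finds vbar in (0.05, 1/rho) such that mass_from_hydro at the given
    conditions-with-that-vbar equals target_mass. Used to report how far the
    default vbar is from reproducing a printed mass exactly.
    """
    def f(vbar: float) -> float:
        c = replace(cond, partial_specific_volume=vbar)
        return mass_from_hydro(s, ff0, c) - target_mass

    hi = 1.0 / cond.density - 1e-6
    return float(brentq(f, 0.05, hi, xtol=1e-12))


@dataclass(frozen=True)
class HydroSpecies:
    """A sedimenting species: s, f/f0, and derived mass / diffusion.

    `molar_mass` and `diffusion_coeff` are derived from (s, f/f0, cond) if
    not given; if given they must be consistent with the Svedberg relation.
    """

    label: str
    s: float                       # Svedberg
    frictional_ratio: float        # f/f0 >= 1
    loading_signal: float = 1.0    # AU
    signal_weight: float = 1.0     # AU per molar
    conditions: SolutionConditions = WATER_20C
    molar_mass: float = field(default=None)        # type: ignore[assignment]
    diffusion_coeff: float = field(default=None)   # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be non-negative")
        if self.frictional_ratio < 1:
            raise ValueError("f/f0 must be >= 1")
        if self.s == 0:
            # non-sedimenting tracer: diffusion must be given explicitly
            if self.diffusion_coeff is None:
                raise ValueError("s=0 species needs an explicit diffusion_coeff")
            if self.molar_mass is None:
                object.__setattr__(self, "molar_mass", 0.0)
            return
        mass = mass_from_hydro(self.s, self.frictional_ratio, self.conditions)
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", mass)
        elif abs(self.molar_mass - mass) > 1e-6 * mass:
            raise ValueError("molar_mass inconsistent with (s, f/f0) under the Svedberg relation")
        d = diffusion_from_hydro(self.s, self.frictional_ratio, self.conditions)
        if self.diffusion_coeff is None:
            object.__setattr__(self, "diffusion_coeff", d)
        elif abs(self.diffusion_coeff - d) > 1e-6 * d:
            raise ValueError("diffusion_coeff inconsistent with (s, f/f0)")


def diffusion_from_hydro(s: float, ff0: float, cond: SolutionConditions = WATER_20C) -> float:
    """Stokes-Einstein diffusion coefficient (cm^2/s) from (s, f/f0)."""
    mass = mass_from_hydro(s, ff0, cond)
    friction = ff0 * 6.0 * np.pi * cond.viscosity_poise * _stokes_radius_coeff(cond) * mass ** (1.0 / 3.0)
    return float(BOLTZMANN * cond.temperature / friction)


def diffusion_coefficient(species: HydroSpecies, cond: SolutionConditions | None = None) -> float:
    """Diffusion coefficient D = kT/f of a species (cm^2/s).

    Satisfies the Svedberg identity D = s R T / (M (1 - vbar rho)).
    """
    cond = cond or species.conditions
    return diffusion_from_hydro(species.s, species.frictional_ratio, cond)


@dataclass(frozen=True)
class CellGeometry:
    """Sector-shaped centrifuge cell: radial extent and rotor speed."""

    meniscus: float = 6.0     # cm
    base: float = 7.25        # cm
    rotor_speed: float = 50000.0  # rpm

    def __post_init__(self) -> None:
        if not (self.base > self.meniscus > 0):
            raise ValueError("require base > meniscus > 0")
        if self.rotor_speed <= 0:
            raise ValueError("rotor speed must be positive")

    @property
    def omega(self) -> float:
        return self.rotor_speed * 2.0 * np.pi / 60.0

    @property
    def omega_sq(self) -> float:
        return self.omega ** 2


@dataclass(frozen=True)
class RadialScan:
    """One absorbance scan: signal over a strictly increasing radial grid."""

    time: float              # s since speed attained
    radius: np.ndarray       # cm
    signal: np.ndarray       # AU

    def __post_init__(self) -> None:
        r = np.asarray(self.radius, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if r.ndim != 1 or sig.shape != r.shape:
            raise ValueError("radius and signal must be matching 1-D arrays")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radius grid must be strictly increasing")
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class CSDistribution:
    """Differential sedimentation-coefficient distribution c(s)."""

    s_grid: np.ndarray        # Svedberg, strictly increasing
    c: np.ndarray             # AU per Svedberg, >= 0
    frictional_ratio: float
    regularization: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.s_grid, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if np.any(np.diff(s) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if c.shape != s.shape:
            raise ValueError("c and s_grid must match")
        if np.any(c < -1e-12):
            raise ValueError("c(s) must be non-negative")
        object.__setattr__(self, "s_grid", s)
        object.__setattr__(self, "c", np.maximum(c, 0.0))

    @property
    def total_signal(self) -> float:
        return float(np.trapezoid(self.c, self.s_grid))

    @property
    def mode(self) -> float:
        return float(self.s_grid[int(np.argmax(self.c))])


# ---------------------------------------------------------------------------
# Lamm equation solver
# ---------------------------------------------------------------------------

def _lamm_operator(r_faces: np.ndarray, r_centers: np.ndarray, dr: float,
                   s_sec: float, d_coeff: float, omega_sq: float) -> np.ndarray:
    """Banded (3, n) matrix L with dc/dt = L c for the sector-cell Lamm flux.

    Conservative finite volume on the sector measure r dr: the flux through
    a face at radius r is F = s w^2 r^2 c_up - D r dc/dr, upwinded in the
    (outward) sedimentation term, with zero flux at meniscus and base.
    Returns scipy solve_banded layout: row 0 upper, 1 diag, 2 lower.
    """
    n = r_centers.size
    band = np.zeros((3, n))
    # interior faces j between cell j-1 and j (j = 1..n-1)
    rf = r_faces[1:-1]
    adv = s_sec * omega_sq * rf ** 2         # advective face speed * r
    dif = d_coeff * rf / dr                  # diffusive face conductance
    inv_vol = 1.0 / (r_centers * dr)
    for j in range(1, n):
        a, d = adv[j - 1], dif[j - 1]
        # flux_j = a * c_{j-1} (upwind, sedimentation is outward) - d*(c_j - c_{j-1})
        f_lo = a + d     # coefficient on c_{j-1}
        f_hi = -d        # coefficient on c_j
        # cell j-1 loses flux_j ; cell j gains flux_j
        band[1, j - 1] -= f_lo * inv_vol[j - 1]
        band[0, j] -= f_hi * inv_vol[j - 1]       # upper diag, col j, row j-1
        band[1, j] += f_hi * inv_vol[j]
        band[2, j - 1] += f_lo * inv_vol[j]       # lower diag, col j-1, row j
    return band


def _band_combine(band: np.ndarray, scale: float, add_identity: float) -> np.ndarray:
    out = band * scale
    out[1] += add_identity
    return out


def _band_matvec(band: np.ndarray, c: np.ndarray) -> np.ndarray:
    n = c.size
    out = band[1] * c
    out[:-1] += band[0, 1:] * c[1:]
    out[1:] += band[2, :-1] * c[:-1]
    return out


def lamm_simulate(species: Sequence[HydroSpecies], geom: CellGeometry,
                  times: Sequence[float], cond: SolutionConditions = WATER_20C,
                  n_radial: int = 400, cfl: float = 0.5,
                  initial_profiles: Sequence[np.ndarray] | None = None) -> list[RadialScan]:
    """Simulate radial absorbance scans by solving the Lamm equation.

    Crank-Nicolson time stepping of a conservative finite-volume
    discretisation with upwinded sedimentation flux; automatic sub-stepping
    keeps the advective CFL number at `cfl`. Initial condition is uniform
    loading (species.loading_signal) over the whole cell; boundaries are
    zero-flux, so sector mass is conserved until material pellets at the
    base. Total signal is the sum over species. `initial_profiles`, if
    given, overrides the uniform loading with one array of cell-center
    values per species (used e.g. for step-profile diffusion checks).
    """
    if n_radial < 100:
        raise ValueError("n_radial must be >= 100")
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    r_faces = np.linspace(geom.meniscus, geom.base, n_radial + 1)
    dr = r_faces[1] - r_faces[0]
    r_centers = 0.5 * (r_faces[:-1] + r_faces[1:])

    if initial_profiles is not None and len(initial_profiles) != len(species):
        raise ValueError("need one initial profile per species")

    total = np.zeros((times.size, n_radial))
    for i_sp, sp in enumerate(species):
        s_sec = sp.s * SVEDBERG
        d_coeff = sp.diffusion_coeff
        if initial_profiles is not None:
            c = np.asarray(initial_profiles[i_sp], dtype=float).copy()
            if c.shape != (n_radial,):
                raise ValueError("initial profile length must equal n_radial")
        else:
            c = np.full(n_radial, sp.loading_signal, dtype=float)
        if s_sec == 0 and d_coeff == 0:
            profiles = np.tile(c, (times.size, 1))
            total += profiles
            continue
        band = _lamm_operator(r_faces, r_centers, dr, s_sec, d_coeff, geom.omega_sq)
        v_max = s_sec * geom.omega_sq * geom.base
        dt_cfl = cfl * dr / v_max if v_max > 0 else np.inf
        if d_coeff > 0:
            dt_cfl = min(dt_cfl, 4.0 * dr ** 2 / d_coeff)  # accuracy cap, CN is stable
        t_now = 0.0
        for k, t_out in enumerate(times):
            span = t_out - t_now
            if span > 0:
                n_sub = max(1, int(np.ceil(span / dt_cfl)))
                dt = span / n_sub
                lhs = _band_combine(band, -0.5 * dt, 1.0)
                for _ in range(n_sub):
                    rhs = c + 0.5 * dt * _band_matvec(band, c)
                    c = solve_banded((1, 1), lhs, rhs)
                t_now = t_out
            total[k] += c
    return [RadialScan(time=float(t), radius=r_centers.copy(), signal=total[k].copy())
            for k, t in enumerate(times)]


def sector_mass(scan: RadialScan) -> float:
    """Sector-weighted mass integral of a scan, int c(r) r dr.

    Midpoint (cell-sum) rule, which is the exactly conserved discrete
    quantity of the finite-volume solver on its uniform grid.
    """
    return float(np.sum(scan.signal * scan.radius * np.gradient(scan.radius)))


# ---------------------------------------------------------------------------
# c(S) deconvolution
# ---------------------------------------------------------------------------

def default_s_grid(n: int = 30, s_min: float = 1.0, s_max: float = 15.0) -> np.ndarray:
    """Default log-spaced sedimentation-coefficient grid (Svedberg)."""
    return np.geomspace(s_min, s_max, n)


def _second_difference(n: int) -> np.ndarray:
    p = np.zeros((max(n - 2, 0), n))
    for i in range(n - 2):
        p[i, i:i + 3] = (1.0, -2.0, 1.0)
    return p


def fit_cs(scans: Sequence[RadialScan], geom: CellGeometry,
           cond: SolutionConditions = WATER_20C,
           s_grid: np.ndarray | None = None, ff0: float = 1.38,
           lam: float | str = "auto", noise_sd: float = 0.005,
           n_radial: int = 200, fit_margins: tuple[float, float] = (0.015, 0.06)
           ) -> CSDistribution:
    """Fit a regularised non-negative c(S) distribution to boundary scans.

    The model is data = sum_j c_j K_j with K_j the Lamm-equation kernel of a
    unit-loading species at grid value s_j (D derived from the shared f/f0),
    fitted by non-negative least squares with a second-difference Tikhonov
    penalty lam * ||P c||^2. With lam="auto" the penalty weight is chosen by
    the discrepancy principle at the given noise SD: the largest lam whose
    residual RMS does not exceed noise_sd (bisection on log lam).

    Radii within `fit_margins` (cm inside the meniscus and base) are
    excluded from the fit, so the solvent-depletion region and the
    grid-resolution-dependent pellet build-up at the base do not bias
    the deconvolution.

    Raises if fewer than 3 scans are provided; returns an all-zero
    distribution (with a warning) for all-zero data.
    """
    if len(scans) < 3:
        raise ValueError("need at least 3 scans")
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = np.asarray(s_grid, dtype=float)
    times = [sc.time for sc in scans]
    if np.any(np.diff(times) < 0):
        raise ValueError("scans must be time-ordered")

    radii = scans[0].radius
    for sc in scans:
        if sc.radius.shape != radii.shape or not np.allclose(sc.radius, radii):
            raise ValueError("all scans must share one radial grid")
    window = (radii >= geom.meniscus + fit_margins[0]) & (radii <= geom.base - fit_margins[1])
    if window.sum() < s_grid.size:
        raise ValueError("fit window leaves too few radii")
    radii_fit = radii[window]
    data = np.concatenate([sc.signal[window] for sc in scans])

    if not np.any(np.abs(data) > 0):
        import warnings
        warnings.warn("all-zero scan data; returning zero distribution")
        return CSDistribution(s_grid=s_grid, c=np.zeros_like(s_grid),
                              frictional_ratio=ff0, regularization=0.0)

    # Kernel: one unit-loading simulation per grid species, interpolated to
    # the scan radii.
    kernel = np.empty((data.size, s_grid.size))
    for j, s_j in enumerate(s_grid):
        sp = HydroSpecies(label=f"grid_{j}", s=float(s_j), frictional_ratio=ff0,
                          loading_signal=1.0, conditions=cond)
        sims = lamm_simulate([sp], geom, times, cond, n_radial=n_radial)
        cols = [np.interp(radii_fit, sim.radius, sim.signal) for sim in sims]
        kernel[:, j] = np.concatenate(cols)

    cond_no = np.linalg.cond(kernel.T @ kernel)
    if cond_no > 1e14 and lam == 0:
        raise np.linalg.LinAlgError(
            "c(S) kernel is ill-conditioned; widen the regularization weight lam")

    p = _second_difference(s_grid.size)
    scale = np.linalg.norm(kernel, ord="fro") / max(np.linalg.norm(p, ord="fro"), 1e-12)

    def solve(lam_val: float) -> tuple[np.ndarray, float]:
        aug = np.vstack([kernel, np.sqrt(lam_val) * scale * p])
        rhs = np.concatenate([data, np.zeros(p.shape[0])])
        coef, _ = nnls(aug, rhs)
        resid = kernel @ coef - data
        return coef, float(np.sqrt(np.mean(resid ** 2)))

    if lam == "auto":
        # discrepancy principle: largest lam with residual RMS <= noise_sd
        lo, hi = 1e-8, 1e2
        c_lo, r_lo = solve(lo)
        if r_lo > noise_sd:
            coef, lam_used = c_lo, lo
        else:
            for _ in range(30):
                mid = np.sqrt(lo * hi)
                _, r_mid = solve(mid)
                if r_mid <= noise_sd:
                    lo = mid
                else:
                    hi = mid
            coef, _ = solve(lo)
            lam_used = lo
    else:
        lam_used = float(lam)
        coef, _ = solve(lam_used)

    # convert per-grid-point amplitudes to a density per Svedberg
    widths = np.gradient(s_grid)
    return CSDistribution(s_grid=s_grid, c=coef / widths, frictional_ratio=ff0,
                          regularization=lam_used)


def integrate_sw(cs: CSDistribution, s_range: tuple[float, float] | None = None) -> float:
    """Weight-average sedimentation coefficient over `s_range` (trapezoid).

    s_w = int s c(s) ds / int c(s) ds. Raises on zero total signal in range.
    """
    s, c = cs.s_grid, cs.c
    if s_range is not None:
        lo, hi = s_range
        if lo < s[0] - 1e-9 or hi > s[-1] + 1e-9:
            raise ValueError("s_range outside the distribution grid")
        mask = (s >= lo) & (s <= hi)
        s, c = s[mask], c[mask]
    denom = np.trapezoid(c, s)
    if denom <= 0:
        raise ValueError("zero total signal in integration range")
    return float(np.trapezoid(s * c, s) / denom)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def scans_to_frame(scans: Sequence[RadialScan]) -> pd.DataFrame:
    """Long-format scan table with columns time_s, radius_cm, signal_au."""
    rows = [pd.DataFrame({"time_s": sc.time, "radius_cm": sc.radius,
                          "signal_au": sc.signal}) for sc in scans]
    return pd.concat(rows, ignore_index=True)


def frame_to_scans(frame: pd.DataFrame) -> list[RadialScan]:
    """Inverse of :func:`scans_to_frame`."""
    required = {"time_s", "radius_cm", "signal_au"}
    if not required.issubset(frame.columns):
        raise ValueError(f"scan table must have columns {sorted(required)}")
    scans = []
    for t, grp in frame.groupby("time_s", sort=True):
        grp = grp.sort_values("radius_cm")
        scans.append(RadialScan(time=float(t),
                                radius=grp["radius_cm"].to_numpy(),
                                signal=grp["signal_au"].to_numpy()))
    return scans


def cs_to_frame(cs: CSDistribution) -> pd.DataFrame:
    return pd.DataFrame({"s_svedberg": cs.s_grid, "c_au_per_s": cs.c})
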