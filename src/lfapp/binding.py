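"""Two-site APP-lactoferrin binding equilibria and titration fitting.

The sedimentation arm models the sequential scheme

    A + L <=> AL    (Kd1)
    AL + L <=> AL2  (Kd2)

whose species concentrations follow from mass action and the two
conservation balances. The observable is the signal-weighted
weight-average sedimentation coefficient over {A, L, AL, AL2}. The
fluorescence arm models two independent sites with fractional
occupancies theta_i = L_free/(Kd_i + L_free) and exact ligand
depletion. Both observables are fitted by weighted least squares with
multi-start local optimisation over log-uniform Kd starts, and one-site
vs two-site fits are compared by delta-R^2, an exact Wald-Wolfowitz
runs test on residual signs, and small-sample-corrected AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "TwoSiteParams",
    "SpeciesState",
    "FluorParams",
    "SwTitration",
    "FluorTitration",
    "FitResult",
    "ModelComparison",
    "solve_equilibrium",
    "sw_model",
    "fluor_model",
    "fit_binding",
    "compare_models",
    "runs_test_exact",
    "stoichiometry_select",
]

KD_START_RANGE = (1e-9, 1e-3)   # molar, log-uniform multi-start window
BASE_SEED = 20210816

# Observed c(S) peak positions (Svedberg) used as default fixed species
# s values during Kd fitting: free APP, free holo-Lf, 1:1 and 1:2 complex.
DEFAULT_S = {"s_A": 3.9, "s_L": 5.1, "s_AL": 6.9, "s_AL2": 9.8}
# A280-like signal weights proportional to species molar mass (kDa).
DEFAULT_W = {"signal_weight_A": 61.0, "signal_weight_L": 79.0,
             "signal_weight_AL": 140.0, "signal_weight_AL2": 219.0}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoSiteParams:
    """Sequential two-site parameters for the s_w observable."""

    kd1: float
    kd2: float
    s_A: float = DEFAULT_S["s_A"]
    s_L: float = DEFAULT_S["s_L"]
    s_AL: float = DEFAULT_S["s_AL"]
    s_AL2: float = DEFAULT_S["s_AL2"]
    signal_weight_A: float = DEFAULT_W["signal_weight_A"]
    signal_weight_L: float = DEFAULT_W["signal_weight_L"]
    signal_weight_AL: float = DEFAULT_W["signal_weight_AL"]
    signal_weight_AL2: float = DEFAULT_W["signal_weight_AL2"]
    include_free_ligand: bool = True

    def __post_init__(self) -> None:
        if self.kd1 <= 0 or self.kd2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if not (self.s_AL2 > self.s_AL > self.s_A):
            raise ValueError("complex species must sediment faster: s_AL2 > s_AL > s_A")
        for name in ("signal_weight_A", "signal_weight_L",
                     "signal_weight_AL", "signal_weight_AL2"):
            if getattr(self, name) < 0:
                raise ValueError("signal weights must be non-negative")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (molar) of free and bound species."""

    conc_A: float
    conc_L: float
    conc_AL: float
    conc_AL2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.conc_A, self.conc_L, self.conc_AL, self.conc_AL2])


@dataclass(frozen=True)
class FluorParams:
    """Independent-two-site fluorescence parameters.

    F = f0 + df1*theta1 + df2*theta2; the amplitudes are fluorescence
    changes at full fractional occupancy of each site.
    """

    f0: float
    df1: float
    df2: float
    kd1: float
    kd2: float

    def __post_init__(self) -> None:
        if self.kd1 <= 0 or self.kd2 <= 0:
            raise ValueError("dissociation constants must be positive")


@dataclass(frozen=True)
class SwTitration:
    """Observed weight-average s as a function of total concentrations."""

    points: pd.DataFrame  # columns a_tot_molar, l_tot_molar, observable, sigma

    observable_name = "sw_svedberg"

    def __post_init__(self) -> None:
        _check_titration_frame(self.points)


@dataclass(frozen=True)
class FluorTitration:
    """Observed 340 nm fluorescence as a function of total concentrations."""

    points: pd.DataFrame

    observable_name = "fluorescence"

    def __post_init__(self) -> None:
        _check_titration_frame(self.points)


def _check_titration_frame(df: pd.DataFrame) -> None:
    required = {"a_tot_molar", "l_tot_molar", "observable", "sigma"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration table needs columns {sorted(required)}")
    if (df["a_tot_molar"] < 0).any() or (df["l_tot_molar"] < 0).any():
        raise ValueError("total concentrations must be non-negative")
    if (df["sigma"] <= 0).any():
        raise ValueError("sigma must be positive")


@dataclass
class FitResult:
    """Result of a titration fit."""

    model_tag: str                       # "one-site" | "two-site"
    estimates: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_starts_used: int
    observable: str = ""
    data: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "observable": self.observable,
            "estimates": self.estimates,
            "stderr": self.stderr,
            "r_squared": self.r_squared,
            "residuals": list(map(float, self.residuals)),
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }


# ---------------------------------------------------------------------------
# Equilibrium solvers
# ---------------------------------------------------------------------------

def _free_ligand_cubic(a_tot, l_tot, kd1, kd2):
    """Vectorised free-ligand root of the sequential two-site scheme.

    The ligand balance reduces to the cubic
        L^3/(kd1 kd2) + c2 L^2 + c1 L + c0 = 0
    with a unique root in [0, l_tot]; solved by safeguarded Newton from
    bisection brackets.
    """
    a_tot = np.asarray(a_tot, dtype=float)
    l_tot = np.asarray(l_tot, dtype=float)
    c3 = 1.0 / (kd1 * kd2)
    c2 = 1.0 / kd1 + (2.0 * a_tot - l_tot) / (kd1 * kd2)
    c1 = 1.0 + (a_tot - l_tot) / kd1
    c0 = -l_tot

    def poly(x):
        return ((c3 * x + c2) * x + c1) * x + c0

    def dpoly(x):
        return (3.0 * c3 * x + 2.0 * c2) * x + c1

    lo = np.zeros_like(l_tot)
    hi = l_tot.astype(float).copy()
    x = 0.5 * hi
    scale = np.maximum(l_tot, 1e-30)
    for _ in range(100):
        fx = poly(x)
        if np.all(np.abs(fx) <= 1e-12 * scale):
            break
        pos = fx > 0
        hi = np.where(pos, x, hi)
        lo = np.where(pos, lo, x)
        step = fx / np.where(np.abs(d := dpoly(x)) > 1e-300, d, 1.0)
        xn = x - step
        bad = ~np.isfinite(xn) | (xn <= lo) | (xn >= hi)
        x = np.where(bad, 0.5 * (lo + hi), xn)
    return x


def solve_equilibrium(a_tot: float, l_tot: float, kd1: float, kd2: float) -> SpeciesState:
    """Equilibrium species of the sequential scheme A+L<=>AL, AL+L<=>AL2.

    Finds free ligand by monotone bracketing (Brent) on [0, l_tot]; the
    remaining species follow from mass action. Both conservation balances
    hold to 1e-9 relative and both mass-action laws to 1e-8 relative.
    """
    if a_tot < 0 or l_tot < 0:
        raise ValueError("total concentrations must be non-negative")
    if kd1 <= 0 or kd2 <= 0:
        raise ValueError("dissociation constants must be positive")
    if l_tot == 0:
        return SpeciesState(conc_A=a_tot, conc_L=0.0, conc_AL=0.0, conc_AL2=0.0)

    def l_balance(l_free: float) -> float:
        p = l_free / kd1 + l_free ** 2 / (kd1 * kd2)
        a_free = a_tot / (1.0 + p)
        al = a_free * l_free / kd1
        al2 = al * l_free / kd2
        return l_free + al + 2.0 * al2 - l_tot

    l_free = brentq(l_balance, 0.0, l_tot, xtol=1e-30, rtol=1e-15)
    p = l_free / kd1 + l_free ** 2 / (kd1 * kd2)
    a_free = a_tot / (1.0 + p)
    al = a_free * l_free / kd1
    al2 = al * l_free / kd2
    return SpeciesState(conc_A=a_free, conc_L=l_free, conc_AL=al, conc_AL2=al2)


def _species_arrays(a_tot, l_tot, kd1, kd2):
    """Vectorised species concentrations (A, L, AL, AL2) via the cubic root."""
    l_free = _free_ligand_cubic(a_tot, l_tot, kd1, kd2)
    p = l_free / kd1 + l_free ** 2 / (kd1 * kd2)
    a_free = np.asarray(a_tot, dtype=float) / (1.0 + p)
    al = a_free * l_free / kd1
    al2 = al * l_free / kd2
    return a_free, l_free, al, al2


def sw_model(params: TwoSiteParams, a_tot, l_tot):
    """Signal-weighted weight-average sedimentation coefficient.

    s_w = sum_i w_i c_i s_i / sum_i w_i c_i over {A, L, AL, AL2}; free Lf
    contributes because the experiment integrates whole-mixture c(S)
    distributions (set include_free_ligand=False to restrict to A and the
    complexes).
    """
    a, l, al, al2 = _species_arrays(a_tot, l_tot, params.kd1, params.kd2)
    w = np.array([params.signal_weight_A, params.signal_weight_L,
                  params.signal_weight_AL, params.signal_weight_AL2])
    if not np.any(w > 0):
        raise ValueError("all signal weights are zero")
    s = np.array([params.s_A, params.s_L, params.s_AL, params.s_AL2])
    conc = np.stack([a, l, al, al2], axis=0)
    if not params.include_free_ligand:
        w = w.copy()
        w[1] = 0.0
    num = np.tensordot(w * s, conc, axes=(0, 0))
    den = np.tensordot(w, conc, axes=(0, 0))
    return num / den


def _one_site_free_ligand(a_tot, l_tot, kd):
    """Exact 1:1 depletion closed form for free ligand (quadratic root)."""
    a_tot = np.asarray(a_tot, dtype=float)
    l_tot = np.asarray(l_tot, dtype=float)
    b = kd + a_tot - l_tot
    return 0.5 * (-b + np.sqrt(b * b + 4.0 * kd * l_tot))


def sw_model_one_site(kd: float, a_tot, l_tot, s_A=DEFAULT_S["s_A"],
                      s_L=DEFAULT_S["s_L"], s_AL=DEFAULT_S["s_AL2"],
                      w_A=DEFAULT_W["signal_weight_A"],
                      w_L=DEFAULT_W["signal_weight_L"],
                      w_AL=DEFAULT_W["signal_weight_AL2"],
                      include_free_ligand: bool = True):
    """Single-site s_w model (A + L <=> AL only), exact depletion.

    The complex is assigned the largest observed peak position by default
    so the one-site model has its best chance of spanning the data range.
    """
    l_free = _one_site_free_ligand(a_tot, l_tot, kd)
    a_free = np.asarray(a_tot, dtype=float) / (1.0 + l_free / kd)
    al = a_free * l_free / kd
    wl = w_L if include_free_ligand else 0.0
    num = w_A * s_A * a_free + wl * s_L * l_free + w_AL * s_AL * al
    den = w_A * a_free + wl * l_free + w_AL * al
    return num / den


def fluor_model(params: FluorParams, a_tot, l_tot):
    """Independent-two-site fluorescence model with exact ligand depletion.

    F = f0 + df1*theta1 + df2*theta2, theta_i = L/(kd_i + L), with free L
    the unique root of l_tot = L + a_tot*(theta1 + theta2).
    """
    a_tot = np.asarray(a_tot, dtype=float)
    l_tot = np.asarray(l_tot, dtype=float)
    kd1, kd2 = params.kd1, params.kd2
    lo = np.zeros_like(l_tot)
    hi = l_tot.copy()
    # monotone bisection + Newton on g(L) = L + a_tot*(th1+th2) - l_tot
    x = 0.5 * hi
    scale = np.maximum(l_tot, 1e-30)
    for _ in range(100):
        th1 = x / (kd1 + x)
        th2 = x / (kd2 + x)
        g = x + a_tot * (th1 + th2) - l_tot
        if np.all(np.abs(g) <= 1e-13 * scale):
            break
        pos = g > 0
        hi = np.where(pos, x, hi)
        lo = np.where(pos, lo, x)
        dg = 1.0 + a_tot * (kd1 / (kd1 + x) ** 2 + kd2 / (kd2 + x) ** 2)
        xn = x - g / dg
        bad = ~np.isfinite(xn) | (xn < lo) | (xn > hi)
        x = np.where(bad, 0.5 * (lo + hi), xn)
    th1 = x / (kd1 + x)
    th2 = x / (kd2 + x)
    return params.f0 + params.df1 * th1 + params.df2 * th2


def fluor_model_one_site(f0: float, df: float, kd: float, a_tot, l_tot):
    """Single-site fluorescence model via the exact quadratic closed form."""
    l_free = _one_site_free_ligand(a_tot, l_tot, kd)
    return f0 + df * l_free / (kd + l_free)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _titration_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    df = data.points
    return (df["a_tot_molar"].to_numpy(), df["l_tot_molar"].to_numpy(),
            df["observable"].to_numpy(), df["sigma"].to_numpy())


def fit_binding(data: SwTitration | FluorTitration, model_tag: str = "two-site",
                fixed: Mapping[str, float] | None = None, n_starts: int = 32,
                seed: int = BASE_SEED) -> FitResult:
    """Weighted least-squares fit of a titration to a binding model.

    Kd parameters are optimised on a log scale from `n_starts` log-uniform
    random starts over [1 nM, 1 mM]; fluorescence amplitude parameters are
    initialised from the data range. The best converged start is returned
    with parameter standard errors from the Jacobian, R^2 on the fitted
    observable, and per-point residuals (observed - fitted).

    `fixed` overrides default fixed quantities: species s values and signal
    weights for s_w fits (s_A, s_L, s_AL, s_AL2, signal_weight_*), or any
    of f0, df1, df2 for fluorescence fits.
    """
    if model_tag not in ("one-site", "two-site"):
        raise ValueError("model_tag must be 'one-site' or 'two-site'")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    fixed = dict(fixed or {})
    a_tot, l_tot, obs, sigma = _titration_arrays(data)
    if np.var(obs) == 0:
        raise ValueError("degenerate data: observable has zero variance")
    is_fluor = isinstance(data, FluorTitration)

    lo, hi = KD_START_RANGE
    rng = np.random.default_rng(seed)

    if is_fluor:
        f_span = float(obs.max() - obs.min())
        f_base = float(obs[np.argmin(l_tot)])
        if model_tag == "two-site":
            names = ["f0", "df1", "df2", "kd1", "kd2"]

            def predict(theta):
                f0, df1, df2, lk1, lk2 = theta
                p = FluorParams(f0=f0, df1=df1, df2=df2,
                                kd1=10.0 ** lk1, kd2=10.0 ** lk2)
                return fluor_model(p, a_tot, l_tot)
        else:
            names = ["f0", "df1", "kd1"]

            def predict(theta):
                f0, df1, lk1 = theta
                return fluor_model_one_site(f0, df1, 10.0 ** lk1, a_tot, l_tot)

        def draw_start():
            kds = np.sort(10.0 ** rng.uniform(np.log10(lo), np.log10(hi),
                                              2 if model_tag == "two-site" else 1))
            amp = f_span if f_span > 0 else 1.0
            if model_tag == "two-site":
                return np.array([f_base, 0.7 * amp, 0.3 * amp,
                                 np.log10(kds[0]), np.log10(kds[1])])
            return np.array([f_base, amp, np.log10(kds[0])])
    else:
        s_fixed = {**DEFAULT_S, **{k: v for k, v in fixed.items() if k in DEFAULT_S}}
        w_fixed = {**DEFAULT_W, **{k: v for k, v in fixed.items() if k in DEFAULT_W}}
        if model_tag == "two-site":
            names = ["kd1", "kd2"]

            def predict(theta):
                p = TwoSiteParams(kd1=10.0 ** theta[0], kd2=10.0 ** theta[1],
                                  **s_fixed, **w_fixed)
                return sw_model(p, a_tot, l_tot)
        else:
            names = ["kd1"]

            def predict(theta):
                return sw_model_one_site(10.0 ** theta[0], a_tot, l_tot,
                                         s_A=s_fixed["s_A"], s_L=s_fixed["s_L"],
                                         s_AL=s_fixed["s_AL2"],
                                         w_A=w_fixed["signal_weight_A"],
                                         w_L=w_fixed["signal_weight_L"],
                                         w_AL=w_fixed["signal_weight_AL2"])

        def draw_start():
            kds = np.sort(10.0 ** rng.uniform(np.log10(lo), np.log10(hi),
                                              2 if model_tag == "two-site" else 1))
            return np.log10(kds)

    n_free = len(names)
    if obs.size < n_free + 1:
        raise ValueError("need at least (free parameters + 1) data points")

    def resid(theta):
        return (predict(theta) - obs) / sigma

    # box constraints: log10-Kd within a generous physical window, other
    # parameters free
    lower = np.array([-12.0 if n.startswith("kd") else -np.inf for n in names])
    upper = np.array([0.0 if n.startswith("kd") else np.inf for n in names])

    best = None
    n_used = 0
    for _ in range(n_starts):
        theta0 = np.clip(draw_start(), lower + 1e-9, upper - 1e-9)
        n_used += 1
        try:
            sol = least_squares(resid, theta0, method="trf", bounds=(lower, upper),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=800)
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    obs_frame = data.points.copy()
    if best is None:
        return FitResult(model_tag=model_tag, estimates={}, stderr={},
                         r_squared=float("nan"), residuals=np.full_like(obs, np.nan),
                         converged=False, n_starts_used=n_used,
                         observable=data.observable_name, data=obs_frame)

    theta = best.x
    fitted = predict(theta)
    residuals = obs - fitted
    ss_res = float(np.sum(residuals ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    estimates: dict[str, float] = {}
    for name, val in zip(names, theta):
        estimates[name] = float(10.0 ** val) if name.startswith("kd") else float(val)

    # delta-method standard errors on the natural scale
    stderr: dict[str, float] = {}
    dof = obs.size - n_free
    if dof > 0:
        jac = best.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * 2.0 * best.cost / dof
            se_theta = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for name, val, se in zip(names, theta, se_theta):
                if name.startswith("kd"):
                    stderr[name] = float(10.0 ** val * np.log(10.0) * se)
                else:
                    stderr[name] = float(se)
        except np.linalg.LinAlgError:
            pass

    return FitResult(model_tag=model_tag, estimates=estimates, stderr=stderr,
                     r_squared=r2, residuals=residuals, converged=True,
                     n_starts_used=n_used, observable=data.observable_name,
                     data=obs_frame)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def runs_test_exact(signs: Sequence[int] | np.ndarray) -> float:
    """Exact lower-tail Wald-Wolfowitz runs test p-value.

    `signs` is a sequence of +1/-1 (zeros are dropped). Returns
    P(R <= r_obs) under the null that all arrangements of the observed
    numbers of positive and negative signs are equally likely; small
    p-values indicate clustered (non-random) residual signs.
    """
    signs = [s for s in np.sign(np.asarray(signs, dtype=float)) if s != 0]
    n1 = sum(1 for s in signs if s > 0)
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 1.0
    r_obs = 1 + sum(1 for i in range(1, len(signs)) if signs[i] != signs[i - 1])
    total = math.comb(n1 + n2, n1)

    def count(r: int) -> int:
        if r % 2 == 0:
            k = r // 2
            return 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        k = (r - 1) // 2
        return (math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1)
                + math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k))

    return float(sum(count(r) for r in range(2, r_obs + 1)) / total)


def _aicc(ss_res: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC for least squares (k = params + variance)."""
    k = k + 1
    aic = n * math.log(ss_res / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


@dataclass(frozen=True)
class ModelComparison:
    """Comparison of a one-site and a two-site fit on the same data."""

    delta_r_squared: float            # two-site minus one-site
    runs_p_one_site: float
    runs_p_two_site: float
    delta_aicc: float                 # two-site minus one-site (negative favours two-site)
    preferred: str                    # "one-site" | "two-site" | "none"


def compare_models(fit_one: FitResult, fit_two: FitResult) -> ModelComparison:
    """Compare one-site vs two-site fits of the same titration.

    Reports delta-R^2, the exact runs-test p on each fit's residual signs,
    and the AICc difference. The preferred model must both raise R^2 and
    lower AICc; identical fits yield no preference.
    """
    if fit_one.data is None or fit_two.data is None:
        raise ValueError("fits must carry their data")
    if not fit_one.data[["a_tot_molar", "l_tot_molar", "observable"]].equals(
            fit_two.data[["a_tot_molar", "l_tot_molar", "observable"]]):
        raise ValueError("fits are not on identical data")
    n = len(fit_one.residuals)
    k1 = len(fit_one.estimates)
    k2 = len(fit_two.estimates)
    ss1 = float(np.sum(fit_one.residuals ** 2))
    ss2 = float(np.sum(fit_two.residuals ** 2))
    d_r2 = fit_two.r_squared - fit_one.r_squared
    d_aicc = _aicc(max(ss2, 1e-300), n, k2) - _aicc(max(ss1, 1e-300), n, k1)
    if abs(d_r2) < 1e-12 and abs(d_aicc) < 1e-9:
        preferred = "none"
    elif d_r2 > 0 and d_aicc < 0:
        preferred = "two-site"
    elif d_r2 < 0 and d_aicc > 0:
        preferred = "one-site"
    else:  # criteria disagree; fall back on AICc
        preferred = "two-site" if d_aicc < 0 else "one-site"
    return ModelComparison(
        delta_r_squared=d_r2,
        runs_p_one_site=runs_test_exact(fit_one.residuals),
        runs_p_two_site=runs_test_exact(fit_two.residuals),
        delta_aicc=d_aicc,
        preferred=preferred,
    )


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

def stoichiometry_select(mass_free_a: float, mass_free_l: float,
                         mass_complex: float, max_n: int = 4
                         ) -> tuple[int, int, float]:
    """Integer stoichiometry (n_a, n_l) best matching a complex mass.

    Enumerates n_a, n_l in [1, max_n] and returns the pair minimising the
    relative mass mismatch |n_a Ma + n_l Ml - Mc| / Mc, together with that
    relative error.
    """
    if min(mass_free_a, mass_free_l, mass_complex) <= 0:
        raise ValueError("masses must be positive")
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    best = None
    for n_a in range(1, max_n + 1):
        for n_l in range(1, max_n + 1):
            err = abs(n_a * mass_free_a + n_l * mass_free_l - mass_complex) / mass_complex
            if best is None or err < best[2]:
                best = (n_a, n_l, err)
    return best
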