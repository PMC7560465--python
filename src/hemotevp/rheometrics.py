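"""Derived rheological quantities and curve summaries.

Overshoot/thixotropic-index metrics for startup runs, apparent and
extensional viscosities, the Morris hematocrit--fibrinogen yield-stress
correlation and its inversion, descriptive fits (sigmoidal structure
curve, rational first-normal-stress-difference curve), Lissajous--Bowditch
and Pipkin constructions for LAOS, and the classical generalized-Newtonian
comparator models (Casson, Cross, Carreau--Yasuda).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit, least_squares

from .core import ModelParameters
from .integrator import IntegratorControls, integrate, periodic_steady_state
from .protocols import ProtocolSpec

__all__ = [
    "OvershootMetrics",
    "SigmoidFit",
    "N1RationalFit",
    "overshoot_metrics",
    "thixotropic_index",
    "max_thixotropic_index",
    "apparent_viscosity",
    "morris_yield_stress",
    "fibrinogen_from_yield",
    "fit_sigmoid_structure",
    "sigmoid_structure",
    "fit_n1_rational",
    "n1_rational",
    "extensional_viscosity",
    "lissajous_bowditch",
    "pipkin_grid",
    "gn_viscosity",
    "gn_fit",
]


# ---------------------------------------------------------------------------
# startup overshoot metrics and thixotropic index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OvershootMetrics:
    """Summary of a startup stress transient.

    ``theta`` is the time for the stress to fall from its peak to halfway
    between peak and steady value; it is 0 (with ``overshoot=False``) for
    monotone saturating traces.
    """

    tau_max: float
    t_peak: float
    tau_st: float
    theta: float
    overshoot: bool


#: Relative excess of the peak over the steady value below which a trace is
#: treated as monotone (no overshoot).  Guards against declaring round-off
#: ripples an overshoot.
_OVERSHOOT_RTOL = 1e-3


def overshoot_metrics(r: pd.DataFrame, channel: str = "txy") -> OvershootMetrics:
    """Peak/steady/half-decay summary of a constant-rate startup rheogram.

    The steady value is the mean over the trailing 1% of the time window
    (the run must have reached steady state); the peak is refined by
    parabolic interpolation through the discrete maximum, and the
    half-decay time by monotone (PCHIP) interpolation of the post-peak
    decay.
    """
    if not r.attrs.get("steady", False):
        raise ValueError("rheogram did not reach steady state")
    t = r["t"].to_numpy()
    s = r[channel].to_numpy()
    t_win = t[-1] - 0.01 * (t[-1] - t[0])
    tau_st = float(s[t >= t_win].mean())
    i = int(np.argmax(s))
    tau_max, t_peak = float(s[i]), float(t[i])
    if 0 < i < len(s) - 1:
        # parabolic refinement of the discrete peak
        y0, y1, y2 = s[i - 1], s[i], s[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            h = 0.5 * (y0 - y2) / denom
            h = min(max(h, -1.0), 1.0)
            if h >= 0:
                t_peak = t[i] + h * (t[i + 1] - t[i])
            else:
                t_peak = t[i] + h * (t[i] - t[i - 1])
            tau_max = float(y1 - 0.25 * (y0 - y2) * h)
    if tau_max <= tau_st * (1.0 + _OVERSHOOT_RTOL):
        return OvershootMetrics(tau_st, t_peak, tau_st, 0.0, False)
    level = tau_st + 0.5 * (tau_max - tau_st)
    post = np.nonzero((t > t_peak) & (s < level))[0]
    if len(post) == 0:
        return OvershootMetrics(tau_max, t_peak, tau_st, 0.0, False)
    j = post[0]
    lo = max(i + 1, j - 6)
    seg_t, seg_s = t[lo - 1:j + 1], s[lo - 1:j + 1]
    try:
        interp = PchipInterpolator(seg_t, seg_s)
        t_half = brentq(lambda x: float(interp(x)) - level, seg_t[0], seg_t[-1])
    except ValueError:
        t_half = float(np.interp(level, [s[j], s[j - 1]], [t[j], t[j - 1]]))
    return OvershootMetrics(tau_max, t_peak, tau_st, float(t_half - t_peak), True)


def thixotropic_index(m: OvershootMetrics, gamma_dot: float) -> float:
    """Dimensionless thixotropic index of a startup transient.

    ``xi = (tau_max - tau_st) / (tau_st * theta * gamma_dot)``

    Zero when there is no overshoot; ``inf`` (with a warning) in the
    degenerate case of an overshoot with vanishing decay time.  Being a
    ratio of stresses over (time x rate), xi is invariant to rescaling the
    stress unit.
    """
    if not gamma_dot > 0:
        raise ValueError("gamma_dot must be strictly positive")
    if not m.overshoot:
        return 0.0
    if m.theta <= 0.0:
        warnings.warn("overshoot with zero decay time: xi undefined",
                      stacklevel=2)
        return math.inf
    return (m.tau_max - m.tau_st) / (m.tau_st * m.theta * gamma_dot)


def _xi_at(rate: float, p: ModelParameters, ctrl: IntegratorControls) -> float:
    spec = ProtocolSpec.startup(rate, t_end=max(60.0, 400.0 / rate))
    r = integrate(spec, p, ctrl=ctrl, stop_when_steady=True)
    return thixotropic_index(overshoot_metrics(r), rate)


def max_thixotropic_index(p: ModelParameters,
                          rate_range: tuple[float, float] = (0.1, 1000.0),
                          points_per_decade: int = 8,
                          ctrl: Optional[IntegratorControls] = None,
                          ) -> tuple[float, float]:
    """Maximum of xi over imposed startup shear rate.

    Coarse log-spaced sweep followed by golden-section refinement of the
    bracketed maximum (xi is smooth and unimodal in rate for blood-like
    parameter sets).  Returns ``(xi_max, rate_at_max)``.
    """
    ctrl = ctrl or IntegratorControls()
    lo, hi = rate_range
    n = max(int(round(points_per_decade * math.log10(hi / lo))) + 1, 4)
    grid = np.geomspace(lo, hi, n)
    xi = np.array([_xi_at(g, p, ctrl) for g in grid])
    i = int(np.argmax(xi))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    # golden-section on log-rate
    la, lb = math.log(a), math.log(b)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = lb - invphi * (lb - la)
    d = la + invphi * (lb - la)
    fc, fd = _xi_at(math.exp(c), p, ctrl), _xi_at(math.exp(d), p, ctrl)
    best = max((xi[i], grid[i]), (fc, math.exp(c)), (fd, math.exp(d)))
    for _ in range(12):
        if fc > fd:
            lb, d, fd = d, c, fc
            c = lb - invphi * (lb - la)
            fc = _xi_at(math.exp(c), p, ctrl)
            if fc > best[0]:
                best = (fc, math.exp(c))
        else:
            la, c, fc = c, d, fd
            d = la + invphi * (lb - la)
            fd = _xi_at(math.exp(d), p, ctrl)
            if fd > best[0]:
                best = (fd, math.exp(d))
        if lb - la < 5e-3:
            break
    return best


def apparent_viscosity(tau_xy: float, gamma_dot: float) -> float:
    """Steady apparent viscosity ``tau_xy / gamma_dot`` in Pa·s."""
    if gamma_dot == 0:
        raise ZeroDivisionError("apparent viscosity undefined at zero rate")
    return tau_xy / gamma_dot


# ---------------------------------------------------------------------------
# Morris hematocrit / fibrinogen yield-stress correlation
# ---------------------------------------------------------------------------

_MORRIS = (-0.091, 0.47, 0.22, -0.14, 0.48)  # c0 + c1 Hc + c2 cf + c3 cf^2 + c4 Hc cf
_MORRIS_HC = (0.40, 0.80)
_MORRIS_CF = (0.1, 0.9)
DYN_PER_CM2 = 0.1  # Pa


def _morris_inner(Hc: float, cf: float) -> float:
    c0, c1, c2, c3, c4 = _MORRIS
    return c0 + c1 * Hc + c2 * cf + c3 * cf * cf + c4 * Hc * cf


def _morris_range_check(Hc: float, cf: Optional[float] = None) -> None:
    if not _MORRIS_HC[0] <= Hc <= _MORRIS_HC[1]:
        warnings.warn(f"hematocrit {Hc} outside the correlation's validity "
                      f"range {_MORRIS_HC}", stacklevel=3)
    if cf is not None and not _MORRIS_CF[0] <= cf <= _MORRIS_CF[1]:
        warnings.warn(f"fibrinogen {cf} g/dL outside the correlation's "
                      f"validity range {_MORRIS_CF}", stacklevel=3)


def morris_yield_stress(Hc: float, cf: float) -> float:
    """Blood yield stress (Pa) from hematocrit and fibrinogen concentration.

    Empirical correlation ``tau_y,c = (inner)^2`` with the inner polynomial
    linear in hematocrit ``Hc`` (volume fraction) and quadratic in
    fibrinogen ``cf`` (g/dL); the correlation is stated in dyn/cm^2 and
    converted here (1 dyn/cm^2 = 0.1 Pa).  A negative inner expression is
    clipped to zero yield stress with a warning.
    """
    _morris_range_check(Hc, cf)
    inner = _morris_inner(Hc, cf)
    if inner < 0:
        warnings.warn("inner Morris expression negative; yield stress "
                      "reported as 0", stacklevel=2)
        return 0.0
    return inner * inner * DYN_PER_CM2


def fibrinogen_from_yield(tau_y: float, Hc: float) -> float:
    """Invert the Morris correlation for the fibrinogen concentration (g/dL).

    Takes the smallest positive root of the quadratic in ``cf``; round-trips
    with :func:`morris_yield_stress` to machine accuracy on the validity
    rectangle.
    """
    if tau_y < 0:
        raise ValueError("tau_y must be non-negative")
    _morris_range_check(Hc)
    c0, c1, c2, c3, c4 = _MORRIS
    s = math.sqrt(tau_y / DYN_PER_CM2)
    # c3 cf^2 + (c2 + c4 Hc) cf + (c0 + c1 Hc - s) = 0
    a, b, c = c3, c2 + c4 * Hc, c0 + c1 * Hc - s
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("no real fibrinogen root for this (tau_y, Hc)")
    roots = sorted(((-b + math.sqrt(disc)) / (2 * a),
                    (-b - math.sqrt(disc)) / (2 * a)))
    positive = [r for r in roots if r > 0]
    if not positive:
        if abs(roots[-1]) < 1e-12:
            return 0.0
        raise ValueError("no positive fibrinogen root for this (tau_y, Hc)")
    return positive[0]


# ---------------------------------------------------------------------------
# descriptive fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidFit:
    """Sigmoidal description of the steady structure curve lam(rate).

    ``lam_s = A + (B - A) * rate^n / (k^n + rate^n)`` with plateaus ``A``
    (rest) and ``B`` (strong flow), crossover rate ``k`` (1/s) and
    steepness ``n``.
    """

    A: float
    B: float
    k: float
    n: float
    rms: float = float("nan")

    def __call__(self, rate):
        return sigmoid_structure(rate, self.A, self.B, self.k, self.n)


def sigmoid_structure(rate, A, B, k, n):
    rate = np.asarray(rate, dtype=float)
    rn = rate ** n
    return A + (B - A) * rn / (k ** n + rn)


def fit_sigmoid_structure(rates, lams) -> SigmoidFit:
    """Least-squares sigmoid fit to steady structure-parameter samples."""
    rates = np.asarray(rates, dtype=float)
    lams = np.asarray(lams, dtype=float)
    if len(rates) < 8:
        raise ValueError("need at least 8 samples spanning the transition")
    p0 = (float(lams.max()), float(lams.min()),
          float(np.sqrt(rates.min() * rates.max())), 1.5)
    try:
        popt, _ = curve_fit(sigmoid_structure, rates, lams, p0=p0,
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"sigmoid fit did not converge from initial guess {p0}") from exc
    resid = sigmoid_structure(rates, *popt) - lams
    return SigmoidFit(*popt, rms=float(np.sqrt(np.mean(resid ** 2))))


@dataclass(frozen=True)
class N1RationalFit:
    """Rational description of the steady N1(elongation-rate) curve.

    ``N1 = (A1 + A2 e) / (1 + A3 e + A4 e^2)`` with A1 in Pa, A2 in Pa·s,
    A3 in s and A4 in s^2; the denominator must stay positive over the
    fitted range.
    """

    A1: float
    A2: float
    A3: float
    A4: float
    rms: float = float("nan")

    def __call__(self, rate):
        return n1_rational(rate, self.A1, self.A2, self.A3, self.A4)


def n1_rational(rate, A1, A2, A3, A4):
    rate = np.asarray(rate, dtype=float)
    return (A1 + A2 * rate) / (1.0 + A3 * rate + A4 * rate ** 2)


def fit_n1_rational(rates, n1) -> N1RationalFit:
    """Least-squares rational fit to steady N1 samples.

    A linearised solve (multiplying through by the denominator) provides
    the initial guess for the nonlinear refinement; fits whose denominator
    changes sign inside the data range are rejected.
    """
    rates = np.asarray(rates, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    A = np.column_stack([np.ones_like(rates), rates, -n1 * rates,
                         -n1 * rates ** 2])
    p0, *_ = np.linalg.lstsq(A, n1, rcond=None)
    popt, _ = curve_fit(n1_rational, rates, n1, p0=p0, maxfev=20000)
    den = 1.0 + popt[2] * rates + popt[3] * rates ** 2
    if np.any(den <= 0):
        raise ValueError("fitted denominator not positive over the data range")
    resid = n1_rational(rates, *popt) - n1
    return N1RationalFit(*popt, rms=float(np.sqrt(np.mean(resid ** 2))))


def extensional_viscosity(fit: N1RationalFit, rate):
    """Extensional viscosity ``eta_e = N1 / rate`` (Pa·s) from a fit."""
    rate = np.asarray(rate, dtype=float)
    return fit(rate) / rate


# ---------------------------------------------------------------------------
# LAOS constructions
# ---------------------------------------------------------------------------

def lissajous_bowditch(cycle: pd.DataFrame) -> pd.DataFrame:
    """Elastic and viscous projections of one periodic LAOS cycle.

    Returns a frame with strain, rate, shear stress, normal stress and the
    structure channel; plotting stress against strain gives the elastic
    projection, against rate the viscous one.  Non-periodic input (cycle
    cap hit before alternance) is flagged with a warning.
    """
    if not cycle.attrs.get("periodic", True):
        warnings.warn("cycle is flagged non-periodic; projections describe "
                      "the last transient cycle", stacklevel=2)
    cols = ["phase", "strain", "rate", "txy", "txx", "lam"]
    missing = [c for c in cols if c not in cycle.columns]
    if missing:
        raise ValueError(f"cycle rheogram lacks channels {missing}")
    return cycle[cols].copy()


def pipkin_grid(p: ModelParameters, gamma0_list, omega_list,
                ctrl: Optional[IntegratorControls] = None,
                n_cycles: int = 40, cycle_tol: float = 1e-4) -> pd.DataFrame:
    """Grid of LAOS projections over strain amplitude and frequency.

    Long-format frame: one row per phase sample per (gamma_0, omega) cell,
    with the stress, strain, rate and structure channels — the raw material
    for a Pipkin diagram.
    """
    frames = []
    for g0 in gamma0_list:
        for w in omega_list:
            spec = ProtocolSpec.laos(g0, w, n_cycles=n_cycles)
            cyc = periodic_steady_state(spec, p, ctrl=ctrl,
                                        cycle_tol=cycle_tol)
            proj = lissajous_bowditch(cyc)
            proj.insert(0, "gamma_0", g0)
            proj.insert(1, "omega", w)
            proj["periodic"] = bool(cyc.attrs.get("periodic"))
            frames.append(proj)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# generalized-Newtonian comparators
# ---------------------------------------------------------------------------

GN_MODELS = ("casson", "cross", "carreau_yasuda")


def gn_viscosity(model: str, params: dict, gamma_dot):
    """Steady viscosity (Pa·s) of a generalized-Newtonian comparator model.

    casson:          sqrt(tau) = sqrt(tau_y) + sqrt(eta_c * rate)
    cross:           eta = eta_inf + (eta_0 - eta_inf) / (1 + (K rate)^m)
    carreau_yasuda:  eta = eta_inf + (eta_0 - eta_inf)
                           * (1 + (lam_c rate)^a)^((n - 1)/a)
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g <= 0):
        raise ValueError("gamma_dot must be strictly positive")
    if any(v < 0 for v in params.values()):
        raise ValueError("generalized-Newtonian parameters must be >= 0")
    if model == "casson":
        tau = (np.sqrt(params["tau_y"]) + np.sqrt(params["eta_c"] * g)) ** 2
        return tau / g
    if model == "cross":
        return params["eta_inf"] + (params["eta_0"] - params["eta_inf"]) / (
            1.0 + (params["K"] * g) ** params["m"])
    if model == "carreau_yasuda":
        return params["eta_inf"] + (params["eta_0"] - params["eta_inf"]) * (
            1.0 + (params["lam_c"] * g) ** params["a"]
        ) ** ((params["n"] - 1.0) / params["a"])
    raise ValueError(f"unknown model {model!r}; choose from {GN_MODELS}")


_GN_PARAM_NAMES = {
    "casson": ("tau_y", "eta_c"),
    "cross": ("eta_inf", "eta_0", "K", "m"),
    "carreau_yasuda": ("eta_inf", "eta_0", "lam_c", "a", "n"),
}


def gn_fit(model: str, gamma_dot, eta) -> dict:
    """Fit a generalized-Newtonian model to steady flow-curve data.

    Least squares on log-viscosity (the flow curve spans decades), with the
    parameters log-parameterised to enforce positivity.
    """
    g = np.asarray(gamma_dot, dtype=float)
    eta = np.asarray(eta, dtype=float)
    names = _GN_PARAM_NAMES[model]
    guesses = {
        "casson": (eta[-1] * g[-1] * 0.1, eta[-1]),
        "cross": (eta[-1], eta[0], 1.0 / np.sqrt(g[0] * g[-1]), 1.0),
        "carreau_yasuda": (eta[-1], eta[0], 1.0 / np.sqrt(g[0] * g[-1]),
                           2.0, 0.5),
    }[model]
    x0 = np.log(np.maximum(guesses, 1e-12))

    def resid(x):
        params = dict(zip(names, np.exp(x)))
        return np.log(gn_viscosity(model, params, g)) - np.log(eta)

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    return dict(zip(names, np.exp(sol.x)))
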