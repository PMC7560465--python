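"""Time integration of the coupled stress/structure ODE system.

The state is the seven-vector ``y = (txx, tyy, tzz, txy, txz, tyz, lam)``.
Integration uses a second-order predictor--corrector pair with an adjustable
time step: an explicit Adams--Bashforth-2 predictor (Euler on the first step
after an event) and an A-stable trapezoidal-rule corrector solved by a
damped modified-Newton iteration with a finite-difference Jacobian.  Step
acceptance is controlled by the predictor--corrector discrepancy measured
against ``rtol``/``atol``; kinematic discontinuities of the protocol are
treated as exact restart events with state carried over continuously.

Steady states are obtained by time-marching until the scaled right-hand
side norm drops below ``steady_tol`` and then polishing the algebraic
system with a Newton solve; :func:`flow_curve` sweeps rates from high to
low with parameter continuation, which is robust near the yield point.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import root

from .core import (
    ModelParameters,
    MaterialState,
    SymmetricTensor,
    effective_stress,
    flow_parameter,
    ptt_factor,
    relaxation_time,
    thixotropic_viscosity,
)
from .protocols import ProtocolSpec

__all__ = [
    "IntegratorControls",
    "integrate",
    "steady_state",
    "steady_channels",
    "flow_curve",
    "periodic_steady_state",
    "rheogram_metadata",
    "export_rheogram",
]

IDX = {"txx": 0, "tyy": 1, "tzz": 2, "txy": 3, "txz": 4, "tyz": 5, "lam": 6}


@dataclass(frozen=True)
class IntegratorControls:
    """Numerical controls of the predictor--corrector integrator.

    The defaults resolve all bundled parameter sets comfortably; they are
    plumbing, not physics.  ``steady_tol`` is the scaled norm of the
    right-hand side (relative state change per second) below which a
    constant-rate run is declared stationary.
    """

    rtol: float = 1e-6
    atol: float = 1e-9
    dt_init: float = 1e-4
    dt_min: float = 1e-12
    dt_max: float = 0.25
    newton_tol: float = 1e-11
    steady_tol: float = 1e-6
    max_newton: int = 12

    def __post_init__(self):
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("need 0 < dt_min <= dt_init <= dt_max")
        for name in ("rtol", "atol", "newton_tol", "steady_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# fast scalar right-hand side
# ---------------------------------------------------------------------------

def _rhs(t: float, y, rate_fn: Callable[[float], float], mode: str,
         p: ModelParameters) -> np.ndarray:
    """d/dt of (txx, tyy, tzz, txy, txz, tyz, lam) for homogeneous flow.

    Specialised closed forms of the tensor expression in
    :func:`hemotevp.core.stress_rate` for the two kinematic modes; the
    general matrix route is retained in the core module and serves as the
    cross-check oracle in the test suite.
    """
    txx, tyy, tzz, txy, txz, tyz, lam = y
    tr = txx + tyy + tzz
    pr = tr / 3.0
    dxx, dyy, dzz = txx - pr, tyy - pr, tzz - pr
    j2 = 0.5 * (dxx * dxx + dyy * dyy + dzz * dzz) + txy * txy + txz * txz + tyz * tyz
    sigma = math.sqrt(j2) if j2 > 0.0 else 0.0
    phi = sigma - p.tau_y
    lc = min(max(lam, 0.0), 1.0)
    if phi > 0.0:
        eta_t = max(p.eta0 * lc ** p.m1, p.eta_floor)
        beta = (1.0 + p.eps_ptt * tr / p.G) * phi / (2.0 * eta_t * sigma)
        dlam = (p.k1 + p.k2 * phi ** p.n1) * (1.0 - lam) \
            - p.k3 * phi ** p.n3 * lc ** p.n2
    else:
        beta = 0.0
        dlam = p.k1 * (1.0 - lam)
    g = rate_fn(t)
    c = 2.0 * p.G * beta
    if mode == "shear":
        return np.array([
            2.0 * g * txy - c * txx,
            -c * tyy,
            -c * tzz,
            g * tyy + p.G * g - c * txy,
            g * tyz - c * txz,
            -c * tyz,
            dlam,
        ])
    # uniaxial: L = diag(e, -e/2, -e/2)
    return np.array([
        2.0 * g * txx + 2.0 * p.G * g - c * txx,
        -g * tyy - p.G * g - c * tyy,
        -g * tzz - p.G * g - c * tzz,
        0.5 * g * txy - c * txy,
        0.5 * g * txz - c * txz,
        -g * tyz - c * tyz,
        dlam,
    ])


def _fd_jacobian(t, y, rate_fn, mode, p, f0) -> np.ndarray:
    J = np.empty((7, 7))
    for j in range(7):
        h = 1e-7 * max(abs(y[j]), 1e-4)
        yp = y.copy()
        yp[j] += h
        J[:, j] = (_rhs(t, yp, rate_fn, mode, p) - f0) / h
    return J


# ---------------------------------------------------------------------------
# one adaptive segment (smooth kinematics between events)
# ---------------------------------------------------------------------------

class _StepError(RuntimeError):
    pass


def _integrate_segment(t0, t1, y, rate_fn, mode, p, ctrl, out_t, out_y,
                       steady_check=False, adaptive=True):
    """Advance y from t0 to t1, appending accepted samples to out_t/out_y.

    Returns (y, reached_steady)."""
    t = t0
    dt = min(ctrl.dt_init, max(t1 - t0, ctrl.dt_min))
    f_prev = None
    dt_prev = None
    scale_floor = 1e-6
    # steadiness is judged on the mean state change per second over a
    # trailing horizon, which averages out step-level integration wobble
    ref_t, ref_y = t0, y.copy()
    while t < t1 - 1e-13 * max(1.0, t1):
        dt = min(dt, t1 - t)
        f_n = _rhs(t, y, rate_fn, mode, p)
        if not np.all(np.isfinite(f_n)):
            raise _StepError(f"non-finite right-hand side at t={t}")
        if steady_check and t - ref_t >= max(0.5, 0.05 * (t - t0)):
            change = np.max(np.abs(y - ref_y) /
                            ((t - ref_t) * (np.abs(y) + scale_floor)))
            if change < ctrl.steady_tol:
                return y, True
            ref_t, ref_y = t, y.copy()
        # predictor: variable-step AB2, Euler on the first step of a segment
        if f_prev is not None:
            r = dt / dt_prev
            y_p = y + dt * ((1.0 + 0.5 * r) * f_n - 0.5 * r * f_prev)
        else:
            y_p = y + dt * f_n
        # corrector: trapezoidal rule, modified Newton
        y_c, converged = _trapezoid_solve(t, y, dt, f_n, y_p, rate_fn, mode, p, ctrl)
        accept = converged
        err = 0.0
        if converged:
            err = np.max(np.abs(y_c - y_p) /
                         (ctrl.atol + ctrl.rtol * np.maximum(np.abs(y), np.abs(y_c))))
            accept = err <= 1.0 or not adaptive
            lam_new = y_c[6]
            if adaptive and (lam_new < -1e-6 or lam_new > 1.0 + 1e-6):
                accept = False  # overshot [0,1] by more than round-off
        if accept:
            y_c[6] = min(max(lam_new, 0.0), 1.0)
            t += dt
            y = y_c
            out_t.append(t)
            out_y.append(y)
            f_prev, dt_prev = f_n, dt
            if adaptive:
                dt = min(dt * min(4.0, max(0.2, 0.85 * err ** (-1.0 / 3.0)
                                           if err > 0 else 4.0)),
                         ctrl.dt_max)
        else:
            dt *= 0.5
            f_prev = None  # restart the multistep history after a rejection
            if dt < ctrl.dt_min:
                raise _StepError(
                    f"step size underflow at t={t} (corrector "
                    f"{'diverged' if not converged else 'error too large'})")
    return y, False


def _trapezoid_solve(t, y, dt, f_n, y_guess, rate_fn, mode, p, ctrl):
    """Solve y1 = y + dt/2 (f_n + f(t+dt, y1)) by damped modified Newton."""
    t1 = t + dt
    yk = y_guess.copy()
    J = None
    for _ in range(ctrl.max_newton):
        fk = _rhs(t1, yk, rate_fn, mode, p)
        if not np.all(np.isfinite(fk)):
            return yk, False
        g = yk - y - 0.5 * dt * (f_n + fk)
        # residual kept well below the step-acceptance tolerance so the
        # corrector solve never pollutes the local-error estimate
        gn = np.max(np.abs(g) / (ctrl.atol + ctrl.rtol * np.maximum(np.abs(yk), 1.0)))
        if gn < 1e-2:
            return yk, True
        if J is None:
            J = np.eye(7) - 0.5 * dt * _fd_jacobian(t1, yk, rate_fn, mode, p, fk)
        try:
            step = np.linalg.solve(J, g)
        except np.linalg.LinAlgError:
            return yk, False
        yk = yk - step
    return yk, False


# ---------------------------------------------------------------------------
# public driver
# ---------------------------------------------------------------------------

def integrate(spec: ProtocolSpec, p: ModelParameters,
              init: Optional[MaterialState] = None,
              ctrl: Optional[IntegratorControls] = None,
              t_end: Optional[float] = None,
              stop_when_steady: bool = False,
              fixed_dt: Optional[float] = None) -> pd.DataFrame:
    """Integrate a protocol and return a rheogram (tidy DataFrame).

    The rheogram has one row per accepted step with the state, the imposed
    rate and all derived channels (effective stress, structural viscosity,
    relaxation time, elastic/viscoplastic deformation-rate splits, N1).
    Protocol events are hit exactly and the state is continuous across
    them.  ``stop_when_steady`` terminates a constant-rate run once the
    scaled right-hand side drops below ``ctrl.steady_tol``.
    ``fixed_dt`` disables step adaptivity (used for order verification).
    """
    ctrl = ctrl or IntegratorControls()
    init = init or MaterialState.rest()
    tau = init.tau
    y = np.array([tau.xx, tau.yy, tau.zz, tau.xy, tau.xz, tau.yz, init.lam],
                 dtype=float)
    pts = spec.breakpoints(t_end)
    mode = spec.mode
    out_t: list[float] = [pts[0]]
    out_y: list[np.ndarray] = [y.copy()]
    reached = False
    if fixed_dt is not None:
        ctrl = replace(ctrl, dt_init=fixed_dt, dt_max=fixed_dt,
                       dt_min=fixed_dt * 0.999999)
    rate_fn = spec.rate
    try:
        for t0, t1 in zip(pts[:-1], pts[1:]):
            # probe the segment interior so discontinuities at t0 do not leak
            seg_rate = lambda t, _lo=t0, _hi=t1: rate_fn(
                min(max(t, _lo), _hi - 1e-12 * max(1.0, _hi)))
            y, reached = _integrate_segment(
                t0, t1, y, seg_rate, mode, p, ctrl, out_t, out_y,
                steady_check=stop_when_steady, adaptive=fixed_dt is None)
            if reached:
                break
    except _StepError as exc:
        raise RuntimeError(
            f"integration of {spec.kind} protocol failed: {exc}") from exc
    df = _as_rheogram(np.array(out_t), np.array(out_y), spec, p)
    df.attrs.update(protocol=_spec_dict(spec), params=p.to_dict(),
                    controls=asdict(ctrl), steady=bool(reached))
    return df


def _spec_dict(spec: ProtocolSpec) -> dict:
    return {"kind": spec.kind, **spec.params}


def _as_rheogram(tt: np.ndarray, yy: np.ndarray, spec: ProtocolSpec,
                 p: ModelParameters) -> pd.DataFrame:
    df = pd.DataFrame(yy, columns=list(IDX))
    df.insert(0, "t", tt)
    df["rate"] = [spec.rate(min(t, (spec.duration or np.inf))) for t in tt]
    derive_channels(df, p, spec.mode)
    return df


def derive_channels(df: pd.DataFrame, p: ModelParameters, mode: str) -> pd.DataFrame:
    """Recompute all derived channels in-place from the raw state columns."""
    tr = df.txx + df.tyy + df.tzz
    dxx, dyy, dzz = df.txx - tr / 3, df.tyy - tr / 3, df.tzz - tr / 3
    j2 = 0.5 * (dxx**2 + dyy**2 + dzz**2) + df.txy**2 + df.txz**2 + df.tyz**2
    sigma = np.sqrt(np.clip(j2, 0.0, None))
    phi = np.clip(sigma - p.tau_y, 0.0, None)
    eta_t = np.maximum(p.eta0 * np.clip(df.lam, 0, 1) ** p.m1, p.eta_floor)
    f_ptt = 1.0 + p.eps_ptt * tr / p.G
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(phi > 0, f_ptt * phi / (2.0 * eta_t * sigma), 0.0)
    df["sigma_eff"] = sigma
    df["phi"] = phi
    df["eta_t"] = eta_t
    df["chi"] = eta_t / p.G
    df["N1"] = df.txx - df.tyy
    df["Dvp_xx"] = beta * df.txx
    df["Dvp_xy"] = beta * df.txy
    df["Dvp_yy"] = beta * df.tyy
    if mode == "shear":
        df["De_xx"] = -df.Dvp_xx
        df["De_xy"] = 0.5 * df.rate - df.Dvp_xy
    else:
        df["De_xx"] = df.rate - df.Dvp_xx
        df["De_xy"] = -df.Dvp_xy
    return df


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _state_from_vector(t: float, y: np.ndarray) -> MaterialState:
    return MaterialState(
        t, SymmetricTensor(y[0], y[1], y[2], y[3], y[4], y[5]),
        float(min(max(y[6], 0.0), 1.0)))


def steady_state(rate: float, mode: str, p: ModelParameters,
                 ctrl: Optional[IntegratorControls] = None,
                 t_cap: Optional[float] = None,
                 polish: bool = True) -> MaterialState:
    """Long-time attractor at constant imposed rate (shear or uniaxial).

    Time-marches from rest until the scaled state change per second drops
    below ``ctrl.steady_tol``, then (optionally) polishes with a Newton
    solve of the algebraic system using the marched state as the initial
    guess.  The polished root is only accepted when it agrees with the
    marched state, which guards against the solver sliding across the
    yield surface.
    """
    if not rate > 0:
        raise ValueError("rate must be strictly positive")
    if mode not in ("shear", "uniaxial"):
        raise ValueError("mode must be 'shear' or 'uniaxial'")
    ctrl = ctrl or IntegratorControls()
    if t_cap is None:
        t_cap = 1e4 * max(p.chi0, 1.0 / p.k1)
    spec = (ProtocolSpec.startup(rate, t_end=t_cap) if mode == "shear"
            else ProtocolSpec.uniaxial(rate, t_end=t_cap))
    df = integrate(spec, p, ctrl=ctrl, stop_when_steady=True)
    if not df.attrs.get("steady"):
        raise RuntimeError(
            f"no steady state within t_cap={t_cap:g} s at rate {rate:g}; "
            f"last state lam={df.lam.iloc[-1]:.4g}")
    y = df[list(IDX)].iloc[-1].to_numpy()
    if polish:
        sol = root(lambda z: _rhs(0.0, z, lambda t: rate, mode, p), y,
                   method="hybr", tol=1e-13)
        if sol.success and np.all(np.abs(sol.x - y) <=
                                  1e-4 * (np.abs(y) + 1e-6)):
            y = sol.x
    return _state_from_vector(df.t.iloc[-1], y)


def steady_channels(state: MaterialState, rate: float, mode: str,
                    p: ModelParameters) -> dict:
    """Derived steady quantities for a single (rate, state) pair."""
    tau = state.tau
    sigma = effective_stress(tau)
    phi = flow_parameter(sigma, p)
    eta_t = max(thixotropic_viscosity(state.lam, p), p.eta_floor)
    beta = ptt_factor(tau, p) * phi / (2.0 * eta_t * sigma) if phi > 0 else 0.0
    out = {
        "rate": rate, "mode": mode,
        "txx": tau.xx, "tyy": tau.yy, "txy": tau.xy, "lam": state.lam,
        "sigma_eff": sigma, "eta_t": eta_t, "chi": relaxation_time(state.lam, p),
        "N1": tau.xx - tau.yy,
        "Dvp_xx": beta * tau.xx, "Dvp_xy": beta * tau.xy,
    }
    out["eta_app"] = tau.xy / rate if mode == "shear" else np.nan
    out["eta_e"] = out["N1"] / rate if mode == "uniaxial" else np.nan
    return out


def _steady_residual_shear(z, rate, p):
    """Reduced steady simple-shear system in (log tau_xy, lam).

    At steady state tyy = tzz = 0 exactly and txx = 2 txy^2 / G, leaving a
    2x2 root problem; used for fast continuation sweeps over rate.
    """
    txy = math.exp(z[0])
    lam = z[1]
    txx = 2.0 * txy * txy / p.G
    pr = txx / 3.0
    sigma = math.sqrt(0.5 * ((txx - pr) ** 2 + 2.0 * pr * pr) + txy * txy)
    phi = sigma - p.tau_y
    lc = min(max(lam, 1e-12), 1.0)
    eta_t = max(p.eta0 * lc ** p.m1, p.eta_floor)
    f = 1.0 + p.eps_ptt * txx / p.G
    beta = f * phi / (2.0 * eta_t * sigma) if phi > 0 else 0.0
    r1 = beta - rate / (2.0 * txy)
    r2 = (p.k1 + p.k2 * max(phi, 0.0) ** p.n1) * (1.0 - lam) \
        - p.k3 * max(phi, 0.0) ** p.n3 * lc ** p.n2
    return [r1, r2]


def flow_curve(p: ModelParameters, rates, mode: str = "shear",
               ctrl: Optional[IntegratorControls] = None) -> pd.DataFrame:
    """Steady flow curve over a set of rates (one row per rate).

    Shear sweeps use continuation on the reduced algebraic system from the
    highest rate downward (low-rate states are stiff near the yield
    surface); uniaxial sweeps fall back to the generic
    :func:`steady_state` solver per rate.
    """
    rates = np.sort(np.asarray(rates, dtype=float))[::-1]
    rows = []
    if mode == "shear":
        guess = None
        for r in rates:
            if guess is None:
                lam0 = 0.5
                txy0 = p.tau_y + p.eta0 * lam0 ** p.m1 * r
                guess = [math.log(txy0), lam0]
            sol = root(_steady_residual_shear, guess, args=(r, p),
                       method="hybr", tol=1e-13)
            if not sol.success:
                st = steady_state(r, "shear", p, ctrl)
                rows.append(steady_channels(st, r, "shear", p))
                guess = [math.log(max(st.tau.xy, 1e-300)), st.lam]
                continue
            txy = math.exp(sol.x[0])
            lam = float(min(max(sol.x[1], 0.0), 1.0))
            txx = 2.0 * txy * txy / p.G
            st = MaterialState(0.0, SymmetricTensor(xx=txx, xy=txy), lam)
            rows.append(steady_channels(st, r, "shear", p))
            guess = sol.x
    else:
        for r in rates:
            st = steady_state(r, "uniaxial", p, ctrl)
            rows.append(steady_channels(st, r, "uniaxial", p))
    return pd.DataFrame(rows[::-1]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# oscillatory (alternating) steady state
# ---------------------------------------------------------------------------

def periodic_steady_state(spec: ProtocolSpec, p: ModelParameters,
                          ctrl: Optional[IntegratorControls] = None,
                          cycle_tol: float = 1e-5,
                          n_phase: int = 400) -> pd.DataFrame:
    """Integrate LAOS cycles until the periodic (alternance) state.

    Cycles are integrated one at a time; once the relative L2 distance
    between consecutive cycles' (tau_xy, lam) traces falls below
    ``cycle_tol`` the final cycle is returned with a ``phase`` channel
    (radians in [0, 2 pi)).  If the cap ``spec.params['n_cycles']`` is
    reached first, the last cycle is returned flagged non-periodic.
    """
    if spec.kind != "laos":
        raise ValueError("periodic_steady_state expects a laos protocol")
    ctrl = ctrl or IntegratorControls()
    omega = spec.params["omega"]
    gamma_0 = spec.params["gamma_0"]
    T = 2.0 * math.pi / omega
    ctrl = replace(ctrl, dt_max=min(ctrl.dt_max, T / 100.0))
    phase_grid = np.linspace(0.0, T, n_phase, endpoint=False)
    y = np.array([0.0] * 6 + [1.0])
    prev_sample = None
    converged = False
    rate_fn = spec.rate
    n_cycles = spec.params["n_cycles"]
    for cycle in range(n_cycles):
        t0 = cycle * T
        out_t, out_y = [t0], [y.copy()]
        y, _ = _integrate_segment(
            t0, t0 + T, y,
            lambda t: gamma_0 * omega * math.cos(omega * t),
            "shear", p, ctrl, out_t, out_y)
        tt = np.array(out_t) - t0
        yy = np.array(out_y)
        sample = np.column_stack([
            np.interp(phase_grid, tt, yy[:, IDX["txy"]]),
            np.interp(phase_grid, tt, yy[:, IDX["lam"]]),
        ])
        if prev_sample is not None:
            num = np.linalg.norm(sample - prev_sample, axis=0)
            den = np.linalg.norm(sample, axis=0) + 1e-30
            if float(np.max(num / den)) < cycle_tol:
                converged = True
                break
        prev_sample = sample
    df = _as_rheogram(np.array(out_t), np.array(out_y), spec, p)
    df["phase"] = (df.t % T) * omega
    df["strain"] = gamma_0 * np.sin(omega * df.t)
    df.attrs.update(protocol=_spec_dict(spec), params=p.to_dict(),
                    controls=asdict(ctrl), periodic=converged,
                    cycles_run=cycle + 1)
    return df


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def rheogram_metadata(df: pd.DataFrame) -> dict:
    """Reproducibility metadata (protocol, parameters, controls, run hash)."""
    meta = {k: df.attrs.get(k) for k in
            ("protocol", "params", "controls", "steady", "periodic")}
    h = hashlib.sha256()
    h.update(json.dumps(meta, sort_keys=True, default=float).encode())
    h.update(np.ascontiguousarray(df.to_numpy()).tobytes())
    meta["run_hash"] = h.hexdigest()[:16]
    return meta


def export_rheogram(df: pd.DataFrame, csv_path, meta_path=None) -> None:
    """Write a rheogram as tidy CSV plus a JSON metadata side-car."""
    df.to_csv(csv_path, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump(rheogram_metadata(df), fh, indent=2, default=float)
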