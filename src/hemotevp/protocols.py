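"""Imposed-kinematics protocols for homogeneous rheometric flows.

Every protocol is a prescribed velocity-gradient history ``L(t)``.  Shear
protocols use the convention ``u = (gd(t) * y, 0, 0)``, i.e. the single
nonzero entry of ``L`` is ``L[1, 0] = gd`` (with ``L_ij = du_j / dx_i``), so
the shear stress is ``tau_xy`` and the normal stress generated by the
upper-convected elasticity is ``tau_xx``.  Uniaxial extension imposes the
traceless diagonal gradient ``diag(e, -e/2, -e/2)``.

Discontinuous rate switches (startup, cessation, intermittent steps) are
represented as exact event times; the integrator restarts at events instead
of smoothing the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolSpec",
    "velocity_gradient",
    "shear_rate",
    "exp_rampdown_rate",
    "transformed_time",
    "schedule_table",
]

KINDS = (
    "steady_shear", "startup", "cessation", "intermittent",
    "triangular", "exp_rampdown", "laos", "uniaxial",
)


@dataclass(frozen=True)
class ProtocolSpec:
    """A named imposed-kinematics history and its parameters.

    Use the class-method constructors (:meth:`startup`, :meth:`cessation`,
    ...) rather than filling fields by hand; they validate the
    per-protocol parameter sets.
    """

    kind: str
    params: dict = field(default_factory=dict)
    #: if True, querying beyond the protocol end holds the final kinematics
    #: instead of raising.
    hold_last: bool = False

    # ---------------------------------------------------------- constructors
    @classmethod
    def startup(cls, gamma_dot_0: float, t_end: Optional[float] = None,
                **kw) -> "ProtocolSpec":
        """Step change to constant shear rate ``gamma_dot_0`` at t = 0.

        A zero rate is admitted and describes a rest (relaxation) hold."""
        if gamma_dot_0 < 0:
            raise ValueError("gamma_dot_0 must be non-negative")
        return cls("startup", {"gamma_dot_0": gamma_dot_0, "t_end": t_end}, **kw)

    steady_shear = startup  # a startup run to steady state *is* the steady test

    @classmethod
    def cessation(cls, gamma_dot_0: float, t_ces: float,
                  t_end: Optional[float] = None, **kw) -> "ProtocolSpec":
        """Constant shear until ``t_ces``, then the flow is switched off."""
        _positive(gamma_dot_0=gamma_dot_0, t_ces=t_ces)
        return cls("cessation",
                   {"gamma_dot_0": gamma_dot_0, "t_ces": t_ces, "t_end": t_end},
                   **kw)

    @classmethod
    def intermittent(cls, gamma_dot_0: float, t_on: float, t_rest: float,
                     n_pulses: int = 2, **kw) -> "ProtocolSpec":
        """Rectangular shear steps: ``n_pulses`` pulses of duration ``t_on``
        at rate ``gamma_dot_0``, separated (and followed) by rest intervals
        of duration ``t_rest``."""
        _positive(gamma_dot_0=gamma_dot_0, t_on=t_on)
        if t_rest < 0 or n_pulses < 1:
            raise ValueError("t_rest must be >= 0 and n_pulses >= 1")
        return cls("intermittent",
                   {"gamma_dot_0": gamma_dot_0, "t_on": t_on,
                    "t_rest": t_rest, "n_pulses": int(n_pulses)}, **kw)

    @classmethod
    def triangular(cls, a: float, t_max: float, **kw) -> "ProtocolSpec":
        """Hysteresis ramp: rate ``a * t`` up to ``t_max / 2``, then
        ``a * (t_max - t)`` back down to zero.  Peak rate ``a * t_max / 2``."""
        _positive(a=a, t_max=t_max)
        return cls("triangular", {"a": a, "t_max": t_max}, **kw)

    @classmethod
    def exp_rampdown(cls, gamma_dot_start: float, gamma_dot_end: float,
                     a: float, dt: float, stepped: bool = False,
                     **kw) -> "ProtocolSpec":
        """Exponential ramp-down ``gd(t) = gd_start * exp(-t / (a dt))``
        from ``gd_start`` to ``gd_end``; ``a`` is the number of transition
        steps and ``dt`` the per-step duration.  ``stepped=True`` holds the
        rate piecewise-constant over each step instead of the continuous
        exponential."""
        _positive(gamma_dot_start=gamma_dot_start, gamma_dot_end=gamma_dot_end,
                  a=a, dt=dt)
        if not gamma_dot_start > gamma_dot_end:
            raise ValueError("gamma_dot_start must exceed gamma_dot_end")
        return cls("exp_rampdown",
                   {"gamma_dot_start": gamma_dot_start,
                    "gamma_dot_end": gamma_dot_end,
                    "a": a, "dt": dt, "stepped": bool(stepped)}, **kw)

    @classmethod
    def laos(cls, gamma_0: float, omega: float, n_cycles: int = 20,
             **kw) -> "ProtocolSpec":
        """Large-amplitude oscillatory shear, ``gd(t) = gamma_0 w cos(w t)``
        (strain starts at zero, rate at its maximum)."""
        _positive(gamma_0=gamma_0, omega=omega)
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        return cls("laos", {"gamma_0": gamma_0, "omega": omega,
                            "n_cycles": int(n_cycles)}, **kw)

    @classmethod
    def uniaxial(cls, eps_dot_0: float, t_end: Optional[float] = None,
                 **kw) -> "ProtocolSpec":
        """Startup of uniaxial elongation at rate ``eps_dot_0``."""
        _positive(eps_dot_0=eps_dot_0)
        return cls("uniaxial", {"eps_dot_0": eps_dot_0, "t_end": t_end}, **kw)

    # ------------------------------------------------------------ geometry
    @property
    def mode(self) -> str:
        """'uniaxial' or 'shear' kinematics."""
        return "uniaxial" if self.kind == "uniaxial" else "shear"

    @property
    def duration(self) -> Optional[float]:
        """Natural protocol duration, or None for open-ended protocols."""
        p = self.params
        if self.kind in ("startup", "steady_shear", "cessation", "uniaxial"):
            return p.get("t_end")
        if self.kind == "intermittent":
            return p["n_pulses"] * (p["t_on"] + p["t_rest"])
        if self.kind == "triangular":
            return p["t_max"]
        if self.kind == "exp_rampdown":
            n_steps = p["a"] * math.log(p["gamma_dot_start"] / p["gamma_dot_end"])
            if p["stepped"]:
                n_steps = math.ceil(n_steps)
            return n_steps * p["dt"]
        if self.kind == "laos":
            return p["n_cycles"] * 2.0 * math.pi / p["omega"]
        raise ValueError(f"unknown protocol kind {self.kind!r}")

    def breakpoints(self, t_end: Optional[float] = None) -> list[float]:
        """Exact event times (kinematic discontinuities) in [0, t_end]."""
        t_end = self._resolve_end(t_end)
        pts = [0.0]
        p = self.params
        if self.kind == "cessation":
            pts.append(p["t_ces"])
        elif self.kind == "intermittent":
            t = 0.0
            for _ in range(p["n_pulses"]):
                t += p["t_on"]
                pts.append(t)
                if p["t_rest"] > 0:
                    t += p["t_rest"]
                    pts.append(t)
        elif self.kind == "triangular":
            pts.append(p["t_max"] / 2.0)
        elif self.kind == "exp_rampdown" and p["stepped"]:
            n = int(math.ceil(self.duration / p["dt"]))
            pts.extend(i * p["dt"] for i in range(1, n))
        pts.append(t_end)
        pts = sorted({t for t in pts if 0.0 <= t <= t_end + 1e-15})
        return pts

    def _resolve_end(self, t_end: Optional[float]) -> float:
        if t_end is None:
            t_end = self.duration
        if t_end is None:
            raise ValueError(f"{self.kind} protocol needs an explicit t_end")
        return float(t_end)

    # ------------------------------------------------------------- kinematics
    def rate(self, t: float) -> float:
        """Scalar imposed rate (shear rate, or elongation rate) at time t."""
        if t < 0:
            raise ValueError("t must be >= 0")
        p = self.params
        dur = self.duration
        if dur is not None and t > dur + 1e-12:
            if not self.hold_last:
                raise ValueError(
                    f"t={t} beyond the {self.kind} protocol end ({dur} s); "
                    "construct with hold_last=True to hold the last value"
                )
            t = dur
        k = self.kind
        if k in ("startup", "steady_shear"):
            return p["gamma_dot_0"]
        if k == "cessation":
            return p["gamma_dot_0"] if t < p["t_ces"] else 0.0
        if k == "intermittent":
            period = p["t_on"] + p["t_rest"]
            i = min(int(t // period), p["n_pulses"] - 1)
            local = t - i * period
            return p["gamma_dot_0"] if local < p["t_on"] else 0.0
        if k == "triangular":
            return p["a"] * transformed_time(self, min(t, p["t_max"]))
        if k == "exp_rampdown":
            return exp_rampdown_rate(self, t)
        if k == "laos":
            return p["gamma_0"] * p["omega"] * math.cos(p["omega"] * t)
        if k == "uniaxial":
            return p["eps_dot_0"]
        raise ValueError(f"unknown protocol kind {k!r}")

    def velocity_gradient(self, t: float) -> np.ndarray:
        return velocity_gradient(self, t)


def _positive(**kv) -> None:
    for name, value in kv.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


def velocity_gradient(spec: ProtocolSpec, t: float) -> np.ndarray:
    """Velocity-gradient tensor ``L(t)`` (1/s) for a protocol.

    Shear protocols return ``L`` with the single nonzero entry
    ``L[1, 0]``; uniaxial extension returns the traceless
    ``diag(e, -e/2, -e/2)``.
    """
    r = spec.rate(t)
    L = np.zeros((3, 3))
    if spec.mode == "uniaxial":
        L[0, 0], L[1, 1], L[2, 2] = r, -0.5 * r, -0.5 * r
    else:
        L[1, 0] = r
    return L


def shear_rate(spec: ProtocolSpec, t) -> np.ndarray:
    """Vectorised scalar rate history (convenience wrapper over .rate)."""
    return np.array([spec.rate(float(ti)) for ti in np.atleast_1d(t)])


def exp_rampdown_rate(spec: ProtocolSpec, t: float) -> float:
    """Shear rate of the exponential ramp-down protocol at time t.

    Continuous form ``gd(t) = gd_start * exp(-t / (a dt))``; the stepped
    variant samples that exponential at the start of each step of duration
    ``dt`` and holds it constant over the step.
    """
    if spec.kind != "exp_rampdown":
        raise ValueError("spec is not an exp_rampdown protocol")
    if t < 0:
        raise ValueError("t must be >= 0")
    p = spec.params
    if p["stepped"]:
        t = math.floor(t / p["dt"]) * p["dt"]
    return max(p["gamma_dot_start"] * math.exp(-t / (p["a"] * p["dt"])),
               p["gamma_dot_end"])


def transformed_time(spec: ProtocolSpec, t: float) -> float:
    """Folded time ``t' = t`` (ramp up) or ``t_max - t`` (ramp down).

    Maps both branches of the triangular protocol onto [0, t_max/2] so that
    up- and down-sweep rheograms overlay at equal instantaneous rate.
    """
    if spec.kind != "triangular":
        raise ValueError("spec is not a triangular protocol")
    t_max = spec.params["t_max"]
    if not 0.0 <= t <= t_max + 1e-12:
        raise ValueError(f"t={t} outside the protocol window [0, {t_max}]")
    return t if t < t_max / 2.0 else t_max - t


def schedule_table(spec: ProtocolSpec, t_end: Optional[float] = None) -> pd.DataFrame:
    """Human-readable breakpoint schedule (exportable as CSV)."""
    pts = spec.breakpoints(t_end)
    rows = []
    for t0, t1 in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (t0 + t1)
        rows.append({
            "t_start": t0,
            "t_end": t1,
            "mode": spec.mode,
            "rate_start": spec.rate(t0),
            "rate_mid": spec.rate(mid),
            "rate_end": spec.rate(min(t1, pts[-1]) - 1e-12),
        })
    return pd.DataFrame(rows)
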