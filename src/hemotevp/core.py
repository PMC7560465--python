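"""Constitutive core of the TEVP (thixotropic elasto-visco-plastic) blood model.

Blood is modelled as a single-mode viscoelastic stress ``tau`` (the plasma
solvent is folded into the viscoelastic contribution, so there is no separate
Newtonian stress) coupled to a scalar structure parameter ``lam`` in [0, 1]
that tracks the instantaneous level of rouleaux aggregation: ``lam = 1`` is
fully structured (jammed rouleaux network), ``lam -> 0`` fully dispersed
red cells.  Plastic flow switches on through a von Mises criterion on the
effective (deviatoric) stress with yield stress ``tau_y``; the plastic
multiplier is modulated by a linear Phan-Thien/Tanner (PTT) factor that
bounds the extensional viscosity.  The plastic viscosity and relaxation time
are structure-dependent power laws, which is what makes the material a
*non-ideal* thixotropic one.

All quantities are strict SI internally (Pa, s); unit conversions happen at
the reporting layer only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "SymmetricTensor",
    "MaterialState",
    "PRESETS",
    "load_preset",
    "deviatoric",
    "effective_stress",
    "ptt_factor",
    "thixotropic_viscosity",
    "relaxation_time",
    "flow_parameter",
    "structure_rate",
    "viscoplastic_deformation",
    "stress_rate",
]

#: Canonical field order of a parameter table / config file.
PARAMETER_FIELDS = (
    "G", "eta0", "tau_y", "eps_ptt",
    "k1", "k2", "k3", "n1", "n2", "n3", "m1",
)

#: Floor applied to the structural viscosity inside the plastic multiplier.
#: The dynamics keep lam strictly positive so the floor is never active in
#: practice; it only protects the integrator against transient round-off.
ETA_FLOOR_DEFAULT = 1e-12


@dataclass(frozen=True)
class ModelParameters:
    """The eleven fitted constants of the TEVP blood model.

    Parameters
    ----------
    G : float
        Elastic modulus, Pa.
    eta0 : float
        Structural (plastic) viscosity at full structure, Pa·s.
    tau_y : float
        Yield stress, Pa.
    eps_ptt : float
        Mobility of the linear PTT function, dimensionless.
    k1 : float
        Brownian (rest) rebuild rate of rouleaux, 1/s.
    k2 : float
        Flow-induced rebuild coefficient.
    k3 : float
        Flow-induced breakdown coefficient.
    n1, n2, n3 : float
        Kinetic exponents.  The rebuild driving stress enters as
        ``phi**n1``; in the breakdown term the driving stress enters as
        ``phi**n3`` and the structure level as ``lam**n2`` (see
        :func:`structure_rate`).
    m1 : float
        Exponent of the structural viscosity power law ``eta_t = eta0 *
        lam**m1``.

    Notes
    -----
    The derived relaxation time at full structure is ``chi0 = eta0 / G``.
    ``tau_y``, ``k2`` and ``k3`` may be zero, which yields degenerate
    (Maxwell-type) limits that are useful for verification; the remaining
    constants must be strictly positive.  For blood-like sets the breakdown
    coefficient must dominate the flow-induced rebuild (``k3 > k2``) and
    ``n1 < n2``; violating sets are accepted with a warning.
    """

    G: float
    eta0: float
    tau_y: float
    eps_ptt: float
    k1: float
    k2: float
    k3: float
    n1: float
    n2: float
    n3: float
    m1: float
    eta_floor: float = field(default=ETA_FLOOR_DEFAULT, compare=False)

    def __post_init__(self) -> None:
        for name in ("G", "eta0", "k1", "n1", "n2", "n3", "m1"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in ("tau_y", "k2", "k3", "eps_ptt"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if self.k3 and not (self.k3 > self.k2 and self.n1 < self.n2):
            warnings.warn(
                "blood-like parameter sets require k3 > k2 and n1 < n2; "
                "this set violates that ordering",
                stacklevel=2,
            )

    @property
    def chi0(self) -> float:
        """Relaxation time at full structure, ``eta0 / G`` (s)."""
        return self.eta0 / self.G

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("eta_floor")
        d["chi0"] = self.chi0
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        d.pop("chi0", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _load_builtin(name: str) -> ModelParameters:
    text = resources.files("hemotevp.presets").joinpath(f"{name}.yaml").read_text()
    return ModelParameters.from_dict(yaml.safe_load(text))


class _PresetMap(dict):
    """Lazy mapping of bundled parameter sets."""

    _names = ("mcmillan1987_subject", "armstrong2018_donor1")

    def __missing__(self, key):
        if key in self._names:
            self[key] = _load_builtin(key)
            return self[key]
        raise KeyError(key)

    def keys(self):  # pragma: no cover - cosmetic
        return self._names


PRESETS = _PresetMap()


def load_preset(name: str) -> ModelParameters:
    """Return one of the bundled fitted parameter sets by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PresetMap._names)}"
        ) from None


# ---------------------------------------------------------------------------
# tensors and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymmetricTensor:
    """Symmetric second-order tensor with six independent components.

    Used for stresses (Pa) and deformation rates (1/s) alike.
    """

    xx: float = 0.0
    yy: float = 0.0
    zz: float = 0.0
    xy: float = 0.0
    xz: float = 0.0
    yz: float = 0.0

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.xx, self.xy, self.xz],
                [self.xy, self.yy, self.yz],
                [self.xz, self.yz, self.zz],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, *, rtol: float = 1e-9) -> "SymmetricTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 matrix")
        scale = max(1.0, float(np.abs(m).max()))
        if not np.allclose(m, m.T, atol=rtol * scale):
            raise ValueError("matrix is not symmetric")
        s = 0.5 * (m + m.T)
        return cls(s[0, 0], s[1, 1], s[2, 2], s[0, 1], s[0, 2], s[1, 2])

    @property
    def trace(self) -> float:
        return self.xx + self.yy + self.zz

    def __add__(self, other: "SymmetricTensor") -> "SymmetricTensor":
        return SymmetricTensor(
            self.xx + other.xx, self.yy + other.yy, self.zz + other.zz,
            self.xy + other.xy, self.xz + other.xz, self.yz + other.yz,
        )

    def __mul__(self, c: float) -> "SymmetricTensor":
        return SymmetricTensor(
            c * self.xx, c * self.yy, c * self.zz,
            c * self.xy, c * self.xz, c * self.yz,
        )

    __rmul__ = __mul__


TensorLike = Union[SymmetricTensor, np.ndarray]


def _as_tensor(z: TensorLike) -> SymmetricTensor:
    if isinstance(z, SymmetricTensor):
        return z
    return SymmetricTensor.from_matrix(np.asarray(z, dtype=float))


@dataclass
class MaterialState:
    """Material point state: time, viscoelastic stress and structure level."""

    t: float = 0.0
    tau: SymmetricTensor = field(default_factory=SymmetricTensor)
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not -1e-12 <= self.lam <= 1.0 + 1e-12:
            raise ValueError("structure parameter lam must lie in [0, 1]")
        self.lam = min(max(self.lam, 0.0), 1.0)

    @classmethod
    def rest(cls) -> "MaterialState":
        """Fully structured, stress-free initial state (tau = 0, lam = 1)."""
        return cls(0.0, SymmetricTensor(), 1.0)


# ---------------------------------------------------------------------------
# algebraic constitutive relations
# ---------------------------------------------------------------------------

def deviatoric(z: TensorLike) -> SymmetricTensor:
    """Deviatoric part ``z - (tr z / 3) I`` of a symmetric tensor."""
    z = _as_tensor(z)
    p = z.trace / 3.0
    return SymmetricTensor(z.xx - p, z.yy - p, z.zz - p, z.xy, z.xz, z.yz)


def effective_stress(tau: TensorLike) -> float:
    """Von Mises effective stress ``sqrt((tauD : tauD) / 2)`` in Pa.

    Invariant under addition of an isotropic tensor; reduces to ``|tau_xy|``
    in simple shear with vanishing normal stresses.
    """
    d = deviatoric(tau)
    j2 = 0.5 * (d.xx ** 2 + d.yy ** 2 + d.zz ** 2) + d.xy ** 2 + d.xz ** 2 + d.yz ** 2
    return math.sqrt(max(j2, 0.0))


def ptt_factor(tau: TensorLike, p: ModelParameters) -> float:
    """Linear PTT function ``f = 1 + eps_ptt * tr(tau) / G``."""
    return 1.0 + p.eps_ptt * _as_tensor(tau).trace / p.G


def _check_lam(lam: float) -> float:
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"structure parameter lam={lam} outside [0, 1]")
    return lam


def thixotropic_viscosity(lam: float, p: ModelParameters) -> float:
    """Structural (plastic) viscosity ``eta_t = eta0 * lam**m1`` in Pa·s."""
    return p.eta0 * _check_lam(lam) ** p.m1


def relaxation_time(lam: float, p: ModelParameters) -> float:
    """Structure-dependent relaxation time ``chi = chi0 * lam**m1`` in s."""
    return p.chi0 * _check_lam(lam) ** p.m1


def flow_parameter(sigma_eff: float, p: ModelParameters) -> float:
    """Stress-controlled driving force ``phi = max(0, sigma_eff - tau_y)``.

    Zero at and below the yield surface, so both the plastic flow and the
    flow-induced structure kinetics switch off in the unyielded regime.
    """
    if sigma_eff < 0.0:
        raise ValueError("effective stress must be non-negative")
    return max(0.0, sigma_eff - p.tau_y)


def structure_rate(lam: float, sigma_eff: float, p: ModelParameters) -> float:
    """Net rate of change of the structure parameter, 1/s.

    ``dlam/dt = (k1 + k2 * phi**n1) * (1 - lam) - k3 * phi**n3 * lam**n2``

    The first term is rouleaux rebuild — Brownian collisions (``k1``) plus a
    flow-induced contribution — proportional to the unstructured fraction
    ``1 - lam``; the second is flow-induced breakdown proportional to a
    power of the structured fraction.  Because the two stress exponents are
    equal for the fitted blood sets (``n1 = n3``), the balance at strong
    flow becomes stress-independent and the structure level saturates at a
    finite ``lam_inf`` solving ``k2 (1 - lam) = k3 lam**n2``: blood never
    becomes fully unstructured, and the high-shear viscosity plateaus at a
    value a few times the plasma viscosity.
    """
    lam = _check_lam(lam)
    phi = flow_parameter(sigma_eff, p)
    rebuild = (p.k1 + p.k2 * phi ** p.n1) * (1.0 - lam)
    breakdown = p.k3 * phi ** p.n3 * lam ** p.n2
    return rebuild - breakdown


def equilibrium_structure(sigma_eff: float, p: ModelParameters,
                          tol: float = 1e-14) -> float:
    """Fixed point ``lam*`` of :func:`structure_rate` at fixed effective stress.

    Solved by bisection on the monotone rebuild/breakdown balance; used as an
    independent check that long-time integrations converge to the algebraic
    equilibrium.
    """
    lo, hi = 0.0, 1.0
    f_hi = structure_rate(hi, sigma_eff, p)
    if f_hi >= 0.0:
        return 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if structure_rate(mid, sigma_eff, p) >= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def viscoplastic_deformation(tau: TensorLike, lam: float,
                             p: ModelParameters) -> SymmetricTensor:
    """Viscoplastic part of the deformation-rate tensor, 1/s.

    ``Dvp = f[tr tau] * max(0, (sigma_eff - tau_y) / (2 eta_t sigma_eff)) * tau``

    Below the yield surface (``sigma_eff <= tau_y``) the multiplier clamps
    to zero and the material deforms purely elastically.  Above yield the
    viscoplastic rate is colinear with the stress tensor, so component
    ratios of ``Dvp`` equal the corresponding stress ratios.  The scalar
    multiplier is evaluated without ever forming a 0/0 quotient.
    """
    tau = _as_tensor(tau)
    _check_lam(lam)
    sigma = effective_stress(tau)
    if sigma <= p.tau_y or sigma == 0.0:
        return SymmetricTensor()
    eta_t = max(thixotropic_viscosity(lam, p), p.eta_floor)
    mult = ptt_factor(tau, p) * (sigma - p.tau_y) / (2.0 * eta_t * sigma)
    return mult * tau


def stress_rate(state: MaterialState, L: np.ndarray,
                p: ModelParameters) -> SymmetricTensor:
    """Right-hand side ``d tau / dt`` for homogeneous flow, Pa/s.

    The elastic part of the deformation rate is ``De = (1 / 2G) * tau^nabla``
    (upper-convected derivative), and ``D = De + Dvp`` closes the system:

    ``d tau / dt = L^T . tau + tau . L + 2 G (D - Dvp)``

    where ``L = grad(u)`` with the convention ``L_ij = du_j / dx_i`` (simple
    shear ``u = (gd * y, 0, 0)`` puts the rate in ``L[1, 0]``) and
    ``D = (L + L^T) / 2``.  For homogeneous rheometric flow the advection
    term vanishes.  At ``tau = 0`` this reduces to neo-Hookean loading
    ``2 G D``.
    """
    L = np.asarray(L, dtype=float)
    tau_m = state.tau.as_matrix()
    D = 0.5 * (L + L.T)
    dvp = viscoplastic_deformation(state.tau, state.lam, p).as_matrix()
    rate = L.T @ tau_m + tau_m @ L + 2.0 * p.G * (D - dvp)
    return SymmetricTensor.from_matrix(0.5 * (rate + rate.T))
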