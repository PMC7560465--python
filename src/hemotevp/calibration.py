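"""Parameter estimation from rheometric data, and synthetic-data generation.

The calibration follows the protocol used to obtain the bundled parameter
sets: the eleven model constants are regressed *simultaneously* against a
steady flow curve and one or more transient stress traces.  Steady
residuals are taken in log-stress (the flow curve spans several decades),
transient residuals in linear stress; each block is normalised by its own
RMS so steady and transient data contribute comparably.

Because the original rheometer data are not redistributable, the module
also provides a synthetic-data generator that simulates exact curves from a
known parameter set and applies multiplicative log-normal noise — the
standard device for parameter-recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ModelParameters, PARAMETER_FIELDS
from .integrator import IntegratorControls, flow_curve, integrate
from .protocols import ProtocolSpec

__all__ = [
    "RheometricDataset",
    "FitResult",
    "generate_synthetic_dataset",
    "residuals",
    "fit_parameters",
    "DEFAULT_BOUNDS",
]


@dataclass
class RheometricDataset:
    """Steady + transient rheometric data for a single blood sample.

    ``steady`` holds (rate, stress) pairs of the steady simple-shear flow
    curve; ``transients`` is a list of (protocol, trace) pairs where each
    trace has (t, stress) columns.  Optional small-amplitude oscillatory
    sweeps (omega, G', G'') may be attached but are not used by the default
    objective.
    """

    steady: pd.DataFrame
    transients: list[tuple[ProtocolSpec, pd.DataFrame]] = field(
        default_factory=list)
    oscillatory: Optional[pd.DataFrame] = None
    weights: Optional[dict] = None
    label: str = ""

    def __post_init__(self):
        s = self.steady
        if not {"rate", "stress"} <= set(s.columns):
            raise ValueError("steady block needs 'rate' and 'stress' columns")
        if len(s) == 0:
            raise ValueError("at least one steady block is required")
        if not (s["rate"] > 0).all():
            raise ValueError("steady rates must be positive")
        if not s["rate"].is_monotonic_increasing:
            raise ValueError("steady rates must be sorted increasing")
        for spec, tr in self.transients:
            if not {"t", "stress"} <= set(tr.columns):
                raise ValueError("transient traces need 't' and 'stress'")
            if not tr["t"].is_monotonic_increasing or (tr["t"] < 0).any():
                raise ValueError("transient times must be sorted and >= 0")


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    params: ModelParameters
    cost: float
    block_rms: dict
    n_starts: int
    start_costs: list
    success: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "cost": self.cost,
            "block_rms": self.block_rms,
            "n_starts": self.n_starts,
            "start_costs": list(self.start_costs),
            "success": self.success,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

def default_design() -> dict:
    """Measurement design mirroring the fitting blocks of the bundled sets:
    a steady sweep over 0.01--1000 1/s plus an intermittent rectangular
    shear-step trace (7 1/s, 2.5 s pulses, 1.5 s rests) and a triangular
    ramp (a = 10 1/s^2, t_max = 6 s)."""
    return {
        "steady_rates": np.geomspace(0.01, 1000.0, 24),
        "transients": [
            (ProtocolSpec.intermittent(7.0, 2.5, 1.5, n_pulses=2),
             np.linspace(0.02, 8.0, 240)),
            (ProtocolSpec.triangular(10.0, 6.0),
             np.linspace(0.03, 6.0, 200)),
        ],
    }


def generate_synthetic_dataset(p: ModelParameters,
                               design: Optional[dict] = None,
                               noise_cv: float = 0.02,
                               seed: Optional[int] = None,
                               ctrl: Optional[IntegratorControls] = None,
                               ) -> RheometricDataset:
    """Simulate a rheometric dataset from known parameters.

    Exact model curves are computed for every block of the design, then
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` is applied (``noise_cv = 0`` returns the exact curves).
    Reproducible for a fixed ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    design = design or default_design()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))

    def noisy(x):
        x = np.asarray(x, dtype=float)
        if noise_cv == 0:
            return x.copy()
        return x * np.exp(rng.normal(0.0, sigma, size=x.shape)
                          - 0.5 * sigma ** 2)

    rates = np.sort(np.asarray(design["steady_rates"], dtype=float))
    fc = flow_curve(p, rates, mode="shear", ctrl=ctrl)
    steady = pd.DataFrame({"rate": fc["rate"].to_numpy(),
                           "stress": noisy(fc["txy"].to_numpy())})
    transients = []
    for spec, t_sample in design.get("transients", []):
        r = integrate(spec, p, ctrl=ctrl)
        stress = np.interp(t_sample, r["t"], r["txy"])
        transients.append((spec, pd.DataFrame({"t": t_sample,
                                               "stress": noisy(stress)})))
    return RheometricDataset(steady=steady, transients=transients,
                             label=f"synthetic(cv={noise_cv}, seed={seed})")


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

_PENALTY = 1e3


def residuals(p: ModelParameters, d: RheometricDataset,
              ctrl: Optional[IntegratorControls] = None) -> np.ndarray:
    """Concatenated weighted residual vector of a parameter set.

    Steady block: log-stress residuals.  Transient blocks: linear stress
    residuals normalised by the block RMS.  A failed simulation at a trial
    point contributes a large finite penalty instead of raising, which
    keeps bounded least-squares optimisers alive.
    """
    ctrl = ctrl or IntegratorControls(rtol=1e-5, atol=1e-8)
    weights = d.weights or {}
    blocks = []
    w = weights.get("steady", 1.0)
    try:
        fc = flow_curve(p, d.steady["rate"].to_numpy(), mode="shear",
                        ctrl=ctrl)
        model = fc["txy"].to_numpy()
        if np.any(~np.isfinite(model)) or np.any(model <= 0):
            raise FloatingPointError("non-positive steady stress")
        blocks.append(w * (np.log(model)
                           - np.log(d.steady["stress"].to_numpy())))
    except Exception as exc:  # noqa: BLE001 - optimizer robustness by design
        warnings.warn(f"steady simulation failed ({exc}); penalised",
                      stacklevel=2)
        blocks.append(np.full(len(d.steady), _PENALTY))
    for i, (spec, tr) in enumerate(d.transients):
        w = weights.get(f"transient_{i}", 1.0)
        scale = float(np.sqrt(np.mean(tr["stress"] ** 2)))
        try:
            r = integrate(spec, p, ctrl=ctrl)
            model = np.interp(tr["t"], r["t"], r["txy"])
            if np.any(~np.isfinite(model)):
                raise FloatingPointError("non-finite transient stress")
            blocks.append(w * (model - tr["stress"].to_numpy()) / scale)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"transient {i} simulation failed ({exc}); "
                          "penalised", stacklevel=2)
            blocks.append(np.full(len(tr), _PENALTY))
    return np.concatenate(blocks)


#: Default (lower, upper) calibration bounds per parameter.  Wide but
#: physical: moduli and viscosities within a couple of decades of healthy
#: blood, exponents order one.
DEFAULT_BOUNDS = {
    "G": (1e-2, 10.0),
    "eta0": (1e-3, 1.0),
    "tau_y": (1e-4, 0.1),
    "eps_ptt": (1e-5, 0.1),
    "k1": (1e-3, 10.0),
    "k2": (1e-2, 1e3),
    "k3": (1.0, 1e6),
    "n1": (0.5, 6.0),
    "n2": (0.5, 8.0),
    "n3": (0.5, 6.0),
    "m1": (0.1, 3.0),
}


def fit_parameters(d: RheometricDataset,
                   bounds: Optional[dict] = None,
                   n_starts: int = 8,
                   seed: Optional[int] = 0,
                   x0: Optional[ModelParameters] = None,
                   ctrl: Optional[IntegratorControls] = None,
                   max_nfev: Optional[int] = None,
                   xtol: float = 1e-10, ftol: float = 1e-10) -> FitResult:
    """Multi-start bounded least squares over the eleven model constants.

    Parameters are optimised in log space (all are positive scale
    parameters).  Starts are drawn log-uniformly inside ``bounds`` (the
    first start is ``x0`` when given); the best converged start wins.
    Deterministic for a fixed ``seed``.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for name, (lo, hi) in bounds.items():
        if not 0 < lo < hi:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    lo = np.log([bounds[f][0] for f in PARAMETER_FIELDS])
    hi = np.log([bounds[f][1] for f in PARAMETER_FIELDS])

    def unpack(x) -> ModelParameters:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ModelParameters(**dict(zip(PARAMETER_FIELDS, np.exp(x))))

    def fun(x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return residuals(unpack(x), d, ctrl=ctrl)

    starts = []
    if x0 is not None:
        starts.append(np.clip(np.log([getattr(x0, f)
                                      for f in PARAMETER_FIELDS]), lo, hi))
    while len(starts) < n_starts:
        starts.append(lo + rng.uniform(size=len(lo)) * (hi - lo))

    best = None
    start_costs = []
    for x_start in starts:
        try:
            sol = least_squares(fun, x_start, bounds=(lo, hi), method="trf",
                                xtol=xtol, ftol=ftol, gtol=None,
                                max_nfev=max_nfev)
            start_costs.append(float(sol.cost))
            if best is None or sol.cost < best.cost:
                best = sol
        except Exception as exc:  # noqa: BLE001
            start_costs.append(float("inf"))
            warnings.warn(f"start failed: {exc}", stacklevel=2)
    if best is None:
        raise RuntimeError(
            f"all {n_starts} starts failed; per-start costs: {start_costs}")
    p_best = unpack(best.x)
    res = residuals(p_best, d, ctrl=ctrl)
    n_steady = len(d.steady)
    block_rms = {"steady": float(np.sqrt(np.mean(res[:n_steady] ** 2)))}
    ofs = n_steady
    for i, (_, tr) in enumerate(d.transients):
        block_rms[f"transient_{i}"] = float(
            np.sqrt(np.mean(res[ofs:ofs + len(tr)] ** 2)))
        ofs += len(tr)
    return FitResult(params=p_best, cost=float(best.cost),
                     block_rms=block_rms, n_starts=len(starts),
                     start_costs=start_costs, success=bool(best.success),
                     message=str(best.message))
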