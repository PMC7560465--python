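"""Unit tests of the algebraic constitutive relations."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hemotevp as h
from hemotevp.core import PARAMETER_FIELDS
from hemotevp.integrator import _rhs

finite = st.floats(-10.0, 10.0, allow_nan=False)


# ---------------------------------------------------------------- parameters

def test_parameter_validation_and_chi0(mcmillan):
    assert mcmillan.chi0 == mcmillan.eta0 / mcmillan.G
    assert mcmillan.chi0 == pytest.approx(0.012 / 0.382)
    with pytest.raises(ValueError):
        h.ModelParameters(G=-1.0, eta0=0.012, tau_y=0.0035, eps_ptt=0.001,
                          k1=0.1, k2=1.0, k3=10.0, n1=1.0, n2=2.0, n3=1.0,
                          m1=1.0)
    with pytest.warns(UserWarning, match="k3 > k2"):
        h.ModelParameters(G=1.0, eta0=1.0, tau_y=0.01, eps_ptt=0.0, k1=0.1,
                          k2=10.0, k3=1.0, n1=1.0, n2=2.0, n3=1.0, m1=1.0)


def test_preset_yaml_roundtrip(tmp_path, mcmillan):
    path = tmp_path / "params.yaml"
    mcmillan.to_yaml(path)
    again = h.ModelParameters.from_yaml(path)
    assert again == mcmillan


def test_preset_table_values(mcmillan, armstrong):
    assert (mcmillan.G, mcmillan.eta0, mcmillan.tau_y) == (0.382, 0.012, 0.0035)
    assert (mcmillan.k1, mcmillan.k2, mcmillan.k3) == (0.0918, 7.249, 6974.9)
    assert (mcmillan.n1, mcmillan.n2, mcmillan.n3, mcmillan.m1) == \
        (3.03, 4.068, 3.03, 0.701)
    assert (armstrong.G, armstrong.eta0, armstrong.tau_y) == (0.15, 0.035, 0.006)


# ----------------------------------------------------------------- deviatoric

@pytest.mark.parametrize("tensor,expected", [
    (h.SymmetricTensor(), h.SymmetricTensor()),
    (h.SymmetricTensor(xy=2.5), h.SymmetricTensor(xy=2.5)),
    (h.SymmetricTensor(xx=3.0),
     h.SymmetricTensor(xx=2.0, yy=-1.0, zz=-1.0)),
])
def test_deviatoric_cases(tensor, expected):
    d = h.deviatoric(tensor)
    assert np.allclose(d.as_matrix(), expected.as_matrix())


def test_deviatoric_traceless_and_idempotent(random_symmetric_tensors):
    for z in random_symmetric_tensors:
        d = h.deviatoric(z)
        assert abs(d.trace) < 1e-12 * max(1.0, abs(z.trace))
        assert np.allclose(h.deviatoric(d).as_matrix(), d.as_matrix())


# ----------------------------------------------------------- effective stress

@pytest.mark.parametrize("tensor,expected", [
    (h.SymmetricTensor(), 0.0),
    (h.SymmetricTensor(xy=0.7), 0.7),
    (h.SymmetricTensor(xx=0.9), 0.9 / math.sqrt(3.0)),
])
def test_effective_stress_cases(tensor, expected):
    assert h.effective_stress(tensor) == pytest.approx(expected, abs=1e-15)


@given(c=finite)
@settings(max_examples=30, deadline=None)
def test_effective_stress_isotropic_invariance(c):
    z = h.SymmetricTensor(1.1, -0.4, 0.2, 0.3, -0.7, 0.05)
    shifted = z + h.SymmetricTensor(xx=c, yy=c, zz=c)
    assert h.effective_stress(shifted) == pytest.approx(
        h.effective_stress(z), rel=1e-12, abs=1e-12)


# ------------------------------------------------------------------ PTT factor

def test_ptt_factor(mcmillan):
    assert h.ptt_factor(h.SymmetricTensor(), mcmillan) == 1.0
    no_ptt = h.ModelParameters(**{**{f: getattr(mcmillan, f)
                                     for f in PARAMETER_FIELDS},
                                  "eps_ptt": 0.0})
    assert h.ptt_factor(h.SymmetricTensor(xx=5.0, yy=-1.0), no_ptt) == 1.0
    # eps_ptt = 0.001, G = 0.382, tr(tau) = 0.382 -> 1.001
    tau = h.SymmetricTensor(xx=0.382)
    assert h.ptt_factor(tau, mcmillan) == pytest.approx(1.001)


# --------------------------------------------- structural viscosity/relaxation

def test_thixotropic_viscosity(mcmillan):
    assert h.thixotropic_viscosity(1.0, mcmillan) == pytest.approx(0.012)
    assert h.thixotropic_viscosity(0.0, mcmillan) == 0.0
    # at the strong-flow plateau the viscosity is 3.5-4x that of plasma
    assert h.thixotropic_viscosity(0.1763, mcmillan) == pytest.approx(
        3.5e-3, rel=0.03)
    lams = np.linspace(0.01, 1.0, 50)
    etas = [h.thixotropic_viscosity(l, mcmillan) for l in lams]
    assert np.all(np.diff(etas) > 0)
    with pytest.raises(ValueError):
        h.thixotropic_viscosity(1.2, mcmillan)
    with pytest.raises(ValueError):
        h.relaxation_time(-0.1, mcmillan)


def test_relaxation_time(mcmillan):
    assert h.relaxation_time(1.0, mcmillan) == pytest.approx(0.0314, rel=1e-3)
    assert h.relaxation_time(0.0, mcmillan) == 0.0
    # strong-flow structure plateau: equal stress exponents in rebuild and
    # breakdown make the balance k2 (1 - lam) = k3 lam^n2 stress-independent
    lam_inf = h.equilibrium_structure(100.0, mcmillan)
    assert h.relaxation_time(lam_inf, mcmillan) == pytest.approx(
        9.1e-3, rel=0.03)


# ------------------------------------------------------------- flow parameter

def test_flow_parameter(mcmillan):
    assert h.flow_parameter(0.0, mcmillan) == 0.0
    assert h.flow_parameter(mcmillan.tau_y, mcmillan) == 0.0
    assert h.flow_parameter(mcmillan.tau_y + 0.01, mcmillan) == \
        pytest.approx(0.01)
    with pytest.raises(ValueError):
        h.flow_parameter(-1.0, mcmillan)


# ------------------------------------------------------------- structure rate

def test_structure_rate_cases(mcmillan):
    p = mcmillan
    assert h.structure_rate(1.0, 0.5 * p.tau_y, p) == 0.0
    assert h.structure_rate(0.0, 0.5 * p.tau_y, p) == pytest.approx(p.k1)
    # independent brute-force arithmetic of the kinetic balance
    lam, phi = 0.5, 0.01
    expected = (0.0918 + 7.249 * 0.01 ** 3.03) * 0.5 \
        - 6974.9 * 0.01 ** 3.03 * 0.5 ** 4.068
    assert h.structure_rate(lam, p.tau_y + phi, p) == pytest.approx(
        expected, rel=1e-12)


def test_structure_fixed_point_attracts(mcmillan):
    """Long-time integration at fixed stress converges to the bisection
    root of the rebuild/breakdown balance."""
    sigma = mcmillan.tau_y + 0.08
    lam_star = h.equilibrium_structure(sigma, mcmillan)
    assert 0.0 < lam_star < 1.0
    lam = 1.0
    dt = 1e-3
    for _ in range(400_000):
        lam += dt * h.structure_rate(lam, sigma, mcmillan)
    assert lam == pytest.approx(lam_star, rel=1e-4)
    assert h.structure_rate(lam_star, sigma, mcmillan) == pytest.approx(
        0.0, abs=1e-10)


# --------------------------------------------------- viscoplastic deformation

def test_viscoplastic_below_yield_is_zero(mcmillan):
    tau = h.SymmetricTensor(xy=0.9 * mcmillan.tau_y)
    dvp = h.viscoplastic_deformation(tau, 0.8, mcmillan)
    assert np.allclose(dvp.as_matrix(), 0.0)


def test_viscoplastic_proportionality_and_continuity(mcmillan):
    tau = h.SymmetricTensor(xx=0.04, xy=0.02)
    dvp = h.viscoplastic_deformation(tau, 0.6, mcmillan)
    assert dvp.xy / dvp.xx == pytest.approx(tau.xy / tau.xx, rel=1e-12)
    # multiplier vanishes continuously as sigma_eff -> tau_y from above
    eps = 1e-9
    tau_near = h.SymmetricTensor(xy=mcmillan.tau_y + eps)
    dvp_near = h.viscoplastic_deformation(tau_near, 1.0, mcmillan)
    assert abs(dvp_near.xy) < 1e-5


# ------------------------------------------------------------------ stress rate

def test_stress_rate_rest_and_neo_hookean(mcmillan):
    state = h.MaterialState.rest()
    rate = h.stress_rate(state, np.zeros((3, 3)), mcmillan)
    assert np.allclose(rate.as_matrix(), 0.0)
    gd = 4.0
    L = np.zeros((3, 3))
    L[1, 0] = gd
    rate = h.stress_rate(state, L, mcmillan)
    expected = np.zeros((3, 3))
    expected[0, 1] = expected[1, 0] = mcmillan.G * gd
    assert np.allclose(rate.as_matrix(), expected)


@pytest.mark.parametrize("mode", ["shear", "uniaxial"])
def test_fast_rhs_matches_tensor_route(mcmillan, mode, random_symmetric_tensors):
    """The integrator's specialised scalar right-hand side agrees with the
    general tensor assembly of the core module."""
    rng = np.random.default_rng(3)
    for z in random_symmetric_tensors[:8]:
        tau = 0.05 * z
        lam = float(rng.uniform(0.05, 1.0))
        g = float(rng.uniform(0.1, 50.0))
        if mode == "shear":
            L = np.zeros((3, 3))
            L[1, 0] = g
        else:
            L = np.diag([g, -0.5 * g, -0.5 * g])
        state = h.MaterialState(0.0, tau, lam)
        ref = h.stress_rate(state, L, mcmillan).as_matrix()
        y = np.array([tau.xx, tau.yy, tau.zz, tau.xy, tau.xz, tau.yz, lam])
        fast = _rhs(0.0, y, lambda t: g, mode, mcmillan)
        got = np.array([[fast[0], fast[3], fast[4]],
                        [fast[3], fast[1], fast[5]],
                        [fast[4], fast[5], fast[2]]])
        scale = max(1.0, np.abs(ref).max())
        assert np.allclose(got, ref, atol=1e-9 * scale)
        sigma = h.effective_stress(tau)
        assert fast[6] == pytest.approx(
            h.structure_rate(lam, sigma, mcmillan), rel=1e-12, abs=1e-12)
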