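"""Tests of derived rheometric metrics, fits and comparator models."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hemotevp as h
from hemotevp.rheometrics import sigmoid_structure, n1_rational


def _fake_startup(t, tau_st, tau_pk, t_pk, decay):
    """Analytic overshoot trace: linear rise to the peak, exponential decay
    back to the steady value."""
    s = np.where(t <= t_pk, tau_pk * t / t_pk,
                 tau_st + (tau_pk - tau_st) * np.exp(-(t - t_pk) / decay))
    df = pd.DataFrame({"t": t, "txy": s})
    df.attrs["steady"] = True
    return df


# ----------------------------------------------------------- overshoot metrics

def test_overshoot_metrics_on_analytic_trace():
    t = np.linspace(0.0, 60.0, 30001)
    m = h.overshoot_metrics(_fake_startup(t, 0.05, 0.12, 1.0, 2.0))
    assert m.overshoot
    assert m.tau_max == pytest.approx(0.12, rel=1e-3)
    assert m.tau_st == pytest.approx(0.05, rel=1e-3)
    # half decay of an exponential takes decay * ln 2
    assert m.theta == pytest.approx(2.0 * math.log(2.0), rel=1e-2)


def test_overshoot_metrics_monotone_trace_flagged():
    t = np.linspace(0.0, 30.0, 2000)
    df = pd.DataFrame({"t": t, "txy": 0.1 * (1.0 - np.exp(-t))})
    df.attrs["steady"] = True
    m = h.overshoot_metrics(df)
    assert not m.overshoot
    assert m.theta == 0.0
    assert m.tau_max == pytest.approx(m.tau_st)
    assert h.thixotropic_index(m, 5.0) == 0.0


def test_overshoot_metrics_requires_converged_run():
    df = pd.DataFrame({"t": [0.0, 1.0], "txy": [0.0, 1.0]})
    with pytest.raises(ValueError):
        h.overshoot_metrics(df)


@given(scale=st.floats(1e-3, 1e3))
@settings(max_examples=25, deadline=None)
def test_thixotropic_index_stress_unit_invariance(scale):
    m = h.OvershootMetrics(0.12, 1.0, 0.05, 1.4, True)
    m_scaled = h.OvershootMetrics(0.12 * scale, 1.0, 0.05 * scale, 1.4, True)
    assert h.thixotropic_index(m_scaled, 7.0) == pytest.approx(
        h.thixotropic_index(m, 7.0), rel=1e-12)


def test_thixotropic_index_degenerate_theta_warns():
    m = h.OvershootMetrics(0.12, 1.0, 0.05, 0.0, True)
    with pytest.warns(UserWarning):
        assert h.thixotropic_index(m, 1.0) == math.inf
    with pytest.raises(ValueError):
        h.thixotropic_index(m, 0.0)


def test_apparent_viscosity():
    assert h.apparent_viscosity(0.012, 2.0) == pytest.approx(6e-3)
    with pytest.raises(ZeroDivisionError):
        h.apparent_viscosity(1.0, 0.0)


# ------------------------------------------------------------ Morris relation

def test_morris_inversion_reference_point():
    cf = h.fibrinogen_from_yield(0.00351, 0.45)
    assert cf == pytest.approx(0.1617, rel=0.01)
    assert h.morris_yield_stress(0.45, cf) == pytest.approx(0.00351, rel=1e-9)


def test_morris_monotone_in_fibrinogen():
    cfs = np.linspace(0.1, 0.9, 50)
    taus = [h.morris_yield_stress(0.45, c) for c in cfs]
    assert np.all(np.diff(taus) > 0)


def test_morris_inner_zero_and_validity_warnings():
    with pytest.warns(UserWarning):
        assert h.morris_yield_stress(0.091 / 0.47, 0.0) == pytest.approx(
            0.0, abs=1e-25)
    with pytest.warns(UserWarning):
        h.morris_yield_stress(0.95, 0.5)


@given(Hc=st.floats(0.40, 0.80), cf=st.floats(0.1, 0.9))
@settings(max_examples=60, deadline=None)
def test_morris_round_trip_identity(Hc, cf):
    tau = h.morris_yield_stress(Hc, cf)
    assert h.fibrinogen_from_yield(tau, Hc) == pytest.approx(cf, abs=1e-10)


# ------------------------------------------------------------------- fits

TABLE_SIGMOID = dict(A=1.0, B=0.1763, k=4.795, n=1.262)


def test_sigmoid_fit_self_recovery():
    rates = np.geomspace(0.01, 1000.0, 30)
    lams = sigmoid_structure(rates, **TABLE_SIGMOID)
    fit = h.fit_sigmoid_structure(rates, lams)
    for name, val in TABLE_SIGMOID.items():
        assert getattr(fit, name) == pytest.approx(val, rel=1e-6)
    assert fit.rms < 1e-10
    # zero-rate limit of the sigmoid is the A plateau
    assert fit(0.0) == pytest.approx(fit.A)
    with pytest.raises(ValueError):
        h.fit_sigmoid_structure(rates[:5], lams[:5])


def test_sigmoid_fit_to_model_flow_curve(mcmillan):
    """Fitting the model's own steady structure curve regenerates plateaus
    and crossover close to the published description (the fit is loose and
    grid-dependent by nature)."""
    rates = np.geomspace(0.01, 1000.0, 40)
    fc = h.flow_curve(mcmillan, rates)
    fit = h.fit_sigmoid_structure(fc.rate, fc.lam)
    assert fit.A == pytest.approx(1.0, rel=0.05)
    assert fit.B == pytest.approx(0.1763, rel=0.10)
    assert fit.k == pytest.approx(4.795, rel=0.15)
    assert fit.n == pytest.approx(1.262, rel=0.15)


TABLE_N1 = dict(A1=-1.69, A2=1.30, A3=-0.427, A4=0.0931)


def test_n1_rational_self_recovery_and_viscosity_identity():
    rates = np.geomspace(0.5, 400.0, 40)
    vals = n1_rational(rates, **TABLE_N1)
    fit = h.fit_n1_rational(rates, vals)
    for name, val in TABLE_N1.items():
        assert getattr(fit, name) == pytest.approx(val, rel=1e-5)
    ee = h.extensional_viscosity(fit, rates)
    assert np.allclose(ee * rates, fit(rates), rtol=1e-12)


def test_n1_rational_rejects_singular_denominator():
    rates = np.linspace(0.5, 10.0, 30)
    vals = n1_rational(rates, 1.0, 1.0, 0.0, 0.0)
    # force data whose linearised denominator flips sign inside the range
    bad = vals.copy()
    bad[10:] *= -50.0
    with pytest.raises((ValueError, RuntimeError)):
        h.fit_n1_rational(rates, bad)


# --------------------------------------------------- generalized-Newtonian

def test_gn_model_limits():
    g = np.geomspace(1e-4, 1e6, 60)
    eta = h.gn_viscosity("casson", {"tau_y": 0.0, "eta_c": 4e-3}, g)
    assert np.allclose(eta, 4e-3)
    cross = {"eta_inf": 4e-3, "eta_0": 0.2, "K": 1.0, "m": 1.2}
    eta = h.gn_viscosity("cross", cross, g)
    assert eta[0] == pytest.approx(0.2, rel=1e-3)
    assert eta[-1] == pytest.approx(4e-3, rel=1e-2)
    cy = {"eta_inf": 4e-3, "eta_0": 0.2, "lam_c": 1.0, "a": 2.0, "n": 0.4}
    eta = h.gn_viscosity("carreau_yasuda", cy, g)
    assert eta[0] == pytest.approx(0.2, rel=1e-3)
    # the power-law approach to eta_inf is slow for shear-thinning n < 1
    assert eta[-1] == pytest.approx(4e-3, rel=2e-2)
    with pytest.raises(ValueError):
        h.gn_viscosity("casson", {"tau_y": -1.0, "eta_c": 1.0}, g)
    with pytest.raises(ValueError):
        h.gn_viscosity("herschel", {}, g)


def test_gn_fit_recovers_cross_data_and_fits_model_curve(mcmillan):
    g = np.geomspace(0.01, 1000.0, 40)
    truth = {"eta_inf": 3.5e-3, "eta_0": 0.5, "K": 2.0, "m": 0.9}
    eta = h.gn_viscosity("cross", truth, g)
    fitted = h.gn_fit("cross", g, eta)
    for k, v in truth.items():
        assert fitted[k] == pytest.approx(v, rel=1e-4)
    # comparator fits to the TEVP steady flow curve are well behaved
    fc = h.flow_curve(mcmillan, g)
    for model in ("casson", "cross", "carreau_yasuda"):
        params = h.gn_fit(model, fc.rate, fc.eta_app)
        curve = h.gn_viscosity(model, params, g)
        assert np.all(np.isfinite(curve)) and np.all(curve > 0)


# ------------------------------------------------------------------- LAOS

def test_lissajous_projection_columns(ucm_params):
    cyc = h.periodic_steady_state(h.ProtocolSpec.laos(0.5, 2.0, 20),
                                  ucm_params, cycle_tol=1e-6)
    proj = h.lissajous_bowditch(cyc)
    assert set(proj.columns) == {"phase", "strain", "rate", "txy", "txx", "lam"}
    # linear-regime loop is a closed ellipse: strain extremes map to
    # symmetric stresses
    assert proj.strain.max() == pytest.approx(0.5, rel=1e-3)
    assert proj.txy.max() == pytest.approx(-proj.txy.min(), rel=0.02)


def test_lissajous_warns_on_non_periodic(mcmillan):
    cyc = h.periodic_steady_state(h.ProtocolSpec.laos(10.0, 10.0, 2),
                                  mcmillan, cycle_tol=1e-12)
    with pytest.warns(UserWarning):
        h.lissajous_bowditch(cyc)


def test_pipkin_grid_long_format(ucm_params):
    grid = h.pipkin_grid(ucm_params, [0.2, 1.0], [2.0], n_cycles=12,
                         cycle_tol=1e-4)
    assert set(np.unique(grid.gamma_0)) == {0.2, 1.0}
    assert set(np.unique(grid.omega)) == {2.0}
    assert grid.periodic.all()
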