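"""Unit and property tests for the closed-form steady-state PK engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from lazdose.pk import (
    DoseEvent,
    Regimen,
    StructuralParams,
    css_concentrations,
    css_profile,
    get_regimen,
    load_regimen,
    macro_constants,
    single_dose_concentration,
    steady_state_metrics_batch,
)

TWO_CMT = StructuralParams(cl=30.0, v1=60.0, q=40.0, v2=800.0, ka=0.5)
FAST_TERMINAL = StructuralParams(cl=10.0, v1=50.0, q=5.0, v2=100.0, ka=1.2)
QD240 = get_regimen("240QD")


def ode_concentration(params: StructuralParams, dose_mg: float, times: np.ndarray) -> np.ndarray:
    """Independent oracle: numerically integrate depot -> central <-> peripheral
    with first-order elimination from central."""
    k10 = params.cl / params.v1
    k12 = params.q / params.v1 if params.v1 else 0.0
    k21 = params.q / params.v2 if params.v2 else 0.0

    def rhs(_, y):
        depot, central, peri = y
        return [
            -params.ka * depot,
            params.ka * depot - (k10 + k12) * central + k21 * peri,
            k12 * central - k21 * peri,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        [dose_mg * params.f, 0.0, 0.0],
        t_eval=times,
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
    )
    return sol.y[1] / params.v1


@pytest.mark.parametrize("params", [TWO_CMT, FAST_TERMINAL, StructuralParams(cl=20.0, v1=400.0, q=0.0, v2=0.0, ka=0.8)])
def test_macro_constants_match_ode_oracle(params):
    """The sum-of-exponentials solution agrees with direct ODE integration to
    better than 1e-6 relative over two weeks."""
    times = np.linspace(0.0, 336.0, 500)
    closed = single_dose_concentration(params, 240.0, times)
    numeric = ode_concentration(params, 240.0, times)
    assert np.max(np.abs(closed - numeric)) / np.max(numeric) < 1e-6


def test_one_compartment_reduces_to_bateman():
    p = StructuralParams(cl=20.0, v1=100.0, q=0.0, v2=0.0, ka=0.7)
    coefs, rates = macro_constants(p)
    assert coefs.size == 2
    t = np.linspace(0.0, 96.0, 200)
    ke = p.cl / p.v1
    bateman = 240.0 * p.ka / (p.v1 * (p.ka - ke)) * (np.exp(-ke * t) - np.exp(-p.ka * t))
    np.testing.assert_allclose(single_dose_concentration(p, 240.0, t), bateman, rtol=1e-12)


@given(
    cl=st.floats(5.0, 100.0),
    v1=st.floats(20.0, 500.0),
    q=st.floats(1.0, 100.0),
    v2=st.floats(100.0, 5000.0),
    ka=st.floats(0.06, 2.5),
)
@settings(max_examples=30, derandomize=True, deadline=None)
def test_oral_input_starts_at_zero(cl, v1, q, v2, ka):
    """Macro-constant coefficients sum to zero: C(0)=0 for oral absorption."""
    coefs, rates = macro_constants(StructuralParams(cl=cl, v1=v1, q=q, v2=v2, ka=ka))
    assert np.all(rates > 0)
    assert abs(coefs.sum()) <= 1e-12 * np.max(np.abs(coefs))


def test_q_zero_limit_matches_one_compartment():
    """Letting Q -> 0 continuously recovers the one-compartment profile."""
    t = np.linspace(0.0, 168.0, 300)
    small_q = StructuralParams(cl=20.0, v1=100.0, q=1e-12, v2=50.0, ka=0.7)
    one_cmt = StructuralParams(cl=20.0, v1=100.0, q=0.0, v2=0.0, ka=0.7)
    a = css_concentrations(small_q, QD240, t)
    b = css_concentrations(one_cmt, QD240, t)
    assert np.max(np.abs(a - b)) / np.max(b) < 1e-9


def test_steady_state_matches_brute_force_superposition():
    """Closed-form accumulation equals explicitly summing 200 single doses."""
    t_in_period = np.array([0.0, 1.0, 3.0, 7.5, 12.0, 23.99])
    n_periods = 200
    offset = (n_periods - 1) * QD240.period_h
    brute = np.zeros_like(t_in_period)
    for k in range(n_periods):
        brute += single_dose_concentration(
            FAST_TERMINAL, 240.0, offset + t_in_period - k * QD240.period_h
        )
    closed = css_concentrations(FAST_TERMINAL, QD240, t_in_period)
    np.testing.assert_allclose(closed, brute, rtol=1e-6)


def test_profile_is_periodic():
    prof_t = np.linspace(0.0, 120.0, 777)
    c0 = css_concentrations(TWO_CMT, QD240, prof_t)
    c1 = css_concentrations(TWO_CMT, QD240, prof_t + QD240.period_h)
    assert np.max(np.abs(c0 - c1)) / np.max(c0) < 1e-9


@given(alpha=st.floats(0.1, 5.0))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_dose_linearity(alpha):
    """Scaling every dose amount scales the whole profile by the same factor."""
    reg = Regimen(48.0, (DoseEvent(0.0, 80.0), DoseEvent(24.0, 160.0)), "alt")
    t = np.linspace(0.0, 48.0, 50)
    base = css_concentrations(TWO_CMT, reg, t)
    scaled = css_concentrations(TWO_CMT, reg.scaled(alpha), t)
    np.testing.assert_allclose(scaled, alpha * base, rtol=1e-12)


def test_higher_clearance_lowers_trough_and_average():
    lo = StructuralParams(cl=20.0, v1=60.0, q=40.0, v2=800.0, ka=0.5)
    hi = StructuralParams(cl=40.0, v1=60.0, q=40.0, v2=800.0, ka=0.5)
    tr_lo, cav_lo = _metrics(lo, QD240)
    tr_hi, cav_hi = _metrics(hi, QD240)
    assert tr_hi < tr_lo
    assert cav_hi < cav_lo


def _metrics(params, regimen):
    tr, cav = steady_state_metrics_batch(
        *(np.array([getattr(params, k)]) for k in ("cl", "v1", "q", "v2", "ka")),
        regimen=regimen,
    )
    return tr[0], cav[0]


def test_every_other_day_trough_below_daily_trough():
    """Same per-dose amount, doubled interval: the trough must drop."""
    tr_qd, _ = _metrics(TWO_CMT, get_regimen("240QD"))
    tr_qod, _ = _metrics(TWO_CMT, get_regimen("240QOD"))
    assert tr_qod < tr_qd


def test_weekly_average_matches_dose_over_clearance():
    """Trapezoidal average of the QD profile equals 240/(CL*24) within 0.5%."""
    prof = css_profile(TWO_CMT, QD240, window_h=24.0, grid_step_h=0.1)
    avg = np.trapezoid(prof.concentrations, prof.times) / 24.0
    assert abs(avg / (240.0 / (TWO_CMT.cl * 24.0)) - 1.0) < 0.005


def test_ka_eigenvalue_collision_warns_and_stays_finite():
    p = StructuralParams(cl=20.0, v1=100.0, q=0.0, v2=0.0, ka=20.0 / 100.0)
    with pytest.warns(RuntimeWarning, match="perturbing ka"):
        coefs, rates = macro_constants(p)
    assert np.all(np.isfinite(coefs))
    t = np.linspace(0, 48, 100)
    with pytest.warns(RuntimeWarning):
        assert np.all(np.isfinite(single_dose_concentration(p, 240.0, t)))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(cl=0.0, v1=60.0, q=40.0, v2=800.0, ka=0.5),
        dict(cl=30.0, v1=-1.0, q=40.0, v2=800.0, ka=0.5),
        dict(cl=30.0, v1=60.0, q=-40.0, v2=800.0, ka=0.5),
        dict(cl=30.0, v1=60.0, q=40.0, v2=800.0, ka=0.0),
    ],
)
def test_invalid_structural_params_rejected(kwargs):
    with pytest.raises(ValueError):
        StructuralParams(**kwargs)


def test_invalid_regimens_rejected():
    with pytest.raises(ValueError):
        Regimen(24.0, ())
    with pytest.raises(ValueError):
        Regimen(24.0, (DoseEvent(25.0, 240.0),))  # time beyond period
    with pytest.raises(ValueError):
        Regimen(48.0, (DoseEvent(10.0, 80.0), DoseEvent(10.0, 80.0)))  # not increasing
    with pytest.raises(ValueError):
        DoseEvent(0.0, -80.0)
    with pytest.raises(ValueError):
        css_profile(TWO_CMT, QD240, grid_step_h=0.0)


def test_regimen_presets_and_tablet_composability():
    alt = get_regimen("80_160_ALT")
    assert alt.dosing_days_fraction == 1.0
    assert get_regimen("240QOD").dosing_days_fraction == 0.5
    assert all(e.tablet_compatible for r in ("240QD", "160QD", "240QOD", "80_160_ALT")
               for e in get_regimen(r).events)
    assert not DoseEvent(0.0, 100.0).tablet_compatible
    with pytest.raises(KeyError):
        get_regimen("999TID")


def test_regimen_config_roundtrip(tmp_path):
    path = tmp_path / "alt.yaml"
    path.write_text("period: 48\nlabel: alt\ndoses:\n  - {time: 0, amount: 80}\n  - {time: 24, amount: 160}\n")
    reg = load_regimen(path)
    assert reg.period_h == 48.0
    assert [e.amount_mg for e in reg.events] == [80.0, 160.0]

    jpath = tmp_path / "qd.json"
    jpath.write_text('{"period": 24, "doses": [{"time": 0, "amount": 240}]}')
    assert load_regimen(jpath).dose_per_period_mg == 240.0


def test_profile_csv_export(tmp_path):
    prof = css_profile(TWO_CMT, QD240, window_h=24.0, grid_step_h=1.0)
    out = tmp_path / "profile.csv"
    prof.to_csv(out)
    header = out.read_text().splitlines()[0]
    assert header == "time_h,conc_mg_per_L"
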