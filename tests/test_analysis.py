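"""Tests for the scenario engine: summaries, comparisons, attainment, costs."""

import numpy as np
import pytest

from lazdose.analysis import (
    DEFAULT_SCENARIOS,
    ExposureSummary,
    annual_cost,
    compare,
    exposure_metrics,
    fraction_above,
    run_scenarios,
    summarize,
)
from lazdose.pk import StructuralParams, css_profile, get_regimen
from lazdose.population import CovariateModel, IIVModel, TypicalModel


def test_summarize_basic_cases():
    s = summarize(np.full(10, 3.3), "Ctrough")
    assert s.gm == pytest.approx(3.3)
    assert s.cv_pct == 0.0

    s = summarize(np.array([1.0, 4.0]), "Ctrough")
    assert s.gm == pytest.approx(2.0)
    # sample SD (n-1): SD/mean = 2.1213/2.5
    assert s.cv_pct == pytest.approx(84.85, abs=0.01)

    with pytest.raises(ValueError):
        summarize(np.array([1.0, 0.0]), "Ctrough")
    with pytest.raises(ValueError):
        summarize(np.array([]), "Ctrough")


def test_summarize_recovers_lognormal_parameters():
    rng = np.random.default_rng(0)
    sigma = np.sqrt(np.log1p(0.4**2))
    x = 0.2 * np.exp(rng.normal(0.0, sigma, 200_000))
    s = summarize(x, "Caverage")
    assert s.gm == pytest.approx(0.2, rel=0.01)
    assert s.cv_pct == pytest.approx(40.0, abs=1.0)


def test_compare_identity_and_flags():
    ref = ExposureSummary("Ctrough", 0.0962, 64.1, 1000)
    same = compare(ref, ref, threshold=0.0, test_values=np.array([1.0]))
    assert same.gmr == 1.0
    assert same.equivalence_pass and same.not_lower_pass
    assert same.fraction_above_threshold_pct == 100.0

    test = ExposureSummary("Ctrough", 0.138, 56.0, 1000)
    c = compare(test, ref, 0.0568, np.array([0.1, 0.2]))
    assert round(c.gmr, 2) == 1.43  # the published 160 QD trough ratio

    with pytest.raises(ValueError, match="metric"):
        compare(ExposureSummary("Caverage", 1, 1, 1), ref, 0.0, np.array([1.0]))


def test_equivalence_verdict_symmetric_under_inversion():
    a = ExposureSummary("Ctrough", 0.10, 50.0, 100)
    b = ExposureSummary("Ctrough", 0.12, 50.0, 100)
    ab = compare(a, b, 0.0, np.array([1.0]))
    ba = compare(b, a, 0.0, np.array([1.0]))
    assert ab.gmr * ba.gmr == pytest.approx(1.0, rel=1e-12)
    assert ab.equivalence_pass == ba.equivalence_pass


def test_fraction_above_uses_strict_inequality():
    assert fraction_above(np.array([1.0, 2.0, 3.0]), 2.0) == pytest.approx(100.0 / 3.0)


def test_annual_costs_match_price_arithmetic():
    """$728/day gives $265,720/year daily and a $132,860 saving every other
    day; 160 mg QD (two 80 mg tablets) saves nothing."""
    qd = get_regimen("240QD")
    assert annual_cost(qd, 728.0).annual_cost == pytest.approx(265_720.0)
    qod = annual_cost(get_regimen("240QOD"), 728.0, reference=qd)
    assert qod.annual_cost == pytest.approx(132_860.0)
    assert qod.savings_vs_reference == pytest.approx(132_860.0)
    assert annual_cost(get_regimen("160QD"), 728.0, reference=qd).savings_vs_reference == 0.0
    # alternating 80/160 mg doses daily: still one dosing-day price per day
    assert annual_cost(get_regimen("80_160_ALT"), 728.0).dosing_days_per_year == 365.0
    with pytest.raises(ValueError):
        annual_cost(qd, 0.0)


def test_exposure_metrics_flat_profile_limit():
    """Fast absorption, slow elimination, short interval: trough -> average."""
    p = StructuralParams(cl=1.0, v1=500.0, q=0.0, v2=0.0, ka=20.0)
    reg = get_regimen("240QD")
    ctrough, caverage = exposure_metrics(p, reg)
    assert 0.95 < ctrough / caverage < 1.0


def test_exposure_metrics_against_quadrature():
    p = StructuralParams(cl=30.0, v1=60.0, q=40.0, v2=800.0, ka=0.5)
    reg = get_regimen("240QOD")
    _, caverage = exposure_metrics(p, reg)
    prof = css_profile(p, reg, window_h=reg.period_h, grid_step_h=0.01)
    quad = np.trapezoid(prof.concentrations, prof.times) / reg.period_h
    assert abs(quad / caverage - 1.0) < 1e-4


ZERO_VAR = TypicalModel(
    tvcl_nonnull=57.47,
    gstm1_cl_fraction=0.5613,
    tvv1=60.0,
    tvq=40.0,
    tvv2=2500.0,
    tvka=0.15,
    iiv=IIVModel(),
)


def test_zero_variance_study_report_equals_typical_ratios():
    """With all variability off, %CVs vanish and GMRs reduce to closed-form
    dose/clearance-fraction ratios."""
    rep = run_scenarios(
        ZERO_VAR, n=50, seed=1, cov=CovariateModel(weight_cv=0.0)
    )
    tab = rep.table()
    assert (tab.ctrough_cv_pct == 0).all()
    assert (tab.caverage_cv_pct == 0).all()
    frac = ZERO_VAR.gstm1_cl_fraction
    gmr_cav_160 = rep.comparisons[("null", "160QD")]["Caverage"].gmr
    gmr_cav_qod = rep.comparisons[("null", "240QOD")]["Caverage"].gmr
    assert gmr_cav_160 == pytest.approx((160.0 / 240.0) / frac, rel=1e-9)
    assert gmr_cav_qod == pytest.approx(0.5 / frac, rel=1e-9)


def test_caverage_gmr_is_disposition_free(study_report, calibrated):
    """Caverage GMRs depend only on dose ratio and the clearance fraction, up
    to Monte Carlo error in independent cohorts."""
    frac = calibrated.typical.gstm1_cl_fraction
    gmr = study_report.comparisons[("null", "160QD")]["Caverage"].gmr
    assert gmr == pytest.approx((160.0 / 240.0) / frac, rel=0.02)


def test_scenario_substreams_independent_of_order(calibrated):
    a = run_scenarios(calibrated.typical, n=200, seed=9,
                      scenarios=DEFAULT_SCENARIOS)
    b = run_scenarios(calibrated.typical, n=200, seed=9,
                      scenarios=tuple(reversed(DEFAULT_SCENARIOS)))
    for key in DEFAULT_SCENARIOS:
        np.testing.assert_array_equal(a.values[key]["Ctrough"], b.values[key]["Ctrough"])


def test_study_report_passes_equivalence_for_alternatives(study_report):
    """Both genotype-guided alternatives keep exposure not >20% below the
    reference; the every-other-day arm is fully within 0.80-1.25."""
    for key in (("null", "160QD"), ("null", "240QOD")):
        for metric in ("Ctrough", "Caverage"):
            assert study_report.comparisons[key][metric].not_lower_pass
    for metric in ("Ctrough", "Caverage"):
        assert study_report.comparisons[("null", "240QOD")][metric].equivalence_pass


def test_report_serialization(study_report, tmp_path):
    study_report.to_csv(tmp_path / "table.csv")
    study_report.to_json(tmp_path / "table.json")
    long = study_report.long_values()
    assert set(long.metric) == {"Ctrough", "Caverage"}
    assert len(long) == 2 * 4 * study_report.n
    assert (tmp_path / "table.csv").read_text().startswith("genotype,regimen")


def test_missing_reference_scenario_rejected(calibrated):
    with pytest.raises(ValueError, match="reference"):
        run_scenarios(calibrated.typical, n=10, seed=1, scenarios=(("null", "160QD"),))
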