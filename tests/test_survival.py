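"""Survival endpoints, product-limit estimation, log-rank and Cox fits."""

import numpy as np
import pytest

from milgrade.survival import (
    KaplanMeierCurve,
    PatientOutcome,
    SurvivalRecord,
    build_endpoint,
    build_endpoint_table,
    cox_fit,
    km_estimate,
    logrank_test,
)


def rec(time, event, group=0, **kw):
    return SurvivalRecord(time=time, event=event, group=group, **kw)


# ---------------------------------------------------------------- endpoints


def test_os_administrative_censoring_at_eight_years():
    out = PatientOutcome(patient_id="a", last_followup_time=9.0)
    r = build_endpoint(out, "OS")
    assert (r.time, r.event) == (8.0, 0)


def test_death_is_event_for_os_and_drfs():
    out = PatientOutcome(patient_id="a", last_followup_time=3.0, death_time=3.0)
    assert (build_endpoint(out, "OS").time, build_endpoint(out, "OS").event) == (3.0, 1)
    drfs = build_endpoint(out, "DRFS")
    assert (drfs.time, drfs.event) == (3.0, 1)


def test_second_primary_censors_drfs_before_distant_recurrence():
    out = PatientOutcome(
        patient_id="a", last_followup_time=6.0,
        distant_recurrence_time=4.0, second_primary_time=2.0,
    )
    r = build_endpoint(out, "DRFS")
    assert (r.time, r.event) == (2.0, 0)


def test_rfs_any_recurrence_is_event():
    out = PatientOutcome(
        patient_id="a", last_followup_time=6.0, any_recurrence_time=3.5,
    )
    r = build_endpoint(out, "RFS")
    assert (r.time, r.event) == (3.5, 1)


def test_drfs_has_no_default_horizon():
    out = PatientOutcome(patient_id="a", last_followup_time=12.0,
                         distant_recurrence_time=10.0)
    r = build_endpoint(out, "DRFS")
    assert (r.time, r.event) == (10.0, 1)


def test_invalid_outcome_quarantined_not_fatal():
    good = PatientOutcome(patient_id="ok", last_followup_time=5.0)
    with pytest.raises(ValueError):
        PatientOutcome(patient_id="bad", last_followup_time=-1.0)
    records, quarantine = build_endpoint_table([good], "OS")
    assert len(records) == 1 and not quarantine


def test_drfs_events_at_least_os_events_when_deaths_recorded():
    rng = np.random.default_rng(0)
    outcomes = []
    for i in range(200):
        death = float(rng.exponential(6.0))
        distant = float(rng.exponential(5.0))
        fu = min(death, 10.0)
        outcomes.append(
            PatientOutcome(
                patient_id=str(i), last_followup_time=fu,
                death_time=death if death <= fu else None,
                distant_recurrence_time=distant if distant <= fu else None,
            )
        )
    os_records, _ = build_endpoint_table(outcomes, "OS", horizon=8.0)
    drfs_records, _ = build_endpoint_table(outcomes, "DRFS", horizon=8.0)
    assert sum(r.event for r in drfs_records) >= sum(r.event for r in os_records)


# ------------------------------------------------------------ Kaplan–Meier


def test_km_matches_hand_computed_product_limit_on_worked_set():
    # events at 1, 2, 4; censored at 3, 5, 6
    records = [rec(1, 1), rec(2, 1), rec(3, 0), rec(4, 1), rec(5, 0), rec(6, 0)]
    curve = km_estimate(records)
    assert curve.times.tolist() == [1, 2, 4]
    assert curve.survival == pytest.approx([5 / 6, 2 / 3, 4 / 9])
    assert curve.at_risk.tolist() == [6, 5, 3]
    assert curve.survival_at(0.5) == 1.0
    assert curve.survival_at(3.9) == pytest.approx(2 / 3)
    assert curve.survival_at(100.0) == pytest.approx(4 / 9)


def test_km_no_censoring_equals_empirical_survivor_function():
    rng = np.random.default_rng(1)
    times = rng.exponential(2.0, 40)
    records = [rec(t, 1) for t in times]
    curve = km_estimate(records)
    for q in (0.5, 1.0, 2.0, 5.0):
        assert curve.survival_at(q) == pytest.approx((times > q).mean())


def test_km_all_censored_is_constant_one():
    curve = km_estimate([rec(t, 0) for t in (1, 2, 3)])
    assert curve.survival_at(2.5) == 1.0


def test_km_monotone_nonincreasing_bounded():
    rng = np.random.default_rng(2)
    records = [rec(float(t), int(e)) for t, e in
               zip(rng.exponential(2, 200), rng.integers(0, 2, 200))]
    curve = km_estimate(records)
    assert (np.diff(curve.survival) <= 1e-12).all()
    assert ((curve.survival >= 0) & (curve.survival <= 1)).all()
    assert (curve.ci_lower <= curve.survival + 1e-12).all()
    assert (curve.survival <= curve.ci_upper + 1e-12).all()


def test_km_agrees_with_lifelines():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(3)
    t = rng.exponential(3, 150)
    e = rng.integers(0, 2, 150)
    records = [rec(float(ti), int(ei)) for ti, ei in zip(t, e)]
    curve = km_estimate(records)
    kmf = KaplanMeierFitter().fit(t, e)
    for q in (0.5, 1.5, 3.0, 6.0):
        assert curve.survival_at(q) == pytest.approx(
            float(kmf.predict(q)), abs=1e-10
        )


# ------------------------------------------------------------------ log-rank


def test_logrank_identical_groups_statistic_zero():
    base = [rec(t, 1) for t in (1, 2, 3, 4)] + [rec(5, 0)]
    records = [rec(r.time, r.event, 0) for r in base] + [
        rec(r.time, r.event, 1) for r in base
    ]
    chi2, p = logrank_test(records)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_invariant_to_monotone_time_transform():
    rng = np.random.default_rng(4)
    records = [
        rec(float(t), int(e), int(g))
        for t, e, g in zip(
            rng.exponential(2, 200), rng.integers(0, 2, 200), rng.integers(0, 2, 200)
        )
    ]
    chi2_a, _ = logrank_test(records)
    transformed = [rec(r.time ** 2, r.event, r.group) for r in records]
    chi2_b, _ = logrank_test(transformed)
    assert chi2_a == pytest.approx(chi2_b, rel=1e-12)


def test_logrank_agrees_with_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(5)
    t0 = rng.exponential(2.0, 120)
    t1 = rng.exponential(1.2, 130)
    e0 = (t0 < 4).astype(int)
    e1 = (t1 < 4).astype(int)
    records = [rec(min(t, 4.0), int(e), 0) for t, e in zip(t0, e0)] + [
        rec(min(t, 4.0), int(e), 1) for t, e in zip(t1, e1)
    ]
    chi2, p = logrank_test(records)
    ll = ll_logrank(
        np.minimum(t0, 4), np.minimum(t1, 4), event_observed_A=e0, event_observed_B=e1
    )
    assert chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
    assert p == pytest.approx(ll.p_value, rel=1e-9)


def test_logrank_requires_two_groups_with_events():
    with pytest.raises(ValueError):
        logrank_test([rec(1, 1, 0), rec(2, 1, 0)])
    with pytest.raises(ValueError):
        logrank_test([rec(1, 1, 0), rec(2, 0, 1)])


# ----------------------------------------------------------------------- Cox


def _exponential_cohort(n, hr, rng, horizon=10.0, strata=None):
    group = rng.integers(0, 2, n)
    hazard = 0.1 * hr ** group
    t = rng.exponential(1.0 / hazard)
    records = []
    for i in range(n):
        time = min(t[i], horizon)
        records.append(
            SurvivalRecord(
                time=time, event=int(t[i] <= horizon), group=int(group[i]),
                stratum=(strata[i] if strata is not None else None),
            )
        )
    return records


def test_cox_recovers_moderate_hazard_ratio():
    rng = np.random.default_rng(6)
    records = _exponential_cohort(2000, 2.0, rng)
    fit = cox_fit(records)
    assert 1.7 < fit.hazard_ratio("group") < 2.3
    lo, hi = fit.ci("group")
    assert lo < 2.0 < hi


def test_cox_stratified_matches_unstratified_when_strata_equal():
    rng = np.random.default_rng(7)
    strata = np.where(rng.random(4000) < 0.5, "A", "B")
    records = _exponential_cohort(4000, 1.8, rng, strata=strata)
    plain = cox_fit(records)
    strat = cox_fit(records, stratify_by_subtype=True)
    assert np.log(strat.hazard_ratio("group")) == pytest.approx(
        np.log(plain.hazard_ratio("group")), abs=1e-2 * 5
    )


def test_cox_categorical_covariate_uses_reference_level():
    rng = np.random.default_rng(8)
    records = []
    for r in _exponential_cohort(500, 1.5, rng):
        cat = "small" if rng.random() < 0.5 else "large"
        records.append(
            SurvivalRecord(time=r.time, event=r.event, group=r.group,
                           covariates={"size": cat})
        )
    fit = cox_fit(records, covariates=["size"], reference_levels={"size": "small"})
    assert "size[large]" in fit.table.index
    assert "size[small]" not in fit.table.index


def test_cox_warns_on_few_events_per_coefficient():
    rng = np.random.default_rng(9)
    records = _exponential_cohort(40, 1.0, rng, horizon=1.0)
    fit = cox_fit(records)
    assert fit.n_events < 10 or not fit.warnings  # warning iff < 10 events/coef
    if fit.n_events < 10:
        assert any("events" in w for w in fit.warnings)
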