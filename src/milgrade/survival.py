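"""Survival endpoints, Kaplan–Meier estimation, log-rank tests and Cox models.

Three endpoints are supported, following their clinical definitions:

* OS   — overall survival: time from diagnosis to death from any cause,
  administratively censored at a configurable horizon (default 8 years).
* DRFS — distant-recurrence-free survival: time to distant recurrence or
  death from any cause; a second primary tumor occurring first censors the
  patient at the time of second primary.
* RFS  — recurrence-free survival: time to any recurrence (local, regional
  or distant); second primaries censor as for DRFS.

The Kaplan–Meier product-limit estimator and the two-group log-rank test
are implemented from first principles (they carry this package's numeric
guarantees); proportional-hazards fitting delegates to lifelines with
Efron tie handling and optional stratification by molecular subtype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientOutcome",
    "SurvivalRecord",
    "KaplanMeierCurve",
    "CoxResult",
    "build_endpoint",
    "build_endpoint_table",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]

ENDPOINTS = ("OS", "DRFS", "RFS")

#: Default administrative censoring horizon, in years, applied to OS only.
DEFAULT_OS_HORIZON = 8.0


@dataclass(frozen=True)
class PatientOutcome:
    """Raw follow-up information for one patient, times in years from diagnosis."""

    patient_id: str
    last_followup_time: float
    death_time: float | None = None
    distant_recurrence_time: float | None = None
    any_recurrence_time: float | None = None
    second_primary_time: float | None = None
    grade_group: int = 0
    subtype_stratum: str | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = {
            "last_followup_time": self.last_followup_time,
            "death_time": self.death_time,
            "distant_recurrence_time": self.distant_recurrence_time,
            "any_recurrence_time": self.any_recurrence_time,
            "second_primary_time": self.second_primary_time,
        }
        for name, t in times.items():
            if t is not None and (not math.isfinite(t) or t < 0):
                raise ValueError(
                    f"patient {self.patient_id}: {name} must be a finite "
                    f"non-negative time, got {t!r}"
                )
        if self.death_time is not None and self.death_time > self.last_followup_time:
            raise ValueError(
                f"patient {self.patient_id}: death_time exceeds last_followup_time"
            )


@dataclass(frozen=True)
class SurvivalRecord:
    """A (time, event) pair with group, stratum and adjustment covariates."""

    time: float
    event: int
    group: int
    stratum: str | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"time must be positive and finite, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")


def _first_event(*candidates: float | None) -> float | None:
    present = [t for t in candidates if t is not None]
    return min(present) if present else None


def build_endpoint(
    outcome: PatientOutcome,
    endpoint: str,
    horizon: float | None = None,
) -> SurvivalRecord:
    """Derive the (time, event) pair for one endpoint from raw follow-up.

    ``horizon`` is the administrative censoring time; it defaults to 8
    years for OS and to no horizon for DRFS/RFS.
    """
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")

    if endpoint == "OS":
        if horizon is None:
            horizon = DEFAULT_OS_HORIZON
        event_time = outcome.death_time
        censor_time = outcome.last_followup_time
        if horizon is not None:
            censor_time = min(censor_time, horizon)
        if event_time is not None and event_time <= censor_time:
            return SurvivalRecord(
                time=event_time, event=1, group=outcome.grade_group,
                stratum=outcome.subtype_stratum, covariates=outcome.covariates,
            )
        return SurvivalRecord(
            time=censor_time, event=0, group=outcome.grade_group,
            stratum=outcome.subtype_stratum, covariates=outcome.covariates,
        )

    if endpoint == "DRFS":
        event_time = _first_event(outcome.distant_recurrence_time, outcome.death_time)
    else:  # RFS
        event_time = _first_event(outcome.any_recurrence_time)

    censor_time = outcome.last_followup_time
    if horizon is not None:
        censor_time = min(censor_time, horizon)
    # a second primary before the event censors at the second-primary time
    sp = outcome.second_primary_time
    if sp is not None and (event_time is None or sp < event_time):
        censor_time = min(censor_time, sp)
        event_time = None
    if event_time is not None and event_time <= censor_time:
        return SurvivalRecord(
            time=event_time, event=1, group=outcome.grade_group,
            stratum=outcome.subtype_stratum, covariates=outcome.covariates,
        )
    return SurvivalRecord(
        time=censor_time, event=0, group=outcome.grade_group,
        stratum=outcome.subtype_stratum, covariates=outcome.covariates,
    )


def build_endpoint_table(
    outcomes: Iterable[PatientOutcome],
    endpoint: str,
    horizon: float | None = None,
) -> tuple[list[SurvivalRecord], list[tuple[str, str]]]:
    """Build records for a cohort; invalid records are quarantined.

    Returns (records, quarantine) where quarantine holds
    (patient_id, error message) pairs for records that failed validation.
    """
    records: list[SurvivalRecord] = []
    quarantine: list[tuple[str, str]] = []
    for outcome in outcomes:
        try:
            records.append(build_endpoint(outcome, endpoint, horizon))
        except ValueError as exc:
            quarantine.append((outcome.patient_id, str(exc)))
    return records, quarantine


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit step function with Greenwood log–log 95% CIs."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n at risk at each event time
    events: np.ndarray         # d events at each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous: the step value at the last event time <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return (float(self.ci_lower[idx]), float(self.ci_upper[idx]))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def _times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValueError("at least one record is required")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord], alpha: float = 0.05) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), with the
    Greenwood variance on the log–log (complementary log-log) scale for
    the confidence band.
    """
    t, e = _times_events(records)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    event_times, d = np.unique(t[e == 1], return_counts=True)
    if event_times.size == 0:
        one = np.array([])
        return KaplanMeierCurve(one, one, one, one, one, one)

    # number at risk just before each event time
    n_risk = n - np.searchsorted(t, event_times, side="left")

    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)

    # Greenwood on log-log scale: var(log(-log S)) = sum(d/(n(n-d))) / log(S)^2
    with np.errstate(divide="ignore", invalid="ignore"):
        green = np.cumsum(d / (n_risk * (n_risk - d).clip(min=0).astype(float)))
        log_s = np.log(surv)
        se_cll = np.sqrt(green) / np.abs(log_s)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = surv ** np.exp(z * se_cll)
        upper = surv ** np.exp(-z * se_cll)
    lower = np.where(surv <= 0.0, 0.0, lower)
    upper = np.where(surv <= 0.0, 0.0, upper)
    return KaplanMeierCurve(event_times, surv, n_risk, d, lower, upper)


# ---------------------------------------------------------------------------
# Log-rank


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test on the group field of the records.

    Returns (chi-square statistic with 1 df, p-value).
    """
    t, e = _times_events(records)
    g = np.array([r.group for r in records], dtype=int)
    groups = np.unique(g)
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, found {groups.size}")
    for grp in groups:
        if e[g == grp].sum() == 0:
            raise ValueError(f"group {grp} has no events; log-rank undefined")

    in_g1 = g == groups[1]
    event_times, d_total = np.unique(t[e == 1], return_counts=True)
    d_total = d_total.astype(float)

    # at each event time: n at risk (total, group 1), d events (total, group 1)
    t_sorted = np.sort(t)
    t1_sorted = np.sort(t[in_g1])
    n_total = (t.size - np.searchsorted(t_sorted, event_times, side="left")).astype(float)
    n1 = (t1_sorted.size - np.searchsorted(t1_sorted, event_times, side="left")).astype(float)
    ev1 = t[in_g1 & (e == 1)]
    d1 = np.bincount(
        np.searchsorted(event_times, ev1), minlength=event_times.size
    ).astype(float)

    expected = d_total * n1 / n_total
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_total * (n1 / n_total) * (1.0 - n1 / n_total)
            * (n_total - d_total) / (n_total - 1.0)
        )
    var = np.nan_to_num(var)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((d1 - expected).sum() ** 2 / v)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


# ---------------------------------------------------------------------------
# Cox proportional hazards (delegated fit)


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate hazard ratios with 95% CIs and p-values."""

    table: pd.DataFrame  # index: covariate; columns: hr, ci_lower, ci_upper, p
    n: int
    n_events: int
    warnings: tuple[str, ...] = ()

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.table.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _records_to_frame(records: Sequence[SurvivalRecord], covariates: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"time": r.time, "event": r.event, "group": r.group}
        if r.stratum is not None:
            row["stratum"] = r.stratum
        for c in covariates:
            if c not in r.covariates:
                raise ValueError(f"record missing covariate {c!r}")
            row[c] = r.covariates[c]
        rows.append(row)
    return pd.DataFrame(rows)


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str] = (),
    stratify_by_subtype: bool = False,
    reference_levels: Mapping[str, str] | None = None,
) -> CoxResult:
    """Proportional-hazards fit with Efron tie handling.

    The binary group indicator is always included; ``covariates`` names
    additional adjustment variables carried on the records (categorical
    values are dummy-coded against ``reference_levels`` or the first level).
    With ``stratify_by_subtype`` the baseline hazard is fit separately per
    molecular-subtype stratum.
    """
    from lifelines import CoxPHFitter

    df = _records_to_frame(records, covariates)
    n_events = int(df["event"].sum())
    warnings: list[str] = []

    design_cols = ["group"]
    for c in covariates:
        col = df[c]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            ref = (reference_levels or {}).get(c, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {c!r}")
            for level in levels:
                if level == ref:
                    continue
                name = f"{c}[{level}]"
                df[name] = (col.astype(str) == level).astype(int)
                design_cols.append(name)
        else:
            df[c] = col.astype(float)
            design_cols.append(c)

    n_coef = len(design_cols)
    if n_events < 10 * n_coef:
        warnings.append(
            f"only {n_events} events for {n_coef} coefficients "
            "(< 10 per coefficient); estimates may be unstable"
        )

    fit_cols = ["time", "event"] + design_cols
    kwargs = {}
    if stratify_by_subtype:
        if "stratum" not in df.columns:
            raise ValueError("stratification requested but records carry no stratum")
        fit_cols.append("stratum")
        kwargs["strata"] = ["stratum"]

    cph = CoxPHFitter()
    cph.fit(df[fit_cols], duration_col="time", event_col="event", **kwargs)

    summary = cph.summary
    table = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    return CoxResult(table=table, n=len(df), n_events=n_events, warnings=tuple(warnings))
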