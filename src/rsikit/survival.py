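"""Survival analysis for score-stratified cohorts.

Kaplan-Meier product-limit estimation, the two-group log-rank test and the
univariate Cox proportional-hazards fit are delegated to lifelines (Efron
tie handling in Cox, Wald confidence intervals). The maximally selected
log-rank cutpoint — scan all admissible score splits and keep the one with
the largest standardised log-rank statistic — is implemented here.

The optimal cutpoint is selected on the same data it then stratifies, which
inflates the apparent separation; validate on an independent cohort or
replicate when the stratification matters (see docs/methods.md).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .errors import ValidationError

__all__ = [
    "KMCurve",
    "HazardEstimate",
    "SurvCutpoint",
    "km_fit",
    "logrank",
    "cox_univariate",
    "surv_cutpoint",
]


def _validate_records(time: np.ndarray, event: np.ndarray) -> None:
    if (time < 0).any():
        raise ValidationError("survival times must be non-negative")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event indicator must be 0 (censored) or 1 (death)")


@dataclass
class KMCurve:
    """Product-limit curve: event times, survival after each, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations shrink the risk set without producing steps.
    Returns the curve at the distinct observed times (events and censorings).
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValidationError("need >= 1 record")
    _validate_records(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].to_numpy(float)
    keep = times > 0  # lifelines prepends t=0
    return KMCurve(times[keep], surv[keep], at_risk[keep])


def logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test (1 df). Returns (chi-square, p)."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    group = np.asarray(group)
    _validate_records(time, event)
    levels = pd.unique(group)
    if levels.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {levels.size}")
    if event.sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    mask = group == levels[0]
    res = logrank_test(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardEstimate:
    """Univariate Cox fit: hazard ratio with Wald 95% CI and p."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_hr: float
    converged: bool = True


def cox_univariate(
    time: np.ndarray, event: np.ndarray, covariate: np.ndarray
) -> HazardEstimate:
    """Single-covariate Cox proportional-hazards fit (Efron ties, Wald CI).

    Non-convergence (including monotone likelihood from perfect separation)
    yields a flagged estimate rather than an exception.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    covariate = np.asarray(covariate, float)
    _validate_records(time, event)
    if np.unique(covariate).size < 2:
        raise ValidationError("covariate does not vary")
    if event.sum() == 0:
        raise ValidationError("no events observed")
    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return HazardEstimate(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    s = cph.summary.loc["x"]
    return HazardEstimate(
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        log_hr=float(s["coef"]),
    )


def _logrank_z(time: np.ndarray, event: np.ndarray, in_group: np.ndarray) -> float:
    """Standardised two-group log-rank statistic (O-E)/sqrt(V) for group 1."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), in_group[order].astype(bool)
    n = t.size
    # walk distinct event times; at each, risk sets are suffix counts
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        d = d1 = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                d1 += int(g[j])
            j += 1
        if d > 0:
            n_at = n - i
            n1_at = int(g[i:].sum())
            o_minus_e += d1 - d * n1_at / n_at
            if n_at > 1:
                var += (d * (n1_at / n_at) * (1 - n1_at / n_at)
                        * (n_at - d) / (n_at - 1))
        i = j
    return o_minus_e / np.sqrt(var) if var > 0 else 0.0


@dataclass
class SurvCutpoint:
    """Maximally selected log-rank split of a continuous score."""

    value: float
    statistic: float  # |standardised log-rank| at the split
    minprop: float
    n_low: int
    n_high: int


def surv_cutpoint(
    time: np.ndarray,
    event: np.ndarray,
    scores: np.ndarray,
    minprop: float = 0.1,
) -> SurvCutpoint:
    """Optimal survival cutpoint for a continuous score.

    Scans midpoints between consecutive distinct scores whose induced split
    leaves at least ``minprop`` of the samples on each side, and returns the
    split maximising the absolute standardised log-rank statistic.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    scores = np.asarray(scores, float)
    _validate_records(time, event)
    if np.unique(scores).size < 2:
        raise ValidationError("scores do not vary")
    if event.sum() == 0:
        raise ValidationError("no events observed")
    n = scores.size
    min_n = int(np.ceil(minprop * n))
    distinct = np.unique(scores)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best: tuple[float, float, int] | None = None
    for c in candidates:
        high = scores > c
        n_high = int(high.sum())
        if n_high < min_n or n - n_high < min_n:
            continue
        z = float(abs(_logrank_z(time, event, high)))
        if best is None or z > best[0] + 1e-12:
            best = (z, float(c), n_high)
    if best is None:
        raise ValidationError(
            f"no admissible split leaves >= {min_n} samples on each side"
        )
    z, c, n_high = best
    return SurvCutpoint(c, z, minprop, n - n_high, n_high)
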