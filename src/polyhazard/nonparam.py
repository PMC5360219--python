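"""Nonparametric survival statistics with left-truncation support.

Kaplan-Meier product-limit curves with Greenwood variance, the two-sample
log-rank test, the Cochran-Armitage trend test on a 2xk table, and a
graphical proportional-hazards diagnostic comparing Cox-implied survivor
curves to stratum Kaplan-Meier curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import CoxFit, FitError

__all__ = [
    "StepSurvival",
    "kaplan_meier",
    "logrank_test",
    "cochran_armitage_trend",
    "ph_diagnostic",
    "PHDiagnostic",
]


@dataclass
class StepSurvival:
    """Step survivor estimate with Greenwood variance and log-transformed 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else np.inf


def _risk_counts(entry, exit, event):
    """Unique event times with tied-death counts and truncation-aware risk-set sizes."""
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    event = np.asarray(event).astype(bool)
    times = np.unique(exit[event])
    exit_sorted = np.sort(exit)
    entry_sorted = np.sort(entry)
    n = exit.size
    at_risk = (n - np.searchsorted(exit_sorted, times, side="left")) - (
        n - np.searchsorted(entry_sorted, times, side="left")
    )
    death_times = np.sort(exit[event])
    d = np.searchsorted(death_times, times, side="right") - np.searchsorted(
        death_times, times, side="left"
    )
    return times, d.astype(float), at_risk.astype(float)


def kaplan_meier(exit, event, entry=None, alpha: float = 0.05) -> StepSurvival:
    """Product-limit survivor estimate.

    Greenwood's formula supplies the variance; the confidence interval is
    computed on the log-survival scale, S * exp(+-z * se(log S)), which keeps
    the lower bound nonnegative.
    """
    exit = np.asarray(exit, dtype=float)
    if exit.size == 0:
        raise FitError("empty input to kaplan_meier")
    event = np.asarray(event).astype(bool)
    if entry is None:
        entry = np.full(exit.size, -np.inf)
    times, d, y = _risk_counts(entry, exit, event)
    if times.size == 0:
        return StepSurvival(
            times=np.array([]), survival=np.array([]), variance=np.array([]),
            ci_lower=np.array([]), ci_upper=np.array([]),
            n_risk=np.array([]), n_events=np.array([]),
        )
    surv = np.cumprod(1.0 - d / y)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(y > d, d / (y * (y - d)), np.inf)
    cumgw = np.cumsum(gw_terms)
    variance = surv**2 * cumgw
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_se = np.sqrt(cumgw)
        lower = surv * np.exp(-z * log_se)
        upper = np.minimum(surv * np.exp(z * log_se), 1.0)
    lower = np.where(surv == 0.0, 0.0, lower)
    upper = np.where(surv == 0.0, 0.0, upper)
    return StepSurvival(times, surv, variance, lower, upper, y, d)


def logrank_test(group_a: pd.DataFrame | dict, group_b: pd.DataFrame | dict,
                 *, entry_col: str | None = "entry_age",
                 exit_col: str = "exit_age", event_col: str = "event"):
    """Two-sample log-rank test (1 df), truncation-aware.

    Returns ``(chi2, p)``.
    """
    groups = []
    for g in (group_a, group_b):
        frame = pd.DataFrame(g)
        if len(frame) == 0:
            raise FitError("log-rank test requires non-empty groups")
        exit = frame[exit_col].to_numpy(dtype=float)
        event = frame[event_col].to_numpy().astype(bool)
        if entry_col is not None and entry_col in frame.columns:
            entry = frame[entry_col].to_numpy(dtype=float)
        else:
            entry = np.full(exit.size, -np.inf)
        groups.append((entry, exit, event))

    all_times = np.unique(np.concatenate([ex[ev] for _, ex, ev in groups]))
    if all_times.size == 0:
        raise FitError("no events in either group")

    y_g, d_g = [], []
    for entry, exit, event in groups:
        exit_sorted = np.sort(exit)
        entry_sorted = np.sort(entry)
        n = exit.size
        y = (n - np.searchsorted(exit_sorted, all_times, side="left")) - (
            n - np.searchsorted(entry_sorted, all_times, side="left")
        )
        death_times = np.sort(exit[event])
        d = np.searchsorted(death_times, all_times, side="right") - np.searchsorted(
            death_times, all_times, side="left"
        )
        y_g.append(y.astype(float))
        d_g.append(d.astype(float))

    y_tot = y_g[0] + y_g[1]
    d_tot = d_g[0] + d_g[1]
    keep = y_tot > 0
    o_minus_e = d_g[0][keep] - d_tot[keep] * y_g[0][keep] / y_tot[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (
            d_tot[keep]
            * (y_g[0][keep] / y_tot[keep])
            * (y_g[1][keep] / y_tot[keep])
            * (y_tot[keep] - d_tot[keep])
            / np.maximum(y_tot[keep] - 1.0, 1.0)
        )
    num = o_minus_e.sum()
    var = v.sum()
    if var == 0:
        return 0.0, 1.0
    chi2 = num**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cochran_armitage_trend(progressed, totals, scores):
    """Cochran-Armitage trend test for a 2xk table with user-supplied bin scores.

    Returns ``(Z, p)`` with a two-sided normal p-value. Z is positive when
    the progression proportion increases with the score.
    """
    r = np.asarray(progressed, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    if r.size != n.size or r.size != s.size:
        raise ValueError("progressed, totals and scores must have equal length")
    if r.size < 2:
        raise ValueError("trend test requires at least 2 bins")
    if np.any(n <= 0):
        raise ValueError("every bin total must be positive")
    if np.any(r < 0) or np.any(r > n):
        raise ValueError("progressed counts must lie in [0, total]")
    N = n.sum()
    pbar = r.sum() / N
    if pbar in (0.0, 1.0):
        raise ValueError("degenerate table: all or none progressed")
    num = np.sum(s * (r - n * pbar))
    var = pbar * (1.0 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        raise ValueError("zero trend variance (constant scores?)")
    z = num / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class PHDiagnostic:
    """Per-stratum model-vs-empirical survivor comparison."""

    strata: dict = field(default_factory=dict)  # label -> (model StepSurvival-like, km)
    max_gap: dict = field(default_factory=dict)
    ci_coverage: dict = field(default_factory=dict)  # fraction of event times covered


def ph_diagnostic(
    frame: pd.DataFrame,
    fit: CoxFit,
    strata: pd.Series | np.ndarray,
    covariates: list[str] | None = None,
    *,
    entry_col: str | None = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> PHDiagnostic:
    """Graphical proportional-hazards check.

    For each stratum, compares the Cox-implied survivor curve at the
    stratum's mean covariate vector, S(t) = exp(-H0(t) e^{beta.xbar}),
    with the stratum's Kaplan-Meier estimate, reporting the maximum
    absolute vertical gap and the fraction of stratum event times at which
    the KM 95% band covers the model curve.
    """
    if covariates is None:
        covariates = list(fit.params.index)
    strata = np.asarray(strata)
    out = PHDiagnostic()
    for label in pd.unique(strata):
        sub = frame.loc[strata == label]
        if int(sub[event_col].sum()) == 0:
            warnings.warn(f"stratum {label!r} has no events; skipped")
            continue
        entry = (
            sub[entry_col].to_numpy(dtype=float)
            if entry_col is not None and entry_col in sub.columns
            else None
        )
        km = kaplan_meier(sub[exit_col].to_numpy(dtype=float),
                          sub[event_col].to_numpy(), entry=entry)
        xbar = sub[covariates].to_numpy(dtype=float).mean(axis=0)
        rr = float(np.exp(xbar @ fit.params.to_numpy()))
        model_surv = np.exp(-fit.cumhaz(km.times) * rr)
        gap = np.abs(model_surv - km.survival)
        covered = (km.ci_lower <= model_surv) & (model_surv <= km.ci_upper)
        out.strata[label] = (km.times, model_surv, km)
        out.max_gap[label] = float(gap.max()) if gap.size else 0.0
        out.ci_coverage[label] = float(covered.mean()) if covered.size else 1.0
    return out
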