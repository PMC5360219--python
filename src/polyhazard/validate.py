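"""Replication analyses for a frozen polygenic hazard score.

These procedures consume pre-computed scores and a frozen weight table /
calibrated hazard; none of them refits coefficients, preserving train/test
discipline: percentile risk stratification with Kaplan-Meier curves,
predicted-vs-empirical onset-age correlation over percentile bins, the
progression-rate trend test for initially unaffected individuals, and the
top-vs-bottom decile hazard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import IncidenceCalibrator
from .nonparam import StepSurvival, cochran_armitage_trend, kaplan_meier, logrank_test
from .score import PHSDistribution, percentile_of
from .survival import FitError, fit_cox

__all__ = [
    "StratifiedCurves",
    "stratify_km",
    "OnsetCalibrationResult",
    "onset_correlation",
    "progression_trend",
    "decile_hr",
]


@dataclass
class StratifiedCurves:
    labels: list[str]
    curves: dict[str, StepSurvival]
    counts: dict[str, int]
    logrank_chi2: float | None
    logrank_p: float | None


def stratify_km(
    cohort: pd.DataFrame,
    scores,
    dist: PHSDistribution,
    bin_edges=(0, 25, 50, 75, 100),
) -> StratifiedCurves:
    """Kaplan-Meier curves by score-percentile stratum.

    Each individual is placed in a percentile bin of the reference
    distribution; a KM curve is estimated per bin (empty bins dropped with
    a warning) and a log-rank test compares the extreme bins.
    """
    scores = np.asarray(scores, dtype=float)
    pct = percentile_of(scores, dist)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least two values")
    idx = np.clip(np.digitize(pct, edges[1:-1]), 0, edges.size - 2)
    labels = [f"p{edges[i]:g}-{edges[i + 1]:g}" for i in range(edges.size - 1)]
    curves, counts = {}, {}
    frames = {}
    for i, lab in enumerate(labels):
        sub = cohort.loc[idx == i]
        if len(sub) == 0:
            warnings.warn(f"empty percentile bin {lab}; dropped")
            continue
        entry = sub["entry_age"].to_numpy(float) if "entry_age" in sub.columns else None
        curves[lab] = kaplan_meier(
            sub["exit_age"].to_numpy(float), sub["event"].to_numpy(), entry=entry
        )
        counts[lab] = len(sub)
        frames[lab] = sub
    kept = [lab for lab in labels if lab in curves]
    chi2 = p = None
    if len(kept) >= 2:
        lo, hi = frames[kept[0]], frames[kept[-1]]
        if lo["event"].sum() > 0 or hi["event"].sum() > 0:
            try:
                chi2, p = logrank_test(lo, hi)
            except FitError as exc:
                warnings.warn(f"log-rank test skipped: {exc}")
    else:
        warnings.warn("fewer than two populated strata; log-rank test skipped")
    return StratifiedCurves(kept, curves, counts, chi2, p)


@dataclass
class OnsetCalibrationResult:
    bins: pd.DataFrame  # per bin: n, mean score, empirical onset, predicted onset
    pearson_r: float
    p_value: float
    q: float


def onset_correlation(
    cases: pd.DataFrame,
    scores,
    cal: IncidenceCalibrator,
    n_bins: int = 20,
    q: float = 0.5,
    min_bin_cases: int = 5,
) -> OnsetCalibrationResult:
    """Predicted vs empirical onset age over score-percentile bins of cases.

    Cases are binned by score quantile; the empirical value is the mean
    observed onset age in the bin and the predicted value the model onset
    age at cumulative risk ``q`` for the bin's median score. Bins with
    fewer than ``min_bin_cases`` cases are merged with their neighbour.
    Returns the Pearson correlation over bins with its two-sided p-value.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be at least 3")
    cases = cases.loc[cases["event"] == 1]
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(cases):
        raise ValueError("scores must align with the case rows")
    if len(cases) < n_bins:
        raise ValueError("fewer cases than requested bins")
    edges = np.quantile(scores, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], scores, side="right"), 0, n_bins - 1)
    onset = cases["exit_age"].to_numpy(float)

    groups: list[np.ndarray] = [np.flatnonzero(idx == i) for i in range(n_bins)]
    merged: list[np.ndarray] = []
    for g in groups:
        if merged and (g.size < min_bin_cases or merged[-1].size < min_bin_cases):
            merged[-1] = np.concatenate([merged[-1], g])
        elif g.size:
            merged.append(g)
    rows = []
    for g in merged:
        med = float(np.median(scores[g]))
        rows.append(
            {
                "n": int(g.size),
                "median_score": med,
                "empirical_onset": float(onset[g].mean()),
                "predicted_onset": cal.expected_onset_age(med, q=q),
            }
        )
    table = pd.DataFrame(rows)
    finite = np.isfinite(table["predicted_onset"])
    if finite.sum() < 3:
        raise ValueError("too few bins with finite predicted onset")
    r, p = stats.pearsonr(
        table.loc[finite, "predicted_onset"], table.loc[finite, "empirical_onset"]
    )
    return OnsetCalibrationResult(table, float(r), float(p), q)


def progression_trend(
    normals: pd.DataFrame,
    scores,
    cal: IncidenceCalibrator,
    n_bins: int = 4,
):
    """Observed progression vs model-predicted incidence, with a trend test.

    ``normals`` holds initially unaffected individuals with columns
    ``baseline_age``, ``followup_years`` (>= 2 required) and
    ``progressed`` (0/1). Individuals are binned by predicted annualized
    incidence at baseline age; the 2xk progressed/total table is passed to
    the Cochran-Armitage trend test with the per-bin mean predicted
    incidence as scores. Returns ``(Z, p, per-bin table)`` where the table
    carries observed proportions with Wilson 95% intervals.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if (normals["followup_years"] < 2).any():
        raise ValueError("every individual requires at least 2 years of follow-up")
    scores = np.asarray(scores, dtype=float)
    pred = np.asarray(
        cal.annualized_incidence(scores, normals["baseline_age"].to_numpy(float))
    )
    prog = normals["progressed"].to_numpy()
    if prog.sum() == 0 or prog.sum() == prog.size:
        raise ValueError("degenerate table: all or none progressed")
    edges = np.quantile(pred, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], pred, side="right"), 0, n_bins - 1)
    rows = []
    for i in range(n_bins):
        mask = idx == i
        if mask.sum() == 0:
            continue
        n, r = int(mask.sum()), int(prog[mask].sum())
        phat = r / n
        z = stats.norm.ppf(0.975)
        denom = 1 + z**2 / n
        center = (phat + z**2 / (2 * n)) / denom
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        rows.append(
            {
                "predicted_incidence": float(pred[mask].mean()),
                "n": n,
                "progressed": r,
                "observed_rate": phat,
                "ci_lower": max(center - half, 0.0),
                "ci_upper": min(center + half, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("fewer than 2 populated bins for the trend test")
    z_stat, p = cochran_armitage_trend(
        table["progressed"], table["n"], table["predicted_incidence"]
    )
    return z_stat, p, table


def decile_hr(
    cohort: pd.DataFrame,
    scores,
    covariate_adjustment: list[str] | None = None,
):
    """Hazard ratio of the top vs bottom score decile.

    Restricts to the extreme deciles, fits a Cox model on the top-decile
    indicator (plus optional adjusters) and runs a log-rank test between
    the deciles. Returns ``(HR, (ci_low, ci_high), logrank_p)``.
    """
    scores = np.asarray(scores, dtype=float)
    lo_edge, hi_edge = np.quantile(scores, [0.1, 0.9])
    lo = scores <= lo_edge
    hi = scores >= hi_edge
    sub = cohort.loc[lo | hi].copy()
    sub["top_decile"] = hi[lo | hi].astype(float)
    for part, name in ((cohort.loc[lo], "bottom"), (cohort.loc[hi], "top")):
        if part["event"].sum() == 0:
            raise FitError(f"{name} decile contains no events")
    covs = ["top_decile"] + list(covariate_adjustment or [])
    if np.isclose(sub["top_decile"].std(), 0.0):
        # identical strata (e.g. all-equal scores): no contrast to estimate
        return 1.0, (1.0, 1.0), 1.0
    fit = fit_cox(sub, covs)
    beta = float(fit.params["top_decile"])
    se = float(fit.se["top_decile"])
    z = stats.norm.ppf(0.975)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    _, p = logrank_test(cohort.loc[lo], cohort.loc[hi])
    return hr, ci, p
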