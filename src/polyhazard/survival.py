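"""Cox proportional-hazards engine on the age axis.

Implements partial-likelihood fitting by Newton iteration with Efron or
Breslow handling of tied event ages, left truncation (delayed entry: a
subject enters the risk set at study-entry age rather than at birth, which
is required when age rather than time-on-study is the time axis), the
Breslow baseline cumulative hazard, and Martingale residuals.

All risk-set sums are evaluated with sorted cumulative sums, so one Newton
iteration costs O(n log n + n p^2); repeated fits on the same cohort (as in
stepwise selection and bootstrapping) reuse the sorted index structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "FitError",
    "ConvergenceWarning",
    "StepFunction",
    "fit_cox",
    "breslow_cumhaz",
    "martingale_residuals",
]


class FitError(ValueError):
    """Raised when a survival model cannot be fit (no events, empty data...)."""


class ConvergenceWarning(UserWarning):
    """Emitted when Newton iteration fails to converge or the likelihood is monotone."""


@dataclass
class StepFunction:
    """Right-continuous step function, 0 before the first jump."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[0.0], self.values])
        return vals[idx]


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, uncertainty, baseline hazard."""

    params: pd.Series
    se: pd.Series
    loglik: float
    cumhaz: StepFunction
    wald_p: pd.Series
    converged: bool
    n_events: int
    n: int
    ties: str
    n_iter: int
    covariance: np.ndarray

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def neg_log10_p(self) -> pd.Series:
        with np.errstate(divide="ignore"):
            return -np.log10(self.wald_p)

    def confidence_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.se, "upper": self.params + z * self.se}
        )


def _suffix_sum(arr: np.ndarray) -> np.ndarray:
    """Suffix sums with a trailing 0 so position n indexes an empty sum."""
    out = np.zeros((arr.shape[0] + 1,) + arr.shape[1:], dtype=float)
    out[:-1] = np.cumsum(arr[::-1], axis=0)[::-1]
    return out


class SurvivalData:
    """Sorted index structures for (entry, exit, event), reusable across fits.

    Risk set at event age t is {i : entry_i < t <= exit_i}; because
    entry < exit always, the truncation correction is a plain suffix sum
    over entry ages.
    """

    def __init__(self, entry, exit, event):
        entry = np.asarray(entry, dtype=float)
        exit = np.asarray(exit, dtype=float)
        event = np.asarray(event)
        if entry.shape != exit.shape or entry.shape != event.shape:
            raise FitError("entry, exit and event must have equal length")
        if entry.size == 0:
            raise FitError("empty survival data")
        if np.any(exit <= entry):
            raise FitError("all exit ages must exceed entry ages")
        if not np.isin(event, [0, 1]).all():
            raise FitError("event indicator must be 0/1")
        self.entry = entry
        self.exit = exit
        self.event = event.astype(bool)
        self.n = entry.size
        self.n_events = int(self.event.sum())
        if self.n_events == 0:
            raise FitError("no events in the data")

        self.order_exit = np.argsort(exit, kind="stable")
        self.exit_sorted = exit[self.order_exit]
        self.order_entry = np.argsort(entry, kind="stable")
        self.entry_sorted = entry[self.order_entry]

        death_idx = np.flatnonzero(self.event)
        self.death_order = death_idx[np.argsort(exit[death_idx], kind="stable")]
        death_times = exit[self.death_order]
        self.event_times, group_starts = np.unique(death_times, return_index=True)
        self.group_starts = group_starts
        self.tie_counts = np.diff(np.append(group_starts, death_times.size))

        self.pos_exit = np.searchsorted(self.exit_sorted, self.event_times, side="left")
        self.pos_entry = np.searchsorted(self.entry_sorted, self.event_times, side="left")

        # expansion indices for the Efron correction: one row per (event time, l)
        m = death_times.size
        self.rep_idx = np.repeat(np.arange(self.event_times.size), self.tie_counts)
        offsets = np.repeat(group_starts, self.tie_counts)
        self.l_frac = (np.arange(m) - offsets) / np.repeat(
            self.tie_counts.astype(float), self.tie_counts
        )


def _loglik_only(data: SurvivalData, X: np.ndarray, beta: np.ndarray, efron: bool) -> float:
    eta = X @ beta
    eta = eta - eta.max()  # stabilise; partial likelihood is shift-invariant
    r = np.exp(eta)
    s0 = (
        _suffix_sum(r[data.order_exit])[data.pos_exit]
        - _suffix_sum(r[data.order_entry])[data.pos_entry]
    )
    s0d = np.add.reduceat(r[data.death_order], data.group_starts)
    frac = data.l_frac if efron else 0.0
    denom = s0[data.rep_idx] - frac * s0d[data.rep_idx]
    if np.any(denom <= 0):
        return -np.inf
    return float(eta[data.death_order].sum() - np.log(denom).sum())


def _derivatives(data: SurvivalData, X: np.ndarray, beta: np.ndarray, efron: bool):
    """Partial log-likelihood, score vector and information matrix."""
    n, p = X.shape
    eta = X @ beta
    shift = eta.max()
    r = np.exp(eta - shift)
    rx = r[:, None] * X
    rxx = rx[:, :, None] * X[:, None, :]

    s0 = (
        _suffix_sum(r[data.order_exit])[data.pos_exit]
        - _suffix_sum(r[data.order_entry])[data.pos_entry]
    )
    s1 = (
        _suffix_sum(rx[data.order_exit])[data.pos_exit]
        - _suffix_sum(rx[data.order_entry])[data.pos_entry]
    )
    s2 = (
        _suffix_sum(rxx[data.order_exit])[data.pos_exit]
        - _suffix_sum(rxx[data.order_entry])[data.pos_entry]
    )

    s0d = np.add.reduceat(r[data.death_order], data.group_starts)
    s1d = np.add.reduceat(rx[data.death_order], data.group_starts)
    s2d = np.add.reduceat(rxx[data.death_order], data.group_starts)

    rep, frac = data.rep_idx, (data.l_frac if efron else np.zeros_like(data.l_frac))
    denom = s0[rep] - frac * s0d[rep]
    if np.any(denom <= 0):
        return -np.inf, None, None
    z = (s1[rep] - frac[:, None] * s1d[rep]) / denom[:, None]
    w = (s2[rep] - frac[:, None, None] * s2d[rep]) / denom[:, None, None]

    loglik = (eta - shift)[data.death_order].sum() - np.log(denom).sum()
    score = X[data.death_order].sum(axis=0) - z.sum(axis=0)
    info = w.sum(axis=0) - np.einsum("mi,mj->ij", z, z)
    return float(loglik), score, info


def _newton_cox(
    data: SurvivalData,
    X: np.ndarray,
    efron: bool,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    p = X.shape[1]
    beta = np.zeros(p)
    loglik, score, info = _derivatives(data, X, beta, efron)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-8 * np.eye(p), score)
        # step-halving on likelihood decrease keeps the iteration monotone
        new_beta = beta + step
        new_ll = _loglik_only(data, X, new_beta, efron)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik - 1e-12) and halvings < 25:
            step = step / 2.0
            new_beta = beta + step
            new_ll = _loglik_only(data, X, new_beta, efron)
            halvings += 1
        beta = new_beta
        loglik, score, info = _derivatives(data, X, beta, efron)
        if score is None:
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(score)) < tol:
        converged = True
    monotone = bool(np.any(np.abs(beta) > 50))
    if monotone:
        converged = False
    return beta, loglik, score, info, converged, it, monotone


def fit_cox(
    frame: pd.DataFrame,
    covariates: list[str] | None = None,
    *,
    entry_col: str | None = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
    ties: str = "efron",
    data: SurvivalData | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by maximum partial likelihood.

    Age is the time axis; when ``entry_col`` is present (or ``data`` is
    supplied), subjects are left-truncated at their entry age. Efron's tie
    correction is the default; ``ties="breslow"`` selects Breslow's.

    Non-convergence and monotone partial likelihood (perfect separation)
    are flagged on the returned :class:`CoxFit` and warned about, never
    silently ignored.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if covariates is None:
        reserved = {entry_col, exit_col, event_col}
        covariates = [c for c in frame.columns if c not in reserved]
    if not covariates:
        raise FitError("no covariates to fit")
    X = frame[covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise FitError("covariates contain missing values")
    if data is None:
        if entry_col is not None and entry_col in frame.columns:
            entry = frame[entry_col].to_numpy(dtype=float)
        else:
            entry = np.full(len(frame), -np.inf)
        data = SurvivalData(entry, frame[exit_col].to_numpy(dtype=float),
                            frame[event_col].to_numpy())
    # guard covariates constant within the sample (no information)
    if np.any(X.std(axis=0) == 0):
        bad = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise FitError(f"covariates constant across the sample: {bad}")

    efron = ties == "efron"
    beta, loglik, score, info, converged, n_iter, monotone = _newton_cox(data, X, efron)
    if not monotone and converged:
        # flat-likelihood signature of separation: huge beta or exploding SE
        try:
            diag = np.diag(np.linalg.inv(info))
        except np.linalg.LinAlgError:
            diag = np.full(X.shape[1], np.inf)
        big_se = np.sqrt(np.clip(diag, 0.0, None)) > 100.0 * np.maximum(1.0, np.abs(beta))
        if np.any(np.abs(beta) > 10) and np.any(big_se):
            monotone, converged = True, False
    if monotone:
        warnings.warn(
            "monotone partial likelihood (possible perfect separation); "
            "coefficients diverged",
            ConvergenceWarning,
        )
    elif not converged:
        warnings.warn("Newton iteration did not converge", ConvergenceWarning)

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta / se, np.nan)
    wald_p = 2.0 * stats.norm.sf(np.abs(zval))

    fit = CoxFit(
        params=pd.Series(beta, index=covariates, name="beta"),
        se=pd.Series(se, index=covariates, name="se"),
        loglik=loglik,
        cumhaz=_breslow_from_parts(data, X, beta),
        wald_p=pd.Series(wald_p, index=covariates, name="p"),
        converged=converged,
        n_events=data.n_events,
        n=data.n,
        ties=ties,
        n_iter=n_iter,
        covariance=cov,
    )
    return fit


def _breslow_from_parts(data: SurvivalData, X: np.ndarray, beta: np.ndarray) -> StepFunction:
    r = np.exp(X @ beta)
    s0 = (
        _suffix_sum(r[data.order_exit])[data.pos_exit]
        - _suffix_sum(r[data.order_entry])[data.pos_entry]
    )
    jumps = data.tie_counts / s0
    return StepFunction(times=data.event_times.copy(), values=np.cumsum(jumps))


def breslow_cumhaz(
    fit: CoxFit,
    frame: pd.DataFrame,
    covariates: list[str] | None = None,
    *,
    entry_col: str | None = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> StepFunction:
    """Breslow estimator H0(t) = sum over event ages <= t of d_k / sum_{risk} exp(beta.x)."""
    if covariates is None:
        covariates = list(fit.params.index)
    X = frame[covariates].to_numpy(dtype=float)
    if entry_col is not None and entry_col in frame.columns:
        entry = frame[entry_col].to_numpy(dtype=float)
    else:
        entry = np.full(len(frame), -np.inf)
    data = SurvivalData(entry, frame[exit_col].to_numpy(dtype=float),
                        frame[event_col].to_numpy())
    return _breslow_from_parts(data, X, fit.params.to_numpy())


def martingale_residuals(
    frame: pd.DataFrame,
    fit: CoxFit,
    covariates: list[str] | None = None,
    *,
    entry_col: str | None = "entry_age",
    exit_col: str = "exit_age",
    event_col: str = "event",
) -> np.ndarray:
    """Martingale residuals M_i = delta_i - [H0(exit_i) - H0(entry_i)] exp(beta.x_i).

    With left truncation only the hazard accumulated while under observation
    counts. Residuals are bounded above by 1 and sum to ~0 at the MLE.
    """
    if covariates is None:
        covariates = list(fit.params.index)
    X = frame[covariates].to_numpy(dtype=float)
    exit = frame[exit_col].to_numpy(dtype=float)
    event = frame[event_col].to_numpy(dtype=float)
    H = fit.cumhaz(exit)
    if entry_col is not None and entry_col in frame.columns:
        H = H - fit.cumhaz(frame[entry_col].to_numpy(dtype=float))
    return event - H * np.exp(X @ fit.params.to_numpy())
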