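"""Absolute-risk calibration against published population incidence.

Case-control training data cannot supply a usable baseline hazard, so the
score-zero baseline h0*(t) is solved from published age-specific incidence:
marching up an age grid, the population hazard among survivors under the
proportional-hazards model,

    h_pop(t) = h0*(t) * E[ e^s | T >= t ]
             = h0*(t) * sum_k w_k(t) e^{s_k} / sum_k w_k(t),
    w_k(t) = f(s_k) * exp(-e^{s_k} * H0*(t)),

is matched exactly at every grid age. The expectation is over the score
reference distribution f(s) and shrinks toward low-risk profiles with age
as high-risk individuals are depleted. Published rates in percent per year
are read as one-year conditional probabilities q and converted to hazards
by h = -ln(1 - q); the model hazard is piecewise constant on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .score import PHSDistribution

__all__ = [
    "BaselineIncidence",
    "interpolate_baseline",
    "IncidenceCalibrator",
    "calibrate_baseline",
    "annualized_incidence",
    "survival_curve",
    "expected_onset_age",
    "incidence_table",
]


@dataclass
class BaselineIncidence:
    """Published annualized incidence: ages (years) and rates per 100 person-years."""

    ages: np.ndarray
    rates_per_100: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.rates_per_100 = np.asarray(self.rates_per_100, dtype=float)
        if self.ages.size != self.rates_per_100.size or self.ages.size == 0:
            raise ValueError("ages and rates must be equal-length, nonempty")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age knots must be strictly increasing")
        if np.any(self.rates_per_100 <= 0):
            raise ValueError("rates must be positive")

    @property
    def hazards(self) -> np.ndarray:
        return -np.log1p(-self.rates_per_100 / 100.0)

    @classmethod
    def from_csv(cls, path) -> "BaselineIncidence":
        frame = pd.read_csv(path)
        return cls(frame["age"].to_numpy(), frame["rate_per_100py"].to_numpy())


def interpolate_baseline(
    table: BaselineIncidence, grid, extrapolate: bool = False
) -> np.ndarray:
    """Per-year hazard h_pop on ``grid`` by log-linear interpolation between knots.

    Below the first knot the hazard is held flat; above the last knot it is
    log-linearly extrapolated from the last two knots. Both require
    ``extrapolate=True``.
    """
    grid = np.asarray(grid, dtype=float)
    log_h = np.log(table.hazards)
    inside = (grid >= table.ages[0]) & (grid <= table.ages[-1])
    if not extrapolate and not inside.all():
        raise ValueError("grid extends beyond the incidence knots; pass extrapolate=True")
    out = np.interp(grid, table.ages, log_h)
    if extrapolate:
        if table.ages.size >= 2:
            slope = (log_h[-1] - log_h[-2]) / (table.ages[-1] - table.ages[-2])
        else:
            slope = 0.0
        above = grid > table.ages[-1]
        out[above] = log_h[-1] + slope * (grid[above] - table.ages[-1])
        # below the first knot: flat extension (np.interp already clamps)
    return np.exp(out)


class IncidenceCalibrator(BaseEstimator):
    """Solve the score-zero baseline hazard from population incidence.

    ``fit(baseline, dist)`` marches over an age grid (default step 0.25 y,
    from 5 y before the first knot, flat-extended, to ``max_age``) keeping
    per-support-point survival, and solves h0*(t) so the survivor-averaged
    hazard reproduces the published incidence exactly at every grid age.

    Fitted attributes: ``grid_`` (cell-edge ages), ``midpoints_`` (cell
    midpoints), ``h0_`` (per-year baseline hazard, constant on each cell,
    matched at midpoints — a second-order scheme), ``cumhaz0_`` (cumulative
    baseline hazard at cell edges), ``dist_``, ``diagnostics_``
    (reconstruction residual per cell, ~0 by construction).
    """

    def __init__(self, dt: float = 0.25, max_age: float = 100.0, lead_in: float = 5.0):
        self.dt = dt
        self.max_age = max_age
        self.lead_in = lead_in

    def fit(self, baseline: BaselineIncidence, dist: PHSDistribution):
        start = baseline.ages[0] - self.lead_in
        n_cells = int(np.ceil((self.max_age - start) / self.dt))
        edges = start + self.dt * np.arange(n_cells + 1)
        mids = edges[:-1] + self.dt / 2.0
        h_pop = interpolate_baseline(baseline, mids, extrapolate=True)
        if np.any(h_pop <= 0):
            raise ValueError("population hazard must be positive everywhere")

        s = np.clip(dist.support, -700.0, 50.0)
        rr = np.exp(s)
        if not np.isfinite(rr).all():
            raise ValueError("score distribution produces non-finite relative risks")
        w = dist.weights.copy()
        surv = np.ones_like(w)
        h0 = np.empty(n_cells)
        resid = np.empty(n_cells)
        # midpoint scheme, second order in dt: per cell solve the implicit
        # fixed point h * E[e^s | survivors at cell midpoint under h] = h_pop
        for j in range(n_cells):
            ws = w * surv
            mean_rr = (ws @ rr) / ws.sum()
            h = h_pop[j] / mean_rr
            for _ in range(50):
                s_half = ws * np.exp(-h * rr * (self.dt / 2.0))
                mean_rr = (s_half @ rr) / s_half.sum()
                h_new = h_pop[j] / mean_rr
                if abs(h_new - h) <= 1e-15 * max(1.0, h):
                    h = h_new
                    break
                h = h_new
            h0[j] = h
            resid[j] = h * mean_rr - h_pop[j]
            surv = surv * np.exp(-h * rr * self.dt)

        self.grid_ = edges
        self.midpoints_ = mids
        self.h0_ = h0
        self.h_pop_ = h_pop
        self.cumhaz0_ = np.concatenate([[0.0], np.cumsum(h0 * self.dt)])
        self.dist_ = dist
        self.baseline_ = baseline
        self.diagnostics_ = resid
        return self

    # -- model evaluation -------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "h0_"):
            raise ValueError("calibrator is not fitted")

    def cumhaz0(self, t) -> np.ndarray:
        """Baseline cumulative hazard H0*(t), linear within grid cells."""
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        if np.any(t < self.grid_[0] - 1e-9) or np.any(t > self.grid_[-1] + 1e-9):
            raise ValueError("age outside the calibrated grid")
        return np.interp(t, self.grid_, self.cumhaz0_)

    def annualized_incidence(self, s, age) -> np.ndarray:
        """One-year conditional onset probability, percent, for score ``s`` at ``age``.

        100 * (1 - exp(-e^s * [H0*(age+1) - H0*(age)])), capped at 100.
        """
        self._check_fitted()
        age = np.asarray(age, dtype=float)
        dH = self.cumhaz0(age + 1.0) - self.cumhaz0(age)
        val = 100.0 * (1.0 - np.exp(-np.exp(np.asarray(s, dtype=float)) * dH))
        return np.minimum(val, 100.0)

    def survival_curve(self, s, from_age: float, ages=None):
        """S(t | s, alive at from_age) on the grid (or at requested ages)."""
        self._check_fitted()
        if ages is None:
            ages = self.grid_[self.grid_ >= from_age]
        ages = np.asarray(ages, dtype=float)
        if from_age < self.grid_[0] or from_age > self.grid_[-1]:
            raise ValueError("from_age outside the calibrated grid")
        dH = self.cumhaz0(ages) - self.cumhaz0(from_age)
        return ages, np.exp(-np.exp(float(s)) * dH)

    def expected_onset_age(self, s, q: float = 0.5, from_age: float | None = None) -> float:
        """Smallest age at which cumulative onset risk reaches ``q``.

        Linearly interpolated between grid ages; ``inf`` if the risk level
        is never reached on the grid.
        """
        self._check_fitted()
        if not 0.0 < q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if from_age is None:
            from_age = float(self.grid_[0])
        ages, surv = self.survival_curve(s, from_age)
        risk = 1.0 - surv
        hit = np.flatnonzero(risk >= q)
        if hit.size == 0:
            return np.inf
        i = hit[0]
        if i == 0:
            return float(ages[0])
        # linear interpolation between the bracketing grid ages
        r0, r1 = risk[i - 1], risk[i]
        frac = (q - r0) / (r1 - r0)
        return float(ages[i - 1] + frac * (ages[i] - ages[i - 1]))

    def survivor_weights(self, dist: PHSDistribution, age) -> np.ndarray:
        """f(s_k) * S(age | s_k): mass of each support point among survivors."""
        self._check_fitted()
        rr = np.exp(np.clip(dist.support, -700.0, 50.0))
        return dist.weights * np.exp(-rr * self.cumhaz0(age))

    def incidence_table(
        self,
        percentiles=(1, 20, 80, 99),
        ages=(60, 65, 70, 75, 80, 85, 90, 95),
        apoe_strata: bool = False,
        mode: str = "fixed_quantile",
        dist: PHSDistribution | None = None,
    ) -> pd.DataFrame:
        """Annualized-incidence grid: rows = ages, columns = percentiles (+ APOE).

        ``mode="fixed_quantile"`` evaluates each column at the single score
        at that percentile of the reference distribution.
        ``mode="survivor_quantile"`` re-takes the percentile within the
        survivor-reweighted distribution at each age, so columns reflect
        the score stratum among still-unaffected individuals.
        APOE columns are survivor-weighted mean incidences within the
        carrier / non-carrier strata of the reference distribution.
        """
        self._check_fitted()
        dist = self.dist_ if dist is None else dist
        percentiles = list(percentiles)
        if any(not 0 < p < 100 for p in percentiles):
            raise ValueError("percentiles must lie in (0, 100)")
        ages = np.asarray(ages, dtype=float)
        idx = ages.astype(int) if np.allclose(ages, np.round(ages)) else ages
        out = pd.DataFrame(index=pd.Index(idx, name="age"))
        # baseline column: one-year probability implied by h_pop itself
        Hpop = np.concatenate([[0.0], np.cumsum(self.h_pop_ * self.dt)])
        dHpop = np.interp(ages + 1.0, self.grid_, Hpop) - np.interp(ages, self.grid_, Hpop)
        out["baseline"] = 100.0 * (1.0 - np.exp(-dHpop))
        for p in percentiles:
            if mode == "fixed_quantile":
                s_p = float(dist.quantile(p / 100.0))
                out[f"phs_p{p:g}"] = self.annualized_incidence(s_p, ages)
            elif mode == "survivor_quantile":
                cells = []
                for a in ages:
                    w = self.survivor_weights(dist, a)
                    cond = PHSDistribution(dist.support, w, dist.e4_carrier, dist.method)
                    s_p = float(cond.quantile(p / 100.0))
                    cells.append(float(self.annualized_incidence(s_p, a)))
                out[f"phs_p{p:g}"] = cells
            else:
                raise ValueError("mode must be 'fixed_quantile' or 'survivor_quantile'")
        if apoe_strata:
            for label, carrier in (("apoe_e4_carrier", True), ("apoe_e4_noncarrier", False)):
                sub = dist.condition_e4(carrier)
                cells = []
                for a in ages:
                    w = self.survivor_weights(sub, a)
                    inc = self.annualized_incidence(sub.support, a)
                    cells.append(float((w @ inc) / w.sum()))
                out[label] = cells
        return out


# -- thin functional wrappers -------------------------------------------------

def calibrate_baseline(
    baseline: BaselineIncidence,
    dist: PHSDistribution,
    dt: float = 0.25,
    max_age: float = 100.0,
) -> IncidenceCalibrator:
    """Fit an :class:`IncidenceCalibrator`; see the class docstring."""
    return IncidenceCalibrator(dt=dt, max_age=max_age).fit(baseline, dist)


def annualized_incidence(cal: IncidenceCalibrator, s, age):
    return cal.annualized_incidence(s, age)


def survival_curve(cal: IncidenceCalibrator, s, from_age: float, ages=None):
    return cal.survival_curve(s, from_age, ages=ages)


def expected_onset_age(cal: IncidenceCalibrator, s, q: float = 0.5, from_age=None):
    return cal.expected_onset_age(s, q=q, from_age=from_age)


def incidence_table(cal: IncidenceCalibrator, dist=None, percentiles=(1, 20, 80, 99),
                    ages=(60, 65, 70, 75, 80, 85, 90, 95), apoe_strata=False,
                    mode="fixed_quantile"):
    return cal.incidence_table(percentiles=percentiles, ages=ages,
                               apoe_strata=apoe_strata, mode=mode, dist=dist)
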