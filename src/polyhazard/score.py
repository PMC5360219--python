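"""Polygenic hazard score derivation.

The score for individual i is s_i = sum_j beta_j g_ij over a set of
selected risk variants (including two APOE allele-dosage terms), where the
beta_j are log hazard ratios from a joint Cox model. Derivation has three
stages: (1) prescreen GWAS summary statistics at p < 1e-5; (2) forward
stepwise Cox selection that at each step adds the candidate minimising a
Martingale-residual criterion of the refitted joint model (by default the
sum of squared deviance residuals, the variance-normalised transform of
the Martingale residuals), halting when no candidate improves it beyond
chance; (3) nonparametric bootstrap over individuals, refitting the fixed
selected model on each resample and averaging the coefficients.

A population reference distribution f(s) of the score is composed from
per-variant allele frequencies under Hardy-Weinberg and linkage
equilibrium (exact enumeration for small panels, Monte Carlo otherwise),
against which individual scores are expressed as percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import GenotypeMatrix
from .survival import ConvergenceWarning, FitError, SurvivalData, fit_cox, martingale_residuals

__all__ = [
    "prescreen",
    "SelectionTrace",
    "stepwise_select",
    "bootstrap_betas",
    "compute_phs",
    "PHSDistribution",
    "reference_distribution",
    "empirical_distribution",
    "percentile_of",
    "PolygenicHazardModel",
    "APOE_E2",
    "APOE_E4",
]

APOE_E2 = "apoe_e2"
APOE_E4 = "apoe_e4"
_SURVIVAL_COLS = ("entry_age", "exit_age", "event")


def prescreen(
    stats: pd.DataFrame,
    p_threshold: float = 1e-5,
    direction_filter: bool = False,
) -> list[str]:
    """Candidate variant ids with association p below threshold.

    ``stats`` needs columns ``snp`` and ``p``; with ``direction_filter``
    only risk-increasing effects (column ``beta`` > 0, log odds scale)
    pass. Order of the input is preserved, so the output is deterministic.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    if len(stats) == 0:
        return []
    p = stats["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    keep = p < p_threshold
    if direction_filter:
        keep &= stats["beta"].to_numpy(dtype=float) > 0
    return stats.loc[keep, "snp"].tolist()


@dataclass
class SelectionTrace:
    """Audit record of the forward stepwise search."""

    steps: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    halted_because: str = ""

    def criterion_path(self) -> list[float]:
        return [st["criterion_after"] for st in self.steps]


def _residual_criterion(frame, covariates, data, ties, kind) -> tuple[float, object]:
    """Residual-based model-fit criterion (smaller is better).

    ``deviance``: sum of squared deviance residuals, the variance-
    normalised transform of the Martingale residuals; its reduction when a
    covariate enters tracks the likelihood-ratio statistic, so genuinely
    predictive variants lower it. ``martingale_ssr``: the literal sum of
    squared Martingale residuals.
    """
    fit = fit_cox(frame, covariates, ties=ties, data=data)
    m = martingale_residuals(frame, fit, covariates)
    if kind == "martingale_ssr":
        return float(np.sum(m**2)), fit
    d = frame["event"].to_numpy(float)
    expected = np.maximum(d - m, 1e-300)  # model-expected event count, >= 0
    with np.errstate(invalid="ignore"):
        dev2 = -2.0 * (m + np.where(d > 0, d * np.log(expected), 0.0))
    return float(np.sum(dev2)), fit


def stepwise_select(
    candidates: list[str],
    cohort: pd.DataFrame,
    base_covariates: list[str],
    tol: float | str = "auto",
    ties: str = "efron",
    criterion: str = "deviance",
    alpha: float = 0.05,
    max_steps: int | None = None,
) -> tuple[SelectionTrace, list[str]]:
    """Forward selection by residual improvement.

    At each step every remaining candidate is added to the current joint
    Cox model (base covariates + previously selected variants); the
    candidate with the smallest residual criterion is accepted iff the
    relative criterion reduction exceeds ``tol``. With ``tol="auto"`` the
    per-step threshold is the Bonferroni-adjusted chi-square(1) quantile
    ``chi2.isf(alpha / n_remaining, 1)`` expressed relative to the current
    criterion — the reduction a pure-noise candidate would achieve with
    probability ``alpha``, so under the null selection halts immediately
    with probability ~``1 - alpha``. Candidates whose joint fit fails or
    does not converge are skipped with a warning and logged in the trace.
    """
    if criterion not in ("deviance", "martingale_ssr"):
        raise ValueError("criterion must be 'deviance' or 'martingale_ssr'")
    missing = [c for c in base_covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"base covariates absent from cohort: {missing}")
    trace = SelectionTrace()
    data = SurvivalData(
        cohort["entry_age"].to_numpy(float),
        cohort["exit_age"].to_numpy(float),
        cohort["event"].to_numpy(),
    )
    current, _ = _residual_criterion(cohort, list(base_covariates), data, ties, criterion)
    selected: list[str] = []
    pool = [c for c in candidates if c in cohort.columns]
    if len(pool) < len(candidates):
        absent = sorted(set(candidates) - set(pool))
        warnings.warn(f"candidates missing from cohort, ignored: {absent}")
    if not pool:
        trace.halted_because = "empty candidate pool"
        return trace, selected

    while pool:
        if max_steps is not None and len(selected) >= max_steps:
            trace.halted_because = f"max_steps {max_steps} reached"
            break
        best_id, best_val = None, np.inf
        for cand in pool:
            covs = list(base_covariates) + selected + [cand]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", ConvergenceWarning)
                    val, fit = _residual_criterion(cohort, covs, data, ties, criterion)
            except (FitError, ConvergenceWarning, np.linalg.LinAlgError) as exc:
                trace.skipped.append({"variant": cand, "reason": str(exc)})
                continue
            if val < best_val:
                best_id, best_val = cand, val
        if best_id is None:
            trace.halted_because = "no candidate produced a convergent fit"
            break
        if tol == "auto":
            from scipy import stats as _stats

            step_tol = _stats.chi2.isf(alpha / len(pool), 1) / max(current, 1e-300)
        else:
            step_tol = float(tol)
        rel_gain = (current - best_val) / current if current > 0 else 0.0
        if rel_gain <= step_tol:
            trace.halted_because = (
                f"relative criterion reduction {rel_gain:.2e} <= tol {step_tol:.2e}"
            )
            break
        trace.steps.append(
            {
                "step": len(selected) + 1,
                "variant": best_id,
                "criterion_before": current,
                "criterion_after": best_val,
            }
        )
        selected.append(best_id)
        pool.remove(best_id)
        current = best_val
    else:
        trace.halted_because = "candidate pool exhausted"
    return trace, selected


def bootstrap_betas(
    selected: list[str],
    cohort: pd.DataFrame,
    base_covariates: list[str],
    B: int = 1000,
    seed: int = 0,
    ties: str = "efron",
    score_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Bootstrap-averaged log hazard ratios for the fixed selected model.

    The selected model (base covariates + selected variants) is refit on
    ``B`` resamples of individuals drawn with replacement; ``beta`` is the
    mean over convergent resamples and ``se`` their standard deviation.
    Conditional p-values come from the full-data joint fit's Wald tests.
    Rows are returned for the selected variants plus any score covariates
    (APOE dosage terms by default when present in the base covariates).

    Raises if fewer than half the resamples converge.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    covs = list(base_covariates) + list(selected)
    full = fit_cox(cohort, covs, ties=ties)
    if not full.converged:
        raise FitError("selected model does not converge on the full cohort")
    if score_covariates is None:
        score_covariates = [c for c in (APOE_E2, APOE_E4) if c in base_covariates]
    rows = list(score_covariates) + list(selected)

    rng = np.random.default_rng(seed)
    n = len(cohort)
    draws = np.full((B, len(rows)), np.nan)
    n_ok = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                fit = fit_cox(sample, covs, ties=ties)
        except (FitError, ConvergenceWarning, np.linalg.LinAlgError):
            continue
        draws[n_ok] = fit.params[rows].to_numpy()
        n_ok += 1
    if n_ok < max(1, B // 2):
        raise FitError(f"only {n_ok}/{B} bootstrap resamples converged")
    draws = draws[:n_ok]
    table = pd.DataFrame(
        {
            "variant": rows,
            "beta": draws.mean(axis=0),
            "se": draws.std(axis=0, ddof=1) if n_ok > 1 else np.zeros(len(rows)),
            "neg_log10_p": full.neg_log10_p[rows].to_numpy(),
        }
    )
    table["full_fit_beta"] = full.params[rows].to_numpy()
    return table


def compute_phs(
    betas: pd.DataFrame,
    genotypes: GenotypeMatrix | pd.DataFrame,
    apoe: pd.DataFrame | None = None,
    freqs: dict[str, float] | None = None,
) -> pd.Series:
    """Score individuals: s_i = sum_j beta_j g_ij over the weight-table rows.

    APOE rows (``APOE_e2``/``APOE_e4``) are matched against the ``apoe``
    dosage frame (or columns of a DataFrame genotype input). Effect-allele
    mismatches are resolved by dosage flip g -> 2 - g when the genotype's
    other allele matches; otherwise an error names the variant. Missing
    dosages are mean-imputed as 2f from ``freqs``.
    """
    if isinstance(genotypes, GenotypeMatrix):
        dosage = genotypes.to_frame()
        eff = dict(zip(genotypes.variants, genotypes.effect_alleles))
        oth = dict(zip(genotypes.variants, genotypes.other_alleles))
    else:
        dosage = genotypes
        eff = oth = None
    if apoe is not None:
        dosage = dosage.join(apoe) if not set(apoe.columns) <= set(dosage.columns) else dosage

    s = pd.Series(0.0, index=dosage.index, name="phs")
    for _, row in betas.iterrows():
        vid, beta = row["variant"], float(row["beta"])
        if vid not in dosage.columns:
            if freqs is not None and vid in freqs:
                g = pd.Series(2.0 * freqs[vid], index=dosage.index)
            else:
                raise KeyError(
                    f"variant {vid!r} absent from genotypes and no frequency supplied"
                )
        else:
            g = dosage[vid].astype(float)
            want = row.get("effect_allele")
            if eff is not None and isinstance(want, str) and want:
                have, other = eff.get(vid), oth.get(vid)
                if have != want:
                    if other == want:
                        g = 2.0 - g
                    else:
                        raise ValueError(
                            f"unresolvable effect-allele mismatch for {vid!r}: "
                            f"weights use {want!r}, genotypes carry {have}/{other}"
                        )
            if g.isna().any():
                if freqs is None or vid not in freqs:
                    raise KeyError(
                        f"missing dosages for {vid!r} and no frequency for imputation"
                    )
                g = g.fillna(2.0 * freqs[vid])
        s = s + beta * g
    return s


class PHSDistribution:
    """Population distribution f(s) of the polygenic hazard score.

    Represented as a weighted support (exact enumeration) or an equally
    weighted sample (Monte Carlo / empirical). Scores are centered so the
    population mean is zero; ``mean_shift`` stores the uncentered mean.
    An e4-carrier flag per support point allows conditioning on APOE
    carrier status without leaving the common centered scale.
    """

    def __init__(self, support, weights, e4_carrier, method, mean_shift=0.0):
        support = np.asarray(support, dtype=float)
        weights = np.asarray(weights, dtype=float)
        order = np.argsort(support, kind="stable")
        self.support = support[order]
        self.weights = weights[order] / weights.sum()
        self.e4_carrier = np.asarray(e4_carrier, dtype=bool)[order]
        self.method = method
        self.mean_shift = float(mean_shift)
        self._cum = np.cumsum(self.weights)

    @property
    def mean(self) -> float:
        return float(np.sum(self.support * self.weights))

    def cdf(self, s) -> np.ndarray:
        """P(S <= s), with midpoint convention at atoms."""
        s = np.asarray(s, dtype=float)
        hi = np.searchsorted(self.support, s, side="right")
        lo = np.searchsorted(self.support, s, side="left")
        cum = np.concatenate([[0.0], self._cum])
        return (cum[hi] + cum[lo]) / 2.0

    def quantile(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        idx = np.minimum(np.searchsorted(self._cum, q, side="left"), self.support.size - 1)
        return self.support[idx]

    def condition_e4(self, carrier: bool) -> "PHSDistribution":
        """Distribution restricted to e4 carriers (or non-carriers), same scale."""
        mask = self.e4_carrier if carrier else ~self.e4_carrier
        if not mask.any():
            raise ValueError("no support points in the requested APOE stratum")
        return PHSDistribution(
            self.support[mask], self.weights[mask], self.e4_carrier[mask],
            self.method, self.mean_shift,
        )


def _apoe_genotype_table(apoe_freqs):
    """Ordered allele pairs of the 3-allele APOE locus -> (prob, e2 dosage, e4 dosage)."""
    f = np.asarray(apoe_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValueError("APOE allele frequencies must be nonnegative and sum to 1")
    probs, e2s, e4s = [], [], []
    for a in range(3):
        for b in range(3):
            probs.append(f[a] * f[b])
            e2s.append(float((a == 0) + (b == 0)))
            e4s.append(float((a == 2) + (b == 2)))
    return np.array(probs), np.array(e2s), np.array(e4s)


def reference_distribution(
    betas: pd.DataFrame,
    freqs: dict[str, float],
    apoe_freqs: tuple[float, float, float] | None = None,
    method: str = "monte_carlo",
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> PHSDistribution:
    """Compose f(s) from per-variant frequencies under HWE and linkage equilibrium.

    SNP dosages are Binomial(2, f_j); the APOE genotype is multinomial over
    ordered allele pairs, contributing ``beta_e2 * e2 + beta_e4 * e4``.
    ``method="exact"`` enumerates all dosage combinations (at most 12 SNP
    variants); ``"monte_carlo"`` samples ``n_mc`` individuals. The returned
    distribution is centered at the population mean.
    """
    snp_rows = betas.loc[~betas["variant"].isin([APOE_E2, APOE_E4])]
    missing = [v for v in snp_rows["variant"] if v not in freqs]
    if missing:
        raise KeyError(f"no allele frequency for variants: {missing}")
    f = np.array([freqs[v] for v in snp_rows["variant"]], dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    b = snp_rows["beta"].to_numpy(dtype=float)
    b_e2 = float(betas.loc[betas["variant"] == APOE_E2, "beta"].sum())
    b_e4 = float(betas.loc[betas["variant"] == APOE_E4, "beta"].sum())
    has_apoe = betas["variant"].isin([APOE_E2, APOE_E4]).any()
    if has_apoe and apoe_freqs is None:
        raise ValueError("weight table has APOE rows; apoe_freqs is required")

    mean = float(np.sum(2.0 * f * b))
    if has_apoe:
        f2, _, f4 = apoe_freqs
        mean += 2.0 * f2 * b_e2 + 2.0 * f4 * b_e4

    if method == "exact":
        if len(b) > 12:
            raise ValueError(
                f"exact enumeration limited to 12 variants (got {len(b)}); "
                "use method='monte_carlo'"
            )
        support = np.zeros(1)
        weights = np.ones(1)
        for fj, bj in zip(f, b):
            pg = np.array([(1 - fj) ** 2, 2 * fj * (1 - fj), fj**2])
            vals = bj * np.array([0.0, 1.0, 2.0])
            support = (support[:, None] + vals[None, :]).ravel()
            weights = (weights[:, None] * pg[None, :]).ravel()
        if has_apoe:
            pa, e2s, e4s = _apoe_genotype_table(apoe_freqs)
            contrib = b_e2 * e2s + b_e4 * e4s
            carrier = e4s > 0
            support = (support[:, None] + contrib[None, :]).ravel()
            weights = (weights[:, None] * pa[None, :]).ravel()
            e4_flag = np.broadcast_to(carrier, (weights.size // 9, 9)).ravel()
        else:
            e4_flag = np.zeros(support.size, dtype=bool)
        return PHSDistribution(support - mean, weights, e4_flag, "exact_enumeration", mean)

    if method != "monte_carlo":
        raise ValueError("method must be 'exact' or 'monte_carlo'")
    rng = np.random.default_rng(seed)
    s = np.zeros(n_mc)
    # column-wise sampling keeps peak memory at O(n_mc)
    for fj, bj in zip(f, b):
        s += bj * rng.binomial(2, fj, size=n_mc)
    if has_apoe:
        pa, e2s, e4s = _apoe_genotype_table(apoe_freqs)
        g = rng.choice(9, size=n_mc, p=pa)
        s += b_e2 * e2s[g] + b_e4 * e4s[g]
        e4_flag = e4s[g] > 0
    else:
        e4_flag = np.zeros(n_mc, dtype=bool)
    return PHSDistribution(s - mean, np.ones(n_mc), e4_flag, "monte_carlo", mean)


def empirical_distribution(scores, e4_carrier=None, center: bool = False) -> PHSDistribution:
    """Reference distribution built from a cohort's observed scores."""
    scores = np.asarray(scores, dtype=float)
    if e4_carrier is None:
        e4_carrier = np.zeros(scores.size, dtype=bool)
    shift = scores.mean() if center else 0.0
    return PHSDistribution(
        scores - shift, np.ones(scores.size), e4_carrier, "empirical", shift
    )


def percentile_of(s, dist: PHSDistribution) -> np.ndarray:
    """Population percentile 100 * CDF(s), midpoint convention at ties."""
    return 100.0 * dist.cdf(s)


class PolygenicHazardModel(BaseEstimator):
    """Scikit-learn style estimator wrapping the three PHS derivation stages.

    ``fit`` runs prescreen (optional, when summary statistics are given),
    stepwise Cox selection and bootstrap averaging on a cohort frame;
    ``transform``/``predict`` scores new individuals with the frozen weight
    table.

    Parameters
    ----------
    p_threshold : GWAS prescreen threshold (default 1e-5).
    direction_filter : restrict the prescreen to risk-increasing effects.
    tol : relative Martingale-residual improvement required to accept a step.
    B : bootstrap resamples for model averaging (default 1000).
    ties : 'efron' or 'breslow'.
    base_covariates : always-included adjusters (sex, APOE dosages, PCs).
    seed : RNG seed for the bootstrap.
    """

    def __init__(
        self,
        p_threshold: float = 1e-5,
        direction_filter: bool = False,
        tol: float | str = "auto",
        criterion: str = "deviance",
        B: int = 1000,
        ties: str = "efron",
        base_covariates: tuple = ("sex", APOE_E2, APOE_E4, "pc1", "pc2", "pc3", "pc4", "pc5"),
        seed: int = 0,
    ):
        self.p_threshold = p_threshold
        self.direction_filter = direction_filter
        self.tol = tol
        self.criterion = criterion
        self.B = B
        self.ties = ties
        self.base_covariates = base_covariates
        self.seed = seed

    def fit(self, cohort: pd.DataFrame, summary_stats: pd.DataFrame | None = None,
            candidates: list[str] | None = None):
        if candidates is None:
            if summary_stats is None:
                raise ValueError("provide either summary_stats or candidates")
            candidates = prescreen(summary_stats, self.p_threshold, self.direction_filter)
        self.candidates_ = list(candidates)
        base = [c for c in self.base_covariates if c in cohort.columns]
        absent = [c for c in self.base_covariates if c not in cohort.columns]
        if absent:
            warnings.warn(f"base covariates absent from cohort, dropped: {absent}")
        self.trace_, self.selected_ = stepwise_select(
            self.candidates_, cohort, base, tol=self.tol, ties=self.ties,
            criterion=self.criterion,
        )
        self.beta_table_ = bootstrap_betas(
            self.selected_, cohort, base, B=self.B, seed=self.seed, ties=self.ties
        )
        self.n_features_in_ = len(self.candidates_)
        return self

    def transform(self, genotypes, apoe=None, freqs=None) -> pd.Series:
        if not hasattr(self, "beta_table_"):
            raise FitError("model is not fitted")
        return compute_phs(self.beta_table_, genotypes, apoe=apoe, freqs=freqs)

    predict = transform

    def reference_distribution(self, freqs, apoe_freqs=None, method="monte_carlo",
                               n_mc=1_000_000, seed=None) -> PHSDistribution:
        if not hasattr(self, "beta_table_"):
            raise FitError("model is not fitted")
        return reference_distribution(
            self.beta_table_, freqs, apoe_freqs=apoe_freqs, method=method,
            n_mc=n_mc, seed=self.seed if seed is None else seed,
        )
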