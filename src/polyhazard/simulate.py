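"""Synthetic genotype and age-of-onset cohorts.

Generates data with exactly the statistical structure the polygenic-hazard
framework assumes: independent SNP dosages under Hardy-Weinberg and linkage
equilibrium, a three-allele APOE-like locus (e2/e3/e4) yielding two dosage
covariates, a Gompertz baseline hazard on the age axis, proportional
polygenic effects, non-informative right censoring at a last-visit age, and
optional case-control ascertainment.

Defaults: the Gompertz baseline is anchored to published US population
incidence of Alzheimer disease, 0.08 per 100 person-years at age 60 rising
to 12.10 at age 95, giving rate 8e-4/yr at the age-60 reference and slope
ln(12.10/0.08)/35 ~ 0.1434/yr. European APOE allele frequencies
(e2, e3, e4) = (0.08, 0.78, 0.14) and the published APOE log hazard ratios
(-0.47 for e2, 1.03 for e4) are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "SimConfig",
    "GenotypeMatrix",
    "AscertainmentError",
    "simulate_genotypes",
    "simulate_apoe",
    "simulate_onset",
    "simulate_cohort",
    "ascertain",
    "DEFAULT_GOMPERTZ_RATE",
    "DEFAULT_GOMPERTZ_SLOPE",
    "REFERENCE_AGE",
]

REFERENCE_AGE = 60.0
DEFAULT_GOMPERTZ_RATE = 8e-4  # hazard per year at age 60 (0.08 per 100 PY)
DEFAULT_GOMPERTZ_SLOPE = float(np.log(12.10 / 0.08) / 35.0)  # per-year log slope


class AscertainmentError(ValueError):
    """Requested case/control counts cannot be met by the simulated pool."""


@dataclass(frozen=True)
class Variant:
    id: str
    freq: float
    beta: float


@dataclass
class SimConfig:
    """Stated world of the simulator; validated on construction."""

    n_individuals: int
    variants: list[Variant]
    gompertz_rate: float = DEFAULT_GOMPERTZ_RATE
    gompertz_slope: float = DEFAULT_GOMPERTZ_SLOPE
    followup_window: tuple[float, float] = (70.0, 95.0)
    study_design: str = "cohort"
    n_cases: int | None = None
    n_controls: int | None = None
    apoe_freqs: tuple[float, float, float] = (0.08, 0.78, 0.14)
    beta_e2: float = -0.47
    beta_e4: float = 1.03
    entry_age: float = REFERENCE_AGE
    min_age: float = REFERENCE_AGE
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for v in self.variants:
            if not 0.0 <= v.freq <= 1.0:
                raise ValueError(f"allele frequency of {v.id} outside [0,1]")
        if self.gompertz_rate <= 0 or self.gompertz_slope <= 0:
            raise ValueError("Gompertz rate and slope must be positive")
        lo, hi = self.followup_window
        if not (hi > lo >= REFERENCE_AGE):
            raise ValueError("followup window must satisfy max > min >= 60")
        if self.study_design not in ("cohort", "case_control"):
            raise ValueError("study_design must be 'cohort' or 'case_control'")
        if self.study_design == "case_control" and (
            self.n_cases is None or self.n_controls is None
        ):
            raise ValueError("case_control design requires n_cases and n_controls")
        if abs(sum(self.apoe_freqs) - 1.0) > 1e-9:
            raise ValueError("APOE allele frequencies must sum to 1")

    @property
    def betas(self) -> np.ndarray:
        return np.array([v.beta for v in self.variants])

    @property
    def freqs(self) -> np.ndarray:
        return np.array([v.freq for v in self.variants])

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]


@dataclass
class GenotypeMatrix:
    """Effect-allele dosage matrix (individuals x variants), NaN = missing."""

    individuals: list[str]
    variants: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError("dosage matrix dimensions inconsistent with id lists")
        valid = np.isnan(self.dosages) | (
            (self.dosages >= 0.0) & (self.dosages <= 2.0)
        )
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicated variant ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individuals, columns=self.variants)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw dosages g_ij ~ Binomial(2, f_j), independent across variants and people."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n_individuals, len(config.variants)
    dosages = rng.binomial(2, config.freqs[None, :], size=(n, k)).astype(float)
    ids = [f"ind{i:06d}" for i in range(n)]
    return GenotypeMatrix(
        individuals=ids,
        variants=config.variant_ids,
        effect_alleles=["A"] * k,
        other_alleles=["G"] * k,
        dosages=dosages,
    )


def simulate_apoe(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two alleles per person from the (e2, e3, e4) frequencies; returns e2/e4 dosages.

    Sampling a full 3-allele genotype guarantees e2 + e4 dosage <= 2.
    """
    alleles = rng.choice(3, size=(config.n_individuals, 2), p=list(config.apoe_freqs))
    e2 = (alleles == 0).sum(axis=1).astype(float)
    e4 = (alleles == 2).sum(axis=1).astype(float)
    return e2, e4


def gompertz_inverse(u_exp: np.ndarray, lam: float, gamma: float, rel_risk: np.ndarray) -> np.ndarray:
    """Onset age solving H(t) * rel_risk = E for E ~ Exp(1), H Gompertz from age 60."""
    return REFERENCE_AGE + np.log1p(gamma * u_exp / (lam * rel_risk)) / gamma


def population_mean_score(config: SimConfig) -> float:
    """E[s] under HWE/LE: sum_j 2 f_j beta_j plus the APOE expectation."""
    f2, _, f4 = config.apoe_freqs
    return float(
        np.sum(2.0 * config.freqs * config.betas)
        + 2.0 * f2 * config.beta_e2
        + 2.0 * f4 * config.beta_e4
    )


def simulate_onset(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw onset ages from h(t|s) = lambda e^{gamma (t-60)} e^s and censor.

    The score s = sum_j beta_j g_ij + APOE terms is centered at its
    population mean, so lambda is the baseline hazard of the mean genetic
    profile. Censoring ages are uniform on the follow-up window,
    independent of genotype. Returns a cohort table with dosage columns,
    sex, APOE dosages, five null principal components, entry/exit ages,
    the event flag and the true (centered) score.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.gompertz_rate <= 0 or config.gompertz_slope <= 0:
        raise ValueError("Gompertz rate and slope must be positive")
    n = len(genotypes.individuals)
    e2, e4 = simulate_apoe(config, rng)
    s = (
        genotypes.dosages @ config.betas
        + config.beta_e2 * e2
        + config.beta_e4 * e4
        - population_mean_score(config)
    )
    u = rng.exponential(size=n)
    onset = gompertz_inverse(u, config.gompertz_rate, config.gompertz_slope, np.exp(s))
    censor = rng.uniform(*config.followup_window, size=n)
    event = onset <= censor
    exit_age = np.where(event, onset, censor)

    frame = genotypes.to_frame().copy()
    frame["sex"] = rng.binomial(1, 0.55, size=n).astype(float)
    frame["apoe_e2"] = e2
    frame["apoe_e4"] = e4
    for j in range(1, 6):
        frame[f"pc{j}"] = rng.normal(size=n)
    frame["entry_age"] = config.entry_age
    frame["exit_age"] = exit_age
    frame["event"] = event.astype(int)
    frame["true_score"] = s
    frame.index.name = "individual"
    return frame


def ascertain(cohort: pd.DataFrame, config: SimConfig,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Apply the minimum-age exclusion and, in case-control mode, outcome sampling.

    Rows whose exit age (onset for cases, last visit for controls) falls
    below ``config.min_age`` are removed. In ``case_control`` mode exactly
    ``n_cases`` event rows and ``n_controls`` censored rows are drawn
    without replacement.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    pool = cohort.loc[cohort["exit_age"] >= config.min_age]
    if config.study_design == "cohort":
        if len(pool) == 0:
            raise AscertainmentError("no individuals survive the minimum-age filter")
        return pool.copy()
    cases = pool.loc[pool["event"] == 1]
    controls = pool.loc[pool["event"] == 0]
    if len(cases) < config.n_cases or len(controls) < config.n_controls:
        raise AscertainmentError(
            f"requested {config.n_cases} cases / {config.n_controls} controls, "
            f"pool holds {len(cases)} / {len(controls)}"
        )
    take_cases = rng.choice(len(cases), size=config.n_cases, replace=False)
    take_controls = rng.choice(len(controls), size=config.n_controls, replace=False)
    out = pd.concat([cases.iloc[np.sort(take_cases)], controls.iloc[np.sort(take_controls)]])
    return out


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Genotypes -> onsets -> ascertainment, all from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    cohort = simulate_onset(genotypes, config, rng)
    cohort = ascertain(cohort, config, rng)
    return cohort, genotypes
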