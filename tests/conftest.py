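import numpy as np
import pandas as pd
import pytest

from polyhazard.simulate import SimConfig, Variant, simulate_cohort


@pytest.fixture
def toy_records():
    """Four subjects, three events at distinct times, no truncation."""
    return pd.DataFrame(
        {
            "entry_age": [0.0, 0.0, 0.0, 0.0],
            "exit_age": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )


def grid_search_beta(frame, covariate="x", lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximizer of the (Breslow) partial likelihood, one covariate.

    Independent oracle: enumerates the likelihood over a grid; valid for
    distinct event times (no ties) without truncation.
    """
    x = frame[covariate].to_numpy(float)
    t = frame["exit_age"].to_numpy(float)
    d = frame["event"].to_numpy(bool)
    order = np.argsort(t)
    x, d = x[order], d[order]
    betas = np.arange(lo, hi + step, step)
    r = np.exp(betas[:, None] * x[None, :])  # (B, n)
    # risk set at sorted position i is subjects i..n-1
    suffix = np.cumsum(r[:, ::-1], axis=1)[:, ::-1]
    ll = (betas[:, None] * x[None, :] - np.log(suffix))[:, d].sum(axis=1)
    return betas[int(np.argmax(ll))]


def make_cohort(n=3000, betas=(0.5,), freqs=(0.3,), seed=0, design="cohort",
                n_cases=None, n_controls=None, followup=(70.0, 95.0)):
    variants = [Variant(f"snp{j}", f, b) for j, (f, b) in enumerate(zip(freqs, betas))]
    cfg = SimConfig(
        n_individuals=n, variants=variants, seed=seed, study_design=design,
        n_cases=n_cases, n_controls=n_controls, followup_window=followup,
    )
    cohort, geno = simulate_cohort(cfg)
    return cohort, geno, cfg


BASE_COVARIATES = ["sex", "apoe_e2", "apoe_e4", "pc1", "pc2", "pc3", "pc4", "pc5"]
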