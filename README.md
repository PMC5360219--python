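# polyhazard

Polygenic hazard scores (PHS) for age-dependent disease risk.

Most polygenic risk scores answer a case-control question — "how likely is
this person to be a case?" — which ignores the strong age dependence of
late-onset diseases such as Alzheimer disease. `polyhazard` instead works
in a survival framework: it derives a score whose weights are log hazard
ratios from a Cox model on the age axis, and then converts that score,
together with published population incidence, into quantities a clinician
or epidemiologist can use directly — annualized incidence by age and score
percentile, survivor curves, and expected ages of onset. It is written for
statistical geneticists and epidemiologists building or evaluating
absolute-risk models from GWAS results.

## The model

For an individual with effect-allele dosages `g_j` the score is

    s = Σ_j β_j g_j   (including APOE ε2/ε4 allele-dosage terms)

and onset follows a proportional-hazards law on the age axis,

    h(t | s) = h0*(t) · e^s.

Weights come from a three-stage derivation on a training cohort with ages
of onset / last visit: (1) prescreen GWAS summary statistics at p < 1e-5;
(2) forward stepwise Cox selection (controlling sex, APOE dosages and five
principal components), each step accepting the candidate that most
improves a Martingale-residual criterion; (3) 1000-fold bootstrap over
individuals, averaging the refitted coefficients of the fixed selected
model. Because case-control sampling distorts the baseline, `h0*(t)` is
solved from published population incidence `h_pop(t)`: with `f(s)` the
population score distribution (from allele frequencies under
Hardy-Weinberg and linkage equilibrium),

    h_pop(t) = h0*(t) · E[ e^s | T ≥ t ]

is inverted age by age, the expectation running over survivors so the
depletion of high-risk profiles with age is accounted for exactly.
See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Build the population risk tables from the packaged 33-term Alzheimer
weight table (31 SNPs + APOE ε2/ε4) and packaged US incidence rates. The
published table has no allele frequencies, so this example draws a
synthetic frequency panel — with real data, pass your population's panel.

```python
import numpy as np
from polyhazard import IncidenceCalibrator, reference_distribution
from polyhazard.datasets import load_ad_weights, load_us_incidence

weights = load_ad_weights()
rng = np.random.default_rng(2024)
snps = weights.variant[weights.variant.str.startswith("rs")]
freqs = dict(zip(snps, rng.uniform(0.05, 0.95, len(snps))))

dist = reference_distribution(weights, freqs,
                              apoe_freqs=(0.08, 0.78, 0.14),
                              n_mc=200_000, seed=7)
cal = IncidenceCalibrator().fit(load_us_incidence(), dist)
print(cal.incidence_table(percentiles=(1, 20, 80, 99), apoe_strata=True).round(2))
```

```
     baseline  phs_p1  phs_p20  phs_p80  phs_p99  apoe_e4_carrier  apoe_e4_noncarrier
age
60       0.09    0.01     0.03     0.12     0.46             0.18                0.05
65       0.18    0.03     0.07     0.25     0.98             0.38                0.11
70       0.38    0.06     0.15     0.52     2.03             0.78                0.24
75       0.76    0.13     0.31     1.08     4.19             1.57                0.50
80       1.55    0.27     0.67     2.31     8.79             3.17                1.05
85       3.14    0.60     1.49     5.11    18.64             6.37                2.28
90       6.40    1.45     3.56    11.88    39.21            12.76                5.13
95      12.98    3.79     9.14    28.44    73.21            24.68               11.64
```

Each cell is an annualized incidence rate: the percent of individuals of
that age and score stratum, still disease-free, expected to develop the
disease within one year (so the `baseline` column slightly exceeds the
input knot rates — 0.09 vs 0.08 at 60 — because rates rise within the
year). A 65-year-old at the 80th percentile (s = 0.62) faces 0.25 per 100
person-years now, rising to 1.08 at 75, 5.11 at 85 and 28.4 at 95; the
ε4-carrier column is roughly 3× the non-carrier column at every age.
Expected onset ages follow from the same calibration:

```python
cal.expected_onset_age(float(dist.quantile(0.99)), q=0.5)   # 81.4 y
cal.expected_onset_age(float(dist.quantile(0.50)), q=0.5)   # 94.0 y
```

Training a score from scratch and validating it on a held-out cohort uses
the estimator API (`PolygenicHazardModel().fit(cohort, summary_stats=...)
.transform(genotypes)`) or the CLI:

```bash
polyhazard simulate  --config sim.yaml --out-dir data/
polyhazard prescreen --summary-stats stats.tsv --out candidates.txt
polyhazard train     --genotypes data/genotypes.tsv --phenotypes data/phenotypes.csv \
                     --candidates candidates.txt --out betas.tsv
polyhazard predict   --betas betas.tsv --frequencies freqs.tsv \
                     --baseline incidence.csv --out table.csv
polyhazard run       --config pipeline.yaml     # full pipeline + manifest
```

## Acceptance script

`scripts/acceptance.py` exercises the whole framework from scratch with no
external inputs: it simulates a training cohort, derives the score
(prescreen → stepwise selection → bootstrap), builds the reference
distribution, calibrates to the packaged population incidence, and runs
the replication analyses (onset-age correlation, percentile stratification,
decile hazard ratio) on an independent simulated cohort, printing a
summary and writing the target report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
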