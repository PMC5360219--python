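"""Packaged reference tables.

Two small published tables ship with the package: the 33-term weight table
of a published Alzheimer-disease polygenic hazard score (31 GWAS SNPs plus
the APOE e2/e4 allele-dosage terms, log hazard ratios from a joint Cox
model on a large case-control training cohort) and US community-sampled
population incidence of Alzheimer disease by age (percent per year).

The published weight table prints no effect alleles or allele frequencies,
so scoring real genotypes with it requires a user-supplied allele map, and
reference distributions built from it require an external frequency panel.
"""

from importlib import resources as _resources

import pandas as pd

from .calibrate import BaselineIncidence

__all__ = ["load_ad_weights", "load_us_incidence"]


def _path(name: str):
    return _resources.files("polyhazard.resources").joinpath(name)


def load_ad_weights() -> pd.DataFrame:
    """33-row weight table: variant, chromosome, position, gene, beta, neg_log10_p."""
    with _resources.as_file(_path("ad_phs_weights.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_us_incidence() -> BaselineIncidence:
    """US population Alzheimer incidence, per 100 person-years, ages 60-95."""
    with _resources.as_file(_path("us_ad_incidence.csv")) as p:
        return BaselineIncidence.from_csv(p)
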