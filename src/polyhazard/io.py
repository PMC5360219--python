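"""File formats and configuration.

Dosage TSV dialect: tab-separated, individuals as rows (first column
``individual``), variants as header columns, ``.`` for missing. VCF input
is read with cyvcf2 when available (GT fields converted to ALT-allele
dosage); a plain-text fallback parser handles uncompressed VCFs so the
package works without it. Phenotype CSV: one row per individual with
columns ``individual, sex, apoe_e2, apoe_e4, pc1..pc5, onset_age,
last_visit_age`` and optional ``entry_age``; the event flag is inferred
from onset presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GenotypeMatrix

logger = logging.getLogger("polyhazard")

__all__ = [
    "read_genotypes",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_summary_stats",
    "read_summary_stats",
    "read_frequencies",
    "RunConfig",
]

MISSING = "."
PHENO_REQUIRED = ["individual", "sex", "apoe_e2", "apoe_e4",
                  "pc1", "pc2", "pc3", "pc4", "pc5", "last_visit_age"]


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    frame = genotypes.to_frame()
    out = frame.map(lambda v: MISSING if np.isnan(v) else f"{v:g}")
    out.index.name = "individual"
    out.to_csv(path, sep="\t")


def _read_dosage_tsv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], dtype=str)
    try:
        dosages = frame.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"malformed dosage value in {path}: {exc}") from exc
    variants = list(frame.columns)
    if len(set(variants)) != len(variants):
        raise ValueError("duplicated variant ids in dosage TSV header")
    return GenotypeMatrix(
        individuals=[str(i) for i in frame.index],
        variants=variants,
        effect_alleles=[""] * len(variants),
        other_alleles=[""] * len(variants),
        dosages=dosages,
    )


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    variants, eff, oth, rows = [], [], [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in variants:
            raise ValueError(f"duplicated variant id {vid!r} in VCF")
        variants.append(vid)
        eff.append(rec.ALT[0] if rec.ALT else "")
        oth.append(rec.REF)
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        lut = np.array([0.0, 1.0, np.nan, 2.0])
        rows.append(lut[np.asarray(rec.gt_types)])
    dosages = np.array(rows).T if rows else np.empty((len(individuals), 0))
    return GenotypeMatrix(individuals, variants, eff, oth, dosages)


def _read_vcf_text(path) -> GenotypeMatrix:
    """Minimal parser for uncompressed VCF with GT fields (fallback path)."""
    individuals: list[str] = []
    variants, eff, oth, rows = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                individuals = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"malformed VCF line {lineno}: too few columns")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            vid = vid if vid not in ("", ".") else f"{chrom}:{pos}"
            if vid in variants:
                raise ValueError(f"duplicated variant id {vid!r} at line {lineno}")
            fmt = parts[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError as exc:
                raise ValueError(f"no GT field at line {lineno}") from exc
            dos = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) > 0 for a in alleles)))
            variants.append(vid)
            eff.append(alt.split(",")[0])
            oth.append(ref)
            rows.append(dos)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(individuals), 0))
    return GenotypeMatrix(individuals, variants, eff, oth, dosages)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a dosage TSV or a VCF."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz") else "dosage_tsv"
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "dosage_tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    logger.info("read %d individuals x %d variants from %s",
                len(gm.individuals), len(gm.variants), path)
    return gm


def read_phenotypes(path, min_age: float = 60.0) -> pd.DataFrame:
    """Phenotype/covariate CSV -> cohort frame with entry/exit ages and event flag.

    Event = onset age present; exit = onset age for cases, last-visit age
    for controls. Rows with exit below ``min_age`` are excluded (count
    logged); rows violating exit > entry or event not in {0,1} raise with
    row identifiers.
    """
    frame = pd.read_csv(path)
    for col in PHENO_REQUIRED:
        if col not in frame.columns:
            raise ValueError(f"phenotype file missing required column {col!r}")
    frame = frame.set_index("individual")
    onset = frame["onset_age"] if "onset_age" in frame.columns else pd.Series(
        np.nan, index=frame.index
    )
    frame["event"] = onset.notna().astype(int)
    if "event_flag" in frame.columns:  # explicit flag wins, validated below
        frame["event"] = frame["event_flag"]
    bad = ~frame["event"].isin([0, 1])
    if bad.any():
        raise ValueError(f"invalid event flags for rows: {list(frame.index[bad])}")
    frame["exit_age"] = np.where(frame["event"] == 1, onset, frame["last_visit_age"])
    if "entry_age" not in frame.columns:
        frame["entry_age"] = min_age
    if (frame[["exit_age", "entry_age", "last_visit_age"]] < 0).any().any():
        raise ValueError("negative ages in phenotype file")
    n0 = len(frame)
    frame = frame.loc[frame["exit_age"] >= min_age]
    if n0 - len(frame):
        logger.info("excluded %d rows with exit age < %g", n0 - len(frame), min_age)
    bad = frame["exit_age"] <= frame["entry_age"]
    if bad.any():
        raise ValueError(f"exit age <= entry age for rows: {list(frame.index[bad])}")
    return frame


def write_summary_stats(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    """Summary-statistics TSV with header (snp, chr, pos, a1, a2, beta, p)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("snp", "p"):
        if col not in frame.columns:
            raise ValueError(f"summary statistics missing column {col!r}")
    p = frame["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("summary-statistics p-values must lie in (0, 1]")
    return frame


def read_frequencies(path) -> dict[str, float]:
    """Frequency TSV (snp, effect_allele, freq) -> {snp: freq}."""
    frame = pd.read_csv(path, sep="\t")
    if "snp" not in frame.columns or "freq" not in frame.columns:
        raise ValueError("frequency table requires 'snp' and 'freq' columns")
    f = frame["freq"].to_numpy(dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    return dict(zip(frame["snp"].astype(str), f))


@dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline (paths, thresholds, seed)."""

    summary_stats: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    frequencies: str | None = None
    baseline_incidence: str | None = None
    validation_genotypes: str | None = None
    validation_phenotypes: str | None = None
    out_dir: str = "phs_run"
    p_threshold: float = 1e-5
    direction_filter: bool = False
    tol: float | str = "auto"
    B: int = 1000
    n_mc: int = 1_000_000
    dt: float = 0.25
    ties: str = "efron"
    apoe_freqs: tuple = (0.08, 0.78, 0.14)
    table_mode: str = "fixed_quantile"
    percentiles: tuple = (1, 20, 80, 99)
    table_ages: tuple = (60, 65, 70, 75, 80, 85, 90, 95)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("apoe_freqs", "percentiles", "table_ages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_manifest(self) -> dict:
        import polyhazard

        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for key in ("apoe_freqs", "percentiles", "table_ages"):
            d[key] = list(d[key])
        d["polyhazard_version"] = polyhazard.__version__
        d["numpy_version"] = np.__version__
        d["pandas_version"] = pd.__version__
        return d
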