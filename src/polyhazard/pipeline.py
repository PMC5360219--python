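"""End-to-end orchestration: prescreen -> select -> bootstrap -> score ->
reference distribution -> calibrate -> incidence table (-> validation).

Every stage failure aborts with a stage-labelled message; outputs written
before the failure are renamed with a ``.partial`` suffix. A manifest
(config, seed, package versions) makes any run reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as phio
from .calibrate import BaselineIncidence, IncidenceCalibrator
from .score import APOE_E2, APOE_E4, PolygenicHazardModel
from .validate import decile_hr, onset_correlation, stratify_km

logger = logging.getLogger("polyhazard")

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(config, attr, stage):
    val = getattr(config, attr)
    if val is None:
        raise PipelineError(stage, f"config field {attr!r} is required for this stage")
    return val


def run_pipeline(config: phio.RunConfig) -> dict:
    """Run the full derivation; returns a dict of output paths and results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict = {}

    def _write(name, writer):
        path = out_dir / name
        writer(path)
        written.append(path)
        artifacts[name] = str(path)

    # validate configuration up front so no compute precedes a config error
    _require(config, "summary_stats", "config")
    _require(config, "genotypes", "config")
    _require(config, "phenotypes", "config")
    _require(config, "frequencies", "config")
    _require(config, "baseline_incidence", "config")

    try:
        stage = "read"
        stats = phio.read_summary_stats(config.summary_stats)
        genotypes = phio.read_genotypes(config.genotypes)
        pheno = phio.read_phenotypes(config.phenotypes)
        freqs = phio.read_frequencies(config.frequencies)
        baseline = BaselineIncidence.from_csv(config.baseline_incidence)
        cohort = pheno.join(genotypes.to_frame(), how="inner")
        if len(cohort) == 0:
            raise PipelineError(stage, "no overlap between genotype and phenotype ids")

        stage = "train"
        model = PolygenicHazardModel(
            p_threshold=config.p_threshold,
            direction_filter=config.direction_filter,
            tol=config.tol,
            B=config.B,
            ties=config.ties,
            seed=config.seed,
        )
        model.fit(cohort, summary_stats=stats)
        _write("beta_table.tsv", lambda p: model.beta_table_.to_csv(p, sep="\t", index=False))
        trace = pd.DataFrame(model.trace_.steps)
        _write("selection_trace.tsv", lambda p: trace.to_csv(p, sep="\t", index=False))

        stage = "score"
        scores = model.transform(
            cohort[model.selected_], apoe=cohort[[APOE_E2, APOE_E4]], freqs=freqs
        )
        _write("scores.csv", lambda p: scores.rename("phs").to_csv(p))

        stage = "refdist"
        dist = model.reference_distribution(
            freqs, apoe_freqs=config.apoe_freqs, n_mc=config.n_mc, seed=config.seed
        )

        stage = "calibrate"
        cal = IncidenceCalibrator(dt=config.dt).fit(baseline, dist)
        table = cal.incidence_table(
            percentiles=config.percentiles, ages=config.table_ages,
            apoe_strata=True, mode=config.table_mode,
        )
        _write("incidence_table.csv", lambda p: table.to_csv(p))
        diag = pd.DataFrame({"age": cal.midpoints_, "h0": cal.h0_, "h_pop": cal.h_pop_,
                             "residual": cal.diagnostics_})
        _write("calibration_diagnostics.csv", lambda p: diag.to_csv(p, index=False))

        results = {"selected": model.selected_, "n_selected": len(model.selected_)}

        if config.validation_genotypes and config.validation_phenotypes:
            stage = "validate"
            vgeno = phio.read_genotypes(config.validation_genotypes)
            vpheno = phio.read_phenotypes(config.validation_phenotypes)
            vcohort = vpheno.join(vgeno.to_frame(), how="inner")
            vscores = model.transform(
                vcohort[model.selected_], apoe=vcohort[[APOE_E2, APOE_E4]], freqs=freqs
            )
            strat = stratify_km(vcohort, vscores, dist)
            cases = vcohort.loc[vcohort["event"] == 1]
            onset = onset_correlation(cases, vscores[cases.index].to_numpy(), cal)
            hr, ci, logrank_p = decile_hr(vcohort, vscores.to_numpy())
            report = {
                "logrank_chi2": strat.logrank_chi2,
                "logrank_p": strat.logrank_p,
                "onset_r": onset.pearson_r,
                "onset_p": onset.p_value,
                "decile_hr": hr,
                "decile_hr_ci": list(ci),
                "decile_logrank_p": logrank_p,
            }
            _write("validation_report.json",
                   lambda p: p.write_text(json.dumps(report, indent=2)))
            results["validation"] = report

        stage = "manifest"
        manifest = config.to_manifest()
        manifest["outputs"] = sorted(artifacts)
        _write("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
        results["artifacts"] = artifacts
        return results
    except PipelineError:
        _mark_partial(written)
        raise
    except Exception as exc:
        _mark_partial(written)
        raise PipelineError(stage, str(exc)) from exc


def _mark_partial(written: list[Path]) -> None:
    for path in written:
        if path.exists():
            path.rename(path.with_suffix(path.suffix + ".partial"))
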