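"""End-to-end orchestration: preprocessing, enrichment, classification,
treatment comparison and batch QC, with tab-separated outputs and a run
manifest.

:func:`analyze` is the library entry point (in-memory objects in, results
object out); :func:`run_pipeline` wraps it with file IO, writes every stage
output into an output directory and records a manifest (config hash and
row/column counts at every stage). Outputs are deterministic: rerunning with
identical inputs and config yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import classify as cls
from . import compare as cmp
from . import enrichment as enr
from . import preprocess as pre
from .config import PipelineConfig
from .errors import PipelineError, PlasmaIpError
from .io import (
    LfqMatrix,
    align_metadata,
    read_lfq_table,
    read_metadata,
    write_lfq_table,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisResult:
    """Everything the pipeline computes, by treatment stratum where relevant."""

    config: PipelineConfig
    matrix: LfqMatrix                         # analysis-ready (filtered, log10)
    metadata: pd.DataFrame
    strata: dict[str, enr.TreatmentStratum]
    frequencies: dict[str, pd.Series]
    stats: dict[str, enr.PopulationStats]
    enrichment: dict[str, enr.EnrichmentTable]
    classifications: dict[str, list[cls.AntibodyClassification]]
    contaminants: pd.DataFrame
    comparison: dict | None                   # frequency + z-summary comparison
    batch_qc: dict[str, pd.DataFrame]
    counts: dict[str, dict]                   # per-stage row/column bookkeeping


def analyze(
    matrix: LfqMatrix,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    config = (config or PipelineConfig()).validate()
    counts: dict[str, dict] = {}

    metadata = align_metadata(matrix, metadata)
    counts["input"] = {"proteins": matrix.n_proteins, "ips": matrix.n_ips}

    try:
        matrix, metadata = pre.select_technical_replicate(matrix, metadata)
    except Exception as exc:
        raise PipelineError("select_technical_replicate", str(exc)) from exc
    counts["select_technical_replicate"] = {
        "proteins": matrix.n_proteins, "ips": matrix.n_ips,
    }

    try:
        matrix = pre.filter_contaminant_proteins(matrix)
    except Exception as exc:
        raise PipelineError("filter_contaminant_proteins", str(exc)) from exc
    counts["filter_contaminant_proteins"] = {
        "proteins": matrix.n_proteins, "ips": matrix.n_ips,
    }

    if config.scale == "log10":
        try:
            matrix = pre.impute_and_log(matrix)
        except Exception as exc:
            raise PipelineError("impute_and_log", str(exc)) from exc
    counts["impute_and_log"] = {"proteins": matrix.n_proteins, "ips": matrix.n_ips}

    strata = enr.split_by_treatment(matrix, metadata)
    frequencies = {t: enr.compute_frequency(s) for t, s in strata.items()}
    stats = {t: enr.compute_population_stats(s, config) for t, s in strata.items()}
    enrichment = {}
    for t, s in strata.items():
        merged = enr.merge_biological_replicates(s)
        enrichment[t] = enr.compute_zscores(
            merged, stats[t], frequency=frequencies[t], treatment=t
        )
    counts["enrichment"] = {
        t: {"ips": s.n_ips, "antibodies": int(enrichment[t].data["antibody_id"].nunique())}
        for t, s in strata.items()
    }

    classifications = {
        t: cls.classify_all(enrichment[t], strata[t].metadata, matrix.proteins, config)
        for t in strata
    }
    contaminants = cls.annotate_contaminants(frequencies, config)

    comparison = None
    if "heat" in strata and "untreated" in strata:
        freq_table, rho, pval = cmp.compare_frequencies(
            frequencies["heat"], frequencies["untreated"]
        )
        common = contaminants.index[contaminants["is_contaminant_common"]].tolist()
        zcmp = cmp.compare_z_summaries(
            enrichment["heat"], enrichment["untreated"], common
        )
        comparison = {
            "frequencies": freq_table,
            "spearman_rho": rho,
            "spearman_p": pval,
            "z_summaries": zcmp,
            "n_common_contaminants": len(common),
        }

    batch_qc = {}
    for t, s in strata.items():
        n_batches = s.metadata["batch"].nunique()
        if n_batches >= 2:
            batch_qc[t] = cmp.batch_effect_test(s)
        else:
            logger.info("%s stratum: single batch, QC skipped", t)

    return AnalysisResult(
        config=config,
        matrix=matrix,
        metadata=metadata,
        strata=strata,
        frequencies=frequencies,
        stats=stats,
        enrichment=enrichment,
        classifications=classifications,
        contaminants=contaminants,
        comparison=comparison,
        batch_qc=batch_qc,
        counts=counts,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_outputs(result: AnalysisResult, outdir: str | Path) -> dict:
    """Write every stage output; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}

    def record(stage: str, name: str):
        outputs.setdefault(stage, []).append(name)

    write_lfq_table(
        LfqMatrix(
            proteins=result.matrix.proteins,
            intensity=result.matrix.intensity,
            scale=result.matrix.scale,
            detected=result.matrix.detected,
        ),
        outdir / "filtered_matrix.tsv",
        result.config,
    )
    record("filtered_matrix", "filtered_matrix.tsv")

    for t, f in result.frequencies.items():
        _write_tsv(f.rename("f").rename_axis("protein").reset_index(),
                   outdir / f"frequencies_{t}.tsv")
        record("frequencies", f"frequencies_{t}.tsv")

    for t, table in result.enrichment.items():
        out = table.data.copy()
        out.insert(0, "treatment", t)
        _write_tsv(out, outdir / f"enrichment_{t}.tsv")
        record("enrichment", f"enrichment_{t}.tsv")

    all_cls = [c for lst in result.classifications.values() for c in lst]
    _write_tsv(cls.classification_report(all_cls), outdir / "classification.tsv")
    record("classification", "classification.tsv")
    _write_tsv(cls.merge_verdicts(all_cls), outdir / "classification_merged.tsv")
    record("classification", "classification_merged.tsv")

    _write_tsv(result.contaminants.reset_index(), outdir / "contaminants.tsv")
    record("contaminants", "contaminants.tsv")

    if result.comparison is not None:
        _write_tsv(result.comparison["frequencies"].reset_index(),
                   outdir / "frequency_comparison.tsv")
        _write_tsv(result.comparison["z_summaries"],
                   outdir / "z_summary_comparison.tsv")
        record("treatment_comparison", "frequency_comparison.tsv")
        record("treatment_comparison", "z_summary_comparison.tsv")

    for t, qc in result.batch_qc.items():
        _write_tsv(qc.reset_index(), outdir / f"batch_qc_{t}.tsv")
        record("batch_qc", f"batch_qc_{t}.tsv")

    plotdir = outdir / "plot_data"
    plotdir.mkdir(exist_ok=True)
    for t, table in result.enrichment.items():
        for ab, sub in table.data.groupby("antibody_id"):
            pdata = cls.plot_enrichment_profile(sub, result.config)
            if len(pdata):
                _write_tsv(pdata, plotdir / f"{ab}_{t}.tsv")
    record("plot_data", "plot_data/")

    manifest = {
        "config_hash": result.config.content_hash(),
        "config": result.config.to_dict(),
        "counts": result.counts,
        "spearman_rho": None
        if result.comparison is None
        else result.comparison["spearman_rho"],
        "stages": outputs,
        "n_stage_outputs": len(outputs),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_pipeline(
    lfq_path: str | Path,
    metadata_path: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path = "plasmaip_out",
) -> dict:
    """File-based end-to-end run; returns the manifest."""
    config = (config or PipelineConfig()).validate()
    try:
        matrix = read_lfq_table(lfq_path, config)
    except Exception as exc:
        raise PipelineError("read_lfq", str(exc)) from exc
    try:
        metadata = read_metadata(metadata_path)
    except Exception as exc:
        raise PipelineError("read_metadata", str(exc)) from exc
    result = analyze(matrix, metadata, config)
    return write_outputs(result, outdir)
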