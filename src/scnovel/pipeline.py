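"""End-to-end pipeline: simulate -> classify -> gate -> conserve ->
specificity -> markers -> score -> thresholds -> coexpr -> drugcorr,
communicating only through the documented file formats, plus a
consolidated JSON summary (class-code counts, verdict counts, markers
per type, cells above the novelScore threshold)."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    cell_scoring,
    classifier,
    coding_potential,
    conservation,
    genome_model,
    specificity,
    synthetic_fixtures,
)

logger = logging.getLogger("scnovel")


def _log(stage: str, message: str) -> None:
    logger.info("[%s] %s", stage, message)


@dataclass
class RunConfig:
    """Every input path, threshold and seed of one pipeline run."""

    outdir: str = "scnovel_run"
    seed: int = 42
    simulate_profile: str | None = "gbm_like"  # None -> inputs must exist
    reference_gtf: str | None = None
    assembly_gtf: str | None = None
    genome_fasta: str | None = None
    conservation_track: str | None = None
    matrix_mtx: str | None = None
    features_tsv: str | None = None
    barcodes_tsv: str | None = None
    labels_tsv: str | None = None
    ic50_tsv: str | None = None
    line_scores_tsv: str | None = None
    # thresholds
    min_lncrna_length: int = 200  # strict '>'
    min_cpm: float = 1.0
    min_cells: int = 3
    marker_min_specificity: float = 0.6
    marker_min_detection: float = 0.25
    marker_min_fold: float = 2.0
    auc_mode: str = "full_integral"
    auc_top_fraction: float = 0.05
    threshold_method: str = "mixture"
    fdr_alpha: float = 0.05
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _require(config_value: str | None, stage: str, what: str) -> Path:
    if config_value is None or not Path(config_value).exists():
        raise FileNotFoundError(
            f"stage {stage!r}: required input {what} missing "
            f"({config_value!r})"
        )
    return Path(config_value)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary dict (also written to
    ``outdir/summary.json``). Idempotent for a fixed seed and inputs."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level, format="%(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json() + "\n")

    if config.simulate_profile:
        _log("simulate", f"profile={config.simulate_profile} seed={config.seed}")
        manifest = synthetic_fixtures.emulate_paper_shape(config.simulate_profile)
        manifest.seed = config.seed
        fix_dir = outdir / "fixture"
        paths = synthetic_fixtures.generate_to_dir(manifest, fix_dir)
        config = dataclasses.replace(
            config,
            reference_gtf=str(paths["reference"]),
            assembly_gtf=str(paths["assembly"]),
            genome_fasta=str(paths["genome"]),
            conservation_track=str(paths["conservation"]),
            matrix_mtx=str(paths["matrix"]),
            features_tsv=str(paths["features"]),
            barcodes_tsv=str(paths["barcodes"]),
            labels_tsv=str(paths["labels"]),
            ic50_tsv=str(paths["ic50"]),
            line_scores_tsv=str(paths["line_scores"]),
        )

    # --- classify
    reference = genome_model.read_gtf(_require(config.reference_gtf, "classify", "reference GTF"))
    assembly = genome_model.read_gtf(_require(config.assembly_gtf, "classify", "assembly GTF"))
    index = classifier.build_annotation_index(reference)
    records = classifier.classify_assembly(assembly, index)
    classifier.write_classification(records, outdir / "classification.tsv")
    partition = classifier.partition_assembly(records)
    code_counts = pd.Series(
        [r.class_code.code for r in records]
    ).value_counts().to_dict()
    _log("classify", f"{len(records)} transcripts, codes {code_counts}")

    # --- expression matrix
    matrix = genome_model.read_expression(
        _require(config.matrix_mtx, "expression", "matrix MTX"),
        _require(config.features_tsv, "expression", "features TSV"),
        _require(config.barcodes_tsv, "expression", "barcodes TSV"),
        _require(config.labels_tsv, "expression", "labels TSV"),
    )

    # --- coding-potential gate over unannotated transcripts
    genome = genome_model.read_fasta(_require(config.genome_fasta, "coding", "genome FASTA"))
    unannotated = [t for t in assembly if t.transcript_id in partition["unannotated"]]
    gate = coding_potential.GateThresholds(
        config.min_lncrna_length, config.min_cpm, config.min_cells
    )
    verdicts = coding_potential.gate_assembly(
        unannotated, genome, matrix=matrix, thresholds=gate
    )
    verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    verdict_counts = verdicts["verdict"].value_counts().to_dict()
    _log("coding", f"verdicts {verdict_counts}")

    # --- conservation
    track = genome_model.read_conservation(
        _require(config.conservation_track, "conserve", "conservation track")
    )
    summaries = conservation.summarize_assembly(assembly, track)
    conservation.write_conservation(summaries, outdir / "conservation.tsv")
    by_cat: dict[str, list] = {}
    code_by_id = {r.transcript_id: r.class_code.code for r in records}
    for s in summaries:
        cat = "unannotated" if code_by_id[s.transcript_id] in classifier.UNANNOTATED_CODES else "annotated"
        by_cat.setdefault(cat, []).append(s)
    ecdf, null_counts = conservation.conservation_ecdf(by_cat)
    ecdf.to_csv(outdir / "conservation_ecdf.tsv", sep="\t", index=False)
    _log("conserve", f"{len(summaries)} transcripts, null means {null_counts}")

    # --- specificity + markers (restricted to unannotated lncRNAs)
    spec = specificity.js_specificity_all(matrix)
    specificity.write_specificity(spec, outdir / "specificity.tsv")
    lnc_ids = set(verdicts.loc[verdicts["verdict"] == "unannotated_lncRNA", "transcript_id"])
    markers = specificity.call_markers(
        matrix,
        spec,
        specificity.MarkerThresholds(
            config.marker_min_specificity,
            config.marker_min_detection,
            config.marker_min_fold,
        ),
        restrict_to=lnc_ids,
    )
    specificity.write_markers(markers, outdir / "markers.tsv")
    marker_counts = (
        markers.loc[markers["is_marker"], "cell_type"].value_counts().to_dict()
    )
    _log("markers", f"{int(markers['is_marker'].sum())} markers {marker_counts}")

    # --- novelScore + threshold
    marker_set_ids = set(markers.loc[markers["is_marker"], "transcript_id"])
    summary_scoring: dict = {}
    if marker_set_ids and len(marker_set_ids) < matrix.n_features:
        gene_set = cell_scoring.GeneSet("novel_lncRNA_markers", frozenset(marker_set_ids))
        scores = cell_scoring.novel_score(
            matrix, gene_set, mode=config.auc_mode, top_fraction=config.auc_top_fraction
        )
        thr = cell_scoring.explore_thresholds(
            scores, method=config.threshold_method, seed=config.seed
        )
        cell_scoring.scores_to_frame(scores, gene_set.name).to_csv(
            outdir / "novel_scores.tsv", sep="\t", index=False
        )
        labels = matrix.require_cell_types()
        mean_by_type = (
            pd.Series([s.auc for s in scores], index=matrix.cells)
            .groupby(labels)
            .mean()
            .sort_values(ascending=False)
        )
        summary_scoring = {
            "threshold": thr.threshold,
            "threshold_method": thr.method,
            "cells_above_threshold": thr.n_above,
            "mean_novel_score_by_type": mean_by_type.round(6).to_dict(),
        }
        _log("score", f"threshold {thr.threshold:.4f} ({thr.n_above} cells above)")

    # --- coexpression of the top marker transcript
    summary_coexpr: dict = {}
    if marker_set_ids:
        top_marker = markers.loc[markers["is_marker"]].sort_values(
            "max_specificity", ascending=False
        )["transcript_id"].iloc[0]
        coexpr = cell_scoring.coexpression(
            matrix.log1p_cpm(), top_marker, alpha=config.fdr_alpha
        )
        coexpr.to_csv(outdir / "coexpression.tsv", sep="\t", index=False)
        summary_coexpr = {
            "target": top_marker,
            "n_coexpressed": int(coexpr["coexpressed"].sum()),
        }
        _log("coexpr", f"target {top_marker}: {summary_coexpr['n_coexpressed']} partners")

    # --- drug correlation
    summary_drug: dict = {}
    if config.ic50_tsv and config.line_scores_tsv:
        ic50 = cell_scoring.read_ic50(config.ic50_tsv)
        line_scores = pd.read_csv(
            config.line_scores_tsv, sep="\t", header=None, index_col=0
        )[1]
        corr = cell_scoring.correlate_with_ic50(line_scores, ic50)
        frame = cell_scoring.correlations_to_frame(corr)
        frame.to_csv(outdir / "drug_correlations.tsv", sep="\t", index=False)
        if len(frame):
            best = frame.sort_values("pearson_r").iloc[0]
            summary_drug = {
                "most_negative_drug": str(best["drug"]),
                "pearson_r": float(best["pearson_r"]),
                "fdr_q": float(best["fdr_q"]),
            }
            _log("drugcorr", f"most negative: {summary_drug}")

    summary = {
        "seed": config.seed,
        "n_assembled": len(records),
        "class_code_counts": {k: int(v) for k, v in sorted(code_counts.items())},
        "partition_sizes": {k: len(v) for k, v in partition.items()},
        "verdict_counts": {k: int(v) for k, v in sorted(verdict_counts.items())},
        "conservation_null_means": null_counts,
        "n_marker_transcripts": int(markers["is_marker"].sum()) if len(markers) else 0,
        "markers_per_type": {k: int(v) for k, v in sorted(marker_counts.items())},
        "novel_score": summary_scoring,
        "coexpression": summary_coexpr,
        "drug_correlation": summary_drug,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
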