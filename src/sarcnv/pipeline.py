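"""End-to-end orchestration from a YAML run configuration.

A run maps each cohort's segments to genes, computes per-cohort platform
thresholds, discretizes, writes gene- and band-level frequency tables,
compares cohorts against each other and against the healthy background,
clusters each cohort, derives drug AUCs, and calls CNV-drug biomarkers on
the cell-line panel. Stages whose optional inputs are absent are skipped
and recorded in the run manifest; a stage failure aborts the run with the
stage name, leaving partial outputs plus a FAILED marker in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .biomarker_correlation import call_biomarkers
from .cluster_analysis import export_cluster, hierarchical_cluster, select_variable_genes
from .cnv_profile import (
    band_frequencies,
    compare_cohorts,
    compute_thresholds,
    discretize,
    gene_frequencies,
    healthy_background_frequencies,
    tumor_vs_cellline_table,
)
from .drug_response import auc_table, read_dose_response
from .genomic_data import (
    assign_cytobands,
    read_cytobands,
    read_gene_annotation,
    read_healthy_variants,
    read_matrix,
    read_segments,
    segments_to_gene_matrix,
    write_matrix,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CohortInput:
    label: str
    segments: str
    dialect: str = "zero_based_half_open"


@dataclass
class RunConfig:
    """Everything a run needs; see :func:`RunConfig.from_yaml`."""

    cohorts: list[CohortInput]
    gene_annotation: str
    cytobands: str
    outdir: str
    healthy_variants: Optional[str] = None
    healthy_n_individuals: Optional[int] = None
    cellline_segments: Optional[str] = None
    cellline_matrix: Optional[str] = None
    cellline_dialect: str = "zero_based_half_open"
    dose_response: Optional[str] = None
    auc_input: Optional[str] = None
    r_cut: float = 0.35
    p_cut: float = 0.05
    frequency_floor: float = 0.0
    cluster_k: int = 50
    cluster_axis: str = "samples"
    cluster_distance: str = "one_minus_pearson"
    cluster_linkage: str = "average"
    panel: Optional[list[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be > 0")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        for path in self._input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")

    def _input_paths(self) -> list[str]:
        paths = [self.gene_annotation, self.cytobands]
        paths += [c.segments for c in self.cohorts]
        for p in (self.healthy_variants, self.cellline_segments,
                  self.cellline_matrix, self.dose_response, self.auc_input):
            if p:
                paths.append(p)
        return paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohorts = [CohortInput(**c) for c in raw.pop("cohorts")]
        return cls(cohorts=cohorts, **raw)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "software": "sarcnv",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "r_cut": config.r_cut, "p_cut": config.p_cut,
            "frequency_floor": config.frequency_floor,
            "cluster": {
                "k": config.cluster_k, "axis": config.cluster_axis,
                "distance": config.cluster_distance, "linkage": config.cluster_linkage,
            },
        },
        "inputs": {
            "gene_annotation": config.gene_annotation,
            "cytobands": config.cytobands,
            "cohorts": [{"label": c.label, "segments": c.segments} for c in config.cohorts],
            "healthy_variants": config.healthy_variants,
            "cellline": config.cellline_matrix or config.cellline_segments,
            "drug_response": config.dose_response or config.auc_input,
        },
        "stages": {},
        "outputs": [],
    }

    def write_manifest() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        logger.info("stage %s: %s", stage, status)

    def emit(name: str, frame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    def run_stage(stage: str, fn):
        try:
            result = fn()
        except Exception as exc:
            record(stage, "FAILED")
            write_manifest()
            raise PipelineStageError(stage, exc) from exc
        record(stage, "completed")
        return result

    # -- annotation ---------------------------------------------------------
    def stage_annotation():
        genes = read_gene_annotation(config.gene_annotation)
        bands = read_cytobands(config.cytobands)
        return assign_cytobands(genes, bands)

    genes = run_stage("annotation", stage_annotation)

    # -- per-cohort mapping, discretization, frequencies --------------------
    gene_tables = []
    dmatrices = {}

    def stage_cohorts():
        for cohort in config.cohorts:
            segments = read_segments(cohort.segments, dialect=cohort.dialect)
            matrix = segments_to_gene_matrix(segments, genes, cohort_label=cohort.label)
            write_matrix(matrix, outdir / f"matrix_{cohort.label}.tsv")
            manifest["outputs"].append(f"matrix_{cohort.label}.tsv")
            thresholds = compute_thresholds(matrix)
            dmat = discretize(matrix, thresholds)
            write_matrix(dmat, outdir / f"discrete_{cohort.label}.tsv")
            manifest["outputs"].append(f"discrete_{cohort.label}.tsv")
            gf = gene_frequencies(dmat)
            bf = band_frequencies(dmat)
            emit(f"gene_frequencies_{cohort.label}.tsv", gf)
            emit(f"band_frequencies_{cohort.label}.tsv", bf)
            gene_tables.append(gf)
            dmatrices[cohort.label] = (matrix, dmat)

    run_stage("cohorts", stage_cohorts)

    # -- healthy background -------------------------------------------------
    if config.healthy_variants:
        def stage_healthy():
            records = read_healthy_variants(config.healthy_variants)
            n_ind = config.healthy_n_individuals
            if n_ind is None:
                n_ind = len({r.individual_id for r in records})
            table = healthy_background_frequencies(records, genes, n_ind)
            emit("gene_frequencies_HEALTHY.tsv", table)

        run_stage("healthy_background", stage_healthy)
    else:
        record("healthy_background", "skipped (no healthy_variants input)")

    # -- cross-cohort overlap ------------------------------------------------
    if len(gene_tables) >= 2:
        def stage_overlap():
            overlap = compare_cohorts(gene_tables, config.frequency_floor)
            wide = overlap.table.copy()
            wide.columns = [f"{a}_{b}" for a, b in wide.columns]
            wide.insert(0, "unit", wide.index)
            emit("cohort_comparison.tsv", wide.reset_index(drop=True))
            emit("overlap_genes.tsv", pd.DataFrame({"unit": overlap.overlap_genes}))

        run_stage("cohort_overlap", stage_overlap)
    else:
        record("cohort_overlap", "skipped (fewer than 2 cohorts)")

    # -- clustering ----------------------------------------------------------
    def stage_cluster():
        for label, (matrix, _) in dmatrices.items():
            k = min(config.cluster_k, int(matrix.values.std(axis=1, ddof=1).notna().sum()))
            selected = select_variable_genes(matrix, k)
            sub = matrix.values.loc[selected]
            result = hierarchical_cluster(
                sub, axis=config.cluster_axis,
                distance=config.cluster_distance, linkage=config.cluster_linkage,
            )
            export_cluster(result, sub, outdir / f"cluster_{label}.nwk",
                           outdir / f"cluster_{label}_matrix.tsv")
            manifest["outputs"] += [f"cluster_{label}.nwk", f"cluster_{label}_matrix.tsv"]

    run_stage("clustering", stage_cluster)

    # -- cell-line matrix ----------------------------------------------------
    cellline_matrix = None
    if config.cellline_matrix or config.cellline_segments:
        def stage_cellline():
            if config.cellline_matrix:
                matrix = read_matrix(config.cellline_matrix, cohort_label="CELLLINE")
                if all(g.band is None for g in matrix.genes):
                    lookup = {g.symbol: g for g in genes}
                    matrix.genes = [lookup.get(g.symbol, g) for g in matrix.genes]
            else:
                segments = read_segments(config.cellline_segments,
                                         dialect=config.cellline_dialect)
                matrix = segments_to_gene_matrix(segments, genes, cohort_label="CELLLINE")
            thresholds = compute_thresholds(matrix)
            dmat = discretize(matrix, thresholds)
            panel = config.panel or [g.symbol for g in matrix.genes]
            table = tumor_vs_cellline_table(gene_tables, dmat, panel=panel)
            emit("tumor_vs_cellline.tsv", table)
            return matrix

        cellline_matrix = run_stage("cellline", stage_cellline)
    else:
        record("cellline", "skipped (no cell-line input)")

    # -- drug AUC ------------------------------------------------------------
    aucs = None
    if config.dose_response:
        def stage_auc():
            curves = read_dose_response(config.dose_response)
            table = auc_table(curves)
            emit("auc.tsv", table)
            return table

        aucs = run_stage("auc", stage_auc)
    elif config.auc_input:
        def stage_auc_load():
            table = pd.read_csv(config.auc_input, sep="\t")
            emit("auc.tsv", table)
            return table

        aucs = run_stage("auc", stage_auc_load)
    else:
        record("auc", "skipped (no dose-response or AUC input)")

    # -- biomarker calling ---------------------------------------------------
    if cellline_matrix is not None and aucs is not None:
        def stage_biomarkers():
            calls = call_biomarkers(cellline_matrix, aucs,
                                    r_cut=config.r_cut, p_cut=config.p_cut)
            emit("biomarkers.tsv", calls)

        run_stage("biomarkers", stage_biomarkers)
    else:
        record("biomarkers", "skipped (needs cell-line matrix and AUC table)")

    write_manifest()
    return manifest
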