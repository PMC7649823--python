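"""End-to-end orchestration: transform -> filter -> cluster -> match ->
entropy -> select -> report.  Deterministic for a fixed configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import entropy as ne
from .cluster import GeneClustering, cluster_genes, default_n_clusters
from .io import (
    SCALE_TPM,
    CellLabels,
    ExpressionMatrix,
    PPINetwork,
    write_table,
)
from .ppi import ClusterSubnetwork, match_clusters
from .preprocess import FilterReport, filter_genes, filter_report_frame, log_transform

logger = logging.getLogger("diffge")

#: minimum fraction of expression genes that must appear in the PPI node
#: set; below this the gene namespaces almost certainly do not match.
MIN_GENE_OVERLAP = 0.01


@dataclass
class PipelineConfig:
    """All pipeline knobs with their defaults; inputs are passed separately."""

    v: float = 10.0
    expressed_threshold: float = 0.0
    n_clusters: Optional[int] = None  # None -> max(2, n_genes/100)
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-4
    entropy_mode: str = ne.MODE_PER_CELL
    top_fraction: float = 0.1
    aggregate: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    table: ne.ClusterEntropyTable
    genes: pd.DataFrame          # gene, cluster, score, detected
    filter_report: FilterReport
    clustering: GeneClustering
    subnetworks: list[ClusterSubnetwork]
    selected: list[int]

    @property
    def detected(self) -> set[str]:
        return ne.detected_gene_set(self.genes)


def run_pipeline(
    matrix: ExpressionMatrix,
    ppi: PPINetwork,
    config: PipelineConfig,
    labels: Optional[CellLabels] = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all artifacts.

    Raw-TPM input is log-transformed first; log-scaled input is used as
    is.  Errors carry the failing stage in their message.
    """
    t0 = time.perf_counter()
    overlap = len(set(matrix.genes) & ppi.nodes)
    if overlap < MIN_GENE_OVERLAP * matrix.n_genes:
        raise ValueError(
            f"only {overlap} of {matrix.n_genes} expression genes appear in the "
            "PPI network; the identifier namespaces (e.g. Ensembl protein vs "
            "gene symbol) likely differ — check the alias mapping"
        )
    if config.aggregate and labels is None:
        raise ValueError("aggregate=True requires cell labels")

    if matrix.scale == SCALE_TPM:
        matrix = log_transform(matrix)
    filtered, report = filter_genes(matrix, v=config.v, expressed_threshold=config.expressed_threshold)

    k = config.n_clusters if config.n_clusters is not None else default_n_clusters(filtered.n_genes)
    k = min(k, filtered.n_genes)
    clustering = cluster_genes(filtered, k, seed=config.seed, max_iter=config.max_iter, tol=config.tol)

    subnetworks = match_clusters(clustering, ppi)
    frame = ne.build_sample_frame(filtered, labels=labels, aggregate=config.aggregate)
    activities = ne.activity_matrix(subnetworks, frame)
    table = ne.compute_entropy(activities, mode=config.entropy_mode, samples=frame.samples)
    selected = ne.select_top(table, fraction=config.top_fraction)
    genes = ne.differential_genes(clustering, table)
    logger.info(
        "pipeline: %d genes -> %d filtered -> K=%d clusters, selected %s (%.2fs)",
        report.n_input_genes, len(report.kept_genes), clustering.K, selected,
        time.perf_counter() - t0,
    )
    return PipelineResult(
        table=table,
        genes=genes,
        filter_report=report,
        clustering=clustering,
        subnetworks=subnetworks,
        selected=selected,
    )


def write_results(result: PipelineResult, outdir: str | Path, config: Optional[PipelineConfig] = None) -> None:
    """Write the standard result tables (TSV) plus the config for provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entropy_df = result.table.to_frame(result.subnetworks)
    write_table(entropy_df, outdir / "cluster_entropy.tsv")
    write_table(result.genes, outdir / "differential_genes.tsv")
    write_table(filter_report_frame(result.filter_report), outdir / "filter_report.tsv")
    if config is not None:
        (outdir / "run_config.json").write_text(config.to_json() + "\n")
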