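"""Evaluation protocol: subset precision/recall stability and ROC/AUC.

The stability protocol treats the genes detected on the complete dataset
as the gold standard (DE_full), re-runs the detector on random cell
subsets of increasing size, and scores each subset's detection DE_subset
by

    precision = |DE_full & DE_subset| / |DE_subset|
    recall    = |DE_full & DE_subset| / |DE_full|

with precision recorded as *missing* when the subset detects nothing.
ROC/AUC scores a per-gene ranking against an external validation set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import CellLabels, ExpressionMatrix, PPINetwork
from .pipeline import PipelineConfig, run_pipeline

logger = logging.getLogger("diffge")


def precision_recall(de_full: set[str], de_subset: set[str]) -> tuple[Optional[float], float]:
    """Precision and recall of a subset detection against the full-data
    detection.  Empty subset -> (None, 0.0); empty full set is an error
    (recall undefined)."""
    if not de_full:
        raise ValueError("de_full is empty; recall is undefined")
    overlap = len(de_full & de_subset)
    if not de_subset:
        return None, 0.0
    return overlap / len(de_subset), overlap / len(de_full)


def roc_auc(
    scores: Mapping[str, float],
    truth: set[str],
    universe: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC for a gene ranking.

    The sweep visits each distinct score once (descending); equal-scored
    genes move in one threshold step, giving a diagonal segment.  The
    curve starts at (0, 0) and ends at (1, 1).
    """
    if universe is None:
        universe = set(scores)
    genes = sorted(universe)
    pos = truth & universe
    neg = universe - truth
    if not pos:
        raise ValueError("no validation genes inside the scored universe")
    if not neg:
        raise ValueError("every gene in the universe is a validation gene; FPR undefined")
    y = np.array([g in truth for g in genes], dtype=int)
    s = np.array([float(scores[g]) for g in genes])
    if np.all(s == s[0]):
        logger.warning("roc_auc: all genes share one score; AUC is 0.5 by convention")
        points = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]})
        return points, 0.5
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc


@dataclass
class EvalReport:
    """Per-run records and per-fraction summaries of the subset protocol;
    optionally carries one ROC curve and its AUC."""

    records: pd.DataFrame   # fraction, repeat, n_cells, n_detected, precision, recall, failed
    summary: pd.DataFrame   # fraction, mean_precision, mean_recall, n_missing_precision, n_failed
    n_full_detected: int
    roc: Optional[pd.DataFrame] = None
    auc: Optional[float] = None


def _subsample_cells(
    cells: Sequence[str],
    fraction: float,
    rng: np.random.Generator,
    labels: Optional[CellLabels],
    stratify: bool,
) -> list[str]:
    """Sample ``fraction``% of cells without replacement, stratified by
    cell type when labels are given (each type keeps >= 1 cell)."""
    if labels is not None and stratify:
        chosen: list[str] = []
        for t in labels.types:
            members = [c for c in cells if labels[c] == t]
            if not members:
                continue
            n = max(1, round(fraction / 100.0 * len(members)))
            idx = rng.choice(len(members), size=n, replace=False)
            chosen.extend(members[i] for i in sorted(idx))
        return chosen
    n = max(2, round(fraction / 100.0 * len(cells)))
    idx = rng.choice(len(cells), size=n, replace=False)
    return [cells[i] for i in sorted(idx)]


def subset_experiment(
    matrix: ExpressionMatrix,
    ppi: PPINetwork,
    config: PipelineConfig,
    fractions: Sequence[float] = (10, 30, 50, 70, 90),
    repeats: int = 10,
    seed: int = 0,
    labels: Optional[CellLabels] = None,
    stratify: bool = True,
) -> EvalReport:
    """Run the subsampling stability protocol.

    The detector runs once on all cells (gold standard), then once per
    (fraction, repeat) on a seeded random subset.  A failing subset run
    (e.g. every gene filtered out at a tiny fraction) is recorded as
    failed and skipped.  Per-fraction means ignore missing precisions and
    report how many were missing.  Fully reproducible from ``seed``.
    """
    for f in fractions:
        if not 0 < f <= 100:
            raise ValueError("fractions must lie in (0, 100]")
    if min(fractions) / 100.0 * matrix.n_cells < 2:
        raise ValueError("smallest fraction yields fewer than 2 cells")

    full = run_pipeline(matrix, ppi, config, labels=labels)
    de_full = full.detected
    logger.info("subset_experiment: gold standard has %d detected genes", len(de_full))

    rows = []
    for fi, fraction in enumerate(fractions):
        for rep in range(repeats):
            # one independent, repeat-indexed stream per (fraction, repeat)
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(fi, rep)))
            cells = _subsample_cells(matrix.cells, fraction, rng, labels, stratify)
            sub = matrix.subset_cells(cells)
            sub_labels = labels.subset(cells) if labels is not None else None
            try:
                result = run_pipeline(sub, ppi, config, labels=sub_labels)
            except ValueError as exc:
                logger.warning("subset %s%% repeat %d failed: %s", fraction, rep, exc)
                rows.append((fraction, rep, len(cells), 0, np.nan, np.nan, True))
                continue
            prec, rec = precision_recall(de_full, result.detected)
            rows.append(
                (fraction, rep, len(cells), len(result.detected),
                 np.nan if prec is None else prec, rec, False)
            )
    records = pd.DataFrame(
        rows, columns=["fraction", "repeat", "n_cells", "n_detected", "precision", "recall", "failed"]
    )
    ok = records[~records["failed"]]
    summary = (
        ok.groupby("fraction")
        .agg(
            mean_n_detected=("n_detected", "mean"),
            mean_precision=("precision", "mean"),  # NaN-skipping: missing excluded
            mean_recall=("recall", "mean"),
            n_missing_precision=("precision", lambda s: int(s.isna().sum())),
        )
        .reset_index()
    )
    failed_counts = records.groupby("fraction")["failed"].sum().rename("n_failed").reset_index()
    summary = summary.merge(failed_counts, on="fraction")
    return EvalReport(records=records, summary=summary, n_full_detected=len(de_full))


def plot_roc(roc: pd.DataFrame, auc: float, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc["fpr"], roc["tpr"], label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stability(report: EvalReport, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(report.summary["fraction"], report.summary["mean_precision"], marker="o", label="precision")
    ax.plot(report.summary["fraction"], report.summary["mean_recall"], marker="s", label="recall")
    ax.set_xlabel("Cell subset size (% of all cells)")
    ax.set_ylabel("Mean over repeats")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
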