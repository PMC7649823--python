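"""PPI-weighted network entropy of gene clusters — the core scoring step.

For each sample *s* (a single cell, or a cell type after aggregation) the
expression vector is normalized to relative abundances, so the weight of a
protein-interaction edge (i, j),

    W_ijs = e_si * e_sj,

can be read as the probability that the two gene products meet in sample
*s*.  A cluster *k* with member set C_k and size n_k gets the activity

    W_ks = sum_{(i,j) in matched edges of C_k} W_ijs / n_k,

summing each undirected edge once.  Activities are turned into shares
P_ks and scored by the Shannon entropy (natural log)

    E_k = - sum_s P_ks ln P_ks.

Two normalization axes are supported.  ``per_cell`` divides by the total
activity of all clusters within each sample (so the shares of one sample
sum to 1 across clusters); ``per_cluster`` divides by the cluster's own
total across samples, making P_k. a probability distribution over samples
with E_k bounded by ln(S), attained exactly at uniform activity.
Clusters are ranked by descending entropy and the top fraction selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import GeneClustering
from .io import CellLabels, ExpressionMatrix
from .ppi import ClusterSubnetwork

logger = logging.getLogger("diffge")

MODE_PER_CELL = "per_cell"
MODE_PER_CLUSTER = "per_cluster"
_MODES = (MODE_PER_CELL, MODE_PER_CLUSTER)


@dataclass
class SampleFrame:
    """Per-sample relative expression: each column sums to 1 (or is all zero)."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # genes x samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("value shape does not match genes x samples")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("normalized values must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0)
        if not np.all(ok):
            raise ValueError("each sample must sum to 1 (or be all zero)")

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]


def build_sample_frame(
    matrix: ExpressionMatrix,
    labels: Optional[CellLabels] = None,
    aggregate: bool = False,
) -> SampleFrame:
    """Normalize expression per sample; optionally aggregate cells to types.

    With ``aggregate=True`` each sample is a cell type and its expression
    vector is the mean over that type's cells, taken before normalization.
    All-zero samples stay zero (warned) rather than erroring, since
    dropout-heavy data can produce them.
    """
    if aggregate:
        if labels is None:
            raise ValueError("aggregation requires cell labels")
        labels.check_covers(matrix)
        types = labels.types
        cols = []
        for t in types:
            members = [i for i, c in enumerate(matrix.cells) if labels[c] == t]
            if not members:
                raise ValueError(f"cell type {t!r} covers zero cells")
            cols.append(matrix.values[:, members].mean(axis=1))
        raw = np.column_stack(cols)
        samples = list(types)
    else:
        raw = matrix.values.copy()
        samples = list(matrix.cells)
    sums = raw.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("build_sample_frame: %d all-zero samples left unnormalized", int(zero.sum()))
    normalized = raw / np.where(zero, 1.0, sums)
    return SampleFrame(genes=list(matrix.genes), samples=samples, values=normalized)


def edge_weight(e_si: float, e_sj: float) -> float:
    """Interaction probability of an edge: the product of the two
    normalized expression values (commutative, zero-absorbing)."""
    return e_si * e_sj


def cluster_activity(sub: ClusterSubnetwork, frame: SampleFrame, sample: str) -> float:
    """Activity W_ks of one cluster in one sample."""
    col = frame.column(sample)
    index = {g: i for i, g in enumerate(frame.genes)}
    total = 0.0
    for a, b in sub.edges:
        total += edge_weight(col[index[a]], col[index[b]])
    return total / sub.n_k


def activity_matrix(subnetworks: Sequence[ClusterSubnetwork], frame: SampleFrame) -> np.ndarray:
    """Clusters x samples activity matrix (vectorized over samples)."""
    index = {g: i for i, g in enumerate(frame.genes)}
    W = np.zeros((len(subnetworks), len(frame.samples)))
    for row, sub in enumerate(subnetworks):
        if not sub.edges:
            continue
        ia = np.array([index[a] for a, _ in sub.edges])
        ib = np.array([index[b] for _, b in sub.edges])
        W[row] = (frame.values[ia, :] * frame.values[ib, :]).sum(axis=0) / sub.n_k
    return W


@dataclass
class ClusterEntropyTable:
    """Per-cluster activities, shares, entropies, ranks and selection flags."""

    clusters: list[int]
    samples: list[str]
    activities: np.ndarray  # K x S
    shares: np.ndarray      # K x S
    entropy: np.ndarray     # K
    mode: str
    rank: np.ndarray        # K, 1 = highest entropy
    selected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.selected is None:
            self.selected = np.zeros(len(self.clusters), dtype=bool)
        if np.any(self.entropy < -1e-12):
            raise ValueError("entropies must be non-negative")

    def to_frame(self, subnetworks: Optional[Sequence[ClusterSubnetwork]] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster": self.clusters,
                "entropy": self.entropy,
                "total_activity": self.activities.sum(axis=1),
                "rank": self.rank,
                "selected": self.selected,
            }
        )
        if subnetworks is not None:
            df.insert(1, "n_genes", [s.n_k for s in subnetworks])
            df.insert(2, "n_edges", [len(s.edges) for s in subnetworks])
        return df


def compute_entropy(
    activities: np.ndarray,
    mode: str = MODE_PER_CELL,
    clusters: Optional[Sequence[int]] = None,
    samples: Optional[Sequence[str]] = None,
) -> ClusterEntropyTable:
    """Normalize activities into shares and score each cluster's entropy.

    ``per_cell``: P_ks = W_ks / sum_k' W_k's (column-normalized shares, the
    ratio of cluster k's activity to all clusters' in sample s).
    ``per_cluster``: P_ks = W_ks / sum_s' W_ks' (row-normalized).  In both
    modes E_k = -sum_s P_ks ln P_ks with 0 ln 0 := 0.  Samples (or
    clusters) with zero total activity are excluded from their
    normalization with a warning; their shares stay zero.
    """
    W = np.asarray(activities, dtype=float)
    if W.ndim != 2 or W.shape[0] < 1 or W.shape[1] < 1:
        raise ValueError("activities must be a non-empty clusters x samples matrix")
    if np.any(W < 0):
        raise ValueError("activities must be non-negative")
    if not np.any(W > 0):
        raise ValueError("no expressed cluster edges: all activities are zero")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    K, S = W.shape
    if mode == MODE_PER_CELL:
        totals = W.sum(axis=0, keepdims=True)
        n_zero = int((totals == 0).sum())
        if n_zero:
            logger.warning("compute_entropy: %d zero-activity samples excluded from normalization", n_zero)
    else:
        totals = W.sum(axis=1, keepdims=True)
        n_zero = int((totals == 0).sum())
        if n_zero:
            logger.warning("compute_entropy: %d zero-activity clusters excluded from normalization", n_zero)
    P = np.divide(W, totals, out=np.zeros_like(W), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    E = -terms.sum(axis=1)
    E = np.where(np.abs(E) < 1e-15, 0.0, E)  # clamp -0.0 from rounding

    order = _entropy_order(E, W)
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(1, K + 1)
    return ClusterEntropyTable(
        clusters=list(clusters) if clusters is not None else list(range(1, K + 1)),
        samples=list(samples) if samples is not None else [f"s{j+1}" for j in range(S)],
        activities=W,
        shares=P,
        entropy=E,
        mode=mode,
        rank=rank,
    )


def _entropy_order(E: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row order by descending entropy; ties broken by larger total
    activity, then by lower cluster index."""
    totals = W.sum(axis=1)
    return np.lexsort((np.arange(len(E)), -totals, -E))


def select_top(table: ClusterEntropyTable, fraction: float = 0.1) -> list[int]:
    """Flag the ``ceil(fraction * K)`` highest-entropy clusters as selected.

    Returns the selected cluster indices (at least one; the ceiling
    guarantees a non-empty selection for any positive fraction).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    K = len(table.clusters)
    n_select = max(1, math.ceil(fraction * K))
    order = _entropy_order(table.entropy, table.activities)
    chosen_rows = order[:n_select]
    table.selected[:] = False
    table.selected[chosen_rows] = True
    return [table.clusters[i] for i in chosen_rows]


def differential_genes(
    clustering: GeneClustering,
    table: ClusterEntropyTable,
) -> pd.DataFrame:
    """Per-gene result table: gene, cluster, score (the cluster's entropy),
    and whether the gene is in the detected set (member of a selected
    cluster).  Requires a non-empty selection."""
    selected = {c for c, s in zip(table.clusters, table.selected) if s}
    if not selected:
        raise ValueError("no clusters selected; call select_top first")
    entropy_of = dict(zip(table.clusters, table.entropy))
    rows = [
        (g, k, entropy_of[k], k in selected)
        for g, k in clustering.assignments.items()
    ]
    return pd.DataFrame(rows, columns=["gene", "cluster", "score", "detected"])


def detected_gene_set(genes_table: pd.DataFrame) -> set[str]:
    return set(genes_table.loc[genes_table["detected"], "gene"])
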