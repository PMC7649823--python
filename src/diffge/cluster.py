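"""Gene clustering by expectation-maximization mixture modelling.

Genes are partitioned by fitting a Gaussian mixture (diagonal covariance,
k-means++ initialization) to their expression profiles across cells and
hard-assigning each gene to its maximum-posterior component.  Empty
components are compacted away, so the effective cluster count can be
smaller than requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .io import SCALE_LOG_TPM, ExpressionMatrix

logger = logging.getLogger("diffge")


@dataclass
class GeneClustering:
    """A hard partition of genes into clusters indexed 1..K."""

    assignments: dict[str, int]
    K: int
    sizes: list[int]
    seed: int
    converged: bool
    n_iter: int
    requested_K: int = 0

    def __post_init__(self) -> None:
        if self.requested_K == 0:
            self.requested_K = self.K
        labels = set(self.assignments.values())
        if labels != set(range(1, self.K + 1)):
            raise ValueError(f"cluster indices must be exactly 1..{self.K}, got {sorted(labels)}")
        if len(self.sizes) != self.K or any(s < 1 for s in self.sizes):
            raise ValueError("sizes must list a positive count for each cluster")
        if sum(self.sizes) != len(self.assignments):
            raise ValueError("cluster sizes do not sum to the number of genes")

    def members(self, k: int) -> list[str]:
        """Genes of cluster ``k``, in assignment (input) order."""
        return [g for g, c in self.assignments.items() if c == k]

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)


def default_n_clusters(n_genes: int) -> int:
    """Default K: one cluster per ~100 genes, at least 2."""
    return max(2, round(n_genes / 100))


def cluster_genes(
    matrix: ExpressionMatrix,
    n_clusters: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> GeneClustering:
    """EM-cluster gene expression profiles (rows) into ``n_clusters`` groups.

    Deterministic for a fixed seed.  Ties in posterior responsibility break
    to the lowest component index; empty components are removed and the
    remaining indices compacted to 1..K_effective.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > matrix.n_genes:
        raise ValueError(f"n_clusters={n_clusters} exceeds the {matrix.n_genes} available genes")
    if matrix.scale != SCALE_LOG_TPM:
        raise ValueError("cluster_genes expects log-scaled expression; apply log_transform first")

    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="diag",
        init_params="k-means++",
        random_state=int(seed),
        max_iter=max_iter,
        tol=tol,
    )
    labels = gmm.fit_predict(matrix.values)
    if not gmm.converged_:
        logger.warning("cluster_genes: EM did not converge within %d iterations", max_iter)

    # compact away empty components, keep a stable 1..K indexing
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(sorted(present), start=1)}
    if len(present) < n_clusters:
        logger.info(
            "cluster_genes: %d of %d components empty; effective K=%d",
            n_clusters - len(present), n_clusters, len(present),
        )
    assignments = {g: remap[lab] for g, lab in zip(matrix.genes, labels)}
    sizes = [int(np.sum(labels == old)) for old in sorted(present)]
    return GeneClustering(
        assignments=assignments,
        K=len(present),
        sizes=sizes,
        seed=int(seed),
        converged=bool(gmm.converged_),
        n_iter=int(gmm.n_iter_),
        requested_K=n_clusters,
    )
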