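"""Synthetic scRNA-seq data with planted co-expression structure.

The generator emulates the structure the scoring pipeline assumes: genes
fall into co-expression blocks, cells into discrete types; *differential*
blocks change their mean expression between cell types while constant
blocks keep one mean everywhere; a fraction of expressed values is zeroed
to mimic dropout; and a protein-interaction graph is sampled with dense
edges inside blocks and sparse background edges between them.  Values are
drawn on the log2(TPM+1) scale directly (truncated Gaussians), so the
pipeline's log step is skipped on synthetic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SCALE_LOG_TPM, CellLabels, ExpressionMatrix, PPINetwork

#: STRING-style combined score attached to every sampled interaction;
#: above the default medium-confidence cut so score filtering is neutral.
EDGE_SCORE = 900.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small two-population experiment: 5 blocks of 40
    genes over 120 cells, one block shifted by 2.0 log2-TPM (four noise
    standard deviations) in one cell type, 20% dropout, and a PPI graph
    with 30% within-block / 1% background edge density.
    """

    n_genes: int = 200
    n_cells: int = 120
    n_blocks: int = 5
    n_differential_blocks: int = 1
    n_cell_types: int = 2
    block_mean_shift: float = 2.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.2
    ppi_within_block_prob: float = 0.3
    ppi_background_prob: float = 0.01
    seed: int = 0
    #: baseline block means are drawn uniformly from this range (log2 TPM)
    base_mean_range: tuple[float, float] = (1.5, 3.5)

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "ppi_within_block_prob", "ppi_background_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_differential_blocks > self.n_blocks:
            raise ValueError("n_differential_blocks must not exceed n_blocks")
        if self.n_cell_types < 2:
            raise ValueError("n_cell_types must be >= 2")
        if self.n_blocks < 1 or self.n_genes < self.n_blocks:
            raise ValueError("need at least one gene per block")
        if self.n_cells < self.n_cell_types:
            raise ValueError("need at least one cell per cell type")
        if self.noise_sd < 0 or self.block_mean_shift < 0:
            raise ValueError("noise_sd and block_mean_shift must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: block membership (a partition of
    the genes), which blocks are differential, and the cell types."""

    block_of_gene: dict[str, int]
    differential_blocks: list[int]
    cell_types: dict[str, str]
    block_means: np.ndarray = field(repr=False)  # blocks x cell types

    def genes_of_block(self, b: int) -> list[str]:
        return [g for g, k in self.block_of_gene.items() if k == b]

    @property
    def differential_genes(self) -> set[str]:
        diff = set(self.differential_blocks)
        return {g for g, k in self.block_of_gene.items() if k in diff}


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, CellLabels, PPINetwork, SyntheticTruth]:
    """Draw one dataset.  Fully determined by the config (incl. its seed).

    Genes are split into ``n_blocks`` nearly equal blocks (block index
    0..n_blocks-1); cells into ``n_cell_types`` nearly equal types.  Each
    block draws a baseline mean; differential blocks additionally shift
    their mean by ``block_mean_shift`` in one cell type (round-robin over
    types).  Values are ``max(0, mean + N(0, noise_sd))`` with dropout
    zeroing applied afterwards.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i+1:04d}" for i in range(config.n_genes)]
    cells = [f"C{j+1:04d}" for j in range(config.n_cells)]
    block_of = np.array_split(np.arange(config.n_genes), config.n_blocks)
    block_idx = np.empty(config.n_genes, dtype=int)
    for b, idx in enumerate(block_of):
        block_idx[idx] = b
    type_of = np.array_split(np.arange(config.n_cells), config.n_cell_types)
    type_idx = np.empty(config.n_cells, dtype=int)
    for t, idx in enumerate(type_of):
        type_idx[idx] = t
    type_names = [f"type{t+1}" for t in range(config.n_cell_types)]

    base = rng.uniform(*config.base_mean_range, size=config.n_blocks)
    means = np.tile(base[:, None], (1, config.n_cell_types))
    differential = list(range(config.n_differential_blocks))
    for i, b in enumerate(differential):
        means[b, i % config.n_cell_types] += config.block_mean_shift

    mu = means[block_idx][:, type_idx]  # genes x cells
    values = mu + rng.normal(0.0, config.noise_sd, size=mu.shape) if config.noise_sd > 0 else mu.copy()
    values = np.maximum(values, 0.0)
    if config.dropout_rate > 0:
        values[rng.random(values.shape) < config.dropout_rate] = 0.0

    matrix = ExpressionMatrix(genes, cells, values, SCALE_LOG_TPM)
    labels = CellLabels({c: type_names[t] for c, t in zip(cells, type_idx)})

    iu, ju = np.triu_indices(config.n_genes, k=1)
    same_block = block_idx[iu] == block_idx[ju]
    p_edge = np.where(same_block, config.ppi_within_block_prob, config.ppi_background_prob)
    drawn = rng.random(p_edge.shape) < p_edge
    ppi = PPINetwork.from_edges(
        (genes[i], genes[j], EDGE_SCORE) for i, j in zip(iu[drawn], ju[drawn])
    )

    truth = SyntheticTruth(
        block_of_gene={g: int(b) for g, b in zip(genes, block_idx)},
        differential_blocks=differential,
        cell_types=dict(labels.labels),
        block_means=means,
    )
    return matrix, labels, ppi, truth
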