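"""Readers and writers for the external formats the pipeline consumes.

Expression matrices are dense TSV (genes in rows, cells in columns) or
MatrixMarket coordinate triplets with ``genes.txt`` / ``barcodes.txt``
sidecars.  Protein interaction networks come as STRING-style links files
(``protein1 protein2 combined_score``), optionally translated to gene
symbols through a two-column alias file.  Gene sets are one identifier
per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("diffge")

SCALE_TPM = "tpm"
SCALE_LOG_TPM = "log_tpm"
_VALID_SCALES = (SCALE_TPM, SCALE_LOG_TPM)


def _find_duplicate(items: Sequence[str]) -> Optional[str]:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """A genes x cells non-negative expression matrix.

    ``scale`` records whether values are raw TPM or log-transformed
    (``log2(TPM + 1)``); the transform guard in :mod:`diffge.preprocess`
    relies on it.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_VALID_SCALES}")
        dup = _find_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        dup = _find_duplicate(self.cells)
        if dup is not None:
            raise ValueError(f"duplicate cell identifier: {dup!r}")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at gene {self.genes[r]!r}, cell {self.cells[c]!r}")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(f"negative value at gene {self.genes[r]!r}, cell {self.cells[c]!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.cells), self.values[rows, :], self.scale)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        index = {c: i for i, c in enumerate(self.cells)}
        cols = [index[c] for c in cells]
        return ExpressionMatrix(list(self.genes), list(cells), self.values[:, cols], self.scale)


@dataclass
class CellLabels:
    """Cell identifier -> cell-type label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    def __getitem__(self, cell: str) -> str:
        return self.labels[cell]

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def types(self) -> list[str]:
        """Distinct labels, in first-appearance order."""
        return list(dict.fromkeys(self.labels.values()))

    def subset(self, cells: Iterable[str]) -> "CellLabels":
        return CellLabels({c: self.labels[c] for c in cells})

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [c for c in matrix.cells if c not in self.labels]
        if missing:
            raise ValueError(f"{len(missing)} cells lack a label (first: {missing[0]!r})")
        extra = set(self.labels) - set(matrix.cells)
        if extra:
            raise ValueError(
                f"{len(extra)} labeled cells absent from expression matrix "
                f"(first: {sorted(extra)[0]!r})"
            )


@dataclass
class PPINetwork:
    """Undirected gene-level interaction graph with STRING-style scores.

    Backed by a :class:`networkx.Graph`; edge scores live in the ``score``
    attribute and follow the STRING combined-score convention (0-1000).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b, score in edges:
            a, b = str(a), str(b)
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], float(score))
            else:
                g.add_edge(a, b, score=float(score))
        return cls(g)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def edges_within(self, genes: Iterable[str]) -> list[tuple[str, str]]:
        """Edges with both endpoints in ``genes``, canonical (sorted) order."""
        members = set(genes)
        sub = self.graph.subgraph(members)
        return sorted(tuple(sorted(e)) for e in sub.edges)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, format: str = "tsv", scale: str = SCALE_TPM) -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``mtx_triplet`` format.

    TSV layout: first column = gene IDs, header row = cell IDs.  MTX layout:
    a MatrixMarket coordinate file with ``genes.txt`` and ``barcodes.txt``
    sidecars in the same directory (one identifier per line, matrix rows =
    genes).
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: no data rows") from None
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"{path}: no data rows")
        dup = _find_duplicate([str(g) for g in df.index])
        if dup is not None:
            raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[int(np.argmax(bad.isna().to_numpy()))]
                raise ValueError(f"{path}: non-numeric value at gene {row!r}, cell {col!r}")
        values = df.to_numpy(dtype=float)
        return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values, scale)
    if format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_lines(path.parent / "genes.txt")
        cells = _read_lines(path.parent / "barcodes.txt")
        return ExpressionMatrix(genes, cells, np.asarray(mat, dtype=float), scale)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# cell labels


def read_cell_labels(path: str | Path) -> CellLabels:
    """Two-column TSV: cell identifier, cell-type label.  Header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = df.iloc[0]
    if str(first.iloc[0]).lower() in ("cell", "cell_id", "barcode"):
        df = df.iloc[1:]
    return CellLabels(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_cell_labels(labels: CellLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell, lab in labels.labels.items():
            fh.write(f"{cell}\t{lab}\n")


# ---------------------------------------------------------------------------
# PPI networks


def read_alias(path: str | Path) -> dict[str, str]:
    """Protein ID -> gene symbol.  Collisions resolved first-wins (warned)."""
    mapping: dict[str, str] = {}
    n_collisions = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2 or parts[0].startswith("#"):
                continue
            protein, gene = parts[0], parts[1]
            if protein in mapping:
                if mapping[protein] != gene:
                    n_collisions += 1
                continue
            mapping[protein] = gene
    if n_collisions:
        logger.warning("alias file %s: %d proteins mapped to multiple genes; kept first mapping", path, n_collisions)
    return mapping


def read_ppi(
    links_path: str | Path,
    alias_path: Optional[str | Path] = None,
    min_score: int = 400,
) -> PPINetwork:
    """Read a STRING-dialect protein-links file into a gene-level network.

    Accepts space- or tab-delimited files; a header row is auto-detected by
    a non-numeric score field.  Edges below ``min_score`` are dropped, IDs
    are translated through the alias map when given (unmapped endpoints drop
    the edge), self-loops are removed and reciprocal duplicates collapsed
    keeping the maximum score.
    """
    if not 0 <= min_score <= 1000:
        raise ValueError("min_score must be in [0, 1000]")
    alias = read_alias(alias_path) if alias_path is not None else None
    edges: list[tuple[str, str, float]] = []
    n_unmapped = 0
    n_below = 0
    with open(links_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{links_path}:{lineno}: expected >=3 columns, got {len(parts)}")
            a, b, raw_score = parts[0], parts[1], parts[2]
            try:
                score = float(raw_score)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{links_path}:{lineno}: malformed score {raw_score!r}") from None
            if score < min_score:
                n_below += 1
                continue
            if alias is not None:
                if a not in alias or b not in alias:
                    n_unmapped += 1
                    continue
                a, b = alias[a], alias[b]
            edges.append((a, b, score))
    if n_unmapped:
        logger.info("read_ppi: dropped %d edges with unmapped endpoints", n_unmapped)
    logger.info("read_ppi: dropped %d edges below score %d", n_below, min_score)
    return PPINetwork.from_edges(edges)


def write_ppi(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a} {b} {network.graph[a][b]['score']:.0f}\n")


# ---------------------------------------------------------------------------
# gene sets and result tables


def read_gene_set(path: str | Path) -> set[str]:
    genes = {line.strip() for line in open(path) if line.strip()}
    if not genes:
        raise ValueError(f"{path}: empty gene set")
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a result table as TSV with a header row."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
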