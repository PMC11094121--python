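"""Readers, writers and filters for expression matrices, gene networks and gene sets.

Expression data are normalized, non-negative gene-by-cell matrices, one per
*cell condition* (a cell line at one differentiation time point). Molecular
interaction networks are simple undirected gene graphs; four kinds are
integrated: protein-protein interaction (PPI), genetic interaction (GI),
co-expression (COEX) and metabolic interaction (MI). Gene sets (annotations,
known disease genes, pathways) travel in GMT files.

Gene identifiers are case-sensitive opaque strings; no symbol-to-ID mapping
is performed here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

NETWORK_KINDS = ("PPI", "GI", "COEX", "MI")


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, negatives, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Non-negative normalized counts for one cell condition.

    Rows are genes, columns are cells. ``condition`` is a ``(line, day)``
    pair, e.g. ``("control", 0)``; it is metadata only and never affects
    computation.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    condition: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def expressed_genes(self) -> set[str]:
        """Genes with at least one strictly positive entry."""
        mask = (self.values > 0).any(axis=1)
        return {g for g, m in zip(self.gene_ids, mask) if m}

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Keep the given genes, preserving the current row order."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            values=self.values[idx, :],
            condition=self.condition,
        )


@dataclass
class InteractionNetwork:
    """Simple undirected gene graph of one network kind.

    Edges are stored as sorted 2-tuples of gene ids; self-loops and
    duplicate/reversed edges are rejected by the invariant check.
    """

    kind: str
    node_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        _check_unique(self.node_ids, "node")
        nodes = set(self.node_ids)
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if u not in nodes or v not in nodes:
                raise ValidationError(f"edge endpoint not in node set: ({u!r}, {v!r})")
            canon.add((u, v) if u <= v else (v, u))
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.node_ids}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense binary adjacency matrix in the given gene order.

        Genes in ``order`` absent from the network get all-zero rows, so the
        matrix always aligns with an expression matrix's row order.
        """
        if order is None:
            order = self.node_ids
        pos = {g: i for i, g in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for u, v in self.edges:
            if u in pos and v in pos:
                A[pos[u], pos[v]] = 1.0
                A[pos[v], pos[u]] = 1.0
        return A

    def induce(self, genes: Iterable[str]) -> "InteractionNetwork":
        """Subgraph on ``node_ids`` ∩ ``genes``; keeps node order."""
        keep = set(genes)
        nodes = [g for g in self.node_ids if g in keep]
        edges = {(u, v) for u, v in self.edges if u in keep and v in keep}
        return InteractionNetwork(kind=self.kind, node_ids=nodes, edges=edges)


@dataclass
class GeneSetCollection:
    """Named gene sets (annotations, pathways, disease genes)."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if any(not isinstance(g, str) or not g for g in members):
                raise ValidationError(f"gene set {name!r} has invalid members")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ConditionInputs:
    """One cell condition's expression matrix plus its four aligned networks."""

    expression: ExpressionMatrix
    networks: dict[str, InteractionNetwork]

    def __post_init__(self) -> None:
        if set(self.networks) != set(NETWORK_KINDS):
            raise ValidationError(
                f"networks must cover kinds {NETWORK_KINDS}, got {sorted(self.networks)}"
            )
        genes = set(self.expression.gene_ids)
        for kind, net in self.networks.items():
            extra = set(net.node_ids) - genes
            if extra:
                raise ValidationError(
                    f"{kind} network has nodes outside the expression gene set, "
                    f"e.g. {sorted(extra)[:3]}"
                )

    def matrices(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """(E, [A_PPI, A_GI, A_COEX, A_MI]) in expression row order."""
        order = self.expression.gene_ids
        return self.expression.values, [
            self.networks[k].adjacency(order) for k in NETWORK_KINDS
        ]


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path,
    format: str = "dense_table",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    condition: tuple[str, int] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``format="dense_table"``: TSV with a header row of cell ids and a first
    column of gene ids. ``format="mtx_triplet"``: MatrixMarket file with
    accompanying one-column ``genes_path`` / ``cells_path`` label files
    (defaults: ``genes.tsv`` / ``cells.tsv`` next to the matrix).
    """
    path = Path(path)
    if format == "dense_table":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"cannot parse dense table {path}: {exc}") from exc
        return ExpressionMatrix(
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            condition=condition,
        )
    if format == "mtx_triplet":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "cells.tsv"
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise ParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        genes = _read_label_column(genes_path)
        cells = _read_label_column(cells_path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        return ExpressionMatrix(genes, cells, values, condition=condition)
    raise ValueError(f"unknown expression format {format!r}")


def _read_label_column(path: Path) -> list[str]:
    labels = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            labels.append(line.split("\t")[0])
            if not labels[-1]:
                raise ParseError(f"{path}:{lineno}: empty label")
    return labels


def write_expression(
    e: ExpressionMatrix, path: str | Path, format: str = "dense_table"
) -> None:
    path = Path(path)
    if format == "dense_table":
        df = pd.DataFrame(e.values, index=e.gene_ids, columns=e.cell_ids)
        df.to_csv(path, sep="\t")
        return
    if format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(e.values))
        (path.parent / "genes.tsv").write_text(
            "".join(g + "\n" for g in e.gene_ids), encoding="utf-8"
        )
        (path.parent / "cells.tsv").write_text(
            "".join(c + "\n" for c in e.cell_ids), encoding="utf-8"
        )
        return
    raise ValueError(f"unknown expression format {format!r}")


def read_edge_list(path: str | Path, kind: str) -> InteractionNetwork:
    """Read a 2-column (optionally weighted) TSV edge list.

    Self-loops are dropped; duplicate and reversed-duplicate edges collapse
    to one. Edge weights, if present, are discarded: adjacency is binary.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least two columns")
            u, v = parts[0], parts[1]
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: empty gene identifier")
            nodes.setdefault(u)
            nodes.setdefault(v)
            if u == v:
                continue
            edges.add((u, v) if u <= v else (v, u))
    return InteractionNetwork(kind=kind, node_ids=list(nodes), edges=edges)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
        # isolated nodes are not representable in a plain edge list


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# filters and network construction


def filter_expressed_genes(
    e: ExpressionMatrix,
    protein_coding: Iterable[str],
    ppi: InteractionNetwork,
) -> ExpressionMatrix:
    """Keep protein-coding genes with >= 1 PPI that are expressed in ``e``.

    "Expressed" means at least one strictly positive entry in this
    condition's matrix. Row order of survivors is preserved.
    """
    coding = set(protein_coding)
    deg = ppi.degrees()
    expressed = e.expressed_genes()
    keep = [
        g
        for g in e.gene_ids
        if g in coding and deg.get(g, 0) >= 1 and g in expressed
    ]
    if not keep:
        raise ValidationError("no gene passes the coding/PPI/expression filters")
    return e.restrict_genes(keep)


def induce_condition_network(
    net: InteractionNetwork, genes: Iterable[str]
) -> InteractionNetwork:
    """Restrict a global network to the genes of one cell condition."""
    return net.induce(genes)


def build_mi_from_pathways(pathways: GeneSetCollection) -> InteractionNetwork:
    """Metabolic-interaction network: connect genes sharing a pathway."""
    nodes: dict[str, None] = {}
    edges: set[tuple[str, str]] = set()
    for members in pathways.sets.values():
        ordered = sorted(members)
        for g in ordered:
            nodes.setdefault(g)
        for u, v in itertools.combinations(ordered, 2):
            edges.add((u, v))
    return InteractionNetwork(kind="MI", node_ids=list(nodes), edges=edges)


def build_coex_from_correlation(
    corr: pd.DataFrame, top_fraction: float = 0.01
) -> InteractionNetwork:
    """Co-expression network from the strongest pairwise correlations.

    Keeps the ``ceil(top_fraction * P)`` unordered gene pairs with the
    largest absolute correlation, among all P = n(n-1)/2 pairs (diagonal
    ignored). Ties at the cutoff break by lexicographic pair order.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    genes = [str(g) for g in corr.index]
    if list(corr.columns.astype(str)) != genes:
        raise ValidationError("correlation matrix must have matching row/column labels")
    vals = corr.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    pairs = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        u, v = genes[i], genes[j]
        if u > v:
            u, v = v, u
        pairs.append((abs(vals[i, j]), (u, v)))
    n_keep = int(np.ceil(top_fraction * len(pairs)))
    # sort by |corr| descending, then lexicographic pair order for determinism
    pairs.sort(key=lambda t: (-t[0], t[1]))
    edges = {p for _, p in pairs[:n_keep]}
    return InteractionNetwork(kind="COEX", node_ids=genes, edges=edges)
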