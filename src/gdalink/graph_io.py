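"""Read gene–disease association (GDA) edge lists and build bipartite graphs.

A GDA network is an undirected bipartite graph: one partition holds gene
nodes (e.g. Entrez GeneIDs or symbols), the other disease nodes (e.g. UMLS
CUIs), and every edge is one curated gene–disease association, optionally
carrying an evidence score in [0, 1].

Identifiers are kept as opaque strings end-to-end; numeric encoding happens
only inside the model's arrays, never on the identifiers themselves.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

GENE = "gene"
DISEASE = "disease"


@dataclass(frozen=True)
class GdaRecord:
    """One gene–disease association.

    Parameters
    ----------
    gene_id, disease_id
        Non-empty identifier strings, preserved verbatim.
    weight
        Association score in [0, 1]; 1.0 for unweighted exports.
    """

    gene_id: str
    disease_id: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.gene_id or not self.disease_id:
            raise ValidationError("gene_id and disease_id must be non-empty")
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(
                f"weight {self.weight!r} outside [0, 1] for "
                f"({self.gene_id}, {self.disease_id})"
            )


@dataclass
class BipartiteGraph:
    """Indexed undirected bipartite gene–disease graph.

    Genes occupy indices ``0 .. n_genes-1`` (first-appearance order), diseases
    ``n_genes .. n-1``.  Edges are stored as an ``(m, 2)`` integer array whose
    first column is always the gene index, so the adjacency block structure is
    explicit and runs are reproducible.
    """

    node_ids: list[str]
    n_genes: int
    n_diseases: int
    edges: np.ndarray  # (m, 2) int64, [:, 0] gene idx < n_genes, [:, 1] disease idx
    weights: np.ndarray  # (m,) float64 in [0, 1]
    node_index: dict[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return self.n_genes + self.n_diseases

    @property
    def m(self) -> int:
        return int(self.edges.shape[0])

    def partition_of(self, idx: int) -> str:
        return GENE if idx < self.n_genes else DISEASE

    @property
    def gene_ids(self) -> list[str]:
        return self.node_ids[: self.n_genes]

    @property
    def disease_ids(self) -> list[str]:
        return self.node_ids[self.n_genes:]

    def edge_keys(self) -> np.ndarray:
        """Each edge as a single integer gi * n_diseases + (dj - n_genes)."""
        return self.edges[:, 0] * self.n_diseases + (self.edges[:, 1] - self.n_genes)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.edges.tolist()))

    def degrees(self) -> np.ndarray:
        """Degree of every node, aligned with the node index."""
        return np.bincount(self.edges.ravel(), minlength=self.n)

    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError on breach."""
        e = self.edges
        if e.ndim != 2 or (e.size and e.shape[1] != 2):
            raise ValidationError("edges must be an (m, 2) array")
        if e.size:
            if e[:, 0].min() < 0 or e[:, 0].max() >= self.n_genes:
                raise ValidationError("edge endpoint 0 must be a gene index")
            if e[:, 1].min() < self.n_genes or e[:, 1].max() >= self.n:
                raise ValidationError("edge endpoint 1 must be a disease index")
            if len(np.unique(self.edge_keys())) != self.m:
                raise ValidationError("duplicate edges present")
        if self.weights.shape != (self.m,):
            raise ValidationError("weights misaligned with edges")
        if self.m and (self.weights.min() < 0 or self.weights.max() > 1):
            raise ValidationError("edge weights outside [0, 1]")
        if len(self.node_ids) != self.n or len(self.node_index) != self.n:
            raise ValidationError("node index inconsistent with n_genes + n_diseases")

    def summary(self) -> dict:
        return {
            "n": self.n,
            "n_genes": self.n_genes,
            "n_diseases": self.n_diseases,
            "m": self.m,
        }


def read_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    has_header: bool = False,
    weight_column: str | int | None = None,
) -> list[GdaRecord]:
    """Parse a delimited GDA edge list into records.

    The first two columns are the gene and disease identifiers.  A weight
    column may be named (requires a header) or given as a 0-based index;
    without one, every association gets weight 1.

    Raises
    ------
    ParseError
        Missing file, a data row with fewer than two columns, or an
        unresolvable weight column — the message names the offending line.
    ValidationError
        A weight outside [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"edge list not found: {path}")

    records: list[GdaRecord] = []
    widx: int | None = weight_column if isinstance(weight_column, int) else None
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if has_header and lineno == 1:
                if isinstance(weight_column, str):
                    names = [c.strip() for c in row]
                    if weight_column not in names:
                        raise ParseError(
                            f"{path}:1: weight column {weight_column!r} "
                            f"not in header {names}"
                        )
                    widx = names.index(weight_column)
                continue
            if isinstance(weight_column, str) and not has_header:
                raise ParseError(
                    f"{path}: named weight column {weight_column!r} requires a header"
                )
            if len(row) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 columns, got {len(row)}"
                )
            gene_id, disease_id = row[0].strip(), row[1].strip()
            weight = 1.0
            if widx is not None:
                if widx >= len(row):
                    raise ParseError(
                        f"{path}:{lineno}: weight column {widx} out of range"
                    )
                try:
                    weight = float(row[widx])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {row[widx]!r}"
                    ) from exc
            try:
                records.append(GdaRecord(gene_id, disease_id, weight))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        logger.warning("edge list %s contained no data rows", path)
    return records


def build_bipartite_graph(records: Sequence[GdaRecord]) -> BipartiteGraph:
    """Index records into a BipartiteGraph.

    Genes are indexed first (in order of first appearance), then diseases.
    Duplicate (gene, disease) pairs collapse to a single edge keeping the
    maximum weight — curated exports can repeat a GDA across evidence sources.

    Raises
    ------
    ValidationError
        Empty input, or an identifier used as both a gene and a disease.
    """
    if not records:
        raise ValidationError("cannot build a graph from zero records")

    gene_index: dict[str, int] = {}
    disease_order: dict[str, int] = {}
    for r in records:
        if r.gene_id not in gene_index:
            gene_index[r.gene_id] = len(gene_index)
        if r.disease_id not in disease_order:
            disease_order[r.disease_id] = len(disease_order)

    overlap = gene_index.keys() & disease_order.keys()
    if overlap:
        raise ValidationError(
            f"identifier(s) in both partitions: {sorted(overlap)[:5]}"
        )

    n_genes = len(gene_index)
    node_index = dict(gene_index)
    for did, k in disease_order.items():
        node_index[did] = n_genes + k
    node_ids = [None] * len(node_index)
    for nid, i in node_index.items():
        node_ids[i] = nid

    # collapse duplicates to max weight, keeping first-appearance edge order
    # so write_edge_list -> read_edge_list round-trips to identical indexing
    best: dict[tuple[int, int], float] = {}
    for r in records:
        key = (gene_index[r.gene_id], node_index[r.disease_id])
        prev = best.get(key)
        if prev is None or r.weight > prev:
            best[key] = r.weight

    keys = list(best)
    edges = np.array(keys, dtype=np.int64).reshape(-1, 2)
    weights = np.array([best[k] for k in keys], dtype=np.float64)

    graph = BipartiteGraph(
        node_ids=node_ids,
        n_genes=n_genes,
        n_diseases=len(disease_order),
        edges=edges,
        weights=weights,
        node_index=node_index,
    )
    graph.validate()
    return graph


def write_edge_list(graph: BipartiteGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write the graph back to a three-column (gene, disease, weight) file."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        for (gi, dj), w in zip(graph.edges, graph.weights):
            writer.writerow([graph.node_ids[gi], graph.node_ids[dj], repr(float(w))])


def degree_stats(graph: BipartiteGraph, top_k: int = 10) -> pd.DataFrame:
    """Top-k nodes per partition by degree (hub table).

    Rows are sorted degree-descending within each partition, ties broken by
    node id lexicographically; asking for more rows than a partition holds
    returns the whole partition.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    deg = graph.degrees()
    rows = []
    for part, lo, hi in ((GENE, 0, graph.n_genes), (DISEASE, graph.n_genes, graph.n)):
        entries = sorted(
            ((graph.node_ids[i], int(deg[i])) for i in range(lo, hi)),
            key=lambda t: (-t[1], t[0]),
        )
        rows.extend((nid, part, d) for nid, d in entries[:top_k])
    return pd.DataFrame(rows, columns=["node_id", "partition", "degree"])


def records_from_pairs(
    pairs: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]]
) -> list[GdaRecord]:
    """Convenience: build records from (gene, disease[, weight]) tuples."""
    return [GdaRecord(*p) for p in pairs]


def write_graph_summary(graph: BipartiteGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph.summary(), indent=2) + "\n")
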