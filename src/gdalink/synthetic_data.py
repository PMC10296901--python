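"""Synthetic bipartite gene–disease networks for fully offline runs.

Real curated GDA networks are sparse, clustered (disease modules share
genes) and hub-dominated (a handful of pleiotropic genes and common
diseases carry very high degree).  Two generators emulate this:

* a planted bipartite block model — genes and diseases are assigned to
  latent blocks, matched blocks connect with probability ``p_in`` and
  unmatched with ``p_out``; optional heavy-tailed per-node propensities add
  hub structure;
* an Erdős–Rényi bipartite null with no structure at all, used to verify
  that the pipeline cannot manufacture signal where none exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .graph_io import BipartiteGraph, GdaRecord, build_bipartite_graph


@dataclass
class BlockModelSpec:
    """Parameters of the planted bipartite block model.

    degree_skew >= 0 adds per-node propensities u^(−1/(1+skew)) (u uniform),
    normalised to mean 1, giving Pareto-like heavy-tailed degrees; 0 or None
    leaves degrees homogeneous within blocks.
    """

    n_genes: int
    n_diseases: int
    k_blocks: int
    p_in: float
    p_out: float
    seed: int
    degree_skew: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValidationError("need 0 <= p_out <= p_in <= 1")
        if self.k_blocks < 1 or self.k_blocks > min(self.n_genes, self.n_diseases):
            raise ValidationError("k_blocks must be in [1, min(n_genes, n_diseases)]")
        if self.degree_skew is not None and self.degree_skew < 0:
            raise ValidationError("degree_skew must be >= 0")


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _graph_from_mask(
    mask: np.ndarray, gene_ids: list[str], disease_ids: list[str]
) -> BipartiteGraph:
    gi, dj = np.nonzero(mask)
    if len(gi) < 10:
        raise ValidationError(
            f"generated only {len(gi)} edges; too sparse to train on"
        )
    records = [GdaRecord(gene_ids[g], disease_ids[d]) for g, d in zip(gi, dj)]
    # ensure every node appears so the index covers isolated nodes too:
    # nodes with zero edges simply don't exist in an edge-list world, which
    # matches how real exports behave; no padding records are added.
    return build_bipartite_graph(records)


def generate_block_bipartite(
    spec: BlockModelSpec,
) -> tuple[BipartiteGraph, dict[str, int]]:
    """Sample a planted-block bipartite graph; returns (graph, block labels).

    Each gene and disease is assigned uniformly to one of ``k_blocks``;
    matched-block pairs connect with ``p_in``, others with ``p_out``
    (scaled by node propensities when ``degree_skew`` is set, capped at 1).
    Identical seeds reproduce identical edge sets.
    """
    rng = np.random.default_rng(spec.seed)
    gene_blocks = rng.integers(spec.k_blocks, size=spec.n_genes)
    disease_blocks = rng.integers(spec.k_blocks, size=spec.n_diseases)

    prob = np.where(
        gene_blocks[:, None] == disease_blocks[None, :], spec.p_in, spec.p_out
    ).astype(np.float64)
    if spec.degree_skew is not None and spec.degree_skew > 0:
        prob = prob * _propensities(rng, spec.n_genes, spec.degree_skew)[:, None]
        prob = prob * _propensities(rng, spec.n_diseases, spec.degree_skew)[None, :]
        np.clip(prob, 0.0, 1.0, out=prob)

    expected = float(prob.sum())
    if expected < 10:
        raise ValidationError(
            f"expected edge count {expected:.1f} < 10; graph would be untrainable"
        )
    mask = rng.random(prob.shape) < prob
    gene_ids = _ids("g", spec.n_genes)
    disease_ids = _ids("d", spec.n_diseases)
    graph = _graph_from_mask(mask, gene_ids, disease_ids)
    blocks = {gid: int(b) for gid, b in zip(gene_ids, gene_blocks)}
    blocks.update({did: int(b) for did, b in zip(disease_ids, disease_blocks)})
    return graph, blocks


def _propensities(rng: np.random.Generator, n: int, skew: float) -> np.ndarray:
    """Heavy-tailed per-node propensity u^(−1/(1+skew)), normalised to mean 1."""
    u = rng.random(n)
    a = u ** (-1.0 / (1.0 + skew))
    return a / a.mean()


def generate_er_bipartite(
    n_genes: int, n_diseases: int, p: float, seed: int
) -> BipartiteGraph:
    """Erdős–Rényi bipartite null: every pair is an edge independently w.p. p."""
    if not 0 < p < 1:
        raise ValidationError("need 0 < p < 1")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_genes, n_diseases)) < p
    return _graph_from_mask(mask, _ids("g", n_genes), _ids("d", n_diseases))


def write_blocks_tsv(blocks: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("node_id\tblock\n")
        for nid, b in blocks.items():
            fh.write(f"{nid}\t{b}\n")
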