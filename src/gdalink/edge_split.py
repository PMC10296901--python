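"""Train/validation/test edge splits with negative-link sampling.

The decoder is a binary classifier, so held-out evaluation needs both
positive edges (withheld associations) and negative links (gene–disease
pairs absent from the observed network).  Held-out positives and negatives
are excluded from everything the model sees during training: the
message-passing adjacency is built from training positives only, and
per-epoch training negatives avoid the held-out negative pools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .graph_io import BipartiteGraph


@dataclass
class EdgeSplit:
    """Disjoint positive splits plus held-out negative pairs.

    All arrays are (k, 2) int64 index pairs (gene index, disease index)
    in the graph's node indexing.
    """

    train_pos: np.ndarray
    val_pos: np.ndarray
    test_pos: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray
    seed: int

    def counts(self) -> dict[str, int]:
        return {
            "train_pos": len(self.train_pos),
            "val_pos": len(self.val_pos),
            "test_pos": len(self.test_pos),
            "val_neg": len(self.val_neg),
            "test_neg": len(self.test_neg),
        }


def _pair_keys(pairs: np.ndarray, graph: BipartiteGraph) -> np.ndarray:
    return pairs[:, 0] * graph.n_diseases + (pairs[:, 1] - graph.n_genes)


def _sample_nonedges(
    graph: BipartiteGraph,
    count: int,
    forbidden: set[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample `count` distinct gene–disease pairs whose keys avoid `forbidden`.

    Uses rejection sampling on sparse graphs and falls back to full
    enumeration when the free pool is small relative to the request.
    """
    ng, nd = graph.n_genes, graph.n_diseases
    universe = ng * nd
    available = universe - len(forbidden)
    if count > available:
        raise ValidationError(
            f"requested {count} negative pairs but only {available} "
            "gene-disease non-pairs are available"
        )
    if count == 0:
        return np.empty((0, 2), dtype=np.int64)

    keys: list[int] = []
    if count > available // 2:
        # dense regime: enumerate the free pool and choose without replacement
        mask = np.ones(universe, dtype=bool)
        if forbidden:
            mask[np.fromiter(forbidden, dtype=np.int64, count=len(forbidden))] = False
        pool = np.flatnonzero(mask)
        keys = rng.choice(pool, size=count, replace=False)
    else:
        seen: set[int] = set()
        out: list[int] = []
        while len(out) < count:
            batch = rng.integers(0, universe, size=2 * (count - len(out)) + 8)
            for k in batch:
                k = int(k)
                if k in forbidden or k in seen:
                    continue
                seen.add(k)
                out.append(k)
                if len(out) == count:
                    break
        keys = np.asarray(out, dtype=np.int64)

    keys = np.asarray(keys, dtype=np.int64)
    pairs = np.column_stack([keys // nd, keys % nd + ng])
    return pairs


def split_edges(
    graph: BipartiteGraph,
    val_frac: float = 0.05,
    test_frac: float = 0.10,
    seed: int = 42,
) -> EdgeSplit:
    """Partition edges into train/val/test and sample 1:1 held-out negatives.

    ``round(val_frac * m)`` edges go to validation and ``round(test_frac * m)``
    to test, drawn uniformly without replacement; each held-out set receives
    an equal number of negative links.  The same seed always reproduces the
    same split.
    """
    if val_frac < 0 or test_frac < 0 or val_frac + test_frac >= 1:
        raise ValidationError("need val_frac, test_frac >= 0 and their sum < 1")
    m = graph.m
    if m < 10:
        raise ValidationError(f"graph has only {m} edges; need >= 10 to split")

    n_val = round(val_frac * m)
    n_test = round(test_frac * m)
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    val_pos = graph.edges[order[:n_val]]
    test_pos = graph.edges[order[n_val : n_val + n_test]]
    train_pos = graph.edges[order[n_val + n_test :]]

    forbidden = set(map(int, graph.edge_keys()))
    negs = _sample_nonedges(graph, n_val + n_test, forbidden, rng)
    return EdgeSplit(
        train_pos=train_pos,
        val_pos=val_pos,
        test_pos=test_pos,
        val_neg=negs[:n_val],
        test_neg=negs[n_val:],
        seed=seed,
    )


def sample_training_negatives(
    graph: BipartiteGraph,
    split: EdgeSplit,
    count: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw fresh training negatives: non-edges avoiding the held-out pools.

    Called once per epoch so the model never memorises a fixed negative set.
    `rng` may be a Generator (shared across epochs) or an integer seed.
    """
    if count < 0:
        raise ValidationError("count must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    forbidden = set(map(int, graph.edge_keys()))
    for held in (split.val_neg, split.test_neg):
        if len(held):
            forbidden.update(map(int, _pair_keys(held, graph)))
    return _sample_nonedges(graph, count, forbidden, rng)


def save_split(split: EdgeSplit, graph: BipartiteGraph, outdir: str | Path) -> None:
    """Serialize to TSV edge lists plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("train_pos", "val_pos", "test_pos", "val_neg", "test_neg"):
        pairs = getattr(split, name)
        with (outdir / f"{name}.tsv").open("w") as fh:
            for gi, dj in pairs:
                fh.write(f"{graph.node_ids[gi]}\t{graph.node_ids[dj]}\n")
    manifest = {"seed": split.seed, **split.counts()}
    (outdir / "split_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
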