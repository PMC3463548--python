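"""Neighbor-joining clustering of a distance matrix and species-cluster checks.

The NJ tree summarizes the distance matrix; it is a clustering diagram, not a
phylogenetic hypothesis.  Species-cluster status asks, for each species,
whether some edge of the unrooted tree separates exactly that species' leaves
from everything else (reciprocal monophyly on the distance tree).
"""

from __future__ import annotations

import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from tagbarcode.distance import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "write_newick",
    "species_cluster_status",
    "cluster_status_table",
]


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on a fully defined distance matrix.

    Taxa are presented to the agglomeration in lexicographic id order, so
    the result is independent of the input ordering of sequences.  Negative
    branch-length estimates are clamped to zero.  Undefined (NaN) entries
    are rejected: callers must exclude the offending sequences first.
    """
    if dm.undefined_pairs or pd.DataFrame(dm.values).isna().any().any():
        raise ValueError(
            "distance matrix has undefined entries; exclude these pairs before "
            f"tree building: {dm.undefined_pairs}"
        )
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(dm.n), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    sub = dm.values[order][:, order]
    tree = _skbio_nj(SkbioDM(sub, ids))
    return tree


def write_newick(tree: TreeNode, path) -> None:
    """Serialize with branch lengths, no support values."""
    tree.write(str(path), format="newick")


def species_cluster_status(tree: TreeNode, labels: dict[str, str]) -> dict[str, str]:
    """Classify each species as 'single_cluster' or 'split' on an unrooted tree.

    A species is a single cluster iff its leaf set equals one side of some
    edge bipartition; singleton species (and a species covering every leaf)
    are single clusters by convention.

    Raises on leaves absent from ``labels``.
    """
    leaves = [t.name for t in tree.tips()]
    unlabeled = [l for l in leaves if l not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {sorted(unlabeled)}")
    all_leaves = frozenset(leaves)
    species_sets: dict[str, frozenset] = {}
    for leaf in leaves:
        sp = labels[leaf]
        species_sets[sp] = species_sets.get(sp, frozenset()) | {leaf}

    # every edge's bipartition: the clade below each non-root node vs the rest
    sides = set()
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        sides.add(clade)
        sides.add(all_leaves - clade)

    status = {}
    for sp, members in species_sets.items():
        mono = len(members) == 1 or members == all_leaves or members in sides
        status[sp] = "single_cluster" if mono else "split"
    return status


def cluster_status_table(status: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"species": sp, "status": st} for sp, st in sorted(status.items())]
    )
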