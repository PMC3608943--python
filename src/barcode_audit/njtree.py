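"""Neighbour-joining dendrograms with nonparametric bootstrap support.

The Saitou-Nei agglomeration is implemented directly so that tie-breaking
(lowest label pair, lexicographically) and negative-branch handling
(clamp to zero, transferring the length to the sister edge) are
deterministic and documented; trees are carried as dendropy objects for
newick round-tripping.  Bootstrap support resamples alignment columns with
replacement, rebuilds the K2P matrix and NJ tree per pseudoreplicate, and
maps bipartition frequencies back onto the tree built from the original
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from barcode_audit.distances import (
    DistanceMatrix,
    encode,
    k2p_matrix_from_encoded,
    pairwise_matrix,
)

_TIE_TOL = 1e-12


@dataclass
class Tree:
    """An unrooted specimen tree with optional per-edge bootstrap supports."""

    _dtree: dendropy.Tree
    #: dropped bootstrap pseudoreplicates (saturated pairs), if any
    dropped_replicates: int = 0

    @property
    def labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._dtree.leaf_node_iter()]

    def newick(self) -> str:
        return self._dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    @classmethod
    def from_newick(cls, source: str) -> "Tree":
        dtree = dendropy.Tree.get(data=source, schema="newick")
        return cls(dtree)

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def bipartitions(self) -> dict[frozenset, dendropy.Node]:
        """Non-trivial bipartitions as normalised leaf-label sets.

        Each internal edge splits the leaves in two; the side not
        containing the lexicographically smallest label is the key, so the
        same split hashes identically across trees on the same labels.
        Pendant (trivial) edges are excluded.
        """
        labels = set(self.labels)
        ref = min(labels)
        out: dict[frozenset, dendropy.Node] = {}
        for node in self._dtree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if ref in side:
                side = frozenset(labels - side)
            if 2 <= len(side) <= len(labels) - 2:
                out[side] = node
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length (patristic) distances between all leaf pairs."""
        pdm = self._dtree.phylogenetic_distance_matrix()
        taxa = sorted(self._dtree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        n = len(labels)
        values = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                d = pdm.distance(taxa[a], taxa[b])
                values[a, b] = values[b, a] = d
        return DistanceMatrix(labels, values)

    def supports(self) -> dict[frozenset, float]:
        """Bootstrap support (%) per non-trivial bipartition, if computed."""
        out = {}
        for split, node in self.bipartitions().items():
            if node.label is not None:
                out[split] = float(node.label)
        return out


def _new_leaf(taxon: dendropy.Taxon) -> dendropy.Node:
    node = dendropy.Node(taxon=taxon)
    return node


def nj(dm: DistanceMatrix) -> Tree:
    """Neighbour-joining tree from a complete distance matrix.

    At each step the pair minimising the Q-criterion is joined; exact ties
    are broken by the lexicographically smallest pair of cluster
    representative labels (the representative of a cluster is its smallest
    leaf label), which makes the topology deterministic.  Negative branch
    length estimates are clamped to zero with the length moved to the
    sister edge, preserving the joined pair's distance.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("NJ needs at least 2 labels")
    if not dm.is_complete():
        raise ValueError(
            "distance matrix has undefined (saturated/non-overlapping) pairs; "
            "drop the affected specimens before building a tree"
        )
    namespace = dendropy.TaxonNamespace(dm.labels)
    nodes = [_new_leaf(namespace.get_taxon(l)) for l in dm.labels]
    reps = list(dm.labels)  # representative (smallest leaf) label per cluster
    D = dm.values.copy()
    active = list(range(n))

    def _clamped(b_i: float, b_j: float, dij: float) -> tuple[float, float]:
        if b_i < 0.0:
            b_i, b_j = 0.0, dij
        elif b_j < 0.0:
            b_i, b_j = dij, 0.0
        # dij itself can be (slightly) negative on non-additive inputs
        return max(b_i, 0.0), max(b_j, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + _TIE_TOL * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), (a, b))
            for a, b in cand
            if a < b
        )[1]
        ai, bi = best
        ga, gb = active[ai], active[bi]
        dij = sub[ai, bi]
        b_a = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        b_b = dij - b_a
        b_a, b_b = _clamped(b_a, b_b, dij)
        parent = dendropy.Node()
        parent.add_child(nodes[ga])
        parent.add_child(nodes[gb])
        nodes[ga].edge.length = b_a
        nodes[gb].edge.length = b_b
        # distances from the new node to the remaining clusters
        new_row = 0.5 * (D[ga, active] + D[gb, active] - dij)
        D[ga, active] = new_row
        D[active, ga] = new_row
        D[ga, ga] = 0.0
        nodes[ga] = parent
        reps[ga] = min(reps[ga], reps[gb])
        active.remove(gb)

    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        x_a = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        x_b = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        x_c = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for g, x in ((a, x_a), (b, x_b), (c, x_c)):
            root.add_child(nodes[g])
            nodes[g].edge.length = max(x, 0.0)
    else:  # exactly 2
        a, b = active
        for g in (a, b):
            root.add_child(nodes[g])
            nodes[g].edge.length = max(D[a, b] / 2.0, 0.0)
    dtree = dendropy.Tree(taxon_namespace=namespace, seed_node=root)
    dtree.is_rooted = False
    return Tree(dtree)


def bootstrap_support(
    records: Sequence,
    n_reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """NJ tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    pseudoreplicate is run through K2P + NJ and its bipartitions are
    counted.  Supports (%) are attached to the internal nodes of the tree
    built from the unresampled alignment.  Pseudoreplicates that produce a
    saturated or non-overlapping pair are dropped and counted in
    ``Tree.dropped_replicates``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = pairwise_matrix(records)
    tree = nj(dm)
    labels, seqs = dm.labels, []
    by_id = {
        (r.specimen_id if hasattr(r, "specimen_id") else r[0]): (
            r.sequence if hasattr(r, "sequence") else r[1]
        )
        for r in records
    }
    enc = np.vstack([encode(by_id[l]) for l in labels])
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        values = k2p_matrix_from_encoded(enc[:, cols])
        if np.isnan(values).any():
            dropped += 1
            continue
        rep_tree = nj(DistanceMatrix(list(labels), values))
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    valid = n_reps - dropped
    if valid == 0:
        raise ValueError("every bootstrap pseudoreplicate was saturated")
    for split, node in tree.bipartitions().items():
        node.label = f"{100.0 * counts.get(split, 0) / valid:.1f}"
    tree.dropped_replicates = dropped
    return tree


def is_exclusive_cluster(tree: Tree, species: str, taxonomy: pd.DataFrame) -> bool:
    """True iff the species' specimens form their own subtree.

    Monophyly on the unrooted tree: the specimen set must be one side of
    some edge.  Species with a single specimen on the tree (or owning every
    leaf) are trivially exclusive.
    """
    labels = set(tree.labels)
    members = {
        sid for sid, sp in taxonomy["species"].items() if sp == species and sid in labels
    }
    if not members:
        raise ValueError(f"species {species!r} absent from tree")
    if len(members) == 1 or members == labels:
        return True
    target = frozenset(members)
    ref = min(labels)
    if ref in target:
        target = frozenset(labels - target)
    if len(target) < 2 or len(target) > len(labels) - 2:
        # one side is a single leaf: pendant edge, always a valid split
        return True
    return target in tree.bipartitions()
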