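"""Neighbor-Joining trees with bootstrap support.

NJ follows the Saitou–Nei agglomeration: at each step the pair minimising
the Q criterion is joined; ties are broken by the lexicographically smallest
pair of cluster keys (a cluster's key is its smallest leaf name).  Negative
branch lengths are clamped to zero with a log notice.  The result is an
unrooted tree represented with a trifurcating root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


@dataclass
class TreeNode:
    """A node of a phylogenetic tree; ``length`` is the branch to its parent."""

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None  # percent, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class PhyloTree:
    """An unrooted tree (trifurcating root) over a fixed leaf set."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def newick(self) -> str:
        return self.root.newick()

    def pairwise_path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths along the path between every leaf pair."""
        dists: dict[tuple[str, str], float] = {}
        # distance from every node to each leaf beneath it, then combine at
        # every node acting as the junction of two leaves' paths
        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child in node.children:
                sub = collect(child)
                below.append({k: v + child.length for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for na, da in below[i].items():
                        for nb, db in below[j].items():
                            key = (na, nb) if na < nb else (nb, na)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        collect(self.root)
        return dists

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions, keyed by the leaf set below the edge."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode, is_root: bool) -> None:
            for child in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaf_names())
                    if 1 < len(side) < len(all_leaves) - 1:
                        out[_canonical_split(side, all_leaves)] = child
                walk(child, False)

        walk(self.root, True)
        return out


def _canonical_split(side: frozenset, universe: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not holding the min leaf."""
    anchor = min(universe)
    return frozenset(universe - side) if anchor in side else side


def validate_distance_matrix(d: np.ndarray) -> None:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")


def _clamp(length: float) -> float:
    if length < 0:
        logger.info("negative branch length %.4g clamped to 0", length)
        return 0.0
    return length


def nj_tree(distances: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Saitou–Nei Neighbor-Joining over a symmetric distance matrix.

    Exact on additive matrices: the returned tree's path lengths reproduce
    the input distances.
    """
    d = np.asarray(distances, dtype=float).copy()
    validate_distance_matrix(d)
    if len(ids) != d.shape[0]:
        raise ValueError("ids length must match matrix size")
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in ids]
    keys: list[str] = [str(i) for i in ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + _TIE_EPS)
        pairs = [(i, j) for i, j in cand if i < j]
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamp(0.5 * (dab + dac - dbc))
    b.length = _clamp(0.5 * (dab + dbc - dac))
    c.length = _clamp(0.5 * (dac + dbc - dab))
    order = sorted(range(3), key=lambda k: keys[k])
    return PhyloTree(TreeNode(children=[nodes[k] for k in order]))


# ---------------------------------------------------------------------------
# Distances from alignments, bootstrap
# ---------------------------------------------------------------------------

_SYM_INDEX = {aa: i + 1 for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWYX")}
_SYM_INDEX["-"] = 0


def encode_msa(rows: Sequence[str]) -> np.ndarray:
    """Integer-encode aligned rows; gaps map to 0."""
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows must have equal length")
    return np.array(
        [[_SYM_INDEX.get(ch, len(_SYM_INDEX) + 1) for ch in row] for row in rows],
        dtype=np.int16,
    )


def p_distance_matrix(encoded: np.ndarray) -> np.ndarray:
    """Pairwise fraction of mismatching columns, double-gap columns excluded."""
    n = encoded.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = encoded[i], encoded[j]
            valid = (a > 0) | (b > 0)
            denom = int(valid.sum())
            d[i, j] = d[j, i] = (
                float(((a != b) & valid).sum()) / denom if denom else 0.0
            )
    return d


def bootstrap_support(
    msa_rows: Sequence[str],
    ids: Sequence[str],
    n_replicates: int = 1000,
    seed: Optional[int] = None,
) -> PhyloTree:
    """NJ tree from an MSA with per-edge bootstrap support percentages.

    Columns are resampled with replacement per replicate; an internal edge's
    support is the percentage of replicate trees containing its bipartition.
    Deterministic for a given seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    encoded = encode_msa(msa_rows)
    tree = nj_tree(p_distance_matrix(encoded), ids)
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = encoded.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(p_distance_matrix(encoded[:, cols]), ids)
        rep_splits = rep.bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = 100.0 * counts[s] / n_replicates
    return tree
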