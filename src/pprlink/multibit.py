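"""Multibit trees: popcount-binned split-half trees with lossless Tanimoto pruning.

CLKs are first binned by popcount (the min(a,b)-based part of the similarity
bound needs the candidate popcount).  Within each bin a binary tree is grown
by the split-half technique: each node picks the unused bit position that
most evenly divides its members into set/unset halves, recording that bit as
a match bit on each child.  Threshold queries walk the forest, discarding
any bin or subtree whose Tanimoto upper bound falls below the threshold —
the bound is sound, so pruning never loses a qualifying candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .encoding import CLK
from .errors import DataError

logger = logging.getLogger(__name__)


class TreeNode:
    """One node of a split-half tree.

    ``match_bits`` holds the (position, value) pairs fixed at THIS node
    (empty at a bin root, one pair elsewhere); every CLK in the subtree
    agrees with the match bits of the node and all its ancestors.  ``m0`` /
    ``m1`` cache the accumulated value-0 / value-1 match-bit positions along
    the root path, inclusive.  ``leaf_members`` is non-empty only at leaves.
    """

    __slots__ = (
        "match_bits", "children", "leaf_members", "m0", "m1",
        "_leaf_idx", "_batch_idx",
    )

    def __init__(self, match_bits=(), m0=(), m1=()):
        self.match_bits = tuple(match_bits)
        self.children = None
        self.leaf_members: tuple = ()
        self._leaf_idx: tuple = ()
        # Member indices of small subtrees, cached at build time so queries
        # can batch-evaluate them instead of walking every tail node.  Purely
        # a traversal optimization: candidates are still filtered by their
        # exact similarity, so results are unchanged.
        self._batch_idx: tuple | None = None
        self.m0 = tuple(m0)
        self.m1 = tuple(m1)

    def is_leaf(self) -> bool:
        return self.children is None


#: Subtrees at or below this size are batch-evaluated during queries.
_BATCH_LEAF_SIZE = 16


@dataclass
class MultibitTree:
    """Popcount-binned forest over a CLK dataset."""

    l: int
    leaf_limit: int = 1
    bins: dict = dc_field(default_factory=dict)  # popcount -> root TreeNode
    clks: list = dc_field(default_factory=list)
    # packed bit matrix (n x ceil(l/8)) and per-CLK popcounts, row-aligned
    # with ``clks``; internal fast path for leaf similarity evaluation.
    _matrix: np.ndarray | None = None
    _popcounts: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.clks)


def _best_split(bool_mat: np.ndarray, members: np.ndarray) -> int | None:
    """Lowest-index bit that splits ``members`` most evenly; None if all constant."""
    n = members.size
    counts = bool_mat[members].sum(axis=0, dtype=np.int64)
    nonconstant = (counts > 0) & (counts < n)
    if not nonconstant.any():
        return None
    # |count/n - 1/2| ordering == |2*count - n| ordering (integer, exact).
    score = np.abs(2 * counts - n)
    score[~nonconstant] = np.iinfo(np.int64).max
    return int(np.argmin(score))  # argmin takes the lowest index on ties


def choose_split_bit(members: Sequence[CLK], used: set[int] | None = None) -> int | None:
    """Public split-bit rule over CLK objects (lowest index breaks ties).

    Returns the unused position whose set-count is closest to half of
    ``members``, or None when every unused bit is constant across them.
    """
    if not members:
        raise DataError("choose_split_bit needs at least one member")
    mat = np.stack([c.as_bool() for c in members])
    n = len(members)
    counts = mat.sum(axis=0, dtype=np.int64)
    eligible = (counts > 0) & (counts < n)
    if used:
        eligible[np.asarray(sorted(used), dtype=np.intp)] = False
    if not eligible.any():
        return None
    score = np.abs(2 * counts - n)
    score[~eligible] = np.iinfo(np.int64).max
    return int(np.argmin(score))


def build_tree(clks: Sequence[CLK], leaf_limit: int = 1) -> MultibitTree:
    """Build the popcount-binned forest; empty input yields a valid empty tree."""
    if leaf_limit < 1:
        raise DataError(f"leaf_limit must be >= 1, got {leaf_limit}")
    clks = list(clks)
    if not clks:
        return MultibitTree(l=0, leaf_limit=leaf_limit)
    l = clks[0].l
    if any(c.l != l for c in clks):
        raise DataError("all indexed CLKs must share one length")

    matrix = np.stack([c.bits for c in clks])
    popcounts = np.array([c.popcount for c in clks], dtype=np.int64)
    tree = MultibitTree(
        l=l, leaf_limit=leaf_limit, clks=clks,
        _matrix=matrix, _popcounts=popcounts,
    )

    order = np.argsort(popcounts, kind="stable")
    boundaries = np.flatnonzero(np.diff(popcounts[order])) + 1
    for bin_idx in np.split(order, boundaries):
        pc = int(popcounts[bin_idx[0]])
        bool_mat = np.unpackbits(matrix[bin_idx], axis=1, count=l)
        root = TreeNode()
        # Iterative construction: recursion depth is bounded by l, which
        # exceeds Python's default stack for l = 1000.
        stack = [(root, np.arange(bin_idx.size, dtype=np.intp))]
        while stack:
            node, local = stack.pop()
            if local.size <= _BATCH_LEAF_SIZE:
                node._batch_idx = tuple(int(i) for i in bin_idx[local])
            if local.size <= leaf_limit:
                split = None
            else:
                split = _best_split(bool_mat, local)
            if local.size <= leaf_limit or split is None:
                idx = bin_idx[local]
                node._leaf_idx = tuple(int(i) for i in idx)
                node.leaf_members = tuple(clks[i] for i in idx)
                continue
            col = bool_mat[local, split] == 1
            zeros, ones = local[~col], local[col]
            c0 = TreeNode(match_bits=((split, 0),), m0=node.m0 + (split,), m1=node.m1)
            c1 = TreeNode(match_bits=((split, 1),), m0=node.m0, m1=node.m1 + (split,))
            node.children = (c0, c1)
            stack.append((c0, zeros))
            stack.append((c1, ones))
        tree.bins[pc] = root
    logger.info(
        "built multibit tree: %d CLKs, %d popcount bins, leaf_limit=%d",
        len(clks), len(tree.bins), leaf_limit,
    )
    return tree


def tanimoto_upper_bound(query: CLK, node: TreeNode, bin_popcount: int) -> float:
    """Sound upper bound on Tanimoto(query, c) for every CLK c under ``node``.

    With a = |query|, b = bin popcount, M0/M1 the accumulated value-0/value-1
    match bits on the path:  i_max = min(a - |query∩M0|, b - |M1 \\ query|, a, b)
    and the bound is i_max / (a + b - i_max); 0 when a + b = 0 or i_max <= 0.
    """
    a = query.popcount
    b = bin_popcount
    if a + b == 0:
        return 0.0
    qb = query.as_bool()
    z = sum(1 for p in node.m0 if qb[p])
    o = sum(1 for p in node.m1 if not qb[p])
    i_max = min(a - z, b - o, a, b)
    if i_max <= 0:
        return 0.0
    return i_max / (a + b - i_max)


def query_tree(
    tree: MultibitTree,
    query: CLK,
    threshold: float,
    stats: dict | None = None,
) -> list[tuple[str, float]]:
    """All indexed CLKs with Tanimoto >= threshold (inclusive), with scores.

    Exact: equivalent to a brute-force scan.  Results are sorted by
    similarity descending, ties by record_id ascending.
    """
    if not (0.0 < threshold <= 1.0):
        raise DataError(f"threshold must be in (0, 1], got {threshold}")
    if tree.clks and query.l != tree.l:
        raise DataError(f"query length {query.l} != tree length {tree.l}")
    if not tree.clks:
        return []

    a = query.popcount
    # query bits as raw bytes of 0/1 for cheap positional lookups
    qb = bytes(np.unpackbits(query.bits, count=tree.l))
    qbits = query.bits
    candidates: list[int] = []
    n_bound = 0
    n_bins_pruned = 0
    n_nodes_pruned = 0

    for b, root in tree.bins.items():
        # Popcount-window prune == the bound at the bin root (no match bits).
        n_bound += 1
        m = a if a < b else b
        if m <= 0 or m / (a + b - m) < threshold:
            n_bins_pruned += 1
            continue
        ab = a + b
        stack = [(root, 0, 0)]  # (node, |query ∩ M0|, |M1 \ query|)
        while stack:
            node, z, o = stack.pop()
            batch = node._batch_idx
            if batch is not None:
                candidates.extend(batch)
                continue
            if node.children is None:
                candidates.extend(node._leaf_idx)
                continue
            c0, c1 = node.children
            for child in (c0, c1):
                (p, v), = child.match_bits
                cz, co = z, o
                if v == 0:
                    if qb[p]:
                        cz += 1
                else:
                    if not qb[p]:
                        co += 1
                n_bound += 1
                i_max = a - cz
                bo = b - co
                if bo < i_max:
                    i_max = bo
                if i_max <= 0 or i_max / (ab - i_max) < threshold:
                    n_nodes_pruned += 1
                    continue
                stack.append((child, cz, co))

    results: list[tuple[str, float]] = []
    if candidates:
        idx = np.asarray(candidates, dtype=np.intp)
        inter = np.bitwise_count(tree._matrix[idx] & qbits).sum(axis=1, dtype=np.int64)
        union = a + tree._popcounts[idx] - inter
        with np.errstate(invalid="ignore"):
            sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        keep = sims >= threshold
        results = [
            (tree.clks[int(i)].record_id, float(s))
            for i, s in zip(idx[keep], sims[keep])
        ]
    if stats is not None:
        stats["bound_evaluations"] = stats.get("bound_evaluations", 0) + n_bound
        stats["similarity_evaluations"] = (
            stats.get("similarity_evaluations", 0) + len(candidates)
        )
        stats["bins_pruned"] = stats.get("bins_pruned", 0) + n_bins_pruned
        stats["nodes_pruned"] = stats.get("nodes_pruned", 0) + n_nodes_pruned
    results.sort(key=lambda rs: (-rs[1], rs[0]))
    return results
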