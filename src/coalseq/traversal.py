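"""Sequential generation of marginal trees and subtree leaf counts.

Left-to-right iteration over the distinct marginal genealogies of a tree
sequence works by maintaining a single sparse tree in place: at each
transition, records whose interval ends at the new position are removed
(in decreasing time order) and records whose interval begins there are
inserted (in increasing time order).  Each record is inserted exactly
once and removed at most once, so a full pass costs O(n + rho log n).

The same sweep can maintain, for any tracked subsets S of the sample, a
vector ``beta`` with ``beta[u]`` the number of tracked leaves in the
subtree rooted at ``u`` — the basis for allele-frequency and association
calculations in :mod:`coalseq.mutations`.  The insertion/removal time
ordering guarantees that child subtrees are complete when their counts
are propagated, so ``beta`` is exact at every visit.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

from .trees import NULL_NODE, SparseTree, TreeDiff, TreeSequence

__all__ = [
    "LeafCountTree",
    "iterate_trees",
    "iterate_trees_with_counts",
    "tree_diffs",
]


class LeafCountTree(SparseTree):
    """A sparse tree carrying subtree leaf counts for tracked sample sets.

    ``beta`` has shape ``(num_tracked_sets, num_labels)``;
    ``beta[i, u]`` is the number of leaves of tracked set ``i`` in the
    subtree rooted at ``u``.  :meth:`count` gives the single-set view.
    """

    __slots__ = ("beta", "tracked")

    def __init__(self, parent, n, beta, tracked, interval=None, node_times=None):
        super().__init__(parent, n, interval=interval, node_times=node_times)
        self.beta = beta
        self.tracked = tracked

    def count(self, u: int, set_index: int = 0) -> int:
        return int(self.beta[set_index, u])


def _normalise_tracked(tracked, n: int) -> list[frozenset[int]]:
    if tracked and isinstance(next(iter(tracked)), (set, frozenset, list, tuple)):
        sets = [frozenset(s) for s in tracked]
    else:
        sets = [frozenset(tracked)]
    for s in sets:
        bad = [u for u in s if not (1 <= u <= n)]
        if bad:
            raise ValueError(f"tracked labels {bad} are not leaves 1..{n}")
    return sets


def iterate_trees(
    ts: TreeSequence, *, with_times: bool = False
) -> Iterator[tuple[tuple[int, int], SparseTree]]:
    """Visit ``(interval, tree)`` for every distinct marginal tree,
    left to right.

    The yielded :class:`~coalseq.trees.SparseTree` shares one parent
    vector that is updated in place between visits; treat it as read-only
    and copy it if it must outlive the visit.
    """
    for interval, tree in _sweep(ts, None, with_times):
        yield interval, tree


def iterate_trees_with_counts(
    ts: TreeSequence,
    tracked: Iterable[int] | Sequence[Iterable[int]],
    *,
    with_times: bool = False,
) -> Iterator[tuple[tuple[int, int], LeafCountTree]]:
    """Like :func:`iterate_trees` but maintaining exact subtree leaf
    counts for one tracked set (iterable of leaf labels) or several
    (sequence of iterables)."""
    sets = _normalise_tracked(tracked, ts.n)
    for interval, tree in _sweep(ts, sets, with_times):
        yield interval, tree


def _sweep(ts, tracked_sets, with_times):
    size = ts.max_node + 1
    pi = np.zeros(size, dtype=np.int64)
    times = ts.node_times() if with_times else None
    counting = tracked_sets is not None
    if counting:
        beta = np.zeros((len(tracked_sets), size), dtype=np.int64)
        for i, s in enumerate(tracked_sets):
            for u in s:
                beta[i, u] = 1
        tree = LeafCountTree(
            pi, ts.n, beta, tuple(tracked_sets), node_times=times
        )
    else:
        tree = SparseTree(pi, ts.n, node_times=times)
    I, O = ts.I, ts.O
    left, right, node, children = ts.left, ts.right, ts.node, ts.children
    M = ts.M
    j = k = 0
    x = 0
    while j < M:
        # Insert all records whose interval begins at x, in time order.
        while j < M and left[I[j]] == x:
            h = I[j]
            u = node[h]
            if counting:
                b = beta[:, list(children[h])].sum(axis=1)
            for c in children[h]:
                pi[c] = u
            if counting and b.any():
                v = u
                while v != NULL_NODE:
                    beta[:, v] += b
                    v = pi[v]
            j += 1
        x_right = int(left[I[j]]) if j < M else ts.m
        tree.interval = (x, x_right)
        yield (x, x_right), tree
        if j >= M:
            return
        x = x_right
        # Remove stale records (right coordinate == x), newest first.
        while k < M and right[O[k]] == x:
            h = O[k]
            if counting:
                b = beta[:, list(children[h])].sum(axis=1)
            for c in children[h]:
                pi[c] = NULL_NODE
            if counting and b.any():
                v = node[h]
                while v != NULL_NODE:
                    beta[:, v] -= b
                    v = pi[v]
            k += 1


def tree_diffs(ts: TreeSequence) -> Iterator[TreeDiff]:
    """Yield the records removed and inserted at every tree transition.

    The first diff carries the ``n - 1`` records of the leftmost tree
    with no removals; applying each diff's removals then insertions to
    the previous tree reproduces the iteration of :func:`iterate_trees`.
    """
    records = ts.records()
    I, O = ts.I, ts.O
    left, right = ts.left, ts.right
    M = ts.M
    j = k = 0
    x = 0
    outs: tuple = ()
    while j < M:
        ins = []
        while j < M and left[I[j]] == x:
            ins.append(records[I[j]])
            j += 1
        x_right = int(left[I[j]]) if j < M else ts.m
        yield TreeDiff((x, x_right), tuple(outs), tuple(ins))
        if j >= M:
            return
        x = x_right
        removed = []
        while k < M and right[O[k]] == x:
            removed.append(records[O[k]])
            k += 1
        outs = tuple(removed)
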