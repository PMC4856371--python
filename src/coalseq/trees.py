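"""Tree-sequence data model: coalescence records, sparse trees, index vectors.

A tree sequence encodes the correlated genealogies of a sample of ``n``
haploid genomes along a chromosome of ``m`` discrete sites.  Each
coalescence record ``(left, right, node, children, time)`` states that the
child nodes coalesce into the parent ``node`` at ``time`` (in units of
4Ne generations) over the half-open genomic interval ``[left, right)``.
Sample genomes (leaves) are labelled ``1..n``, internal nodes are arbitrary
integers ``> n``, and label ``0`` is reserved to mean "no parent" (root).

The set of records, together with two index vectors giving the order in
which records are inserted and removed as we sweep along the genome, is
sufficient to recover every marginal genealogy (see
:mod:`coalseq.traversal`).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "NULL_NODE",
    "CoalescenceRecord",
    "SparseTree",
    "TreeSequence",
    "TreeDiff",
    "TreeSequenceError",
    "CoverageError",
    "ChildOrderError",
    "TimeInconsistencyError",
    "make_tree_sequence",
    "compute_index_vectors",
    "build_tree_at",
    "squash_records",
]

#: Reserved parent label marking a root / absent node.
NULL_NODE = 0


class TreeSequenceError(ValueError):
    """Base class for tree-sequence validation failures."""


class CoverageError(TreeSequenceError):
    """Some site is not covered by the correct number of records."""


class ChildOrderError(TreeSequenceError):
    """A record's child labels are not sorted in increasing order."""


class TimeInconsistencyError(TreeSequenceError):
    """Node times are inconsistent or non-increasing along a lineage."""


@dataclasses.dataclass(frozen=True)
class CoalescenceRecord:
    """One coalescence of a contiguous genomic block.

    Parameters
    ----------
    left, right : int
        Half-open interval of sites ``[left, right)`` over which the
        coalescence applies.
    node : int
        Parent node label (``> n``).
    children : tuple of int
        Child node labels in increasing order.  The standard coalescent
        emits pairs; the data model accepts any number >= 2.
    time : float
        Time of the parent node, in units of 4Ne generations.
    """

    left: int
    right: int
    node: int
    children: tuple[int, ...]
    time: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(int(c) for c in self.children))

    @property
    def span(self) -> int:
        return self.right - self.left

    def astuple(self):
        return (self.left, self.right, self.node, self.children, self.time)


@dataclasses.dataclass(frozen=True)
class TreeDiff:
    """Difference between two adjacent marginal trees.

    Applying ``records_out`` (removals) and then ``records_in``
    (insertions) to the previous tree yields the tree covering
    ``interval``.
    """

    interval: tuple[int, int]
    records_out: tuple[CoalescenceRecord, ...]
    records_in: tuple[CoalescenceRecord, ...]


class SparseTree:
    """A marginal genealogy encoded as an oriented forest.

    The tree is a vector ``pi`` of parent pointers over sparse node
    labels: ``parent[u]`` is the parent of node ``u`` and ``parent[u] == 0``
    marks a root.  Leaves are exactly the labels ``1..n``; internal nodes
    may be any integer ``> n``.
    """

    __slots__ = ("parent", "n", "interval", "node_times")

    def __init__(self, parent, n, interval=None, node_times=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        if self.parent.ndim != 1 or len(self.parent) < n + 1:
            raise ValueError("parent vector must cover labels 0..n at least")
        self.n = int(n)
        self.interval = interval
        self.node_times = node_times

    @classmethod
    def from_parent_vector(cls, pi: Sequence[int], n: int | None = None) -> "SparseTree":
        """Build a tree from an oriented-tree sequence ``pi_1 pi_2 ...``.

        ``pi[i]`` is the parent of node ``i + 1``.  If ``n`` is omitted it
        is inferred as one less than the smallest internal (parent) label.
        """
        pi = [int(v) for v in pi]
        if n is None:
            parents = {v for v in pi if v != NULL_NODE}
            if not parents:
                raise ValueError("tree has no internal nodes; cannot infer n")
            n = min(parents) - 1
        size = max(len(pi) + 1, max(pi, default=0) + 1)
        parent = np.zeros(size, dtype=np.int64)
        parent[1 : len(pi) + 1] = pi
        return cls(parent, n)

    # -- queries ---------------------------------------------------------

    def parent_of(self, u: int) -> int:
        return int(self.parent[u])

    def nodes(self) -> set[int]:
        """All node labels present in the tree (leaves plus internals)."""
        present = set(range(1, self.n + 1))
        for u in range(1, len(self.parent)):
            p = int(self.parent[u])
            if p != NULL_NODE:
                present.add(u)
                present.add(p)
        return present

    def roots(self) -> list[int]:
        return sorted(u for u in self.nodes() if self.parent[u] == NULL_NODE)

    def root(self) -> int:
        """The unique root of a complete tree (walks up from leaf 1)."""
        u = 1
        seen = 0
        while self.parent[u] != NULL_NODE:
            u = int(self.parent[u])
            seen += 1
            if seen > len(self.parent):
                raise TreeSequenceError("cycle detected in parent pointers")
        return u

    def path_to_root(self, u: int) -> list[int]:
        path = [u]
        while self.parent[path[-1]] != NULL_NODE:
            path.append(int(self.parent[path[-1]]))
            if len(path) > len(self.parent):
                raise TreeSequenceError("cycle detected in parent pointers")
        return path

    def children_map(self) -> dict[int, list[int]]:
        """Map each internal node to its children, in increasing order."""
        out: dict[int, list[int]] = {}
        for u in range(1, len(self.parent)):
            p = int(self.parent[u])
            if p != NULL_NODE:
                out.setdefault(p, []).append(u)
        return out

    def leaves_below(self, u: int) -> list[int]:
        """Sample labels in the subtree rooted at ``u`` (brute-force DFS)."""
        cmap = self.children_map()
        out = []
        stack = [u]
        while stack:
            v = stack.pop()
            kids = cmap.get(v)
            if kids:
                stack.extend(kids)
            elif 1 <= v <= self.n:
                out.append(v)
        return sorted(out)

    def time(self, u: int) -> float:
        if self.node_times is None:
            raise ValueError("tree carries no node times")
        return float(self.node_times[u])

    def copy(self) -> "SparseTree":
        return SparseTree(
            self.parent.copy(),
            self.n,
            interval=self.interval,
            node_times=None if self.node_times is None else np.array(self.node_times),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SparseTree):
            return NotImplemented
        a, b = self.parent, other.parent
        if len(a) < len(b):
            a = np.concatenate([a, np.zeros(len(b) - len(a), dtype=np.int64)])
        elif len(b) < len(a):
            b = np.concatenate([b, np.zeros(len(a) - len(b), dtype=np.int64)])
        return self.n == other.n and bool(np.array_equal(a, b))

    def __repr__(self) -> str:
        pi = " ".join(str(int(v)) for v in self.parent[1:])
        return f"SparseTree(n={self.n}, interval={self.interval}, pi=<{pi}>)"


class TreeSequence:
    """Column-indexed table of coalescence records plus index vectors.

    Use :func:`make_tree_sequence` to construct a validated instance.
    Columns are exposed as numpy arrays ``left``, ``right``, ``node``,
    ``time`` and the tuple-of-tuples ``children``.  ``I`` and ``O`` are
    0-based permutations of the record indices giving insertion order
    (nondecreasing left coordinate, increasing time) and removal order
    (nondecreasing right coordinate, decreasing time).
    """

    def __init__(self, records: Sequence[CoalescenceRecord], n: int, m: int):
        self.n = int(n)
        self.m = int(m)
        recs = list(records)
        self.left = np.array([r.left for r in recs], dtype=np.int64)
        self.right = np.array([r.right for r in recs], dtype=np.int64)
        self.node = np.array([r.node for r in recs], dtype=np.int64)
        self.time = np.array([r.time for r in recs], dtype=np.float64)
        self.children = tuple(r.children for r in recs)
        self.I, self.O = compute_index_vectors(recs)

    @property
    def M(self) -> int:
        return len(self.left)

    @property
    def max_node(self) -> int:
        return int(max(self.node.max(initial=0), self.n))

    @property
    def num_trees(self) -> int:
        return len(np.unique(self.left))

    def records(self) -> list[CoalescenceRecord]:
        return [
            CoalescenceRecord(
                int(self.left[j]),
                int(self.right[j]),
                int(self.node[j]),
                self.children[j],
                float(self.time[j]),
            )
            for j in range(self.M)
        ]

    def breakpoints(self) -> np.ndarray:
        """Sorted distinct record coordinates, including 0 and m."""
        return np.unique(np.concatenate([self.left, self.right]))

    def at(self, x: int) -> SparseTree:
        return build_tree_at(self, x)

    def trees(self, **kwargs) -> Iterator[tuple[tuple[int, int], SparseTree]]:
        from . import traversal

        return traversal.iterate_trees(self, **kwargs)

    def diffs(self) -> Iterator[TreeDiff]:
        from . import traversal

        return traversal.tree_diffs(self)

    def node_times(self) -> np.ndarray:
        from . import mutations

        return mutations.node_times(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TreeSequence):
            return NotImplemented
        return (
            self.n == other.n
            and self.m == other.m
            and np.array_equal(self.left, other.left)
            and np.array_equal(self.right, other.right)
            and np.array_equal(self.node, other.node)
            and np.array_equal(self.time, other.time)
            and self.children == other.children
        )

    def __repr__(self) -> str:
        return (
            f"TreeSequence(n={self.n}, m={self.m}, M={self.M}, "
            f"num_trees={self.num_trees})"
        )


def _sort_key_insertion(rec: CoalescenceRecord):
    # Nondecreasing left, increasing time; ties (simultaneous coalescences
    # within one common-ancestor event share a time) broken by parent then
    # child labels for cross-platform determinism.
    return (rec.left, rec.time, rec.node, rec.children)


def _sort_key_removal(rec: CoalescenceRecord):
    return (rec.right, -rec.time, rec.node, rec.children)


def compute_index_vectors(records: Sequence[CoalescenceRecord]):
    """Insertion and removal index vectors for a set of records.

    Returns 0-based numpy index arrays ``(I, O)``: ``I`` sorts records by
    nondecreasing left coordinate and increasing time; ``O`` by
    nondecreasing right coordinate and decreasing time.
    """
    recs = list(records)
    idx = range(len(recs))
    I = np.array(sorted(idx, key=lambda j: _sort_key_insertion(recs[j])), dtype=np.int64)
    O = np.array(sorted(idx, key=lambda j: _sort_key_removal(recs[j])), dtype=np.int64)
    return I, O


def _validate_records(records: Sequence[CoalescenceRecord], n: int, m: int) -> None:
    if len(records) == 0:
        raise CoverageError("empty record set cannot cover any site")
    node_time: dict[int, float] = {}
    for rec in records:
        if not (0 <= rec.left < rec.right <= m):
            raise TreeSequenceError(
                f"record interval [{rec.left}, {rec.right}) outside [0, {m})"
            )
        if rec.node <= n:
            raise TreeSequenceError(
                f"parent node {rec.node} must exceed the sample size {n}"
            )
        if rec.time <= 0:
            raise TimeInconsistencyError(f"record time {rec.time} must be > 0")
        if len(rec.children) < 2:
            raise TreeSequenceError("records must have at least two children")
        if any(c < 1 for c in rec.children) or rec.node in rec.children:
            raise TreeSequenceError(f"invalid child labels {rec.children}")
        if any(a >= b for a, b in zip(rec.children, rec.children[1:])):
            raise ChildOrderError(
                f"children {rec.children} of node {rec.node} not increasing"
            )
        t = node_time.setdefault(rec.node, rec.time)
        if t != rec.time:
            raise TimeInconsistencyError(
                f"node {rec.node} has conflicting times {t} and {rec.time}"
            )
    for rec in records:
        for c in rec.children:
            if c <= n:
                ct = 0.0
            else:
                if c not in node_time:
                    raise TimeInconsistencyError(
                        f"internal child {c} never appears as a parent"
                    )
                ct = node_time[c]
            if rec.time <= ct:
                raise TimeInconsistencyError(
                    f"parent {rec.node} at {rec.time} not above child {c} at {ct}"
                )
    # Coverage: each record contributes len(children) - 1 coalescences; a
    # complete genealogy of n leaves needs exactly n - 1 at every site.
    deltas: dict[int, int] = {}
    for rec in records:
        k = len(rec.children) - 1
        deltas[rec.left] = deltas.get(rec.left, 0) + k
        deltas[rec.right] = deltas.get(rec.right, 0) - k
    coords = sorted(deltas)
    if coords[0] != 0 or coords[-1] != m:
        raise CoverageError(f"records cover [{coords[0]}, {coords[-1]}), not [0, {m})")
    total = 0
    for x in coords[:-1]:
        total += deltas[x]
        if total != n - 1:
            raise CoverageError(
                f"sites from {x} are covered by {total} coalescences, expected {n - 1}"
            )


def make_tree_sequence(
    records: Iterable[CoalescenceRecord], n: int, m: int
) -> TreeSequence:
    """Validate a set of coalescence records and build a :class:`TreeSequence`.

    Raises
    ------
    CoverageError
        If some site in ``[0, m)`` is not covered by exactly ``n - 1``
        coalescences.
    ChildOrderError
        If a record's children are not sorted in increasing order.
    TimeInconsistencyError
        If node times conflict or do not increase towards the root.
    """
    recs = [r if isinstance(r, CoalescenceRecord) else CoalescenceRecord(*r) for r in records]
    if n < 2:
        raise TreeSequenceError("sample size n must be >= 2")
    if m < 1:
        raise TreeSequenceError("sequence length m must be >= 1")
    _validate_records(recs, n, m)
    return TreeSequence(recs, n, m)


def build_tree_at(ts: TreeSequence, x: int) -> SparseTree:
    """Build the marginal tree at site ``x`` by a point query on the records.

    Applies every record ``(l, r, u, c, t)`` with ``l <= x < r`` to an
    empty sparse tree: ``pi[c] <- u`` for each child ``c``.
    """
    if not (0 <= x < ts.m):
        raise ValueError(f"site {x} out of range [0, {ts.m})")
    parent = np.zeros(ts.max_node + 1, dtype=np.int64)
    hits = np.flatnonzero((ts.left <= x) & (x < ts.right))
    for j in hits:
        for c in ts.children[j]:
            parent[c] = ts.node[j]
    times = None
    from . import mutations

    try:
        times = mutations.node_times(ts)
    except TreeSequenceError:  # pragma: no cover - validated sequences have times
        times = None
    return SparseTree(parent, ts.n, interval=None, node_times=times)


def squash_records(
    records: Iterable[CoalescenceRecord],
) -> list[CoalescenceRecord]:
    """Merge adjacent records identical in (node, children, time).

    A node assignment shared across adjacent marginal trees is represented
    by a single record; simulation may emit it piecewise, and this
    normalisation merges records whose intervals touch.  Marginal trees
    are unchanged.  Output is sorted by (time, left, node).
    """
    recs = sorted(records, key=lambda r: (r.node, r.children, r.time, r.left))
    out: list[CoalescenceRecord] = []
    for rec in recs:
        if (
            out
            and out[-1].node == rec.node
            and out[-1].children == rec.children
            and out[-1].time == rec.time
            and out[-1].right == rec.left
        ):
            out[-1] = CoalescenceRecord(
                out[-1].left, rec.right, rec.node, rec.children, rec.time
            )
        else:
            out.append(rec)
    out.sort(key=lambda r: (r.time, r.left, r.node))
    return out
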