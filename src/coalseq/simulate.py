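"""Hudson's algorithm for the exact coalescent with recombination.

The simulator tracks the extant ancestors of a sample of ``n`` genomes
backwards in time.  Each ancestor is an ordered list of non-overlapping
ancestral segments ``(left, right, node)`` mapping half-open genomic
intervals to tree nodes.  Two kinds of event occur:

* recombination, at rate ``rho * L / (m - 1)`` where ``L`` is the total
  number of breakable links (for each ancestor, its rightmost coordinate
  minus its leftmost minus one — so "trapped" non-ancestral material
  between segments is breakable);
* common ancestor, at rate ``|P| * (|P| - 1)``, merging two ancestors.

When merged ancestors carry overlapping ancestral material the overlap
coalesces, emitting coalescence records; once no other extant ancestor
carries material for an interval, that interval's genealogy is complete
and its segment is dropped.  The simulation ends when the population of
ancestors is empty, and the accumulated records form a tree sequence.

Time is measured in units of 4Ne generations throughout, the convention
forced by the event rates above (and shared with ms).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .trees import CoalescenceRecord, make_tree_sequence, squash_records

__all__ = [
    "SimulationParams",
    "SimulationState",
    "EventCounts",
    "RECOMBINATION",
    "COMMON_ANCESTOR",
    "initialise_state",
    "ancestor_links",
    "defragment_segments",
    "draw_next_event",
    "recombination_event",
    "common_ancestor_event",
    "merge_ancestors",
    "simulate",
]

RECOMBINATION = "recombination"
COMMON_ANCESTOR = "common_ancestor"


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Parameters of a single simulation run.

    ``rho`` is the population-scaled recombination rate
    ``4 * Ne * r * (m - 1)`` for per-generation, per-link rate ``r``.
    """

    n: int
    m: int
    rho: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if self.m < 1:
            raise ValueError("number of sites m must be >= 1")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.m == 1 and self.rho > 0:
            raise ValueError("rho must be 0 when m == 1 (no links to break)")


@dataclasses.dataclass
class EventCounts:
    """Counters reported alongside a completed simulation."""

    recombination_events: int = 0
    common_ancestor_events: int = 0
    coalescence_events: int = 0
    #: Recombinations whose breakpoint fell strictly inside an ancestral
    #: segment (as opposed to trapped material between segments).
    recombination_within_ancestral: int = 0


def ancestor_links(segments) -> int:
    """Number of breakable links of an ancestor.

    Defined from the ancestor's extreme coordinates: ``max right - min
    left - 1``, so gaps of trapped non-ancestral material count.
    """
    if not segments:
        raise ValueError("ancestor has no segments")
    return segments[-1][1] - segments[0][0] - 1


def defragment_segments(segments):
    """Merge adjacent segments ``(l, k, u), (k, r, u)`` carrying one node.

    Applied to fixpoint; the ancestor's extreme coordinates (hence its
    link count) are unchanged.
    """
    out = []
    for seg in segments:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(tuple(seg))
    return out


class _FenwickTree:
    """Binary indexed tree over ancestor slots, holding per-ancestor link
    counts, so a uniform link can be located in logarithmic time."""

    def __init__(self, size: int = 16):
        self._tree = [0] * (size + 1)
        self._values = [0] * (size + 1)
        self.size = size

    def _grow(self, size: int) -> None:
        new = _FenwickTree(size)
        for i in range(1, self.size + 1):
            if self._values[i]:
                new.add(i, self._values[i])
        self._tree, self._values, self.size = new._tree, new._values, new.size

    def add(self, i: int, delta: int) -> None:
        if i > self.size:
            self._grow(max(2 * self.size, i))
        self._values[i] += delta
        while i <= self.size:
            self._tree[i] += delta
            i += i & (-i)

    def get(self, i: int) -> int:
        return self._values[i] if i <= self.size else 0

    @property
    def total(self) -> int:
        return self.prefix(self.size)

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self._tree[i]
            i -= i & (-i)
        return s

    def find(self, target: int) -> tuple[int, int]:
        """Smallest slot ``i`` with cumulative sum >= ``target``.

        Returns ``(i, residual)`` where ``residual`` in ``1..values[i]``
        is the position of ``target`` within slot ``i``.
        """
        i = 0
        mask = 1 << (self.size.bit_length() - 1)
        remaining = target
        while mask:
            j = i + mask
            if j <= self.size and self._tree[j] < remaining:
                remaining -= self._tree[j]
                i = j
            mask >>= 1
        return i + 1, remaining


class OverlapCounter:
    """Piecewise-constant map from genomic position to the number of
    extant ancestral segments covering it.

    Stored as sorted breakpoints with one count per interval.  Counts
    start at ``n`` everywhere and only decrease, via :meth:`coalesce`;
    a count can never become 1 (an interval covered by a single segment
    could never finish coalescing), so completion is the 2 -> 0 rule.
    """

    def __init__(self, n: int, m: int):
        self.pos = [0, m]
        self.cnt = [n]

    def _split(self, x: int) -> int:
        """Ensure ``x`` is a breakpoint; return its index in ``pos``."""
        import bisect

        i = bisect.bisect_left(self.pos, x)
        if i < len(self.pos) and self.pos[i] == x:
            return i
        self.pos.insert(i, x)
        self.cnt.insert(i, self.cnt[i - 1])
        return i

    def count_at(self, x: int) -> int:
        import bisect

        i = bisect.bisect_right(self.pos, x) - 1
        if not (0 <= i < len(self.cnt)):
            raise ValueError(f"position {x} outside [0, m)")
        return self.cnt[i]

    def coalesce(self, left: int, right: int):
        """Register the coalescence of two segments over ``[left, right)``.

        For each constant-count piece: if the count is 2 the two merging
        segments were the only material there, the marginal tree is
        complete and the piece is dropped (count -> 0); otherwise the two
        segments are replaced by one (count decremented) and the piece is
        retained.  Returns ``[(l, r, kept), ...]`` pieces in order.
        """
        i = self._split(left)
        j = self._split(right)
        pieces = []
        for k in range(i, j):
            c = self.cnt[k]
            if c < 2:
                raise RuntimeError(
                    f"overlap count {c} < 2 during coalescence over "
                    f"[{self.pos[k]}, {self.pos[k + 1]})"
                )
            if c == 2:
                self.cnt[k] = 0
                pieces.append((self.pos[k], self.pos[k + 1], False))
            else:
                self.cnt[k] = c - 1
                pieces.append((self.pos[k], self.pos[k + 1], True))
        return pieces

    def as_pairs(self):
        """(interval, count) pairs, for tests."""
        return [
            ((self.pos[i], self.pos[i + 1]), self.cnt[i])
            for i in range(len(self.cnt))
        ]


class SimulationState:
    """Mutable state of Hudson's algorithm.

    Holds the population of ancestors (in slots addressed by a Fenwick
    tree over link counts), the current time ``t``, the next node label
    ``w``, the total link count ``L``, the overlap counter and the
    growing list of emitted coalescence records.
    """

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.n = params.n
        self.m = params.m
        self.rho = params.rho
        self.rng = rng
        self.t = 0.0
        self.w = params.n + 1
        self.records: list[CoalescenceRecord] = []
        self.counts = EventCounts()
        self.overlap = OverlapCounter(params.n, params.m)
        self._ancestors: list = [None]  # slot 0 unused (Fenwick is 1-based)
        self._free: list[int] = []
        self._occupied: list[int] = []
        self._slot_pos: dict[int, int] = {}
        self._fenwick = _FenwickTree()
        self.L = 0
        for u in range(1, params.n + 1):
            self.add_ancestor([(0, params.m, u)])

    # -- population bookkeeping -----------------------------------------

    @property
    def num_ancestors(self) -> int:
        return len(self._occupied)

    def ancestors(self):
        """Segment lists of all extant ancestors (stable slot order)."""
        return [self._ancestors[s] for s in sorted(self._occupied)]

    def get_ancestor(self, slot: int):
        return self._ancestors[slot]

    def add_ancestor(self, segments) -> int:
        segments = [tuple(s) for s in segments]
        slot = self._free.pop() if self._free else len(self._ancestors)
        if slot == len(self._ancestors):
            self._ancestors.append(None)
        self._ancestors[slot] = segments
        self._slot_pos[slot] = len(self._occupied)
        self._occupied.append(slot)
        links = ancestor_links(segments)
        self._fenwick.add(slot, links)
        self.L += links
        return slot

    def remove_ancestor(self, slot: int):
        segments = self._ancestors[slot]
        links = self._fenwick.get(slot)
        self._fenwick.add(slot, -links)
        self.L -= links
        self._ancestors[slot] = None
        self._free.append(slot)
        pos = self._slot_pos.pop(slot)
        last = self._occupied.pop()
        if last != slot:
            self._occupied[pos] = last
            self._slot_pos[last] = pos
        return segments

    def random_slots(self, k: int) -> list[int]:
        idx = self.rng.choice(len(self._occupied), size=k, replace=False)
        return [self._occupied[int(i)] for i in idx]

    def compute_L(self) -> int:
        """Recompute the total link count from scratch (invariant check)."""
        return sum(ancestor_links(self._ancestors[s]) for s in self._occupied)


def initialise_state(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> SimulationState:
    """Initial state: ``n`` ancestors each holding one segment ``(0, m, u)``,
    ``t = 0``, ``w = n + 1`` and ``L = n * (m - 1)``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return SimulationState(params, rng)


def draw_next_event(state: SimulationState) -> tuple[float, str]:
    """Waiting time and kind of the next event.

    Recombination happens at rate ``rho * L / (m - 1)`` and common
    ancestor events at rate ``|P| * (|P| - 1)``; the waiting time is
    exponential with the summed rate and the kind is chosen
    proportionally.
    """
    p = state.num_ancestors
    ca_rate = float(p * (p - 1))
    re_rate = state.rho * state.L / (state.m - 1) if state.m > 1 else 0.0
    total = ca_rate + re_rate
    if total <= 0:
        raise RuntimeError(
            f"no event possible with |P|={p}, L={state.L}: "
            "simulation cannot terminate"
        )
    dt = float(state.rng.exponential(1.0 / total))
    kind = RECOMBINATION if state.rng.random() * total < re_rate else COMMON_ANCESTOR
    return dt, kind


def recombination_event(state: SimulationState) -> None:
    """Break one of the ``L`` links, chosen uniformly, splitting an
    ancestor in two.

    If the chosen ancestor spans ``[min_l, max_r)`` the breakpoint ``k``
    satisfies ``min_l < k < max_r``: segments with ``r <= k`` go to one
    recombinant, segments with ``l >= k`` to the other, and a straddling
    segment ``(l, r, u)`` with ``l < k < r`` is split into ``(l, k, u)``
    and ``(k, r, u)``.  Ancestral material (and so the overlap counter) is
    unchanged.
    """
    if state.L <= 0:
        raise ValueError("no links available to break")
    g = int(state.rng.integers(1, state.L + 1))
    slot, residual = state._fenwick.find(g)
    segments = state.remove_ancestor(slot)
    k = segments[0][0] + residual  # min_l < k <= min_l + links = max_r - 1
    head, tail = [], []
    within = False
    for l, r, u in segments:
        if r <= k:
            head.append((l, r, u))
        elif l >= k:
            tail.append((l, r, u))
        else:
            within = True
            head.append((l, k, u))
            tail.append((k, r, u))
    state.add_ancestor(head)
    state.add_ancestor(tail)
    state.counts.recombination_events += 1
    if within:
        state.counts.recombination_within_ancestral += 1


def merge_ancestors(state: SimulationState, slot_a: int, slot_b: int) -> None:
    """Merge two ancestors into their common ancestor at the current time.

    Non-overlapping material passes through unchanged.  Each maximal
    exactly-intersecting interval ``[l, r)`` with nodes ``u`` and ``v``
    coalesces: a record ``(l, r, w, (u, v), t)`` is emitted; parts of the
    interval still covered by other extant ancestors are retained as
    segments mapped to ``w``, fully-coalesced parts are dropped.  All
    coalescing intervals within one event share the single new node
    ``w``, which is incremented once at the end.  The merged ancestor is
    defragmented and, if non-empty, returned to the population.
    """
    A = state.remove_ancestor(slot_a)
    B = state.remove_ancestor(slot_b)
    bounds = sorted({c for l, r, _ in A + B for c in (l, r)})
    merged = []
    w = state.w
    coalesced = False
    ia = ib = 0
    for x1, x2 in zip(bounds, bounds[1:]):
        while ia < len(A) and A[ia][1] <= x1:
            ia += 1
        while ib < len(B) and B[ib][1] <= x1:
            ib += 1
        u = A[ia][2] if ia < len(A) and A[ia][0] <= x1 else None
        v = B[ib][2] if ib < len(B) and B[ib][0] <= x1 else None
        if u is not None and v is not None:
            coalesced = True
            c1, c2 = (u, v) if u < v else (v, u)
            state.records.append(CoalescenceRecord(x1, x2, w, (c1, c2), state.t))
            state.counts.coalescence_events += 1
            for pl, pr, kept in state.overlap.coalesce(x1, x2):
                if kept:
                    merged.append((pl, pr, w))
        elif u is not None:
            merged.append((x1, x2, u))
        elif v is not None:
            merged.append((x1, x2, v))
    if coalesced:
        state.w += 1
    merged = defragment_segments(merged)
    if merged:
        state.add_ancestor(merged)


def common_ancestor_event(state: SimulationState) -> None:
    """Choose a uniform pair of distinct ancestors and merge them."""
    slot_a, slot_b = state.random_slots(2)
    state.counts.common_ancestor_events += 1
    merge_ancestors(state, slot_a, slot_b)


def simulate(
    params: SimulationParams | None = None,
    *,
    n: int | None = None,
    m: int | None = None,
    rho: float = 0.0,
    seed: int | None = None,
    max_events: int = 100_000_000,
    return_counts: bool = False,
):
    """Run Hudson's algorithm and return the resulting tree sequence.

    Either pass a :class:`SimulationParams` or the keyword arguments
    ``n``, ``m``, ``rho``, ``seed``.  The output records are squashed and
    validated; identical parameters and seed give identical output.

    With ``return_counts=True`` the event counters are returned as well.
    """
    if params is None:
        if n is None or m is None:
            raise ValueError("n and m are required")
        params = SimulationParams(n=n, m=m, rho=rho, seed=seed)
    state = initialise_state(params)
    events = 0
    while state.num_ancestors > 0:
        events += 1
        if events > max_events:
            raise RuntimeError(
                f"simulation exceeded {max_events} events; "
                "state may be corrupt or parameters extreme"
            )
        dt, kind = draw_next_event(state)
        state.t += dt
        if kind == RECOMBINATION:
            recombination_event(state)
        else:
            common_ancestor_event(state)
    records = squash_records(state.records)
    ts = make_tree_sequence(records, params.n, params.m)
    if return_counts:
        return ts, state.counts
    return ts
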