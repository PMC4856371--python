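"""Infinite-sites mutations, haplotypes, allele frequencies, association.

Mutations are dropped onto the branches of the marginal genealogies under
the infinite-sites model: positions are continuous reals in ``[0, m)``
(even though recombination acts between discrete sites), so every
polymorphic site carries exactly one mutation.  A mutation is stored as
the tuple ``(node, position)`` where ``node`` is the *child* end of the
branch it falls on; a sample carries the mutation iff it is a leaf of the
subtree rooted at that node in the marginal tree covering the position.

For a record ``(l, r, u, (c1, c2), t)`` each child branch is present over
the span ``r - l`` with length ``t - time(child)``, and receives a
Poisson number of mutations with mean ``theta * (r - l) * (t -
time(child))``, where ``theta`` is the scaled mutation rate per unit of
sequence per 4Ne generations.  Summed over a Kingman genealogy this gives
the classical ``E[S] = theta * m * H_{n-1}`` segregating sites.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .trees import TimeInconsistencyError, TreeSequence
from .traversal import iterate_trees, iterate_trees_with_counts

__all__ = [
    "Mutation",
    "HaplotypeSet",
    "AssociationResult",
    "node_times",
    "generate_mutations",
    "haplotypes",
    "allele_frequencies",
    "case_control_odds_ratios",
]


@dataclasses.dataclass(frozen=True)
class Mutation:
    """A single infinite-sites mutation above ``node`` at ``position``."""

    node: int
    position: float


@dataclasses.dataclass
class HaplotypeSet:
    """Binary haplotypes: ``matrix[i, k]`` is 1 iff sample ``i + 1``
    carries the ``k``-th mutation (mutations sorted by position)."""

    matrix: np.ndarray
    mutations: tuple[Mutation, ...]

    @property
    def positions(self) -> np.ndarray:
        return np.array([mut.position for mut in self.mutations])

    def as_strings(self) -> list[str]:
        return ["".join("1" if v else "0" for v in row) for row in self.matrix]


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """2x2 carrier-by-phenotype table and odds ratio for one mutation."""

    mutation: Mutation
    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int
    odds_ratio: float

    @property
    def table(self):
        return (
            (self.case_carriers, self.case_noncarriers),
            (self.control_carriers, self.control_noncarriers),
        )


def node_times(ts: TreeSequence) -> np.ndarray:
    """Time of every node: leaves map to 0, internal node ``u`` to the
    time of any record with parent ``u`` (they must all agree)."""
    times = np.zeros(ts.max_node + 1, dtype=np.float64)
    seen = np.zeros(ts.max_node + 1, dtype=bool)
    for j in range(ts.M):
        u = int(ts.node[j])
        t = float(ts.time[j])
        if seen[u] and times[u] != t:
            raise TimeInconsistencyError(
                f"node {u} has conflicting times {times[u]} and {t}"
            )
        times[u] = t
        seen[u] = True
    return times


def generate_mutations(
    ts: TreeSequence,
    theta: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Mutation]:
    """Drop infinite-sites mutations on a tree sequence.

    For each record and each child branch the mutation count is Poisson
    with mean ``theta * span * branch_length`` and positions are uniform
    on the record's interval.  Returns mutations sorted by position;
    deterministic under a fixed seed.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if theta == 0:
        return []
    times = node_times(ts)
    muts: list[Mutation] = []
    for j in range(ts.M):
        span = float(ts.right[j] - ts.left[j])
        t = float(ts.time[j])
        for c in ts.children[j]:
            branch = t - times[c]
            k = int(rng.poisson(theta * span * branch))
            if k:
                positions = rng.uniform(ts.left[j], ts.right[j], size=k)
                muts.extend(Mutation(int(c), float(p)) for p in positions)
    muts.sort(key=lambda mut: mut.position)
    return muts


def _group_by_tree(ts, mutations):
    """Yield (interval, tree, mutations_in_interval) over one sweep."""
    muts = sorted(mutations, key=lambda mut: mut.position)
    i = 0
    for (x1, x2), tree in iterate_trees(ts):
        batch = []
        while i < len(muts) and muts[i].position < x2:
            if muts[i].position < x1:
                raise ValueError(
                    f"mutation position {muts[i].position} precedes interval {x1}"
                )
            batch.append(muts[i])
            i += 1
        yield (x1, x2), tree, batch
    if i < len(muts):
        raise ValueError(
            f"mutation position {muts[i].position} outside sequence [0, {ts.m})"
        )


def haplotypes(ts: TreeSequence, mutations: Iterable[Mutation]) -> HaplotypeSet:
    """Binary haplotypes of all samples, one sweep over the marginal trees.

    Sample ``i`` carries mutation ``(u, p)`` iff ``i`` is a leaf of the
    subtree rooted at ``u`` in the tree covering ``p``.
    """
    muts = sorted(mutations, key=lambda mut: mut.position)
    matrix = np.zeros((ts.n, len(muts)), dtype=np.uint8)
    order = {id(mut): k for k, mut in enumerate(muts)}
    for _, tree, batch in _group_by_tree(ts, muts):
        if not batch:
            continue
        cmap = tree.children_map()
        cache: dict[int, list[int]] = {}
        for mut in batch:
            leaves = cache.get(mut.node)
            if leaves is None:
                leaves = _leaves_below(cmap, mut.node, ts.n)
                if not leaves and not (1 <= mut.node <= ts.n):
                    raise ValueError(
                        f"mutation node {mut.node} absent from tree at "
                        f"position {mut.position}"
                    )
                cache[mut.node] = leaves
            col = order[id(mut)]
            for leaf in leaves:
                matrix[leaf - 1, col] = 1
    return HaplotypeSet(matrix, tuple(muts))


def _leaves_below(cmap, u, n):
    out = []
    stack = [u]
    while stack:
        v = stack.pop()
        kids = cmap.get(v)
        if kids:
            stack.extend(kids)
        elif 1 <= v <= n:
            out.append(v)
    return out


def allele_frequencies(
    ts: TreeSequence, mutations: Iterable[Mutation], S: Iterable[int]
) -> np.ndarray:
    """Frequency of each mutation within the sample subset ``S``.

    Computed as ``beta[node] / |S|`` from the leaf-count sweep, without
    materialising haplotypes.  Mutations are taken in position order.
    """
    S = frozenset(S)
    if not S:
        raise ValueError("S must be non-empty")
    muts = sorted(mutations, key=lambda mut: mut.position)
    freqs = np.empty(len(muts), dtype=np.float64)
    i = 0
    for (x1, x2), tree in iterate_trees_with_counts(ts, S):
        while i < len(muts) and muts[i].position < x2:
            freqs[i] = tree.count(muts[i].node) / len(S)
            i += 1
    return freqs


def _odds_ratio(a, b, c, d, haldane):
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    num = a * d
    den = b * c
    if den > 0:
        return num / den
    return math.nan if num == 0 else math.inf


def case_control_odds_ratios(
    ts: TreeSequence,
    mutations: Iterable[Mutation],
    cases: Iterable[int],
    controls: Iterable[int],
    *,
    haldane: bool = False,
) -> list[AssociationResult]:
    """Per-mutation 2x2 tables and odds ratios for a case/control split.

    Carrier counts within cases and controls come from two leaf-count
    vectors maintained in a single sweep.  With ``haldane=False`` zero
    cells give an odds ratio of ``inf`` (or ``nan`` when the numerator is
    also zero); ``haldane=True`` applies the +0.5 correction to every
    cell.
    """
    cases = frozenset(cases)
    controls = frozenset(controls)
    if not cases or not controls:
        raise ValueError("cases and controls must be non-empty")
    if cases & controls:
        raise ValueError("cases and controls must be disjoint")
    muts = sorted(mutations, key=lambda mut: mut.position)
    out: list[AssociationResult] = []
    i = 0
    for (x1, x2), tree in iterate_trees_with_counts(ts, [cases, controls]):
        while i < len(muts) and muts[i].position < x2:
            mut = muts[i]
            a = tree.count(mut.node, 0)
            c = tree.count(mut.node, 1)
            b = len(cases) - a
            d = len(controls) - c
            out.append(
                AssociationResult(mut, a, b, c, d, _odds_ratio(a, b, c, d, haldane))
            )
            i += 1
    return out
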