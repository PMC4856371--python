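"""Quantitative verification experiments for the simulator.

These experiments check the simulator against classical coalescent
theory and against the scaling behaviour of Hudson's algorithm:

* with a single site the model reduces to the Kingman coalescent, so
  the time to the MRCA has mean ``1 - 1/n`` (4Ne units) and there are
  always exactly ``n - 1`` records;
* the mean number of recombination breakpoints within ancestral
  material is the Hudson-Kaplan expectation ``rho * H_{n-1}``;
* the mean number of segregating sites is ``theta * m * H_{n-1}``;
* the mean number of coalescence records is bounded by
  ``n + 3 * rho * ln(n) - 1`` (three records per tree transition plus
  ``n - 1`` for the leftmost tree);
* the mean number of recombination events generated by the algorithm
  grows quadratically in ``rho`` for fixed ``n``.

All experiments are fully determined by their parameters and seed.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from typing import Sequence

import numpy as np

from .simulate import simulate
from .traversal import iterate_trees
from .trees import TreeSequence

__all__ = [
    "harmonic",
    "ExperimentCell",
    "count_distinct_trees",
    "distinct_breakpoints",
    "kingman_tmrca_experiment",
    "mean_breakpoints_experiment",
    "segregating_sites_experiment",
    "record_bound_check",
    "fit_event_quadratic",
    "run_grid",
    "write_csv",
]


def harmonic(k: int) -> float:
    """The k-th harmonic number H_k = sum_{i=1..k} 1/i."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


def _seeds(seed: int | None, reps: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(1, 2**31 - 1, size=reps)


def _mean_se(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=np.float64)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), se


def count_distinct_trees(ts: TreeSequence) -> int:
    """Number of distinct marginal trees (visits of the tree sweep)."""
    return sum(1 for _ in iterate_trees(ts))


def distinct_breakpoints(ts: TreeSequence) -> int:
    """Distinct recombination breakpoints observable in the records:
    record coordinates other than 0 and m."""
    coords = set(int(v) for v in ts.left) | set(int(v) for v in ts.right)
    coords.discard(0)
    coords.discard(ts.m)
    return len(coords)


@dataclasses.dataclass(frozen=True)
class ExperimentCell:
    """Per-cell summary of a replicated simulation experiment."""

    n: int
    m: int
    rho: float
    theta: float
    reps: int
    seed: int
    mean_recombination_events: float
    se_recombination_events: float
    mean_common_ancestor_events: float
    se_common_ancestor_events: float
    mean_records: float
    se_records: float
    mean_breakpoints: float
    se_breakpoints: float
    mean_trees: float
    se_trees: float
    mean_mutations: float
    se_mutations: float


def run_grid(
    cells: Sequence[tuple[int, int, float, float]],
    reps: int,
    seed: int | None = None,
) -> list[ExperimentCell]:
    """Run ``reps`` replicates for each ``(n, m, rho, theta)`` cell and
    summarise means and standard errors of the key counts."""
    from .mutations import generate_mutations

    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for n, m, rho, theta in cells:
        cell_seed = int(master.integers(1, 2**31 - 1))
        seeds = _seeds(cell_seed, reps)
        res = {key: [] for key in ("re", "ca", "M", "bp", "trees", "muts")}
        for s in seeds:
            ts, counts = simulate(n=n, m=m, rho=rho, seed=int(s), return_counts=True)
            res["re"].append(counts.recombination_events)
            res["ca"].append(counts.common_ancestor_events)
            res["M"].append(ts.M)
            res["bp"].append(distinct_breakpoints(ts))
            res["trees"].append(count_distinct_trees(ts))
            n_mut = (
                len(generate_mutations(ts, theta, seed=int(s) + 1)) if theta > 0 else 0
            )
            res["muts"].append(n_mut)
        stats = {key: _mean_se(vals) for key, vals in res.items()}
        out.append(
            ExperimentCell(
                n, m, rho, theta, reps, cell_seed,
                *stats["re"], *stats["ca"], *stats["M"],
                *stats["bp"], *stats["trees"], *stats["muts"],
            )
        )
    return out


def write_csv(cells: Sequence[ExperimentCell], sink) -> None:
    """Write experiment cells as CSV with a header row."""
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w", newline="")
        close = True
    try:
        fields = [f.name for f in dataclasses.fields(ExperimentCell)]
        writer = csv.DictWriter(sink, fieldnames=fields)
        writer.writeheader()
        for cell in cells:
            writer.writerow(dataclasses.asdict(cell))
    finally:
        if close:
            sink.close()


def kingman_tmrca_experiment(n: int, reps: int, seed: int | None = None):
    """Single-site simulations: mean and s.e. of the MRCA time, plus the
    record counts (always ``n - 1`` under the Kingman coalescent).

    The analytic mean is ``1 - 1/n`` in units of 4Ne generations.
    """
    seeds = _seeds(seed, reps)
    tmrca = np.empty(reps)
    counts = np.empty(reps, dtype=np.int64)
    for i, s in enumerate(seeds):
        ts = simulate(n=n, m=1, rho=0.0, seed=int(s))
        tmrca[i] = ts.time.max()
        counts[i] = ts.M
    mean, se = _mean_se(tmrca)
    return mean, se, counts


def mean_breakpoints_experiment(
    n: int, rho: float, reps: int, seed: int | None = None, m: int = 10_000
):
    """Mean recombination events within ancestral material against the
    Hudson-Kaplan expectation ``rho * H_{n-1}``.

    An event is within ancestral material when its breakpoint falls
    strictly inside an ancestral segment, splitting it.  (Distinct
    surviving record coordinates systematically undercount this: an
    event erased by a later merge of the two recombinants leaves no
    trace in the records.)  Returns ``(mean, se, expected)``.
    """
    seeds = _seeds(seed, reps)
    values = []
    for s in seeds:
        _, counts = simulate(n=n, m=m, rho=rho, seed=int(s), return_counts=True)
        values.append(counts.recombination_within_ancestral)
    mean, se = _mean_se(values)
    return mean, se, rho * harmonic(n - 1)


def segregating_sites_experiment(
    n: int,
    theta_total: float,
    reps: int,
    seed: int | None = None,
    m: int = 1000,
    rho: float = 0.0,
):
    """Mean segregating sites against ``theta_total * H_{n-1}`` where
    ``theta_total = theta * m``.  Returns ``(mean, se, expected)``."""
    from .mutations import generate_mutations

    seeds = _seeds(seed, reps)
    theta = theta_total / m
    values = []
    for s in seeds:
        ts = simulate(n=n, m=m, rho=rho, seed=int(s))
        values.append(len(generate_mutations(ts, theta, seed=int(s) + 1)))
    mean, se = _mean_se(values)
    return mean, se, theta_total * harmonic(n - 1)


def record_bound_check(
    n: int, rho: float, reps: int, seed: int | None = None, m: int = 1000
):
    """Mean record count against the bound ``n + 3 * rho * ln(n) - 1``.

    Returns ``(mean_M, bound, within_bound)``.  The natural log is used
    since the bound derives from the harmonic number ``H_{n-1}``.
    """
    seeds = _seeds(seed, reps)
    values = [simulate(n=n, m=m, rho=rho, seed=int(s)).M for s in seeds]
    mean, _ = _mean_se(values)
    bound = n + 3 * rho * math.log(n) - 1
    return mean, bound, mean <= bound


def fit_event_quadratic(
    n: int,
    rho_grid: Sequence[float],
    reps: int,
    seed: int | None = None,
    m: int = 1_000_000,
):
    """Least-squares quadratic fit of mean recombination-event count
    against ``rho``.

    Returns ``(a2, a1, a0, r_squared)`` for the model
    ``events = a2 * rho^2 + a1 * rho + a0``.
    """
    rho_grid = [float(r) for r in rho_grid]
    if len(rho_grid) < 4:
        raise ValueError("need at least 4 grid points")
    master = np.random.default_rng(seed)
    means = []
    for rho in rho_grid:
        seeds = _seeds(int(master.integers(1, 2**31 - 1)), reps)
        events = [
            simulate(
                n=n, m=m, rho=rho, seed=int(s), return_counts=True
            )[1].recombination_events
            for s in seeds
        ]
        means.append(float(np.mean(events)))
    x = np.array(rho_grid)
    y = np.array(means)
    if np.ptp(x) == 0:
        if np.allclose(y, 0):
            return 0.0, 0.0, 0.0, 1.0
        raise ValueError("degenerate rho grid: all points identical")
    a2, a1, a0 = np.polyfit(x, y, 2)
    resid = y - np.polyval([a2, a1, a0], x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(a2), float(a1), float(a0), r2
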