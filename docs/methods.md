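# Methods

## Model

The simulator implements the exact (non-Markovian along the genome)
coalescent with recombination for a sample of n haploid genomes over m
discrete sites, neutral and panmictic with constant population size:
no demography, migration, growth, gene conversion, selection or
variable recombination maps.  Time runs backwards in units of 4Nₑ
generations; ρ = 4Nₑr(m − 1) is the population-scaled recombination
rate for per-generation, per-link rate r; θ is the scaled mutation rate
per unit of sequence per 4Nₑ generations.  In these units, with |P|
extant ancestors and L total links, common-ancestor events occur at
rate |P|(|P| − 1) (each unordered pair at rate 2) and recombination at
rate ρL/(m − 1).  With m = 1 the process reduces to the Kingman
coalescent, which fixes the analytic checks used throughout:
E[T_MRCA] = 1 − 1/n, E[total branch length] = H₍ₙ₋₁₎, E[segregating
sites] = θmH₍ₙ₋₁₎, and E[recombination events within ancestral
material] = ρH₍ₙ₋₁₎.

## State and event mechanics

Each ancestor is an ordered list of disjoint segments (ℓ, r, u).  An
ancestor's links are max r − min ℓ − 1, so gaps of "trapped"
non-ancestral material between segments are breakable, per the L
definition above; a breakpoint falling in a gap moves whole segments to
the two recombinants, while a breakpoint inside a segment splits it.
Per-ancestor link counts live in a Fenwick (binary indexed) tree so
that a uniform link among L is located in O(log) time; the contract is
only uniformity (verified by a chi-square test over every link), the
structure is an implementation choice.

Merging two ancestors subdivides their segments into exact
intersections and overhangs.  Overhangs pass through unchanged.  Each
maximal exactly-intersecting interval coalesces: one record
(ℓ, r, w, (u, v), t) is emitted with children sorted, and every
coalescing interval of one event shares the single new node label w
(labels therefore increase with time).  Whether the coalesced interval
stays ancestral is decided by an overlap counter — a sorted
piecewise-constant map position → number of extant segments covering
it.  Counts start at n, never increase, and can never equal 1 (a region
covered by a single segment could never finish coalescing), so the
completion rule is: count 2 → 0, drop the segment (that marginal tree
is done); count c ≥ 3 → c − 1, keep (ℓ', r', w) for the still-covered
part.  Merged ancestors are defragmented (adjacent same-node segments
rejoined).  The simulation ends when no ancestors remain; emitted
records are then squashed (touching intervals with identical node,
children and time merged) and validated: every site of [0, m) must be
covered by exactly n − 1 binary records with strictly increasing times
towards the root.

A single seeded numpy Generator drives every draw, so output is
bit-reproducible given (n, m, ρ, seed).  An event-count safety cap
(10⁸) guards against state corruption; termination is otherwise almost
sure.

## Tree sequence and traversal

Records are held as parallel columns with two index vectors: insertion
order (nondecreasing left, increasing time) and removal order
(nondecreasing right, decreasing time).  Equal-time ties — simultaneous
coalescences within one event — are broken by parent then child labels;
correctness of the sweep requires only the time ordering, the tie rule
just makes output platform-deterministic.  The sweep visits one tree
per distinct insertion left-coordinate; because output is squashed,
consecutive visits always differ, and the final interval extends to m.
The visited tree object reuses one parent vector in place: it is
read-only by contract and must be copied to outlive its visit.  Leaf
counting propagates subtree counts up the current tree on insertion and
down on removal; inserting in increasing and removing in decreasing
time order guarantees child subtrees are complete when counted, so β is
exact at every visit (tested against brute-force subtree enumeration).
Any number of tracked sample sets is maintained simultaneously (the
case/control test needs two).  Point queries (build the tree at site x)
scan the record table; an interval index would be asymptotically
better but the scan is simpler and the contract is only the returned
tree.

## Mutations

Infinite-sites mutations live at continuous positions even though
recombination acts between discrete sites.  A mutation is stored as
(child node, position): the carrier set is the leaf set below that node
in the tree covering the position.  For each record and each child, the
count is Poisson with mean θ · span · branch length, positions uniform
on the record's interval; a node whose branch spans several records
accrues mutations per record, which is forced by interval-dependent
branch presence, and the total intensity is invariant to how records
are fragmented.  Odds ratios for a case/control split are (a·d)/(b·c)
from the two β vectors; zero cells give ∞ (or 0, or NaN when both
products vanish) by default, with an optional Haldane–Anscombe +0.5
correction — the default keeps the statistic transparent rather than
silently smoothed.

## Serialisation

Tab-delimited text stores one record per line with repr-rendered
(shortest round-trip) times, so text round-trips are exact.  The HDF5
container stores /metadata (n, m, format version 1.0), /records columns
left/right/node/children as uint32 and time as float64, and optional
/mutations columns; zlib compression is a flag.  This schema is this
package's own stable layout, not a claim of compatibility with any
other tool's container.  Newick is the only lossy path: it stores
branch lengths (time differences) at a configurable decimal precision,
children in ascending label order.  The ms-style writer emits //
separators, [span]newick tree lines and segsites/positions/haplotype
blocks with positions scaled to [0, 1).  The command line interface is
ms-flavoured but deliberately not a byte-level ms clone; only the
documented flags are supported, and -t takes the total θ across the
sequence.

## Verification experiments and problem sizes

The acceptance script and test suite recompute, from scratch:

* Kingman limit: n = 10, m = 1, 10⁴ replicates — mean T_MRCA vs 0.9,
  record count always 9.
* Hudson–Kaplan: n = 10, ρ = 5, m = 10⁴, 10³ replicates — mean
  recombination events within ancestral material vs ρH₉ ≈ 14.14.  The
  experiment counts events whose breakpoint splits an ancestral
  segment.  Counting *surviving distinct record coordinates* instead
  undercounts substantially (≈ 10.9 here): an event whose two
  recombinants later re-merge leaves no trace in the records.  m = 10⁴
  keeps the discrete-sites bias of the continuum formula negligible.
* Segregating sites: n = 10, θm = 10, m = 10³, ρ = 0, 10³ replicates —
  vs θmH₉ ≈ 28.29.  This is the law that scales to millions of
  mutations on chromosome-sized runs.
* SPR record arithmetic: hand-built sequences exhibiting the three
  transition classes — 3, 2, 1 changed records exactly.
* Record bound: mean table size vs n + 3ρ ln n − 1 (natural log, as the
  bound derives from H₍ₙ₋₁₎) at (n, ρ) = (10, 5) and (100, 20), m = 10³,
  200 replicates.
* Oracle equivalences: 50 random simulations — sweep trees vs per-site
  rebuilds, swept leaf counts vs brute-force enumeration, allele
  frequencies via β vs via haplotypes.
* Event growth: n = 1000, ρ ∈ {250, 500, 1000, 1500, 2000}, m = 10⁶,
  10 replicates per point — quadratic fit of mean recombination-event
  count against ρ.  The fit is extremely good (R² > 0.999) but its
  leading coefficient is range-dependent: the count is slightly
  sub-quadratic, with events/ρ² still decaying through ≈ 1.5 × 10⁻²
  over this grid (a behaviour this implementation shares, at matched
  event counts, with an independent C implementation of the same
  algorithm).  Substantially smaller asymptotic coefficients are only
  reached at ρ ~ 10⁵ — tens of millions of events per replicate —
  which is outside the problem sizes this pure-Python package targets.
* Scaled chromosome-style run: n = 500, m = 10⁶, equal per-unit
  recombination and mutation rates 5 × 10⁻⁵ (ρ = θm ≈ 50) — mutation
  and distinct-tree counts vs θmH₍ₙ₋₁₎ and ρH₍ₙ₋₁₎.  The full
  10⁵-sample, 10⁸-site configuration that yields ~1.2 million mutations
  is not run at desk scale; the scaled run checks the same laws.

## What the generator does and does not emulate

Simulated data are neutral, panmictic, constant-size coalescent samples
with uniform recombination and infinite-sites mutation.  Passing tests
therefore validate the algorithmic machinery and the classical neutral
expectations; they say nothing about demography, selection, recurrent
mutation, genotyping error or any other feature of real data that the
model excludes.

## Known limitations

* The data model accepts records with more than two children, but the
  simulator only emits pairs; multiple-merger coalescents are not
  implemented.
* Only full left-to-right sweeps and single-point tree builds are
  provided — no random-access iteration from an interior site.
* Haplotype generation materialises per-tree children maps and is meant
  for analysis-scale output, not for the largest simulations the
  record encoding itself could hold.
* Reading the text format infers n and m from the records (exact for
  simulator output, where internal labels start at n + 1); pass them
  explicitly for hand-built tables with gaps in the label space.
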