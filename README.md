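# coalseq

Exact coalescent simulation with recombination, built on **sparse trees**
and **coalescence records**, together with the tree-sequence data
structure and traversal algorithms that make storing and analysing large
collections of correlated genealogies cheap.

## Who this is for

Population geneticists and methods developers who need to simulate the
coalescent with recombination for a sample of *n* genomes over *m*
discrete sites — and then actually *work* with the resulting marginal
genealogies: iterate over them, drop infinite-sites mutations, compute
haplotypes and allele frequencies, and run simple association tests,
without ever materialising each tree separately.

## The model and the encoding

Backwards in time, each extant ancestor is a set of non-overlapping
segments *(ℓ, r, u)* mapping the half-open genomic interval [ℓ, r) to a
tree node *u*. With |P| ancestors and L total breakable links
(per ancestor, its rightmost minus leftmost coordinate minus one):

* **recombination** occurs at rate ρL/(m − 1), splitting one ancestor at
  a uniformly chosen link, where ρ = 4Nₑr(m − 1);
* **common ancestor events** occur at rate |P|(|P| − 1), merging two
  ancestors; wherever their material overlaps, the overlap coalesces and
  a **coalescence record** (ℓ, r, w, (u, v), t) is emitted.

Time is measured in units of 4Nₑ generations (the ms convention).  The
record table — a *tree sequence* — encodes every marginal genealogy:
trees are integer parent vectors π over sparse node labels (leaves
1..n, internal labels > n, π = 0 marks a root), and the expected table
size is bounded by n + 3ρ ln n − 1 records, since a single recombination
changes at most three records (a subtree-prune-and-regraft), two if it
changes the root, one if it only changes the root's time.

Sweeping the records left-to-right by their insertion/removal index
vectors regenerates all distinct marginal trees in O(n + ρ log n) total
time, and the same sweep maintains, for any tracked sample subsets S, a
vector β with β(u) = number of tracked leaves below node u — giving
allele frequencies β(u)/|S| and case/control 2×2 tables without ever
touching haplotypes.

## A worked example

```python
import coalseq

ts = coalseq.simulate(n=5, m=10, rho=1.0, seed=42)
for record in ts.records():
    print(record)
for interval, tree in coalseq.iterate_trees(ts):
    print(interval, tree)
```

prints

```
CoalescenceRecord(left=0, right=10, node=6, children=(2, 5), time=0.09616834415863978)
CoalescenceRecord(left=0, right=10, node=7, children=(3, 6), time=0.10157068163978834)
CoalescenceRecord(left=5, right=10, node=8, children=(4, 7), time=0.4534454735371806)
CoalescenceRecord(left=0, right=5, node=9, children=(1, 7), time=0.499261965922828)
CoalescenceRecord(left=5, right=10, node=9, children=(1, 8), time=0.499261965922828)
CoalescenceRecord(left=0, right=5, node=10, children=(4, 9), time=0.6083624589686563)
(0, 5) SparseTree(n=5, interval=(0, 5), pi=<9 6 7 10 6 7 9 0 10 0>)
(5, 10) SparseTree(n=5, interval=(5, 10), pi=<9 6 7 8 6 7 8 9 0 0>)
```

Six records encode two marginal trees of four internal nodes each: the
assignments (2,5)→6 and (3,6)→7 span the whole sequence and are stored
once; a single recombination at site 5 re-roots the tree (two records
out, two in).  Node 9 appears in both trees at the same time 0.499 —
both intervals coalesced in the same common-ancestor event.  Mutations,
haplotypes and association statistics follow the same pattern:

```python
muts = coalseq.generate_mutations(ts, theta=0.5, seed=1)
print(coalseq.haplotypes(ts, muts).as_strings())
print(coalseq.allele_frequencies(ts, muts, S={1, 2, 3}))
```

There is also an ms-flavoured command line, e.g.
`coalseq 10 3 -r 5 1000 -t 10 --seed 1` for three replicates of a
10-sample, 1000-site simulation with ρ = 5 and total θ = 10, and
text/HDF5/Newick serialisation in `coalseq.io`.

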