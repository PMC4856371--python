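"""Shared fixtures: small hand-built tree sequences and simulation helpers."""

import pytest

from coalseq import CoalescenceRecord, make_tree_sequence, simulate


def fig4_records():
    """The worked four-sample, ten-site example tree sequence.

    Three marginal trees over [0,2), [2,7), [7,10).  The printed records
    are (2,10,5,(3,4),0.071) and (0,7,7,(1,6),0.170); the transition at
    x=2 removes the assignments (2,4)->6 and (3,7)->9 and inserts
    (3,4)->5 and (2,5)->6, and the transition at x=7 changes only the
    root's time.  Times 0.090/0.202/0.253 are synthetic (chosen
    consistent with the required time ordering).
    """
    return [
        CoalescenceRecord(2, 10, 5, (3, 4), 0.071),
        CoalescenceRecord(0, 2, 6, (2, 4), 0.090),
        CoalescenceRecord(2, 10, 6, (2, 5), 0.090),
        CoalescenceRecord(0, 7, 7, (1, 6), 0.170),
        CoalescenceRecord(7, 10, 8, (1, 6), 0.202),
        CoalescenceRecord(0, 2, 9, (3, 7), 0.253),
    ]


@pytest.fixture
def fig4_ts():
    return make_tree_sequence(fig4_records(), n=4, m=10)


def spr_records():
    """Synthetic five-sample sequence whose single transition is a
    subtree-prune-and-regraft not involving the root: leaf 2 is pruned
    from (1,2) and regrafted onto the branch above leaf 5, while the root
    record (0,10,9,(7,8),0.5) spans both trees.  Exactly three records
    change."""
    return [
        CoalescenceRecord(0, 5, 6, (1, 2), 0.1),
        CoalescenceRecord(0, 5, 7, (3, 6), 0.2),
        CoalescenceRecord(0, 5, 8, (4, 5), 0.3),
        CoalescenceRecord(5, 10, 7, (1, 3), 0.2),
        CoalescenceRecord(5, 10, 10, (2, 5), 0.25),
        CoalescenceRecord(5, 10, 8, (4, 10), 0.3),
        CoalescenceRecord(0, 10, 9, (7, 8), 0.5),
    ]


@pytest.fixture
def spr_ts():
    return make_tree_sequence(spr_records(), n=5, m=10)


@pytest.fixture
def minimal_ts():
    """n=2, single site, one record."""
    return make_tree_sequence([CoalescenceRecord(0, 1, 3, (1, 2), 0.5)], n=2, m=1)


@pytest.fixture
def sim_factory():
    """Deterministic small simulations for oracle comparisons."""

    def factory(seed, n=10, m=100, rho=5.0):
        return simulate(n=n, m=m, rho=rho, seed=seed)

    return factory
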