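"""Refining ensemble bounds with multi-gene knock-out data.

An uncertain edge (i, j) can be verified experimentally once every
indirect route i -> ... -> j is severed.  A *separatoid* of (i, j) is a
node set whose deletion eliminates every directed path of length >= 2
from i to j; comparing gene j's expression between a background KO V_k
containing a separatoid and the same background plus i then probes the
direct edge alone.  Three cheaply computable separatoids are used
(finding all of them is equivalent to longest-path search, which is
NP-hard):

    Sep1(i, j) = children(i) in G^U      intersect ancestors(j) in G^U0
    Sep2(i, j) = descendants(i) in G^U0  intersect parents(j) in G^U
    Sep3(i, j) = descendants(i) in G^U0  intersect ancestors(j) in G^U0

with G^U the current upper bound, G^U0 the initial one, and i, j removed
from every set.  For every available pair (V_k, V_k u {i}) a two-tailed
two-sample t-test on gene j's replicates casts a vote: rejection supports
the edge, failure to reject opposes it.  Majority voting updates the
bounds; the sign follows the majority direction among confirming pairs
(test mean below background mean => activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .bounds import EnsembleBounds
from .simulate import ExpressionDataset

__all__ = [
    "SeparatoidTable",
    "VerificationPair",
    "VoteRecord",
    "compute_separatoids",
    "find_verification_pairs",
    "edge_ttest",
    "vote_and_update",
    "update_bounds",
]

DEFAULT_ALPHA = 0.01

Edge = tuple[str, str]
KOSet = frozenset

SeparatoidTable = dict  # Edge -> tuple[frozenset, frozenset, frozenset]


@dataclass(frozen=True)
class VerificationPair:
    """A licensed (background, background + i) KO-experiment pair."""

    edge: Edge
    background: KOSet
    test: KOSet
    separatoid_index: int

    def __post_init__(self) -> None:
        i, j = self.edge
        if i in self.background or j in self.background:
            raise ValueError("endpoints cannot belong to the background KO")
        if self.test != self.background | {i}:
            raise ValueError("test KO must equal background plus the source gene")


@dataclass
class VoteRecord:
    """Per-edge record of t-test votes and the aggregate decision."""

    edge: Edge
    tests: list[tuple[bool, str]] = field(default_factory=list)  # (reject, direction)
    decision: str = "undecided"  # confirm | remove | undecided
    sign: int | None = None


def compute_separatoids(bounds: EnsembleBounds) -> SeparatoidTable:
    """The three candidate separatoids for every uncertain edge."""
    table: SeparatoidTable = {}
    gu = bounds.upper
    gu0 = bounds.initial_upper
    for (i, j) in sorted(bounds.uncertain):
        drop = {i, j}
        sep1 = (gu.children(i) & gu0.ancestors(j)) - drop
        sep2 = (gu0.descendants(i) & gu.parents(j)) - drop
        sep3 = (gu0.descendants(i) & gu0.ancestors(j)) - drop
        table[(i, j)] = (frozenset(sep1), frozenset(sep2), frozenset(sep3))
    return table


def find_verification_pairs(
    edge: Edge,
    table: SeparatoidTable,
    ko_sets: Iterable[Iterable[str]],
) -> list[VerificationPair]:
    """All experiment pairs (V_k, V_k u {i}) present in ``ko_sets`` that can
    verify ``edge``: the background must contain at least one separatoid
    (non-strict inclusion: the background may equal the separatoid) and
    exclude both endpoints, and both experiments must have data.  Results
    are deduplicated by background and ordered by (|V_k|, lexicographic).
    """
    i, j = edge
    seps = table[edge]
    available = {frozenset(s) for s in ko_sets}
    pairs: dict[KOSet, VerificationPair] = {}
    for vk in available:
        if i in vk or j in vk:
            continue
        test = vk | {i}
        if test not in available:
            continue
        for l, sep in enumerate(seps, start=1):
            if sep <= vk:
                pairs[vk] = VerificationPair(edge, vk, test, l)
                break
    return sorted(
        pairs.values(), key=lambda p: (len(p.background), sorted(p.background))
    )


def edge_ttest(
    data: ExpressionDataset,
    gene: str,
    background: Iterable[str],
    test: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> tuple[bool, str]:
    """Two-tailed two-sample t-test on one gene's replicate values between
    a background KO and a test KO.

    Returns ``(reject, direction)`` with direction ``below`` iff the test
    mean is under the background mean.  The pooled-variance test is the
    default; set ``equal_var=False`` for Welch.  Degenerate samples with
    zero variance on both sides are decided by exact mean comparison
    (identical means fail to reject), which makes noise-free data behave
    like the infinite-precision limit.
    """
    a = data.gene_values(gene, background)
    b = data.gene_values(gene, test)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per experiment")
    direction = "below" if b.mean() < a.mean() else "above"
    if a.std() == 0.0 and b.std() == 0.0:
        scale = max(1.0, abs(a.mean()), abs(b.mean()))
        return bool(abs(a.mean() - b.mean()) > 1e-9 * scale), direction
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return bool(p < alpha), direction


def vote_and_update(
    bounds: EnsembleBounds,
    edge: Edge,
    votes: Sequence[tuple[bool, str]],
) -> VoteRecord:
    """Aggregate t-test votes for one uncertain edge and mutate the bounds.

    Strictly more rejections than non-rejections confirms the edge into
    the lower bound; strictly more non-rejections removes it from the
    upper bound; a tie leaves the bounds unchanged (the edge stays
    uncertain).  The confirmed sign is the majority direction among
    confirming pairs (+1 for 'below'); a direction tie keeps the upper
    bound's sign.
    """
    if not votes:
        raise ValueError("need at least one vote")
    if edge not in bounds.uncertain:
        raise ValueError(f"edge {edge} is not uncertain")
    record = VoteRecord(edge=edge, tests=list(votes))
    n_for = sum(1 for rej, _ in votes if rej)
    n_against = len(votes) - n_for
    if n_against > n_for:
        bounds.remove_edge(*edge)
        record.decision = "remove"
    elif n_for > n_against:
        below = sum(1 for rej, d in votes if rej and d == "below")
        above = n_for - below
        if below > above:
            sign = 1
        elif above > below:
            sign = -1
        else:
            sign = bounds.upper.sign(*edge)
        bounds.confirm_edge(*edge, sign)
        record.decision = "confirm"
        record.sign = sign
    else:
        record.decision = "undecided"
    return record


def update_bounds(
    bounds: EnsembleBounds,
    data: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> tuple[EnsembleBounds, list[VoteRecord]]:
    """Iterate separatoid computation, pair search and voting to a fixed
    point.

    Each round computes all verdicts against the round-start bounds and
    applies them together, so the result does not depend on the order in
    which uncertain edges are examined.  The loop stops when no uncertain
    edge has a verification pair, when E_U empties, or when a full round
    changes nothing (tie-only rounds).  Returns the updated bounds (a
    copy; the input is left untouched) and the vote records of the final
    pass over each decided edge.
    """
    bounds = bounds.copy()
    records: dict[Edge, VoteRecord] = {}
    while bounds.uncertain:
        table = compute_separatoids(bounds)
        round_votes: dict[Edge, list[tuple[bool, str]]] = {}
        for edge in sorted(bounds.uncertain):
            pairs = find_verification_pairs(edge, table, data.ko_sets)
            if not pairs:
                continue
            round_votes[edge] = [
                edge_ttest(data, edge[1], p.background, p.test, alpha, equal_var)
                for p in pairs
            ]
        if not round_votes:
            break
        changed = False
        for edge, votes in round_votes.items():
            record = vote_and_update(bounds, edge, votes)
            records[edge] = record
            if record.decision != "undecided":
                changed = True
        if not changed:
            break
    return bounds, list(records.values())
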