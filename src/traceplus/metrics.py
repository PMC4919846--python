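"""Scoring ensemble bounds against a reference signed network.

All scores compare edge sets; in signed mode an edge only matches when
its sign agrees (edges of unequal signs are not counted in
intersections).  The true positive rate reads recall off the lower bound;
the total distance measures the residual uncertainty of the bound pair;
the Jaccard distance compares any two digraphs.  The error taxonomy
counts false negatives against the upper bound (a reference edge the
data never surfaced), false positives against the lower bound (a
confidently asserted non-edge) and incorrect signs against the upper
bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .bounds import EnsembleBounds
from .digraph import SignedDigraph

__all__ = [
    "EvaluationReport",
    "signed_edge_intersection",
    "true_positive_rate",
    "total_distance",
    "jaccard_distance",
    "error_tally",
    "evaluate_bounds",
]


@dataclass
class EvaluationReport:
    tpr: float
    td: float
    jd_upper: float
    jd_lower: float
    fn: int
    fp: int
    is_count: int
    mode: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _edge_set(g: SignedDigraph, signed: bool):
    return g.edges if signed else g.edge_pairs


def signed_edge_intersection(
    a: SignedDigraph, b: SignedDigraph, signed: bool = True
) -> set:
    """Edges present in both graphs; in signed mode the signs must agree."""
    return _edge_set(a, signed) & _edge_set(b, signed)


def true_positive_rate(
    lower: SignedDigraph, reference: SignedDigraph, signed: bool = True
) -> float:
    """Fraction of reference edges recovered (with matching sign, in
    signed mode) in the lower bound."""
    if reference.m == 0:
        raise ValueError("TPR undefined for an empty reference network")
    return len(signed_edge_intersection(lower, reference, signed)) / reference.m


def total_distance(
    upper: SignedDigraph,
    lower: SignedDigraph,
    reference: SignedDigraph,
    signed: bool = True,
) -> float:
    """Three-way union-minus-intersection ratio

        TD = [N(E(G^U) u E(G^L) u E(ref)) - N(E(G^U) n E(G^L) n E(ref))]
             / N(E(ref))

    Zero iff both bounds coincide with the reference; larger values mean
    more inference uncertainty."""
    if reference.m == 0:
        raise ValueError("TD undefined for an empty reference network")
    eu = _edge_set(upper, signed)
    el = _edge_set(lower, signed)
    er = _edge_set(reference, signed)
    return (len(eu | el | er) - len(eu & el & er)) / reference.m


def jaccard_distance(a: SignedDigraph, b: SignedDigraph, signed: bool = True) -> float:
    """JD = [N(union) - N(intersection)] / N(union); 0 for identical edge
    sets, 1 for disjoint ones.  Two empty graphs are at distance 0 (with a
    warning)."""
    ea = _edge_set(a, signed)
    eb = _edge_set(b, signed)
    union = ea | eb
    if not union:
        warnings.warn("Jaccard distance of two empty graphs defined as 0",
                      stacklevel=2)
        return 0.0
    return (len(union) - len(ea & eb)) / len(union)


def error_tally(bounds: EnsembleBounds, reference: SignedDigraph) -> tuple[int, int, int]:
    """(FN, FP, IS) error counts.

    FN: reference pairs absent from the upper bound (sign ignored).
    FP: lower-bound pairs absent from the reference (sign ignored).
    IS: reference pairs present in the upper bound with the opposite sign.
    """
    ref_pairs = reference.edge_pairs
    fn = len(ref_pairs - bounds.upper.edge_pairs)
    fp = len(bounds.lower.edge_pairs - ref_pairs)
    is_count = sum(
        1
        for (u, v) in ref_pairs & bounds.upper.edge_pairs
        if reference.sign(u, v) != bounds.upper.sign(u, v)
    )
    return fn, fp, is_count


def evaluate_bounds(
    bounds: EnsembleBounds, reference: SignedDigraph, signed: bool = True
) -> EvaluationReport:
    """Full report: TPR, TD, Jaccard distances of both bounds, FN/FP/IS."""
    fn, fp, is_count = error_tally(bounds, reference)
    return EvaluationReport(
        tpr=true_positive_rate(bounds.lower, reference, signed),
        td=total_distance(bounds.upper, bounds.lower, reference, signed),
        jd_upper=jaccard_distance(bounds.upper, reference, signed),
        jd_lower=jaccard_distance(bounds.lower, reference, signed),
        fn=fn,
        fp=fp,
        is_count=is_count,
        mode="signed" if signed else "unsigned",
    )
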