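"""The bundled five-gene worked example.

A small signed GRN used throughout the documentation and tests: five
genes A-E with seven regulations, three of them repressions, containing a
two-gene positive feedback loop D <-> E.  Its signed transitive closure
is path-consistent, so it serves as the ideal (noise-free) ensemble upper
bound; running the signed local transitive reduction with w_cut = 0.3 and
the bundled regulation weights leaves exactly three uncertain edges
(A, D), (A, E) and (C, E), while the unsigned ConTREx baseline also
discards every edge touching the D <-> E cycle.

The edge weights are illustrative stand-ins on the closure's edge set,
constructed so that direct regulations outweigh two-step detours for the
retained edges and not for the removed ones.
"""

from __future__ import annotations

from .bounds import EnsembleBounds, signed_ltr
from .digraph import SignedDigraph, signed_closure

__all__ = ["worked_example_network", "worked_example_weights", "load_worked_example"]

_EDGES = [
    ("A", "C", 1),
    ("A", "E", -1),
    ("B", "D", 1),
    ("C", "D", -1),
    ("C", "E", -1),
    ("D", "E", 1),
    ("E", "D", 1),
]

# weights over the closure's nine edges (source, target) -> W
_WEIGHTS = {
    ("A", "C"): 0.9,
    ("A", "D"): 0.4,
    ("A", "E"): 0.4,
    ("B", "D"): 0.5,
    ("B", "E"): 0.6,
    ("C", "D"): 0.9,
    ("C", "E"): 0.8,
    ("D", "E"): 0.3,
    ("E", "D"): 0.1,
}

_EXPECTED_UNCERTAIN = {("A", "D"), ("A", "E"), ("C", "E")}


def worked_example_network() -> SignedDigraph:
    """The five-gene reference network (7 edges, 3 repressions)."""
    return SignedDigraph(edges=_EDGES)


def worked_example_weights() -> dict[tuple[str, str], float]:
    """Illustrative regulation-strength weights over the closure edges."""
    return dict(_WEIGHTS)


def load_worked_example(w_cut: float = 0.3) -> tuple[SignedDigraph, EnsembleBounds]:
    """The reference network and its expected ensemble bounds.

    The upper bound is the signed transitive closure of the reference;
    the lower bound is its signed LTR at ``w_cut`` with the bundled
    weights.  The fixture is validated at load time against the
    relations it must satisfy (parent/child/ancestor structure, edge and
    sign counts, and the three expected uncertain edges at the default
    ``w_cut``).
    """
    ref = worked_example_network()
    upper = signed_closure(ref)
    for (u, v), w in _WEIGHTS.items():
        upper.set_weight(u, v, w)
    lower = signed_ltr(upper, w_cut=w_cut)
    bounds = EnsembleBounds(upper=upper, lower=lower)
    _validate(ref, bounds, w_cut)
    return ref, bounds


def _validate(ref: SignedDigraph, bounds: EnsembleBounds, w_cut: float) -> None:
    checks = [
        (ref.n == 5, "five genes"),
        (ref.m == 7, "seven edges"),
        (sum(1 for *_, s in ref.edges if s < 0) == 3, "three repressions"),
        (ref.children("C") == {"D", "E"}, "C regulates D and E"),
        (ref.parents("D") == {"B", "C", "E"}, "D regulated by B, C, E"),
        (ref.descendants("A") == {"C", "D", "E"}, "A upstream of C, D, E"),
        (ref.ancestors("E") >= {"A", "B", "C", "D"}, "E downstream of A-D"),
        (("D", "E") in ref and ("E", "D") in ref, "D <-> E cycle"),
    ]
    if w_cut == 0.3:
        checks.append(
            (bounds.uncertain == _EXPECTED_UNCERTAIN, "expected uncertain edges")
        )
    failed = [msg for ok, msg in checks if not ok]
    if failed:
        raise RuntimeError(f"worked example fixture is inconsistent: {failed}")
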