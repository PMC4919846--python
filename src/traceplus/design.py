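"""Optimal-design surrogate: choosing the next knock-out experiments.

The ensemble shrinks fastest when new KO experiments verify as many
uncertain edges as possible.  The reference optimizer for this task
(REDUCE) solves a constrained optimization over separatoids; here a
greedy weighted set-cover surrogate is implemented: each candidate is a
(background, background + i) experiment pair derived from a separatoid,
and the greedy step picks the pair completing verification for the most
not-yet-covered uncertain edges.  A maximum-KO-size constraint is
enforced and escalated by one whenever no feasible proposal exists, and a
multiplexed mode chains greedy runs — removing already-coverable edges
from the objective — to emit a whole batch of experiments at once.

:func:`iterative_inference` drives the full loop against the simulator:
initial single-KO compendium -> initial bounds -> repeat {design ->
simulate -> update} until the bounds converge to a unique network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bounds import (
    DEFAULT_W_CUT,
    EnsembleBounds,
    build_initial_bounds,
)
from .simulate import (
    ExpressionDataset,
    KineticModel,
    SimConfig,
    generate_compendium,
    single_ko_design,
)
from .update import SeparatoidTable, compute_separatoids, update_bounds

__all__ = [
    "DesignProposal",
    "IterationLog",
    "candidate_backgrounds",
    "greedy_design",
    "escalate_constraint",
    "multiplexed_design",
    "iterative_inference",
]

Edge = tuple[str, str]
KOSet = frozenset


@dataclass
class DesignProposal:
    """KO sets to perform next, with the uncertain edges each one serves."""

    experiments: list[KOSet] = field(default_factory=list)
    covers: dict[KOSet, set[Edge]] = field(default_factory=dict)
    max_size: int = 2

    def __bool__(self) -> bool:
        return bool(self.experiments)

    def covered_edges(self) -> set[Edge]:
        out: set[Edge] = set()
        for edges in self.covers.values():
            out |= edges
        return out


@dataclass
class IterationLog:
    """Per-iteration bookkeeping of the inference loop."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def candidate_backgrounds(
    table: SeparatoidTable, max_size: int
) -> dict[Edge, list[KOSet]]:
    """Feasible background KOs per uncertain edge under a KO-size limit.

    Each separatoid Sep_l(i, j) itself serves as a candidate background
    V_k; the paired test experiment V_k u {i} must respect ``max_size``,
    so only separatoids of size <= max_size - 1 qualify.
    """
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    out: dict[Edge, list[KOSet]] = {}
    for edge, seps in table.items():
        cands = []
        for sep in seps:
            if len(sep) <= max_size - 1 and sep not in cands:
                cands.append(sep)
        out[edge] = sorted(cands, key=lambda s: (len(s), sorted(s)))
    return out


def greedy_design(
    table: SeparatoidTable,
    performed: Iterable[Iterable[str]],
    max_size: int = 2,
    budget: int = 1,
) -> DesignProposal:
    """Greedy cover of uncertain edges by KO-experiment pairs.

    Candidates are (background, background + i) pairs from
    :func:`candidate_backgrounds`.  Each greedy step selects the pair
    whose missing experiments, once added, complete verification for the
    most not-yet-covered uncertain edges; ties break toward fewer and
    smaller new experiments, then lexicographically.  ``budget`` counts
    pairs.  Returns an empty proposal when no uncertain edge is coverable
    at this ``max_size``.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    performed = {frozenset(s) for s in performed}
    cands = candidate_backgrounds(table, max_size)
    # pair -> set of edges it verifies
    pair_edges: dict[tuple[KOSet, KOSet], set[Edge]] = {}
    for edge, backgrounds in cands.items():
        i = edge[0]
        for vk in backgrounds:
            pair_edges.setdefault((vk, vk | {i}), set()).add(edge)

    chosen: list[KOSet] = []
    covers: dict[KOSet, set[Edge]] = {}
    covered: set[Edge] = set()

    def available() -> set[KOSet]:
        return performed | set(chosen)

    for _ in range(budget):
        best = None
        for (vk, test), edges in pair_edges.items():
            gain = edges - covered
            if not gain:
                continue
            new_sets = [s for s in (vk, test) if s not in available()]
            key = (
                -len(gain),
                len(new_sets),
                sum(len(s) for s in new_sets),
                sorted(map(sorted, new_sets)),
            )
            if best is None or key < best[0]:
                best = (key, new_sets, gain)
        if best is None:
            break
        _, new_sets, gain = best
        if not new_sets:
            # pair already fully performed: mark covered, costs nothing
            covered |= gain
            continue
        for s in new_sets:
            chosen.append(s)
            covers.setdefault(s, set()).update(gain)
        covered |= gain
    return DesignProposal(experiments=chosen, covers=covers, max_size=max_size)


def escalate_constraint(max_size: int) -> int:
    """Relax the KO-size constraint by one gene; invoked exactly when the
    design step cannot produce a feasible proposal for a non-empty E_U."""
    return max_size + 1


def multiplexed_design(
    table: SeparatoidTable,
    performed: Iterable[Iterable[str]],
    max_size: int = 2,
) -> DesignProposal:
    """Batch design for multiplexed assays.

    Runs the greedy step repeatedly, removing each run's coverable edges
    from the objective, and concatenates the proposals in generation
    order (earlier runs verify more edges, so a truncated batch should be
    executed in order).
    """
    performed = {frozenset(s) for s in performed}
    remaining = dict(table)
    proposal = DesignProposal(max_size=max_size)
    while remaining:
        step = greedy_design(remaining, performed | set(proposal.experiments),
                             max_size=max_size, budget=1)
        covered = step.covered_edges()
        if not covered and not step.experiments:
            break
        for s in step.experiments:
            if s not in proposal.covers:
                proposal.experiments.append(s)
            proposal.covers.setdefault(s, set()).update(step.covers.get(s, set()))
        for edge in covered:
            remaining.pop(edge, None)
    return proposal


def iterative_inference(
    model: KineticModel,
    config: SimConfig | None = None,
    w_cut: float = DEFAULT_W_CUT,
    multiplex: bool = False,
    max_iters: int = 50,
    alpha: float = 0.01,
    mode: str = "trace+",
    seed: int | None = None,
) -> tuple[EnsembleBounds, IterationLog, ExpressionDataset]:
    """Full closed-loop inference against the simulator.

    Simulates the complete single-KO compendium, builds the initial
    bounds, then alternates experiment design, simulation of the proposed
    KOs (cached into the growing compendium) and bounds updates.  The
    KO-size constraint starts at 2 and escalates when no proposal is
    feasible; the loop ends when E_U empties (a unique network), when no
    proposal exists at any size <= n - 2, or after ``max_iters``
    iterations.  Fully determined by ``seed`` (defaults to
    ``config.seed``).
    """
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    genes = model.genes
    data = generate_compendium(
        model, single_ko_design(genes), config.replicates, rng.spawn(1)[0], config
    )
    bounds = build_initial_bounds(data, w_cut=w_cut, mode=mode)
    log = IterationLog()
    log.append(
        iteration=0,
        proposed=0,
        cumulative_experiments=len(data.ko_sets),
        max_ko_size=1,
        uncertain=len(bounds.uncertain),
        upper_size=bounds.upper.m,
        lower_size=bounds.lower.m,
    )
    max_size = 2
    iteration = 0
    while bounds.uncertain and iteration < max_iters:
        table = compute_separatoids(bounds)
        if multiplex:
            proposal = multiplexed_design(table, data.ko_sets, max_size)
        else:
            proposal = greedy_design(table, data.ko_sets, max_size, budget=1)
        if not proposal:
            if max_size >= len(genes) - 2:
                break
            max_size = escalate_constraint(max_size)
            continue
        iteration += 1
        new_data = generate_compendium(
            model, proposal.experiments, config.replicates, rng.spawn(1)[0], config
        )
        data = data.extend(new_data)
        bounds, _ = update_bounds(bounds, data, alpha=alpha)
        log.append(
            iteration=iteration,
            proposed=len(proposal.experiments),
            cumulative_experiments=len(data.ko_sets),
            max_ko_size=max_size,
            uncertain=len(bounds.uncertain),
            upper_size=bounds.upper.m,
            lower_size=bounds.lower.m,
        )
    return bounds, log, data
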