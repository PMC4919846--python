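"""Initial ensemble bounds from a complete single-gene-KO compendium.

The ensemble upper bound G^U is the signed accessibility relation read
from KO differential-expression z-scores: gene j is accessible from gene i
when the replicate-averaged z-score |Z(i, j)| exceeds a threshold, and the
edge sign is positive when KO of i lowers j (Z <= 0).  The lower bound G^L
is obtained by a signed local transitive reduction (LTR): an upper-bound
edge (i, j) is removed when some length-2 path i -> k -> j in G^U is sign
consistent, S(i,j) = S(i,k) S(k,j), and strong enough,
w_cut * W(i,j) < W(i,k) * W(k,j), where W holds replicate-averaged absolute
correlations.  Every removal test is evaluated against the original upper
bound, so the reduction is independent of edge ordering.  The unsigned
ConTREx baseline (condensation -> DAG transitive reduction -> expansion)
is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .digraph import (
    SignedDigraph,
    condense,
    transitive_reduction_dag,
)
from .simulate import ExpressionDataset

__all__ = [
    "EnsembleBounds",
    "corrected_stats",
    "zscore_matrix",
    "accessibility_from_z",
    "edge_weights",
    "signed_ltr",
    "contrex_unsigned",
    "build_initial_bounds",
]

DEFAULT_Z_CUTOFF = 3.0
DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_W_CUT = 0.3


@dataclass
class EnsembleBounds:
    """Upper/lower signed digraphs bracketing every network consistent with
    the data, plus the frozen initial upper bound used by the separatoid
    formulas.

    Invariant: the lower bound's edges are a subset of the upper bound's
    with matching signs; the uncertain set E_U is their difference.
    """

    upper: SignedDigraph
    lower: SignedDigraph
    initial_upper: SignedDigraph = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.initial_upper is None:
            self.initial_upper = self.upper.copy()
        self.validate()

    def validate(self) -> None:
        for (u, v, s) in self.lower.edges:
            if (u, v) not in self.upper or self.upper.sign(u, v) != s:
                raise ValueError(
                    f"lower-bound edge ({u}, {v}, {s:+d}) missing from upper bound"
                )

    @property
    def uncertain(self) -> set[tuple[str, str]]:
        """E_U: ordered pairs in the upper bound but not the lower bound."""
        return self.upper.edge_pairs - self.lower.edge_pairs

    def confirm_edge(self, i: str, j: str, sign: int) -> None:
        """Move an uncertain edge into the lower bound with the voted sign,
        overwriting the upper bound's sign if the vote disagrees with it."""
        if (i, j) not in self.upper or (i, j) in self.lower:
            raise ValueError(f"edge ({i}, {j}) is not uncertain")
        if self.upper.sign(i, j) != sign:
            self.upper.set_sign(i, j, sign)
        self.lower.add_edge(i, j, sign)

    def remove_edge(self, i: str, j: str) -> None:
        """Remove an uncertain edge from the upper bound."""
        if (i, j) not in self.upper or (i, j) in self.lower:
            raise ValueError(f"edge ({i}, {j}) is not uncertain")
        self.upper.remove_edge(i, j)

    def copy(self) -> "EnsembleBounds":
        return EnsembleBounds(
            self.upper.copy(), self.lower.copy(), self.initial_upper.copy()
        )


# ---------------------------------------------------------------------------
# z-score accessibility
# ---------------------------------------------------------------------------


def corrected_stats(
    values: Sequence[float], z_cutoff: float = DEFAULT_Z_CUTOFF
) -> tuple[float, float]:
    """Outlier-corrected mean and standard deviation of one gene's
    expression across experiments.

    First computes the raw mean mu' and std s', then recomputes both after
    a single pass excluding values farther than ``z_cutoff * s'`` from mu'.
    KO effects on the gene are the outliers this removes, so the corrected
    statistics estimate the unperturbed baseline.  Falls back to the raw
    statistics (with a warning) if the pass excludes everything.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least three values")
    mu0 = float(values.mean())
    s0 = float(values.std(ddof=1))
    keep = np.abs(values - mu0) <= z_cutoff * s0
    if not keep.any():
        warnings.warn("all values excluded; using uncorrected stats", stacklevel=2)
        return mu0, s0
    kept = values[keep]
    mu = float(kept.mean())
    s = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return mu, s


def zscore_matrix(
    data: ExpressionDataset, z_cutoff: float = DEFAULT_Z_CUTOFF
) -> pd.DataFrame:
    """Replicate-averaged KO z-score matrix Z(i, j).

    Within each technical replicate, for each gene j, the corrected
    baseline (mu_j, s_j) is estimated across the experiment axis and
    z(i, j) = (g_ij - mu_j) / s_j is computed for every single-KO
    experiment i; Z is the mean over replicates.  Rows index the KO'd
    gene, columns the read-out gene; the diagonal is undefined (NaN).

    When the corrected s_j collapses to zero (the one-pass exclusion left a
    constant sample) the uncorrected statistics are used instead; a gene
    that is genuinely constant across all experiments contributes z = 0.
    """
    genes = data.genes
    single = [k for k, s in enumerate(data.ko_sets) if len(s) == 1]
    missing = set(genes) - {next(iter(data.ko_sets[k])) for k in single}
    if missing:
        raise ValueError(f"incomplete single-KO design; missing {sorted(missing)}")
    if data.replicates < 2:
        raise ValueError("need at least two technical replicates")
    n = len(genes)
    z_sum = np.zeros((n, n))
    ko_of = {next(iter(data.ko_sets[k])): k for k in single}
    for rep in range(data.replicates):
        mat = data.values[:, :, rep]  # gene x experiment
        for j in range(n):
            col = mat[j, :]
            mu, s = corrected_stats(col, z_cutoff)
            if s == 0.0:
                mu = float(col.mean())
                s = float(col.std(ddof=1))
            for gi, gene_i in enumerate(genes):
                if gi == j:
                    continue
                g_ij = mat[j, ko_of[gene_i]]
                z_sum[gi, j] += (g_ij - mu) / s if s > 0 else 0.0
    z = z_sum / data.replicates
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=genes, columns=genes)


def accessibility_from_z(
    z: pd.DataFrame, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> SignedDigraph:
    """Signed upper bound from the z-score matrix.

    Edge (i, j) exists iff |Z(i, j)| > z_threshold (strict); its sign is
    +1 when Z(i, j) <= 0 (KO of an activator lowers its target) and -1
    otherwise.  The diagonal never yields edges.
    """
    genes = list(z.index)
    g = SignedDigraph(genes)
    mat = z.to_numpy()
    for a, i in enumerate(genes):
        for b, j in enumerate(genes):
            if a == b or not np.isfinite(mat[a, b]):
                continue
            if abs(mat[a, b]) > z_threshold:
                g.add_edge(i, j, 1 if mat[a, b] <= 0 else -1)
    return g


# ---------------------------------------------------------------------------
# Edge weights
# ---------------------------------------------------------------------------


def edge_weights(data: ExpressionDataset) -> pd.DataFrame:
    """Regulation-strength matrix W(i, j): replicate-averaged magnitude of
    the Pearson correlation between genes i and j across single-KO
    experiments, excluding the KO-of-j experiment (whose zero reflects the
    deletion of j, not the influence of i).  W is asymmetric because the
    exclusion differs between (i, j) and (j, i).  Zero-variance vectors
    contribute 0 with a warning.
    """
    genes = data.genes
    n = len(genes)
    keep = [k for k, s in enumerate(data.ko_sets) if len(s) <= 1]
    ko_of = {
        next(iter(data.ko_sets[k])): k for k in keep if len(data.ko_sets[k]) == 1
    }
    if len(keep) - 1 < 3:
        raise ValueError("need at least three experiments after exclusion")
    w_sum = np.zeros((n, n))
    degenerate = False
    for rep in range(data.replicates):
        mat = data.values[:, keep, rep]  # gene x experiment
        for j, gene_j in enumerate(genes):
            mask = np.ones(len(keep), dtype=bool)
            if gene_j in ko_of:
                mask[keep.index(ko_of[gene_j])] = False
            sub = mat[:, mask]
            yj = sub[j, :]
            sj = yj.std()
            si = sub.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = ((sub - sub.mean(axis=1, keepdims=True)) * (yj - yj.mean())).mean(
                    axis=1
                )
                corr = cov / (si * sj)
            bad = ~np.isfinite(corr)
            if bad.any():
                degenerate = True
                corr[bad] = 0.0
            w_sum[:, j] += np.abs(corr)
    if degenerate:
        warnings.warn(
            "zero-variance gene vectors contributed weight 0", stacklevel=2
        )
    w = np.clip(w_sum / data.replicates, 0.0, 1.0)
    np.fill_diagonal(w, np.nan)
    return pd.DataFrame(w, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# Lower bounds
# ---------------------------------------------------------------------------


def signed_ltr(
    upper: SignedDigraph,
    w_cut: float = DEFAULT_W_CUT,
    weights: pd.DataFrame | None = None,
    edge_order: Sequence[tuple[str, str]] | None = None,
) -> SignedDigraph:
    """Signed local transitive reduction of the upper bound.

    Removes every edge (i, j) for which some length-2 path i -> k -> j in
    the *original* upper bound is sign consistent
    (S(i,j) = S(i,k) S(k,j)) and satisfies the strict weight test
    w_cut * W(i,j) < W(i,k) * W(k,j).  Because all tests run against the
    original graph the outcome does not depend on the order in which edges
    are examined; ``edge_order`` only reorders the (equivalent) passes and
    exists so order independence can be exercised directly.

    With ``w_cut = 0`` and no weights the weight test degenerates to
    0 < 1 and only sign consistency matters.
    """
    if not 0.0 <= w_cut <= 1.0:
        raise ValueError("w_cut must lie in [0, 1]")

    def wgt(u: str, v: str) -> float:
        if weights is not None:
            val = float(weights.loc[u, v])
            return val if np.isfinite(val) else 0.0
        w = upper.weight(u, v)
        return 1.0 if w is None else w

    lower = upper.copy()
    order = list(edge_order) if edge_order is not None else sorted(upper.edge_pairs)
    for (i, j) in order:
        if (i, j) not in upper:
            continue
        s_ij = upper.sign(i, j)
        for k in upper.children(i):
            if k in (i, j) or (k, j) not in upper:
                continue
            if s_ij != upper.sign(i, k) * upper.sign(k, j):
                continue
            if w_cut * wgt(i, j) < wgt(i, k) * wgt(k, j):
                lower.remove_edge(i, j)
                break
    return lower


def contrex_unsigned(upper: SignedDigraph) -> SignedDigraph:
    """Unsigned ensemble lower bound: condensation -> DAG transitive
    reduction -> expansion.

    Strongly connected components are lumped, the quotient DAG is
    transitively reduced, and on expansion every edge incident to a
    component of two or more nodes is dropped except the two edges of each
    two-node cycle.  Signs are copied from the upper bound for bookkeeping
    only; the procedure ignores them.
    """
    dag, mapping = condense(upper)
    reduced = transitive_reduction_dag(dag)
    members = {c: set(dag.nodes[c]["members"]) for c in dag.nodes}
    lower = SignedDigraph(upper.nodes, ordered=True)
    # intra-component edges: keep only both edges of 2-node cycles
    for c, nodes_c in members.items():
        if len(nodes_c) == 2:
            u, v = sorted(nodes_c)
            if (u, v) in upper and (v, u) in upper:
                lower.add_edge(u, v, upper.sign(u, v))
                lower.add_edge(v, u, upper.sign(v, u))
    # inter-component edges of the reduced DAG, between singleton components
    for (cu, cv) in reduced:
        if len(members[cu]) > 1 or len(members[cv]) > 1:
            continue
        (u,) = members[cu]
        (v,) = members[cv]
        if (u, v) in upper:
            lower.add_edge(u, v, upper.sign(u, v))
    return lower


def build_initial_bounds(
    data: ExpressionDataset,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    w_cut: float = DEFAULT_W_CUT,
    mode: str = "trace+",
) -> EnsembleBounds:
    """Construct the initial ensemble bounds from single-KO data.

    ``trace+`` chains z-scores -> signed accessibility (upper) -> edge
    weights -> signed LTR (lower).  ``trace`` keeps the same upper-bound
    skeleton but derives the lower bound with the unsigned ConTREx
    baseline (signs carried for bookkeeping only).
    """
    if mode not in ("trace", "trace+"):
        raise ValueError(f"unknown mode {mode!r}")
    single = data.single_ko_subset()
    z = zscore_matrix(single, z_cutoff)
    upper = accessibility_from_z(z, z_threshold)
    if mode == "trace":
        lower = contrex_unsigned(upper)
    else:
        w = edge_weights(single)
        lower = signed_ltr(upper, w_cut, weights=w)
    return EnsembleBounds(upper=upper, lower=lower)
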