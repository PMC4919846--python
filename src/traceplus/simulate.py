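"""Random GRN generation and stochastic steady-state KO expression data.

The simulator produces steady-state mRNA profiles for gene knock-out (KO)
experiments from a chemical-Langevin transcription/translation model

    dx_i = [m_i f_i(y) - lam_i^RNA x_i] dt + sigma_int dW
    dy_i = [r_i x_i  - lam_i^Prot y_i] dt + sigma_int dW

where x is mRNA, y is protein, m_i the maximal transcription rate, r_i the
translation rate constant and lam the degradation constants.  Regulation is
a multiplicative Hill function f_i(y) in [0, 1]: activators contribute
y^h/(K^h + y^h) terms and repressors K^h/(K^h + y^h) terms, with a basal
leak b_i.  A knock-out deletes the gene: its mRNA and protein states are
pinned at zero for the whole trajectory.  Technical replicates receive
independent intrinsic-noise paths and multiplicative log-normal
measurement noise exp(N(0, sigma_meas^2)).

Integration is Euler-Maruyama with non-negativity clipping; the steady
state is the time average over the final fraction of the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .digraph import SignedDigraph

__all__ = [
    "KineticModel",
    "SimConfig",
    "ExpressionDataset",
    "random_grn",
    "random_kinetic_model",
    "regulation_function",
    "simulate_steady_state",
    "generate_compendium",
    "single_ko_design",
    "double_ko_design",
    "read_dataset",
    "write_dataset",
    "SimulationError",
]

KOSet = frozenset


class SimulationError(RuntimeError):
    """Raised when an integration trajectory becomes non-finite."""


@dataclass
class SimConfig:
    """Integration settings for the Langevin simulator.

    ``dt`` and ``horizon`` are in the model's time unit (degradation rates
    ~1 imply relaxation times ~1, so the default horizon covers dozens of
    relaxation times); the steady state is averaged over the trailing
    ``tail_fraction`` of the horizon to damp Langevin fluctuations.
    """

    dt: float = 0.05
    horizon: float = 40.0
    tail_fraction: float = 0.2
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dt < self.horizon:
            raise ValueError("integration step must satisfy 0 < dt < horizon")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass
class KineticModel:
    """Per-gene kinetic parameters plus per-edge regulation parameters.

    Arrays are aligned with ``network.nodes``.  ``hill_k[(j, i)]`` and
    ``hill_h[(j, i)]`` parameterize the regulation of gene i by the protein
    of gene j.  KO masks never alter the stored parameters; knock-outs are
    applied at simulation time.
    """

    network: SignedDigraph
    m: np.ndarray  # maximal transcription rate, concentration / time
    r: np.ndarray  # translation rate constant, 1 / time
    lam_rna: np.ndarray  # mRNA degradation, 1 / time
    lam_prot: np.ndarray  # protein degradation, 1 / time
    hill_k: dict[tuple[str, str], float] = field(default_factory=dict)
    hill_h: dict[tuple[str, str], float] = field(default_factory=dict)
    basal: float = 0.01
    sigma_int: float = 0.02
    sigma_meas: float = 0.05

    def __post_init__(self) -> None:
        n = self.network.n
        for name in ("m", "r", "lam_rna", "lam_prot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, arr)
        for (j, i) in self.network.edge_pairs:
            if self.hill_k.get((j, i), 1.0) <= 0:
                raise ValueError(f"half-saturation K for edge ({j}, {i}) must be > 0")
            if self.hill_h.get((j, i), 1.0) < 1:
                raise ValueError(f"Hill exponent for edge ({j}, {i}) must be >= 1")
        if self.sigma_int < 0 or self.sigma_meas < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.network.nodes

    def unregulated_steady_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Fixed point (x*, y*) of the drift with f_i = 1 for every gene."""
        x = self.m / self.lam_rna
        y = self.r * x / self.lam_prot
        return x, y


@dataclass
class ExpressionDataset:
    """Steady-state expression tensor ``values[gene, experiment, replicate]``
    with one KO set per experiment (the empty set is the wild type)."""

    genes: tuple[str, ...]
    ko_sets: list[KOSet]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.ko_sets = [frozenset(s) for s in self.ko_sets]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(self.genes), len(self.ko_sets)):
            raise ValueError("tensor dimensions must match genes x experiments")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def replicates(self) -> int:
        return self.values.shape[2]

    def experiment_index(self, ko_set: Iterable[str]) -> int:
        key = frozenset(ko_set)
        try:
            return self.ko_sets.index(key)
        except ValueError:
            raise KeyError(f"no experiment with KO set {sorted(key)}") from None

    def has_experiment(self, ko_set: Iterable[str]) -> bool:
        return frozenset(ko_set) in self.ko_sets

    def gene_values(self, gene: str, ko_set: Iterable[str]) -> np.ndarray:
        """Replicate vector of one gene under one experiment."""
        return self.values[self.genes.index(gene), self.experiment_index(ko_set), :]

    def single_ko_subset(self, include_wildtype: bool = True) -> "ExpressionDataset":
        keep = [
            k
            for k, s in enumerate(self.ko_sets)
            if len(s) == 1 or (include_wildtype and len(s) == 0)
        ]
        return ExpressionDataset(
            self.genes, [self.ko_sets[k] for k in keep], self.values[:, keep, :]
        )

    def extend(self, other: "ExpressionDataset") -> "ExpressionDataset":
        """Concatenate experiments (genes and replicate count must match);
        experiments already present are kept once (first occurrence wins)."""
        if other.genes != self.genes or other.replicates != self.replicates:
            raise ValueError("datasets are not alignable")
        keep = [k for k, s in enumerate(other.ko_sets) if s not in self.ko_sets]
        return ExpressionDataset(
            self.genes,
            self.ko_sets + [other.ko_sets[k] for k in keep],
            np.concatenate([self.values, other.values[:, keep, :]], axis=1),
        )


# ---------------------------------------------------------------------------
# Random networks and kinetic parameters
# ---------------------------------------------------------------------------


def _gene_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"G{k:0{width}d}" for k in range(1, n + 1)]


def random_grn(
    n: int,
    mean_out_degree: float = 1.5,
    negative_fraction: float = 0.3,
    allow_cycles: bool = False,
    seed: int | np.random.Generator = 0,
) -> SignedDigraph:
    """Sample a random signed GRN with ``n`` genes.

    Each admissible ordered pair receives an edge independently with the
    probability that makes the expected edge count ``n * mean_out_degree``;
    for DAGs only pairs respecting a random topological order are
    admissible.  Signs are negative with probability ``negative_fraction``.
    """
    if n < 2:
        raise ValueError("need at least two genes")
    if not 0 <= negative_fraction <= 1:
        raise ValueError("negative_fraction must lie in [0, 1]")
    if mean_out_degree >= n - 1 and not allow_cycles:
        raise ValueError("mean out-degree infeasible for a DAG of this order")
    if mean_out_degree > n - 1:
        raise ValueError("mean out-degree cannot exceed n - 1")
    rng = np.random.default_rng(seed)
    names = _gene_names(n)
    order = [str(v) for v in rng.permutation(names)]
    g = SignedDigraph(names)
    if allow_cycles:
        pairs = [(u, v) for u in names for v in names if u != v]
        p = n * mean_out_degree / len(pairs)
    else:
        pairs = [(order[a], order[b]) for a in range(n) for b in range(a + 1, n)]
        p = n * mean_out_degree / len(pairs)
    draws = rng.random(len(pairs))
    neg = rng.random(len(pairs)) < negative_fraction
    for k, (u, v) in enumerate(pairs):
        if draws[k] < p:
            g.add_edge(u, v, -1 if neg[k] else 1)
    return g


def random_kinetic_model(
    network: SignedDigraph,
    seed: int | np.random.Generator = 0,
    basal: float = 0.01,
    sigma_int: float = 0.02,
    sigma_meas: float = 0.05,
) -> KineticModel:
    """Draw kinetic parameters for a network.

    Rates are uniform: m in [0.5, 2], r in [0.5, 2], degradation in
    [0.5, 1.5].  Each edge's half-saturation K is calibrated to the
    regulator's wild-type steady-state protein level (computed by fixed-
    point iteration of the deterministic rate equations), so that in the
    wild type every regulator sits at the midpoint of its response curve
    and knock-out swings produce strong expression changes even deep in
    regulatory cascades.  Hill exponents are drawn from {1, 2}.
    """
    rng = np.random.default_rng(seed)
    n = network.n
    m = rng.uniform(0.5, 2.0, n)
    r = rng.uniform(0.5, 2.0, n)
    lam_rna = rng.uniform(0.5, 1.5, n)
    lam_prot = rng.uniform(0.5, 1.5, n)
    y_free = (m / lam_rna) * r / lam_prot
    idx = {v: k for k, v in enumerate(network.nodes)}
    hill_k = {(j, i): float(y_free[idx[j]]) for (j, i) in sorted(network.edge_pairs)}
    hill_h = {
        (j, i): float(rng.choice([1.0, 2.0])) for (j, i) in sorted(network.edge_pairs)
    }
    model = KineticModel(
        network=network,
        m=m,
        r=r,
        lam_rna=lam_rna,
        lam_prot=lam_prot,
        hill_k=hill_k,
        hill_h=hill_h,
        basal=basal,
        sigma_int=0.0,
        sigma_meas=0.0,
    )
    # calibrate K to the wild-type protein levels: recompute the
    # deterministic fixed point and re-anchor K a few times
    for _ in range(3):
        y_wt = _deterministic_fixed_point(model)[1]
        floor = 0.05 * y_free
        model.hill_k = {
            (j, i): float(max(y_wt[idx[j]], floor[idx[j]]))
            for (j, i) in sorted(network.edge_pairs)
        }
    hill_k = model.hill_k
    return KineticModel(
        network=network,
        m=m,
        r=r,
        lam_rna=lam_rna,
        lam_prot=lam_prot,
        hill_k=hill_k,
        hill_h=hill_h,
        basal=basal,
        sigma_int=sigma_int,
        sigma_meas=sigma_meas,
    )


def _deterministic_fixed_point(
    model: "KineticModel", iters: int = 400, damping: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Damped fixed-point iteration of x = m f(y) / lam_rna,
    y = r x / lam_prot from the unregulated state."""
    edges = _edge_arrays(model)
    x, y = model.unregulated_steady_state()
    x = x.copy()[None, :]
    y = y.copy()[None, :]
    for _ in range(iters):
        f = _regulation_batch(y, edges, model.basal)
        x_new = model.m * f / model.lam_rna
        y_new = model.r * x / model.lam_prot
        x = damping * x_new + (1 - damping) * x
        y = damping * y_new + (1 - damping) * y
    return x[0], y[0]


# ---------------------------------------------------------------------------
# Regulation function and integration
# ---------------------------------------------------------------------------


def _edge_arrays(model: KineticModel):
    """Precompute per-edge index/parameter arrays for vectorized f(y)."""
    idx = {v: k for k, v in enumerate(model.genes)}
    srcs, tgts, ks, hs, acts = [], [], [], [], []
    for (j, i, s) in sorted(model.network.edges):
        srcs.append(idx[j])
        tgts.append(idx[i])
        ks.append(model.hill_k.get((j, i), 1.0))
        hs.append(model.hill_h.get((j, i), 1.0))
        acts.append(s > 0)
    regulated = np.zeros(len(model.genes), dtype=bool)
    regulated[tgts] = True
    return (
        np.array(srcs, dtype=int),
        np.array(tgts, dtype=int),
        np.array(ks, dtype=float),
        np.array(hs, dtype=float),
        np.array(acts, dtype=bool),
        regulated,
    )


def _regulation_batch(y: np.ndarray, edges, basal: float) -> np.ndarray:
    """f(y) for a batch of protein states, shape (paths, n) -> (paths, n)."""
    srcs, tgts, ks, hs, acts, regulated = edges
    f = np.ones(y.shape, dtype=float)
    if srcs.size:
        ya = np.clip(y[:, srcs], 0.0, None)
        num = ya**hs
        den = ks**hs + num
        term = np.where(acts, num / den, (ks**hs) / den)
        prod = np.ones(y.shape, dtype=float)
        rows = np.arange(y.shape[0])[:, None]
        np.multiply.at(prod, (rows, tgts[None, :]), term)
        f = np.where(regulated, basal + (1.0 - basal) * prod, 1.0)
    return f


def regulation_function(model: KineticModel, gene: str, y: Sequence[float]) -> float:
    """Transcription activation level f_i(y) in [0, 1] for one gene.

    Multiplicative Hill regulation: monotone increasing in each activator,
    decreasing in each repressor; genes without regulators return 1.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("protein levels must be non-negative")
    edges = _edge_arrays(model)
    f = _regulation_batch(y[None, :], edges, model.basal)
    return float(f[0, model.genes.index(gene)])


def simulate_steady_state(
    model: KineticModel,
    ko_set: Iterable[str],
    config: SimConfig,
    replicate_seed: int | np.random.Generator = 0,
    n_paths: int = 1,
) -> np.ndarray:
    """Steady-state mRNA levels under a knock-out.

    Integrates the chemical-Langevin system by Euler-Maruyama from the
    zero state, pinning every KO'd gene's mRNA and protein at zero, and
    returns the time average of the mRNA trajectory over the trailing
    ``config.tail_fraction`` of the horizon.  With ``n_paths > 1`` the
    replicate paths share parameters but draw independent noise; the
    result has shape ``(n_paths, n_genes)`` (``(n_genes,)`` otherwise).
    """
    ko = frozenset(ko_set)
    unknown = ko - set(model.genes)
    if unknown:
        raise KeyError(f"unknown KO genes {sorted(unknown)}")
    rng = np.random.default_rng(replicate_seed)
    n = len(model.genes)
    edges = _edge_arrays(model)
    ko_mask = np.array([g in ko for g in model.genes])
    m = np.where(ko_mask, 0.0, model.m)

    steps = int(round(config.horizon / config.dt))
    tail_start = int(np.floor(steps * (1.0 - config.tail_fraction)))
    x = np.zeros((n_paths, n))
    y = np.zeros((n_paths, n))
    sqrt_dt = np.sqrt(config.dt)
    acc = np.zeros((n_paths, n))
    n_acc = 0
    for step in range(steps):
        f = _regulation_batch(y, edges, model.basal)
        dx = (m * f - model.lam_rna * x) * config.dt
        dy = (model.r * x - model.lam_prot * y) * config.dt
        if model.sigma_int > 0:
            dx = dx + model.sigma_int * sqrt_dt * rng.standard_normal((n_paths, n))
            dy = dy + model.sigma_int * sqrt_dt * rng.standard_normal((n_paths, n))
        x = np.clip(x + dx, 0.0, None)
        y = np.clip(y + dy, 0.0, None)
        x[:, ko_mask] = 0.0
        y[:, ko_mask] = 0.0
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise SimulationError(f"non-finite state at step {step}")
        if step >= tail_start:
            acc += x
            n_acc += 1
    out = acc / max(n_acc, 1)
    return out if n_paths > 1 else out[0]


def generate_compendium(
    model: KineticModel,
    ko_sets: Sequence[Iterable[str]],
    replicates: int = 10,
    seed: int | np.random.Generator = 0,
    config: SimConfig | None = None,
) -> ExpressionDataset:
    """Simulate a KO compendium: one steady state per (experiment, replicate)
    with independent intrinsic-noise paths, then multiplicative log-normal
    measurement noise exp(N(0, sigma_meas^2))."""
    if replicates < 2:
        raise ValueError("need at least two technical replicates")
    if not model.genes:
        raise ValueError("model has no genes")
    config = config or SimConfig()
    ko_sets = [frozenset(s) for s in ko_sets]
    if len(set(ko_sets)) < len(ko_sets):
        warnings.warn("duplicate KO sets in design", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(model.genes)
    values = np.empty((n, len(ko_sets), replicates))
    for k, ko in enumerate(ko_sets):
        sub = rng.spawn(1)[0]
        paths = simulate_steady_state(model, ko, config, sub, n_paths=replicates)
        values[:, k, :] = paths.T
    if model.sigma_meas > 0:
        eps = rng.normal(0.0, model.sigma_meas, values.shape)
        values = values * np.exp(eps)
    return ExpressionDataset(model.genes, ko_sets, values)


# ---------------------------------------------------------------------------
# KO designs
# ---------------------------------------------------------------------------


def single_ko_design(genes: Iterable[str]) -> list[KOSet]:
    """Wild type followed by every single-gene KO: [{}, {g1}, ..., {gn}]."""
    genes = list(genes)
    return [frozenset()] + [frozenset([g]) for g in genes]


def double_ko_design(genes: Iterable[str]) -> list[KOSet]:
    """The complete set of double-gene KOs, n*(n-1)/2 experiments."""
    genes = sorted(genes)
    return [
        frozenset([genes[a], genes[b]])
        for a in range(len(genes))
        for b in range(a + 1, len(genes))
    ]


# ---------------------------------------------------------------------------
# Dataset TSV I/O (long format)
# ---------------------------------------------------------------------------


def write_dataset(data: ExpressionDataset, path) -> None:
    """Long-format TSV: experiment_id, ko_genes (comma-joined, empty = WT),
    replicate, gene, value."""
    rows = []
    for k, ko in enumerate(data.ko_sets):
        label = ",".join(sorted(ko))
        for rep in range(data.replicates):
            for gi, gene in enumerate(data.genes):
                rows.append((k, label, rep, gene, data.values[gi, k, rep]))
    frame = pd.DataFrame(
        rows, columns=["experiment_id", "ko_genes", "replicate", "gene", "value"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_dataset(path) -> ExpressionDataset:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"ko_genes": str})
    genes = tuple(sorted(frame["gene"].unique()))
    exp_ids = sorted(frame["experiment_id"].unique())
    reps = sorted(frame["replicate"].unique())
    ko_sets: list[KOSet] = []
    values = np.zeros((len(genes), len(exp_ids), len(reps)))
    gidx = {g: k for k, g in enumerate(genes)}
    ridx = {r: k for k, r in enumerate(reps)}
    eidx = {e: k for k, e in enumerate(exp_ids)}
    for e in exp_ids:
        sub = frame[frame["experiment_id"] == e]
        label = sub["ko_genes"].iloc[0]
        ko_sets.append(frozenset(label.split(",")) if label else frozenset())
    for row in frame.itertuples(index=False):
        values[gidx[row.gene], eidx[row.experiment_id], ridx[row.replicate]] = row.value
    return ExpressionDataset(genes, ko_sets, values)
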