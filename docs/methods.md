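# Methods

## Model and scope

The package treats a gene regulatory network as a signed digraph: one
edge per ordered gene pair, sign +1 for transcriptional activation and
−1 for repression, no self-loops (a gene's own deletion trivially zeroes
it, so self-regulation is invisible to KO data; cycle membership is
tracked on the accessibility matrix diagonal instead).  All inference
operates on steady-state mRNA profiles of gene knock-out experiments
with technical replicates.

The central objects are the ensemble bounds (G^U, G^L): the largest and
smallest signed digraphs bracketing every network consistent with the
data.  The initial upper bound G^{U,0} is frozen at construction because
the separatoid formulas reference it alongside the current G^U.

## Upper bound: z-score accessibility

Within each technical replicate, for each gene j, the sample mean μ'_j
and standard deviation s'_j (ddof = 1) are taken across all provided
single-KO experiments (the wild type included when present — its
expression is a legitimate draw from the unperturbed baseline).  One
exclusion pass removes values farther than z_cutoff·s'_j from μ'_j;
the corrected (μ_j, s_j) then feed z(i, j) = (g_ij − μ_j)/s_j, averaged
over replicates into Z(i, j).  Edges are |Z| > z_threshold (strict),
signed +1 for Z ≤ 0.  Defaults z_cutoff = 3, z_threshold = 2, 10
replicates, α = 0.01 for the update t-tests, w_cut = 0.3 for the
reduction.

Degenerate case: when the exclusion pass leaves a constant sample
(s_j = 0) the uncorrected (μ'_j, s'_j) are used instead; a gene whose
column is genuinely constant contributes z = 0.  Without this fallback a
noise-free compendium — where the corrected sample is exactly constant —
would yield an empty upper bound.

### Detection limit (important)

The z-score is scale-free: if a gene's expression column contains k
comparable KO effects among N experiments, the largest attainable |z|
for any of them is √((N−k)(N−1)/(kN)) — independent of effect size and
of noise level — and the one-pass exclusion at z_cutoff = 3 only fires
for k ≤ 2 when N ≈ 21.  Consequently, with the complete single-KO design
over n genes (N = n + 1 experiments), edges into genes with roughly four
or more strong-effect ancestors fall below z_threshold = 2 and are lost
from G^U as false negatives, which no later update can repair.  This is
a property of the method, not of the implementation: measured
false-negative fractions on simulated 20-gene compendia (~0.3–0.6 of
reference edges) sit in the same regime as published applications of
this inference family to larger networks.  It also means exact recovery
of a dense reference network from a 21-experiment compendium is not
attainable; the acceptance script reports the measured
`exact_recovery_fraction` honestly rather than asserting it.  Unit tests
that exercise "every edge detected" therefore use shallow fixtures
(≤ 2 ancestors per gene, ~20 genes), where the bound clears the
threshold.

## Lower bound

**Signed local transitive reduction.**  An edge (i, j) is removed when
some k ∉ {i, j} with (i, k), (k, j) ∈ E(G^U) satisfies both
S(i,j) = S(i,k)·S(k,j) and w_cut·W(i,j) < W(i,k)·W(k,j) (strict; a tie
retains the edge).  Only length-2 paths are considered, which sidesteps
the sign ambiguity of negative cycles, and every test is evaluated
against the original upper bound, making the outcome independent of the
order in which edges are examined.  Raising w_cut makes removal harder,
so |E(G^L)| is non-decreasing in w_cut.

**Weights.**  W(i, j) is the replicate-averaged |Pearson correlation| of
genes i and j across single-KO experiments, excluding the KO-of-j
experiment (its zero reflects the deletion, not regulation).  Pearson is
used because the length-2 strength heuristic treats influence as
propagating linearly; the exclusion makes W asymmetric.  Zero-variance
vectors contribute 0 with a warning.

**Unsigned baseline.**  Condensation of strongly connected components,
transitive reduction of the quotient DAG, then expansion dropping every
edge incident to a ≥ 2-node component except the two edges of each
two-node cycle.

## Bounds update

Separatoids per uncertain edge (i, j), with i, j removed from each set:

    Sep1 = children(i) in G^U      ∩ ancestors(j) in G^{U,0}
    Sep2 = descendants(i) in G^{U,0} ∩ parents(j) in G^U
    Sep3 = descendants(i) in G^{U,0} ∩ ancestors(j) in G^{U,0}

Only these three are computed; enumerating all separatoids is equivalent
to longest-path search (NP-hard).  "Separatoid contained in the
background" is read as non-strict inclusion, so a background equal to
the separatoid qualifies.  Verification pairs (V_k, V_k ∪ {i}) require
both experiments in the data and i, j ∉ V_k; they are deduplicated by
background and ordered by background size then lexicographically.

Votes: a pooled-variance two-tailed two-sample t-test per pair (Welch
available as an option); rejection is a vote for existence.  Strict
majority against removes the edge from G^U; strict majority for adds it
to G^L with sign +1 if the test mean is more often below the background
mean among confirming pairs (−1 if above; a direction tie keeps G^U's
sign; a confirmed sign that disagrees with G^U overwrites it).  A vote
tie leaves the edge uncertain.  Zero-variance samples on both sides are
decided by exact mean comparison so that noise-free data behaves like
the infinite-precision limit.

Each round computes all verdicts against the round-start bounds and
applies them together (order independence).  The loop stops when E_U is
empty, when no uncertain edge has a pair, or when a full round changes
nothing — the last rule covers perpetual vote ties, which the plain
"no suitable pairs" stopping rule does not.

## Experiment design

The reference optimizer for KO selection is a constrained optimization
over separatoids; since only its interface and objective are published,
this package implements a **greedy weighted set-cover surrogate** and
documents it as such.  Candidates are (background, background ∪ {i})
pairs built directly from separatoids of size ≤ max_size − 1; each
greedy step picks the pair completing verification for the most
uncovered uncertain edges (ties: fewer and smaller new experiments, then
lexicographic).  The non-multiplexed mode proposes one pair per
iteration; the multiplexed mode chains greedy runs, removing each run's
coverable edges from the objective, and preserves generation order so a
truncated batch should be executed front-first.  The KO-size constraint
starts at 2 and increments by 1 exactly when no feasible proposal
exists; the closed loop ends when E_U empties, when no proposal exists
at any size ≤ n − 2, or at max_iters.  All simulated experiments are
cached into the growing compendium, so repeated proposals cost nothing.

## Simulator

Chemical-Langevin transcription/translation per gene i:

    dx_i = [m_i f_i(y) − λ_i^RNA x_i] dt + σ_int dW
    dy_i = [r_i x_i  − λ_i^Prot y_i] dt + σ_int dW

with multiplicative Hill regulation
f_i(y) = b + (1−b)·Π_act y^h/(K^h+y^h) · Π_rep K^h/(K^h+y^h); genes
without regulators have f ≡ 1.  Defaults: rates m, r ~ U[0.5, 2],
degradations λ ~ U[0.5, 1.5] (time unit = one degradation timescale),
Hill h ∈ {1, 2}, basal fraction b = 0.01, σ_int = 0.02 and σ_meas = 0.05
on a concentration scale where steady states are O(1).  Half-saturation
constants are calibrated to each regulator's **wild-type** protein level
(damped deterministic fixed-point iteration, floored at 5% of the
unregulated level): anchoring K at the unregulated level instead drives
genes deep in activation cascades onto the basal floor, where KO effects
vanish — defeating the purpose of the parameter choice.

Integration: Euler–Maruyama, dt = 0.05, horizon 40 time units,
non-negativity clipping, steady state = time average over the trailing
20% of the horizon (damps Langevin fluctuations; the ODE relaxation
times are ≤ 2 time units, so the transient is long gone).  A knock-out
pins the gene's mRNA and protein at exactly zero (gene deletion), so
stored KO-gene expression is exactly zero before measurement noise.
Replicates draw independent intrinsic-noise paths; measurement noise
multiplies every value by exp(ε), ε ~ N(0, σ_meas²).  Everything is
driven by numpy Generators spawned from a single seed, so identical
(model, config, seed) give bit-identical datasets.

**What the simulator does not emulate:** thermodynamic promoter logic
with regulator synergy, partial knockdowns, time-series readouts, or
biological replicate variability beyond the Langevin noise.  Passing
tests therefore certify the inference logic under clean monotone
regulation with strong KO effects, not performance on microarray-scale
noise or combinatorial promoters.

## Random networks

`random_grn` places edges independently over admissible ordered pairs
(all pairs, or ascending pairs of a random permutation for DAGs) with
the probability giving expected size n·mean_out_degree; signs are
negative with probability negative_fraction.  Defaults
mean_out_degree = 1.5 and negative_fraction = 0.3 approximate the
sparsity and repression share of curated transcriptional networks.

## Evaluation

TPR = |E(G^L) ∩ E(ref)| / |E(ref)|;
TD = (|E(G^U) ∪ E(G^L) ∪ E(ref)| − |E(G^U) ∩ E(G^L) ∩ E(ref)|) / |E(ref)|;
JD(G1, G2) = (|union| − |intersection|) / |union| (0 for two empty
graphs, with a warning).  Signed mode counts an edge only when the signs
agree.  Error tallies follow the bound-specific definitions: FN =
reference pairs absent from G^U (sign ignored), FP = lower-bound pairs
absent from the reference, IS = reference pairs present in G^U with the
opposite sign; IS edges are tallied separately and simply drop out of
sign-respecting intersections.

## Problem sizes used by the automated checks

The test suite and `scripts/acceptance.py` run the statistical
properties at: 20 seeds × 20-gene networks for the signed-vs-unsigned
uncertainty comparison and for exact recovery, 10 noise-free 15-gene
DAG seeds for closed-loop convergence, 200 seeded ≤ 8-node digraphs for
separatoid validity, and 100 edge-order permutations for reduction
order-independence.  These sizes put every property in the regime the
method is designed for while keeping a full run under a minute on one
core.

## Known limitations

- The z-score detection limit above: dense or deep networks lose edges
  from G^U irrecoverably; exact recovery should not be expected beyond
  shallow topologies at n ≈ 20.
- False positives in G^L can arise when a separatoid computed on G^U
  fails to cut a true path that G^U itself is missing.
- The greedy design surrogate carries no optimality guarantee; it only
  mirrors the published objective (maximum newly verifiable edges).
- Sign votes use only confirming pairs; perpetually tying votes leave an
  edge uncertain by design.
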