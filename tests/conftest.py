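import numpy as np
import pytest

from traceplus import SignedDigraph


@pytest.fixture
def five_gene_network():
    """The bundled five-gene example network (7 edges, 3 repressions)."""
    from traceplus import worked_example_network

    return worked_example_network()


def random_digraph(rng: np.random.Generator, n: int, p: float) -> SignedDigraph:
    """Erdos-Renyi style random signed digraph (cycles allowed)."""
    names = [f"N{k}" for k in range(n)]
    g = SignedDigraph(names)
    for u in names:
        for v in names:
            if u != v and rng.random() < p:
                g.add_edge(u, v, 1 if rng.random() < 0.7 else -1)
    return g


def closure_pairs_bruteforce(g: SignedDigraph) -> set[tuple[str, str]]:
    """Reachable ordered pairs via boolean matrix powers (independent of
    the networkx-backed implementation)."""
    n = g.n
    adj = np.zeros((n, n), dtype=bool)
    idx = {v: k for k, v in enumerate(g.nodes)}
    for (u, v) in g.edge_pairs:
        adj[idx[u], idx[v]] = True
    reach = adj.copy()
    for _ in range(n):
        reach = reach | (reach @ adj)
    return {
        (g.nodes[i], g.nodes[j])
        for i in range(n)
        for j in range(n)
        if reach[i, j] and i != j
    }


def reaches_avoiding(g: SignedDigraph, i: str, j: str, banned: set[str]) -> bool:
    """Matrix-power oracle: path of length >= 2 from i to j avoiding
    ``banned`` nodes, ignoring the direct edge (i, j)."""
    keep = [v for v in g.nodes if v not in banned]
    idx = {v: k for k, v in enumerate(keep)}
    if i not in idx or j not in idx:
        return False
    n = len(keep)
    adj = np.zeros((n, n), dtype=bool)
    for (u, v) in g.edge_pairs:
        if (u, v) != (i, j) and u in idx and v in idx:
            adj[idx[u], idx[v]] = True
    # with the direct edge removed, any i -> j walk has length >= 2 and
    # implies a simple path of length >= 2
    reach = adj.copy()
    for _ in range(n):
        reach = reach | (reach @ adj)
    return bool(reach[idx[i], idx[j]])
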