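"""Independent brute-force oracles used by the test suite."""

import networkx as nx


def set_partitions(nodes):
    """Enumerate all set partitions (restricted-growth recursion)."""
    nodes = list(nodes)
    n = len(nodes)

    def rec(i, groups):
        if i == n:
            yield [set(g) for g in groups]
            return
        for g in groups:
            g.append(nodes[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([nodes[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    yield from rec(0, [])


def best_modularity_partition(G):
    """Exhaustive maximum-modularity partition (gamma = 1) of a small graph."""
    best_q, best_part = -2.0, None
    for part in set_partitions(G.nodes):
        q = nx.community.modularity(G, part)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def two_clique_fixture(trial, rng_factory):
    """One planted two-community graph: two cliques plus 0-2 inter-edges."""
    from itertools import combinations

    r = rng_factory(1000 + trial)
    s1, s2 = int(r.integers(3, 5)), int(r.integers(3, 5))
    G = nx.Graph()
    block_a = list(range(s1))
    block_b = list(range(s1, s1 + s2))
    for u, v in combinations(block_a, 2):
        G.add_edge(u, v)
    for u, v in combinations(block_b, 2):
        G.add_edge(u, v)
    for _ in range(int(r.integers(0, 3))):
        G.add_edge(int(r.choice(block_a)), int(r.choice(block_b)))
    return G
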