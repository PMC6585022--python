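import numpy as np
import pytest

from paralogon2r import msa, species


@pytest.fixture(scope="session")
def ref():
    return species.load_default()


@pytest.fixture()
def toy_alignment():
    text = (
        ">Hsap|g1|chr1\nACDEFGHIKL\n"
        ">Hsap|g2|chr8\nACDEFGHIKV\n"
        ">Mmus|g1\nACDEFGHIKL\n"
        ">Dmel|g1\nVWYACDEFGH\n"
    )
    return msa.read_alignment(text)


def random_additive_matrix(rng, n):
    """Random binary unrooted tree metric on n taxa.

    Built by sequential leaf insertion with positive edge lengths; returns
    (distance matrix, set of canonical non-trivial splits of the tree).
    """
    # adjacency: node -> {neighbor: length}; leaves are 0..n-1
    adj = {}
    nxt = [n]

    def add_edge(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    def edges():
        return [(u, v) for u in adj for v in adj[u] if u < v]

    c = nxt[0]
    nxt[0] += 1
    for leaf in range(3):
        add_edge(c, leaf, rng.uniform(0.1, 1.0))
    for leaf in range(3, n):
        u, v = edges()[rng.integers(len(edges()))]
        ln = adj[u].pop(v)
        adj[v].pop(u)
        w = nxt[0]
        nxt[0] += 1
        split = rng.uniform(0.2, 0.8)
        add_edge(u, w, ln * split)
        add_edge(w, v, ln * (1 - split))
        add_edge(w, leaf, rng.uniform(0.1, 1.0))

    # pairwise path lengths
    import heapq

    d = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        heap = [(0.0, s)]
        while heap:
            dd, u = heapq.heappop(heap)
            if dd > dist.get(u, np.inf):
                continue
            for v, ln in adj[u].items():
                alt = dd + ln
                if alt < dist.get(v, np.inf):
                    dist[v] = alt
                    heapq.heappush(heap, (alt, v))
        for t in range(n):
            d[s, t] = dist[t]
    d = (d + d.T) / 2.0  # exact symmetry despite float path sums

    # splits: remove each internal edge, collect leaf side
    labels = [str(i) for i in range(n)]
    splits = set()
    for u, v in edges():
        if u < n or v < n:
            continue  # leaf edge (leaves are < n, internals >= n)
        side = set()
        stack, seen = [u], {v}
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                side.add(labels[x])
            stack.extend(adj[x])
        if 2 <= len(side) <= n - 2:
            comp = frozenset(set(labels) - side)
            side = frozenset(side)
            splits.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
    return d, splits
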