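"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: tree topologies are
enumerated exhaustively and scored by non-negative least squares, and
schematic relabeling costs are found by enumerating every label
substitution.
"""

import itertools
import math

import numpy as np
from scipy.optimize import nnls


def _enumerate_unrooted(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge dicts."""
    base = {(0, n): None, (1, n): None, (2, n): None}
    tops = [dict(base)]
    nxt = n + 1
    for leaf in range(3, n):
        new_tops = []
        for top in tops:
            for edge in list(top):
                u, v = edge
                w = nxt
                t2 = dict(top)
                del t2[edge]
                t2[(min(u, w), max(u, w))] = None
                t2[(min(v, w), max(v, w))] = None
                t2[(min(leaf, w), max(leaf, w))] = None
                new_tops.append(t2)
        tops = new_tops
        nxt += 1
    return tops


def _paths_incidence(top, n):
    """0/1 matrix: row per leaf pair, column per edge on its path."""
    adj = {}
    for (u, v) in top:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    edges = sorted(top)
    eidx = {e: i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for r, (s, t) in enumerate(pairs):
        # DFS path
        stack = [(s, [])]
        seen = {s}
        while stack:
            x, path = stack.pop()
            if x == t:
                for e in path:
                    A[r, eidx[e]] = 1.0
                break
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, path + [(min(x, y), max(x, y))]))
    return A, edges, pairs


def _splits_of(top, n):
    adj = {}
    for (u, v) in top:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    labels = set(str(i) for i in range(n))
    out = set()
    for (u, v) in top:
        if u < n or v < n:
            continue
        side, stack, seen = set(), [u], {v}
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                side.add(str(x))
            stack.extend(adj[x])
        if 2 <= len(side) <= n - 2:
            comp = frozenset(labels - side)
            side = frozenset(side)
            out.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
    return out


def least_squares_topology_splits(d):
    """Splits of the best-fitting topology by exhaustive LS search.

    Fits branch lengths by non-negative least squares for every unrooted
    binary topology and returns the split set of the smallest-residual one.
    """
    n = d.shape[0]
    dvec = np.array([d[i, j] for i, j in itertools.combinations(range(n), 2)])
    best, best_res = None, math.inf
    for top in _enumerate_unrooted(n):
        A, _, _ = _paths_incidence(top, n)
        _, res = nnls(A, dvec)
        if res < best_res - 1e-12:
            best, best_res = top, res
    return _splits_of(best, n), best_res


# -- schematic relabeling oracle -----------------------------------------


def _leaves(t):
    if isinstance(t, str):
        return [t]
    return [x for c in t for x in _leaves(c)]


def _relabel(t, labels, pos=None):
    if pos is None:
        pos = [0]
    if isinstance(t, str):
        lab = labels[pos[0]]
        pos[0] += 1
        return lab
    return tuple(_relabel(c, labels, pos) for c in t)


def _canon(t):
    if isinstance(t, str):
        return t
    return tuple(sorted((_canon(c) for c in t), key=str))


def brute_force_relabel_distance(a, b):
    """Min label substitutions making b identical to a (same shapes only).

    Enumerates every assignment of labels (from the union alphabet) to b's
    leaves and keeps those whose canonical form equals a's.
    """
    la, lb = _leaves(a), _leaves(b)
    alphabet = sorted(set(la) | set(lb))
    ca = _canon(a)
    best = math.inf
    for combo in itertools.product(alphabet, repeat=len(lb)):
        if _canon(_relabel(b, list(combo))) == ca:
            cost = sum(1 for old, new in zip(lb, combo) if old != new)
            best = min(best, cost)
    return best
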