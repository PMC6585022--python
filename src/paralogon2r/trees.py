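"""Distance-based tree inference: p/Poisson distances, neighbor joining,
bootstrap support, outgroup rooting and discordant-leaf screening.

Neighbor joining follows the Saitou-Nei agglomeration with deterministic
tie-breaking (the lexicographically smallest pair index in the current
matrix) and negative branch lengths clamped to zero with the deficit
transferred to the sibling branch.  All randomness (bootstrap column
resampling) flows from an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import numpy as np

from .msa import Alignment


class TreeInferenceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise TreeInferenceError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise TreeInferenceError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise TreeInferenceError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise TreeInferenceError("negative distances")
        self.values = v


def _codes(aln: Alignment) -> np.ndarray:
    m = aln.matrix()
    return m.view(np.uint32).reshape(len(aln), aln.length)


def _pairwise_p(codes: np.ndarray) -> np.ndarray:
    diff = codes[:, None, :] != codes[None, :, :]
    return diff.mean(axis=2)


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected proportion of differing amino-acid sites per pair.

    Expects a trimmed (gap- and ambiguity-free) alignment of length >= 1.
    """
    if aln.length < 1:
        raise TreeInferenceError("zero-length alignment")
    return DistanceMatrix(aln.ids, _pairwise_p(_codes(aln)))


def poisson_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Poisson-corrected distance d = -ln(1 - p) per pair.

    Offered as the model-corrected alternative to the plain p-distance;
    saturated pairs (p = 1) are an error naming the offending pair.
    """
    pm = p_distance_matrix(aln)
    p = pm.values
    sat = np.argwhere(p >= 1.0)
    if sat.size:
        i, j = sat[0]
        raise TreeInferenceError(
            f"saturated pair ({pm.taxa[i]}, {pm.taxa[j]}): p = 1 has no Poisson distance"
        )
    return DistanceMatrix(pm.taxa, -np.log1p(-p))


def _nj_merge_order(d: np.ndarray):
    """Yield ((i, j), li, lj) join events; final entry is the 3-star lengths."""
    d = d.copy()
    n = d.shape[0]
    idx = list(range(n))
    while d.shape[0] > 3:
        r = d.shape[0]
        s = d.sum(axis=1)
        q = (r - 2) * d - s[:, None] - s[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major => lexicographically smallest (i, j)
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (s[i] - s[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        yield (i, j), li, lj
        new = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.delete(np.delete(d, (i, j), axis=0), (i, j), axis=1)
        new = np.delete(new, (i, j))
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new
        d[:-1, -1] = new
    a, b, c = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        max(0.0, 0.5 * (a + b - c)),
        max(0.0, 0.5 * (a + c - b)),
        max(0.0, 0.5 * (b + c - a)),
    ]
    yield None, lengths, None


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, trifurcating pseudo-root)."""
    n = len(dm.taxa)
    if n < 3:
        raise TreeInferenceError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace()
    nodes = []
    for label in dm.taxa:
        taxon = ns.new_taxon(label)
        nodes.append(dendropy.Node(taxon=taxon))
    active = list(nodes)
    for pair, li, lj in _nj_merge_order(dm.values):
        if pair is None:
            root = dendropy.Node()
            for child, ln in zip(active, li):
                root.add_child(child)
                child.edge.length = ln
            break
        i, j = pair
        parent = dendropy.Node()
        parent.add_child(active[i])
        parent.add_child(active[j])
        active[i].edge.length = li
        active[j].edge.length = lj
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


# -- splits & bootstrap -------------------------------------------------


def leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    comp = all_leaves - side
    return min(side, comp, key=lambda s: (len(s), sorted(s)))


def tree_splits(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as canonical frozensets of leaf labels."""
    all_leaves = leafset(tree.seed_node)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = leafset(node)
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(_canonical_split(side, all_leaves))
    return out


def _distance_fn(dist: str):
    if dist == "p":
        return p_distance_matrix
    if dist == "poisson":
        return poisson_distance_matrix
    raise TreeInferenceError(f"unknown distance model {dist!r}")


def bootstrap_support(
    aln: Alignment, B: int, seed: int, dist: str = "p"
) -> dendropy.Tree:
    """NJ point-estimate tree with per-branch bootstrap percentages.

    Columns are resampled with replacement ``B`` times; each internal
    branch of the point tree is labeled with the percentage of replicates
    containing its bipartition.  The full split -> percentage map is
    attached as ``tree.split_support``.
    """
    if B < 1:
        raise TreeInferenceError("need at least one bootstrap replicate")
    dfun = _distance_fn(dist)
    point = nj_tree(dfun(aln))
    counts = {s: 0 for s in tree_splits(point)}
    rng = np.random.default_rng(seed)
    codes = _codes(aln)
    ids = aln.ids
    for _ in range(B):
        cols = rng.integers(0, aln.length, aln.length)
        p = _pairwise_p(codes[:, cols])
        if dist == "poisson":
            p = -np.log1p(-np.minimum(p, 1 - 1e-12))
        rep = nj_tree(DistanceMatrix(ids, p))
        for s in tree_splits(rep):
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / B for s, c in counts.items()}
    point.split_support = support
    annotate_supports(point, support)
    return point


def annotate_supports(tree: dendropy.Tree, support: dict) -> None:
    """Write split supports onto internal node labels of ``tree``."""
    all_leaves = leafset(tree.seed_node)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = leafset(node)
        if not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        pct = support.get(_canonical_split(side, all_leaves))
        if pct is not None:
            node.label = f"{round(pct, 1):g}"


# -- rooting ------------------------------------------------------------


def _purity_score(side: frozenset, outgroup: frozenset) -> tuple:
    """(purity, completeness) of treating ``side`` as the outgroup side."""
    if not side:
        return (0.0, 0)
    hit = len(side & outgroup)
    return (hit / len(side), hit)


def root_tree(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not monophyletic in the unrooted tree, the root goes
    on the edge whose one side is purest in outgroup leaves (ties broken by
    how many outgroup leaves it captures, then by preorder) and a warning
    is emitted.
    """
    outgroup = frozenset(outgroup)
    all_leaves = leafset(tree.seed_node)
    if not outgroup:
        raise TreeInferenceError("empty outgroup")
    if not outgroup <= all_leaves:
        raise TreeInferenceError(f"outgroup leaves not in tree: {sorted(outgroup - all_leaves)}")
    if outgroup == all_leaves:
        raise TreeInferenceError("outgroup cannot be every leaf")
    work = tree.clone(depth=1)
    best, best_score, best_side = None, (-1.0, -1), None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        side = leafset(node)
        for cand in (side, all_leaves - side):
            score = _purity_score(cand, outgroup)
            if score > best_score:
                best, best_score, best_side = node.edge, score, cand
    if best_side != outgroup:
        warnings.warn(
            f"outgroup not monophyletic; rooting at best-purity edge "
            f"(purity {best_score[0]:.2f}, {best_score[1]}/{len(outgroup)} outgroup leaves)",
            stacklevel=2,
        )
    ln = best.length
    half = None if ln is None else ln / 2.0
    work.reroot_at_edge(best, length1=half, length2=half, update_bipartitions=False)
    work.is_rooted = True
    support = getattr(tree, "split_support", None)
    if support is not None:
        annotate_supports(work, support)
        work.split_support = support
    return work


def unrooted_splits(tree: dendropy.Tree) -> set:
    """Splits of a tree viewed as unrooted (rooting-invariant comparison)."""
    return tree_splits(tree)


# -- discordant-leaf screening ------------------------------------------


def flag_discordant_leaves(tree: dendropy.Tree, ref) -> list:
    """Leaves whose removal reduces implied cross-divide duplications.

    A sequence placed against the conventional animal history (say a fly
    protein nested among mammal paralogs) manufactures apparent
    duplications older than the invertebrate-vertebrate divide.  This
    screen greedily removes, in deterministic label order, any leaf whose
    deletion strictly decreases the number of species-overlap duplication
    nodes dated to bin B1, and returns the flagged labels.  The caller
    decides whether to actually drop them.
    """
    from .duplications import date_duplication, detect_duplications

    if not tree.is_rooted:
        raise TreeInferenceError("discordance screening needs a rooted tree")

    def b1_count(t) -> int:
        events = [date_duplication(e, ref) for e in detect_duplications(t)]
        return sum(1 for e in events if e.epoch == "B1")

    current = tree
    score = b1_count(current)
    flagged = []
    for label in sorted(leafset(tree.seed_node)):
        leaves_now = leafset(current.seed_node)
        if label not in leaves_now or len(leaves_now) <= 3 or score == 0:
            continue
        keep = sorted(leaves_now - {label})
        candidate = current.extract_tree_with_taxa_labels(labels=keep)
        candidate.is_rooted = True
        cand_score = b1_count(candidate)
        if cand_score < score:
            flagged.append(label)
            current, score = candidate, cand_score
    return flagged
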