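"""Topology-congruence analysis of chromosome-labeled schematic trees.

A gene-family tree is abstracted to a small rooted *schematic topology*:
only duplication nodes dated to the focal epoch window (by default B2, the
vertebrate stem between the invertebrate-vertebrate and teleost-tetrapod
splits) define internal structure, leaves are relabeled with the human
chromosome carrying each paralog, and co-located paralogs merge into one
leaf.  Families whose schematics agree up to a small number of leaf
relabelings (assumed translocations) among physically linked families are
clustered into co-duplicated groups.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from io import StringIO
from itertools import permutations
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd

from .duplications import leaf_species
from .msa import parse_header

WILDCARD = "*"
INFINITY = math.inf


class CongruenceError(ValueError):
    pass


class SchematicExclusionError(CongruenceError):
    """Family lacks the required number of in-window duplications."""


# -- schematic trees as nested tuples -----------------------------------


def parse_schematic(newick: str):
    """Parse a label-only newick string into a nested-tuple tree."""
    t = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def conv(node):
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label is None:
                raise CongruenceError(f"unlabeled leaf in {newick!r}")
            return str(label)
        return tuple(conv(c) for c in node.child_nodes())

    return conv(t.seed_node)


def serialize(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(serialize(c) for c in tree) + ")"


def canonical(tree):
    """Order-insensitive canonical form (children sorted by serialization)."""
    if isinstance(tree, str):
        return tree
    return tuple(sorted((canonical(c) for c in tree), key=serialize))


def schematic_leaves(tree) -> list:
    if isinstance(tree, str):
        return [tree]
    return [lf for c in tree for lf in schematic_leaves(c)]


def _shape(tree):
    if isinstance(tree, str):
        return "L"
    return tuple(sorted((_shape(c) for c in tree), key=str))


SYMMETRIC_SHAPE = (("L", "L"), ("L", "L"))


@dataclass(frozen=True)
class SchematicTopology:
    family_name: str
    tree: object

    @property
    def symmetry_class(self) -> str:
        return "symmetric" if _shape(self.tree) == SYMMETRIC_SHAPE else "asymmetric"

    @property
    def newick(self) -> str:
        return serialize(canonical(self.tree)) + ";"

    @property
    def leaves(self) -> list:
        return schematic_leaves(self.tree)


# -- translocation distance ---------------------------------------------


def _match_cost(x, y) -> float:
    x_leaf, y_leaf = isinstance(x, str), isinstance(y, str)
    if x_leaf and y_leaf:
        return 0.0 if x == y else 1.0
    if x_leaf or y_leaf:
        return INFINITY
    cx, cy = list(x), list(y)
    # harmonize arity: pad the smaller child list with wildcard leaves,
    # each of which can absorb one surplus leaf at cost 1
    if len(cx) < len(cy):
        cx += [WILDCARD] * (len(cy) - len(cx))
    elif len(cy) < len(cx):
        cy += [WILDCARD] * (len(cx) - len(cy))
    best = INFINITY
    for perm in permutations(cy):
        total = 0.0
        for a, b in zip(cx, perm):
            total += _match_cost(a, b)
            if total >= best:
                break
        best = min(best, total)
    return best


def translocation_distance(
    a: Union[SchematicTopology, tuple, str], b: Union[SchematicTopology, tuple, str]
) -> float:
    """Minimum number of leaf relabelings turning one schematic into the other.

    Computed exactly by exhaustive matching over rooted-tree isomorphisms
    (trees are tiny).  Non-isomorphic shapes yield ``inf``; differing
    polytomy arities are harmonized with wildcard leaves, each surplus
    leaf costing one assumed translocation.
    """
    ta = a.tree if isinstance(a, SchematicTopology) else a
    tb = b.tree if isinstance(b, SchematicTopology) else b
    return _match_cost(ta, tb)


def congruent(a, b, k: float) -> bool:
    """True iff the two schematics differ by at most ``k`` translocations."""
    return translocation_distance(a, b) <= k


# -- schematic construction from gene trees ------------------------------


def schematic_topology(
    tree: dendropy.Tree,
    events: Iterable,
    paralog_chrom: Optional[dict] = None,
    window: str = "B2",
    human_species: str = "Hsap",
    min_window_events: int = 2,
) -> SchematicTopology:
    """Collapse a dated rooted gene tree to its window-duplication schematic.

    ``events`` are dated (optionally support-filtered) duplication events of
    this family; only those in the focal ``window`` bin contribute internal
    nodes.  Human paralog leaves are relabeled by chromosome, taken from
    ``paralog_chrom`` (gene tag -> chromosome) or from the ``|chrN`` header
    field.  Families with fewer than ``min_window_events`` in-window
    duplications are excluded, mirroring the published selection rule.
    """
    events = list(events)
    family = events[0].family_name if events else ""
    window_nodes = {id(e.node) for e in events if e.epoch == window}
    if len(window_nodes) < min_window_events:
        raise SchematicExclusionError(
            f"{family or 'family'}: fewer than {min_window_events} duplications in {window}"
        )

    def chrom_of(leaf_node) -> Optional[str]:
        label = leaf_node.taxon.label
        sp, gene, chrom = parse_header(label)
        if paralog_chrom and gene in paralog_chrom:
            return str(paralog_chrom[gene])
        return chrom

    def reduce(node):
        if node.is_leaf():
            if leaf_species(node.taxon.label) != human_species:
                return []
            chrom = chrom_of(node)
            if chrom is None:
                raise CongruenceError(
                    f"no chromosome for human paralog {node.taxon.label!r}"
                )
            return [str(chrom)]
        parts = []
        for c in node.child_nodes():
            parts.extend(reduce(c))
        if len(parts) <= 1:
            return parts
        if id(node) in window_nodes:
            return [tuple(_merge_leaves(parts))]
        return parts  # non-window node: splice children upward

    parts = reduce(tree.seed_node)
    if not parts:
        raise CongruenceError(f"{family or 'family'}: no human paralogs in tree")
    merged = _merge_leaves(parts)
    result = merged[0] if len(merged) == 1 else tuple(merged)
    return SchematicTopology(family_name=family, tree=result)


def _merge_leaves(parts: list) -> list:
    """Merge repeated same-chromosome leaves under one node into one leaf."""
    out, seen = [], set()
    for p in parts:
        if isinstance(p, str):
            if p in seen:
                continue
            seen.add(p)
        out.append(p)
    return out


# -- co-duplication grouping ---------------------------------------------


@dataclass
class CoDuplicatedGroup:
    group_id: str
    members: list
    consensus: str
    symmetry_class: str
    total_assumed_translocations: float
    over_allowance_pairs: list


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def co_duplication_groups(
    schematics: Iterable[SchematicTopology],
    k: Union[float, dict] = 3,
    linkage: Optional[dict] = None,
) -> list:
    """Cluster families into co-duplicated groups.

    Groups are the connected components of the pairwise congruence graph.
    ``k`` is the translocation allowance — a single number, or a mapping
    from linkage block to allowance.  ``linkage`` (family -> synteny block
    label, taken from the catalog, never recomputed) optionally restricts
    which pairs are candidate co-duplicates: joint origin requires physical
    linkage as well as topological congruence.  The grouping accepts the
    non-transitivity of the pairwise predicate; any intra-group pair
    exceeding its allowance is reported, not silently absorbed.
    """
    schematics = sorted(schematics, key=lambda s: s.family_name)
    if not schematics:
        raise CongruenceError("no schematics to cluster")
    names = [s.family_name for s in schematics]
    if len(set(names)) != len(names):
        raise CongruenceError("duplicate family names among schematics")
    by_name = {s.family_name: s for s in schematics}

    def allowance(fa, fb) -> Optional[float]:
        if linkage is not None and linkage.get(fa) != linkage.get(fb):
            return None
        if isinstance(k, dict):
            if linkage is None:
                raise CongruenceError("per-block allowances need a linkage map")
            return k[linkage[fa]]
        return k

    uf = _UnionFind(names)
    dist = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            kk = allowance(a, b)
            if kk is None:
                continue
            d = translocation_distance(by_name[a], by_name[b])
            dist[(a, b)] = (d, kk)
            if d <= kk:
                uf.union(a, b)

    components = {}
    for n in names:
        components.setdefault(uf.find(n), []).append(n)
    groups = []
    for gi, root in enumerate(sorted(components, key=lambda r: min(components[r])), 1):
        members = sorted(components[root])
        forms = [serialize(canonical(by_name[m].tree)) for m in members]
        counts = pd.Series(forms).value_counts()
        top = counts.max()
        consensus = sorted(c for c in counts.index if counts[c] == top)[0]
        cons_tree = parse_schematic(consensus + ";")
        total = sum(translocation_distance(by_name[m].tree, cons_tree) for m in members)
        bad = [
            (a, b, d)
            for (a, b), (d, kk) in sorted(dist.items())
            if a in members and b in members and d > kk
        ]
        groups.append(
            CoDuplicatedGroup(
                group_id=f"G{gi}",
                members=members,
                consensus=consensus + ";",
                symmetry_class=SchematicTopology("", cons_tree).symmetry_class,
                total_assumed_translocations=total,
                over_allowance_pairs=bad,
            )
        )
    return groups


def load_panel():
    """The packaged co-duplication panel (16 families with schematic
    topologies, synteny blocks and per-block translocation allowances).

    Returns ``(schematics, linkage, allowances)``.
    """
    pkg = importlib.resources.files("paralogon2r.data")
    df = pd.read_csv(StringIO((pkg / "coduplication_panel.tsv").read_text()), sep="\t")
    schematics, linkage, allowances = [], {}, {}
    for row in df.itertuples(index=False):
        schematics.append(SchematicTopology(row.family, parse_schematic(row.schematic)))
        linkage[row.family] = row.block
        allowances[row.block] = int(row.allowance)
    return schematics, linkage, allowances


def groups_table(groups: Iterable[CoDuplicatedGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": g.group_id,
                "members": ",".join(g.members),
                "n_members": len(g.members),
                "consensus": g.consensus,
                "symmetry": g.symmetry_class,
                "total_assumed_translocations": g.total_assumed_translocations,
            }
            for g in groups
        ]
    )
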