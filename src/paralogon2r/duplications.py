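"""Species-overlap duplication detection and relative (ordinal) dating.

An internal node of a rooted gene tree is a duplication iff the species
sets of its child subtrees intersect; every other internal node is read as
a speciation.  Each duplication is then dated into an epoch bin bounded by
named speciation splits of the reference species tree: the younger bound is
the split at the LCA of the duplicated copies' species, the older bound the
LCA with the nearest sampled outgroup lineage above the node in the gene
tree.  No gene losses are inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import dendropy
import pandas as pd

from .species import EPOCH_BINS, EpochScale, ReferenceSpeciesTree


class DuplicationError(ValueError):
    pass


def leaf_species(label: str) -> str:
    """Species token of a ``species|gene|chrN`` leaf label."""
    return label.split("|")[0]


@dataclass
class DuplicationEvent:
    family_name: str
    node: object
    left_species: frozenset
    right_species: frozenset
    support: Optional[float] = None
    epoch: Optional[str] = None
    refined_split: Optional[str] = None
    bounds: tuple = (None, None)  # (older split name, younger split name)
    ambiguous: bool = False
    flags: tuple = ()

    @property
    def species(self) -> frozenset:
        return self.left_species | self.right_species


def _node_support(node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _species_set(node) -> frozenset:
    return frozenset(leaf_species(lf.taxon.label) for lf in node.leaf_iter())


def detect_duplications(
    tree: dendropy.Tree, family_name: str = ""
) -> list:
    """All species-overlap duplication nodes of a rooted tree, in preorder.

    For a multifurcating node the first child subtree is reported against
    the union of the rest; the node is a duplication iff any two child
    subtrees share a species.
    """
    if not tree.is_rooted:
        raise DuplicationError("duplication detection needs a rooted tree")
    events = []
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        sets = [_species_set(c) for c in children]
        union = frozenset().union(*sets)
        if sum(len(s) for s in sets) > len(union):
            events.append(
                DuplicationEvent(
                    family_name=family_name,
                    node=node,
                    left_species=sets[0],
                    right_species=frozenset().union(*sets[1:]),
                    support=_node_support(node),
                )
            )
    return events


def date_duplication(
    event: DuplicationEvent, ref: ReferenceSpeciesTree
) -> DuplicationEvent:
    """Fill the epoch bin and bounds of a detected duplication.

    The younger bound is the split at ``lca(left | right)``.  The older
    bound is the split at the LCA of the duplicated species with the
    species of the sister subtree above the node (unbounded for the gene
    tree root).  When the bounds straddle a bin boundary the younger bound
    decides and the event is flagged ambiguous.
    """
    scale = EpochScale(ref)
    younger = ref.lca_node(event.species)
    node = event.node
    parent = node.parent_node
    older_node = None
    older_name = None
    if parent is not None:
        above = _species_set(parent)  # includes the sister lineage's species
        older_node = ref.lca_node(event.species | above)
        older_name = ref.refined_split(older_node)
    epoch, refined, ambiguous = scale.assign(younger, older_node)
    younger_name = ref.refined_split(younger)
    flags = event.flags
    if ambiguous:
        flags = tuple(sorted(set(flags) | {"ambiguous-interval"}))
    return replace(
        event,
        epoch=epoch,
        refined_split=refined,
        bounds=(older_name if parent is not None else None, younger_name),
        ambiguous=ambiguous,
        flags=flags,
    )


def date_all(events: Iterable[DuplicationEvent], ref) -> list:
    return [date_duplication(e, ref) for e in events]


def filter_by_support(events: Iterable[DuplicationEvent], min_support: float) -> list:
    """Keep events with bootstrap support strictly above ``min_support``.

    Root events, which carry no bipartition support by construction, are
    retained with an ``unsupported-root`` flag rather than discarded.
    """
    kept = []
    for e in events:
        if e.support is not None:
            if e.support > min_support:
                kept.append(e)
        elif e.node is not None and e.node.parent_node is None:
            kept.append(replace(e, flags=tuple(sorted(set(e.flags) | {"unsupported-root"}))))
    return kept


def epoch_histogram(events_by_family: dict) -> pd.DataFrame:
    """Per-family and total duplication counts per epoch bin.

    Families are rows (alphabetical, plus a ``total`` row); columns are the
    reporting bins B1..B4 with any off-path events in an extra column.
    Undated events are an error.
    """
    cols = list(EPOCH_BINS)
    extra = set()
    for fam, events in events_by_family.items():
        for e in events:
            if e.epoch is None:
                raise DuplicationError(f"{fam}: undated duplication event")
            if e.epoch not in cols:
                extra.add(e.epoch)
    cols = cols + sorted(extra)
    rows = {}
    for fam in sorted(events_by_family):
        counts = dict.fromkeys(cols, 0)
        for e in events_by_family[fam]:
            counts[e.epoch] += 1
        rows[fam] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols).fillna(0).astype(int)
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "family"
    return df


def events_table(events_by_family: dict) -> pd.DataFrame:
    """Flat event table (family, bin, bounds, support, flags)."""
    rows = []
    for fam in sorted(events_by_family):
        for e in events_by_family[fam]:
            rows.append(
                {
                    "family": fam,
                    "epoch": e.epoch,
                    "refined_split": e.refined_split,
                    "older_bound": e.bounds[0],
                    "younger_bound": e.bounds[1],
                    "support": e.support,
                    "n_species": len(e.species),
                    "flags": ";".join(e.flags),
                }
            )
    return pd.DataFrame(rows)
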