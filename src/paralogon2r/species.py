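"""Reference metazoan species framework.

Houses the fixed 46-taxon species tree, per-taxon clade tags, the named
speciation splits on the human root path, and the ordinal epoch scale used
to date gene duplications relative to speciations.  No absolute times are
involved anywhere: branch lengths on the packaged tree are order-consistent
relative depths (root deepest) and only the ordering of named splits is
load-bearing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Optional

import dendropy
import pandas as pd

PRIMARY_CLADES = ("tetrapod", "teleost", "invertebrate")
KNOWN_TAGS = frozenset(
    {
        "tetrapod",
        "teleost",
        "vertebrate",
        "invertebrate",
        "chordate-invertebrate",
        "protostome",
        "non-bilaterian",
    }
)

#: Reporting bins for relative dating (ordered old -> young; B3/B4 are the
#: two parallel post-divergence lineages).
EPOCH_BINS = ("B1", "B2", "B3", "B4")

#: Human-readable meaning of each reporting bin.
EPOCH_DESCRIPTIONS = {
    "B1": "before the invertebrate-vertebrate split",
    "B2": "after the invertebrate-vertebrate and before the teleost-tetrapod split",
    "B3": "teleost-lineage specific",
    "B4": "tetrapod-lineage specific",
}

#: Bin used for duplications confined to lineages off the human root path
#: (e.g. a within-protostome expansion).  Not one of the reporting bins.
OFF_PATH = "off-path"

SPLIT_ALIASES = {"tunicate-split": "invertebrate-vertebrate"}


class SpeciesFrameworkError(ValueError):
    """Raised for inconsistent taxonomy/tree configuration."""


@dataclass(frozen=True)
class TaxonRecord:
    species_id: str
    binomial: str
    common_name: str
    clade_tags: frozenset

    def __post_init__(self):
        unknown = self.clade_tags - KNOWN_TAGS
        if unknown:
            raise SpeciesFrameworkError(
                f"{self.species_id}: unknown clade tags {sorted(unknown)}"
            )
        primary = self.clade_tags & set(PRIMARY_CLADES)
        if len(primary) != 1:
            raise SpeciesFrameworkError(
                f"{self.species_id}: need exactly one of {PRIMARY_CLADES}, got {sorted(primary)}"
            )
        if primary & {"tetrapod", "teleost"} and "vertebrate" not in self.clade_tags:
            raise SpeciesFrameworkError(
                f"{self.species_id}: tetrapod/teleost taxa must carry the vertebrate tag"
            )
        if "invertebrate" in primary and "vertebrate" in self.clade_tags:
            raise SpeciesFrameworkError(
                f"{self.species_id}: invertebrate taxon tagged vertebrate"
            )


class ReferenceSpeciesTree:
    """A rooted species tree plus clade membership and named splits.

    Parameters
    ----------
    tree:
        Rooted dendropy tree; leaf taxon labels are species ids and internal
        node labels (where present) name speciation splits.
    taxa:
        Mapping species_id -> :class:`TaxonRecord` covering every leaf.
    """

    def __init__(self, tree: dendropy.Tree, taxa: dict):
        self.tree = tree
        self.taxa = dict(taxa)
        self._leafsets = {}
        self._index()
        self._validate()

    # -- construction ---------------------------------------------------

    def _index(self):
        self.named_splits = {}
        for node in self.tree.preorder_node_iter():
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            self._leafsets[node] = leaves
            if not node.is_leaf() and node.label:
                if node.label in self.named_splits:
                    raise SpeciesFrameworkError(
                        f"split name {node.label!r} appears on more than one node"
                    )
                self.named_splits[node.label] = node
        for alias, target in SPLIT_ALIASES.items():
            if target in self.named_splits:
                self.named_splits.setdefault(alias, self.named_splits[target])
        self.species = self._leafsets[self.tree.seed_node]
        self._leaf_by_label = {
            lf.taxon.label: lf for lf in self.tree.leaf_node_iter()
        }

    def _validate(self):
        missing = self.species - set(self.taxa)
        if missing:
            raise SpeciesFrameworkError(f"leaves without taxonomy rows: {sorted(missing)}")
        extra = set(self.taxa) - self.species
        if extra:
            raise SpeciesFrameworkError(f"taxonomy rows without leaves: {sorted(extra)}")
        for clade in ("tetrapod", "teleost", "vertebrate"):
            members = self.clade_species(clade)
            if len(members) > 1 and self._leafsets[self.lca_node(members)] != members:
                raise SpeciesFrameworkError(
                    f"taxa tagged {clade!r} do not form a clade in the tree"
                )

    @classmethod
    def from_config(cls, taxonomy, newick: str) -> "ReferenceSpeciesTree":
        return load_reference_taxonomy(taxonomy, newick)

    # -- queries --------------------------------------------------------

    def clade_species(self, tag: str) -> frozenset:
        return frozenset(s for s, t in self.taxa.items() if tag in t.clade_tags)

    def leafset(self, node) -> frozenset:
        return self._leafsets[node]

    def lca_node(self, species: Iterable[str]):
        """Most recent common ancestor node of a non-empty species set."""
        species = frozenset(species)
        if not species:
            raise SpeciesFrameworkError("lca_node of an empty species set")
        unknown = species - self.species
        if unknown:
            raise SpeciesFrameworkError(f"species not in reference tree: {sorted(unknown)}")
        node = self._leaf_by_label[min(species)]
        while not species <= self._leafsets[node]:
            node = node.parent_node
        return node

    def split_node(self, name: str):
        try:
            return self.named_splits[name]
        except KeyError:
            raise SpeciesFrameworkError(f"unknown split name {name!r}") from None

    def is_ancestor_or_equal(self, anc, node) -> bool:
        return self._leafsets[node] <= self._leafsets[anc]

    # -- epoch scale ----------------------------------------------------

    def classify_node(self, node) -> str:
        """Reporting bin for a duplication whose younger bound is ``node``.

        The node is the species-tree LCA of the duplicated copies; the
        duplication necessarily predates that split, i.e. lies on or above
        the edge leading into it.
        """
        leaves = self._leafsets[node]
        teleosts = self.clade_species("teleost")
        tetrapods = self.clade_species("tetrapod")
        inverts = self.clade_species("invertebrate")
        if leaves <= teleosts:
            return "B3"
        if leaves <= tetrapods:
            return "B4"
        if not leaves & inverts:
            # spans both bony-vertebrate lineages but no invertebrate
            return "B2"
        if leaves & (teleosts | tetrapods):
            return "B1"
        return OFF_PATH

    def refined_split(self, node) -> Optional[str]:
        """Name of the split at ``node`` (or its nearest named ancestor)."""
        while node is not None:
            if not node.is_leaf() and node.label:
                return node.label
            node = node.parent_node
        return None

    def path_child_toward(self, ancestor, descendant):
        """Child of ``ancestor`` on the path down to ``descendant``."""
        node = descendant
        if node is ancestor:
            raise SpeciesFrameworkError("descendant equals ancestor")
        while node.parent_node is not ancestor:
            node = node.parent_node
            if node is None:
                raise SpeciesFrameworkError("nodes are not on one root path")
        return node

    def pruned(self, species: Iterable[str]) -> "ReferenceSpeciesTree":
        """Restriction of the framework to a species subset.

        Suppressed unary nodes keep cumulative branch lengths, so relative
        depths (and thus the split order) are preserved.
        """
        species = sorted(set(species))
        sub = self.tree.extract_tree_with_taxa_labels(
            labels=species, suppress_unifurcations=True
        )
        sub.is_rooted = True
        taxa = {s: self.taxa[s] for s in species}
        return ReferenceSpeciesTree(sub, taxa)


def _parse_taxonomy(taxonomy) -> dict:
    if isinstance(taxonomy, pd.DataFrame):
        df = taxonomy
    else:
        df = pd.read_csv(StringIO(taxonomy) if "\t" in str(taxonomy) else taxonomy, sep="\t")
    records = {}
    for row in df.itertuples(index=False):
        rec = TaxonRecord(
            species_id=row.species_id,
            binomial=row.binomial,
            common_name=row.common_name,
            clade_tags=frozenset(t.strip() for t in row.clade_tags.split(",") if t.strip()),
        )
        if rec.species_id in records:
            raise SpeciesFrameworkError(f"duplicate species_id {rec.species_id}")
        records[rec.species_id] = rec
    return records


def load_reference_taxonomy(taxonomy, newick: str) -> ReferenceSpeciesTree:
    """Build a validated :class:`ReferenceSpeciesTree` from config inputs.

    ``taxonomy`` may be a TSV path, TSV text, or a DataFrame with columns
    species_id / binomial / common_name / clade_tags; ``newick`` is newick
    text (or a path) whose leaves are species ids.
    """
    taxa = _parse_taxonomy(taxonomy)
    if "(" not in newick:
        with open(newick) as fh:
            newick = fh.read()
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    return ReferenceSpeciesTree(tree, taxa)


def load_default() -> ReferenceSpeciesTree:
    """The packaged 46-taxon reference framework."""
    pkg = importlib.resources.files("paralogon2r.data")
    taxonomy = (pkg / "taxonomy.tsv").read_text()
    newick = (pkg / "species_tree.nwk").read_text()
    df = pd.read_csv(StringIO(taxonomy), sep="\t")
    return load_reference_taxonomy(df, newick)


@dataclass
class EpochScale:
    """Ordinal dating scale over a reference tree.

    The four reporting bins partition any duplication placement on the human
    root path or within the bony-vertebrate subclades; duplications confined
    to non-vertebrate side lineages fall in the ``off-path`` overflow bin.
    """

    ref: ReferenceSpeciesTree
    bins: tuple = EPOCH_BINS

    def assign(self, younger_node, older_node=None):
        """Return ``(bin, refined_split, ambiguous)`` for a duplication.

        ``younger_node`` is the species-tree LCA of the duplicated copies
        (the duplication predates that split); ``older_node``, when known,
        is the LCA with the nearest outgroup lineage above the duplication
        in the gene tree (the duplication postdates that split).  ``None``
        means unbounded above (gene-tree root).  When the two bounds fall in
        different bins the younger bound decides and the event is flagged
        ambiguous.
        """
        bin_young = self.ref.classify_node(younger_node)
        refined = None
        if bin_young == "B1":
            refined = self.ref.refined_split(younger_node)
        if older_node is None:
            ambiguous = bin_young != "B1"
            return bin_young, refined, ambiguous
        if older_node is younger_node:
            return bin_young, refined, False
        top = self.ref.path_child_toward(older_node, younger_node)
        bin_old = self.ref.classify_node(top)
        return bin_young, refined, bin_old != bin_young
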