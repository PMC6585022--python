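"""Synthetic gene families with known duplication histories.

The generator embodies the two contrasted hypotheses for the origin of the
Hsa 1/2/8/20 paralogy regions: ``two_round_WGD`` duplicates every family at
the same two points on the vertebrate stem (1 -> 2 -> 4 copies), while
``independent_SD`` gives each family its own small-scale duplications at
family-specific times spread over animal history.  Copies are born onto the
target chromosomes {1, 2, 8, 20} and may be perturbed by translocation;
sequences then evolve along the true gene tree under an exchangeable
(Poisson-style) amino-acid model with no indels, so the emitted FASTA is
already aligned and trimming is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .msa import AMINO_ACIDS, Alignment, AlignmentRecord
from .species import ReferenceSpeciesTree

#: Species panel used for simulations: four tetrapods, two teleosts and
#: four invertebrates spanning every named split needed for dating.
DEFAULT_PANEL = (
    "Hsap", "Mmus", "Ggal", "Xtro", "Drer", "Olat",
    "Cint", "Bflo", "Dmel", "Nvec",
)

TARGET_CHROMS = ("1", "2", "8", "20")
EXTRA_CHROMS = tuple(str(i) for i in (3, 5, 7, 11, 15, 17)) + ("X",)
TRANSLOC_POOL = tuple(str(i) for i in range(3, 23)) + ("X",)

#: Era name -> (how to find the head node of the stem edge, true epoch bin).
ERA_BINS = {
    "stem-bilaterian": "B1",
    "stem-olfactores": "B1",
    "stem-vertebrate": "B2",
    "stem-teleost": "B3",
    "stem-tetrapod": "B4",
}

DEFAULT_SD_ERAS = (
    "stem-bilaterian",
    "stem-olfactores",
    "stem-vertebrate",
    "stem-teleost",
    "stem-tetrapod",
)


class SimulationError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    mode: str
    seed: int
    n_families: int = 6
    sequence_length: int = 1000
    substitution_rate: float = 0.3
    loss_probability: float = 0.0
    translocation_probability: float = 0.0
    species: tuple = DEFAULT_PANEL
    wgd_positions: tuple = (0.35, 0.65)
    sd_eras: tuple = DEFAULT_SD_ERAS
    sd_events_per_family: int = 2
    n_wgd_families: Optional[int] = None  # only for mode="mixed"

    def __post_init__(self):
        if self.mode not in ("two_round_WGD", "independent_SD", "mixed"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.n_families < 1:
            raise SimulationError("n_families must be >= 1")
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        for p in (self.loss_probability, self.translocation_probability):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")
        for era in self.sd_eras:
            if era not in ERA_BINS:
                raise SimulationError(f"unknown era interval {era!r}")
        if self.sequence_length < 1:
            raise SimulationError("sequence_length must be >= 1")


def preset_two_round_wgd(n_families: int = 6, seed: int = 0, **kw) -> ScenarioSpec:
    """The idealized 2R scenario: all families quadruplicate together."""
    return ScenarioSpec(mode="two_round_WGD", n_families=n_families, seed=seed, **kw)


def preset_independent_sd(n_families: int = 6, seed: int = 0, **kw) -> ScenarioSpec:
    """Well-separated small-scale duplications: each family draws its own
    era (round-robin over animal history) with two events per family."""
    return ScenarioSpec(mode="independent_SD", n_families=n_families, seed=seed, **kw)


# -- gene-tree nodes ------------------------------------------------------


@dataclass
class SimNode:
    kind: str  # "spec" | "dup" | "leaf"
    depth: float
    children: list = field(default_factory=list)
    label: Optional[str] = None
    era: Optional[str] = None
    true_bin: Optional[str] = None

    def leaves(self):
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        def fmt(node, parent_depth):
            ln = f":{parent_depth - node.depth:.6f}" if parent_depth is not None else ""
            if not node.children:
                return f"{node.label}{ln}"
            inner = ",".join(fmt(c, node.depth) for c in node.children)
            tag = node.kind if node.kind == "dup" else ""
            return f"({inner}){tag}{ln}"

        return fmt(self, None) + ";"


@dataclass
class TrueEvent:
    family: str
    era: str
    bin: str
    depth: float
    kind: str  # "wgd" | "sd"


@dataclass
class FamilyTruth:
    name: str
    root: SimNode
    events: list
    leaf_records: list  # (label, species, copy, chromosome)


@dataclass
class GroundTruth:
    spec: ScenarioSpec
    tree: ReferenceSpeciesTree  # the pruned panel tree
    families: dict
    partition: dict  # family -> co-duplication block label


# -- placement plumbing ----------------------------------------------------


def _node_depths(ref: ReferenceSpeciesTree) -> dict:
    depths = {}
    for node in ref.tree.postorder_node_iter():
        if node.is_leaf():
            depths[node] = 0.0
        else:
            depths[node] = max(
                depths[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return depths


def _era_head(ref: ReferenceSpeciesTree, era: str):
    if era == "stem-bilaterian":
        return ref.split_node("protostome-deuterostome")
    if era == "stem-olfactores":
        return ref.split_node("invertebrate-vertebrate")
    if era == "stem-vertebrate":
        return ref.split_node("teleost-tetrapod")
    if era == "stem-teleost":
        return ref.lca_node(ref.clade_species("teleost") & ref.species)
    if era == "stem-tetrapod":
        return ref.lca_node(ref.clade_species("tetrapod") & ref.species)
    raise SimulationError(f"unknown era {era!r}")


def simulate_family_trees(spec: ScenarioSpec, ref: ReferenceSpeciesTree) -> GroundTruth:
    """Generate true gene trees, chromosome labels and the co-duplication
    partition for every family under the scenario."""
    panel = ref.pruned(spec.species)
    depths = _node_depths(panel)
    rng = np.random.default_rng([spec.seed, 11])

    n_wgd = {"two_round_WGD": spec.n_families, "independent_SD": 0}.get(
        spec.mode, spec.n_wgd_families if spec.n_wgd_families is not None else spec.n_families // 2
    )

    families, partition = {}, {}
    for fi in range(spec.n_families):
        name = f"FAM{fi + 1:03d}"
        wgd = fi < n_wgd
        if wgd:
            era = "stem-vertebrate"
            placements = [(era, pos, "wgd") for pos in sorted(spec.wgd_positions)]
            partition[name] = "wgd-block"
        else:
            era = spec.sd_eras[fi % len(spec.sd_eras)]
            rel = np.sort(rng.uniform(0.1, 0.9, size=spec.sd_events_per_family))
            placements = [(era, float(r), "sd") for r in rel]
            partition[name] = name
        truth = _simulate_one(name, panel, depths, placements, spec, rng)
        families[name] = truth
    return GroundTruth(spec=spec, tree=panel, families=families, partition=partition)


def _simulate_one(name, panel, depths, placements, spec, rng) -> FamilyTruth:
    # events keyed by the species-tree node whose parent edge carries them
    events_on_edge = {}
    for era, rel, kind in placements:
        head = _era_head(panel, era)
        tail_depth = depths[head] + (head.edge.length or 0.0)
        depth = tail_depth - rel * (tail_depth - depths[head])
        events_on_edge.setdefault(id(head), []).append((depth, era, kind))
    for lst in events_on_edge.values():
        lst.sort(key=lambda t: -t[0])  # oldest first

    copy_counter = [0]
    used_chroms = []
    events = []
    leaf_records = []

    def next_chrom(rng) -> str:
        for c in TARGET_CHROMS + EXTRA_CHROMS:
            if c not in used_chroms:
                if rng.random() < spec.translocation_probability:
                    options = [x for x in TRANSLOC_POOL if x not in used_chroms and x != c]
                    if options:
                        c = options[int(rng.integers(len(options)))]
                used_chroms.append(c)
                return c
        return TARGET_CHROMS[0]

    def new_lineage(parent_node, rng):
        copy_counter[0] += 1
        return {"parent": parent_node, "copy": copy_counter[0], "chrom": next_chrom(rng)}

    def descend(species_node, lineages):
        """Process the edge into species_node, then the node itself."""
        for depth, era, kind in events_on_edge.get(id(species_node), []):
            if kind == "wgd":
                targets = list(range(len(lineages)))
            else:
                targets = [int(rng.integers(len(lineages)))]
            for t in targets:
                lin = lineages[t]
                dup = SimNode("dup", depth, era=era, true_bin=ERA_BINS[era])
                lin["parent"].children.append(dup)
                events.append(TrueEvent(name, era, ERA_BINS[era], depth, kind))
                sib = new_lineage(dup, rng)
                lin["parent"] = dup
                lineages.append(sib)
            lineages.sort(key=lambda l: l["copy"])
            if spec.loss_probability > 0 and len(lineages) > 1:
                survive = rng.random(len(lineages)) >= spec.loss_probability
                if not survive.any():
                    survive[0] = True
                lineages[:] = [l for l, s in zip(lineages, survive) if s]
        node_depth = depths[species_node]
        if species_node.is_leaf():
            sp = species_node.taxon.label
            for lin in lineages:
                label = f"{sp}|{name}_c{lin['copy']:02d}|chr{lin['chrom']}"
                leaf = SimNode("leaf", 0.0, label=label)
                lin["parent"].children.append(leaf)
                leaf_records.append((label, sp, lin["copy"], lin["chrom"]))
            return
        stubs = []
        for lin in lineages:
            sn = SimNode("spec", node_depth)
            lin["parent"].children.append(sn)
            stubs.append(sn)
        for child in species_node.child_nodes():
            branch = [
                {"parent": sn, "copy": lin["copy"], "chrom": lin["chrom"]}
                for sn, lin in zip(stubs, lineages)
            ]
            descend(child, branch)

    root_node = panel.tree.seed_node
    root = SimNode("spec", depths[root_node])
    first = {"parent": root, "copy": 0, "chrom": TARGET_CHROMS[0]}
    used_chroms.append(TARGET_CHROMS[0])
    for child in root_node.child_nodes():
        branch = [{"parent": root, "copy": first["copy"], "chrom": first["chrom"]}]
        descend(child, branch)
    _suppress_unary(root)
    return FamilyTruth(name=name, root=root, events=events, leaf_records=leaf_records)


def _suppress_unary(node: SimNode):
    """Collapse single-child chains left by per-lineage speciation stubs."""
    new_children = []
    for c in node.children:
        _suppress_unary(c)
        while len(c.children) == 1:
            c = c.children[0]
        new_children.append(c)
    node.children = new_children


# -- sequence evolution ----------------------------------------------------


def evolve_sequences(truth: GroundTruth, spec: Optional[ScenarioSpec] = None) -> dict:
    """Evolve aligned amino-acid sequences along each true gene tree.

    i.i.d. sites under the equal-exchange (Poisson) model: along a branch of
    length b the probability a site differs from its ancestor is
    (19/20) * (1 - exp(-(20/19) * rate * b)); a changed site takes one of
    the other 19 residues uniformly.  No indels, so output is aligned.
    Same seed => byte-identical output.
    """
    spec = spec or truth.spec
    if spec.sequence_length < 1:
        raise SimulationError("zero sequence length")
    aas = np.array(list(AMINO_ACIDS))
    out = {}
    for fi, name in enumerate(sorted(truth.families)):
        fam = truth.families[name]
        rng = np.random.default_rng([spec.seed, 17, fi])
        seqs = {}

        def walk(node, parent_seq, parent_depth):
            if parent_seq is None:
                seq = rng.integers(0, 20, spec.sequence_length)
            else:
                b = max(parent_depth - node.depth, 0.0)
                p_diff = 0.95 * (1.0 - np.exp(-(20.0 / 19.0) * spec.substitution_rate * b))
                mask = rng.random(spec.sequence_length) < p_diff
                seq = parent_seq.copy()
                if mask.any():
                    shift = rng.integers(1, 20, int(mask.sum()))
                    seq[mask] = (seq[mask] + shift) % 20
            if node.children:
                for c in node.children:
                    walk(c, seq, node.depth)
            else:
                seqs[node.label] = seq

        walk(fam.root, None, None)
        records = [
            AlignmentRecord(
                sequence_id=label,
                species_id=sp,
                gene_tag=f"{name}_c{copy:02d}",
                chromosome=chrom,
                seq="".join(aas[seqs[label]]),
            )
            for label, sp, copy, chrom in fam.leaf_records
        ]
        out[name] = Alignment(records)
    return out


def true_epoch_bins(truth: GroundTruth) -> dict:
    """family -> list of true epoch bins, one per duplication node."""
    return {name: [e.bin for e in fam.events] for name, fam in truth.families.items()}
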