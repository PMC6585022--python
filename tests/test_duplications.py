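import dendropy
import pytest

from paralogon2r import simulate
from paralogon2r.duplications import (
    DuplicationError,
    date_all,
    detect_duplications,
    epoch_histogram,
    events_table,
    filter_by_support,
)


def rooted(nwk):
    t = dendropy.Tree.get(
        data=nwk, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    t.is_rooted = True
    return t


class TestDetect:
    def test_simple_root_duplication(self):
        evs = detect_duplications(rooted("((Hsap|a,Mmus|a),(Hsap|b,Mmus|b));"), "f")
        assert len(evs) == 1
        assert evs[0].left_species & evs[0].right_species == {"Hsap", "Mmus"}

    def test_speciation_only_tree(self):
        assert detect_duplications(rooted("((Hsap|a,Mmus|a),Ggal|a);")) == []

    def test_single_species_overlap(self):
        evs = detect_duplications(rooted("((Hsap|a,Dmel|a),(Hsap|b,Mmus|b));"))
        assert len(evs) == 1
        assert evs[0].left_species & evs[0].right_species == {"Hsap"}

    def test_unrooted_input_is_error(self):
        t = rooted("((Hsap|a,Mmus|a),(Hsap|b,Mmus|b));")
        t.is_rooted = False
        with pytest.raises(DuplicationError):
            detect_duplications(t)

    def test_events_in_preorder(self):
        nwk = "(((Hsap|a,Hsap|b),Hsap|c),Dmel|o);"
        evs = detect_duplications(rooted(nwk))
        assert len(evs) == 2
        # preorder: the deeper (3-leaf) duplication first
        assert len(evs[0].species) >= len(evs[1].species)

    def test_one_gene_per_species_gives_none(self, ref):
        nwk = "(((Hsap|x,Mmus|x),Drer|x),(Bflo|x,Dmel|x));"
        assert detect_duplications(rooted(nwk)) == []


class TestDating:
    def test_vertebrate_stem_window(self, ref):
        # duplicated in vertebrates, amphioxus sister above: bin B2, ambiguous
        nwk = "(((Hsap|a,Drer|a),(Hsap|b,Drer|b)),Bflo|o);"
        evs = date_all(detect_duplications(rooted(nwk), "f"), ref)
        assert len(evs) == 1
        e = evs[0]
        assert e.epoch == "B2"
        assert e.ambiguous  # bounds straddle B1/B2 with only amphioxus above
        assert e.bounds == ("cephalochordate-split", "teleost-tetrapod")

    def test_teleost_specific(self, ref):
        nwk = "(((Drer|a,Olat|a),(Drer|b,Olat|b)),Hsap|o);"
        evs = date_all(detect_duplications(rooted(nwk)), ref)
        assert evs[0].epoch == "B3"
        assert not evs[0].ambiguous

    def test_tetrapod_specific(self, ref):
        nwk = "(((Hsap|a,Ggal|a),(Hsap|b,Mmus|b)),Drer|o);"
        evs = date_all(detect_duplications(rooted(nwk)), ref)
        assert evs[0].epoch == "B4"

    def test_pre_bilaterian(self, ref):
        nwk = "((Hsap|a,Dmel|a),(Hsap|b,Nvec|b));"
        evs = date_all(detect_duplications(rooted(nwk)), ref)
        assert evs[0].epoch == "B1"
        assert evs[0].refined_split == "cnidarian-split"
        # dating a copy-set spanning fly and sea anemone lands before the
        # bilaterian/non-bilaterian divergence
        node = ref.lca_node({"Hsap", "Dmel", "Mmus", "Nvec"})
        assert ref.classify_node(node) == "B1"
        assert ref.refined_split(node) == "cnidarian-split"

    def test_unknown_species_is_error(self, ref):
        from paralogon2r.species import SpeciesFrameworkError

        nwk = "((Xxxx|a,Hsap|a),(Xxxx|b,Hsap|b));"
        with pytest.raises(SpeciesFrameworkError):
            date_all(detect_duplications(rooted(nwk)), ref)


class TestSupportFilter:
    def _events(self, ref):
        nwk = "(((Hsap|a,Drer|a)95,(Hsap|b,Drer|b)40)80,Bflo|o);"
        t = rooted("((((Hsap|a,Hsap|c)95,Drer|a)60,((Hsap|b,Hsap|d)40,Drer|b)70)80,Bflo|o);")
        return date_all(detect_duplications(t, "f"), ref)

    def test_threshold(self, ref):
        evs = self._events(ref)
        supports = sorted(e.support for e in evs if e.support is not None)
        assert supports == [40.0, 80.0, 95.0]
        kept = filter_by_support(evs, 50)
        assert sorted(e.support for e in kept) == [80.0, 95.0]

    def test_zero_threshold_keeps_all(self, ref):
        evs = self._events(ref)
        assert len(filter_by_support(evs, 0)) == len(evs)

    def test_unsupported_root_retained_with_flag(self, ref):
        evs = date_all(
            detect_duplications(rooted("((Hsap|a,Drer|a),(Hsap|b,Drer|b));")), ref
        )
        kept = filter_by_support(evs, 50)
        assert len(kept) == 1 and "unsupported-root" in kept[0].flags


class TestHistogram:
    def test_counts(self, ref):
        nwk = "((((Hsap|a,Drer|a),(Hsap|b,Drer|b)),(Dmel|c,(Hsap|d,Nvec|d))),Aque|o);"
        evs = date_all(detect_duplications(rooted(nwk), "fam"), ref)
        h = epoch_histogram({"fam": evs})
        assert h.loc["fam"].sum() == len(evs)
        assert h.loc["total"].equals(h.drop("total").sum(axis=0))

    def test_empty(self):
        h = epoch_histogram({"fam": []})
        assert int(h.values.sum()) == 0

    def test_undated_event_errors(self):
        evs = detect_duplications(rooted("((Hsap|a,Mmus|a),(Hsap|b,Mmus|b));"), "f")
        with pytest.raises(DuplicationError, match="undated"):
            epoch_histogram({"f": evs})

    def test_matches_simulator_ground_truth(self, ref):
        # detection + dating applied to the *true* simulated gene trees must
        # reproduce the simulator's per-bin tally exactly
        from collections import Counter

        spec = simulate.ScenarioSpec(mode="independent_SD", n_families=10, seed=42)
        truth = simulate.simulate_family_trees(spec, ref)
        events_by_family = {}
        for name, fam in truth.families.items():
            t = rooted(fam.root.newick())
            events_by_family[name] = date_all(detect_duplications(t, name), ref)
        h = epoch_histogram(events_by_family)
        expected = Counter(
            e.bin for fam in truth.families.values() for e in fam.events
        )
        for b in ("B1", "B2", "B3", "B4"):
            assert h.loc["total", b] == expected.get(b, 0)

    def test_families_alphabetical(self, ref):
        h = epoch_histogram({"b": [], "a": [], "c": []})
        assert list(h.index) == ["a", "b", "c", "total"]
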