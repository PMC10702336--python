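"""Backbone store: import, lookup, synonym and ancestry resolution, LCA."""

import pytest
from hypothesis import given, settings, strategies as st

from barcodedb import import_backbone, lca
from barcodedb.taxonomy import (
    RANKS,
    Lineage,
    TaxonomyError,
    TaxonNode,
    BackboneStore,
    is_prefix,
    lca_many,
)


class TestImport:
    def test_toy_gbif_counts(self, toy_store):
        store, report = toy_store
        assert (report.n_nodes, report.n_synonyms) == (5, 1)
        assert len(store) == 5

    def test_empty_file_gives_empty_store(self, tmp_path):
        dump = tmp_path / "empty.tsv"
        dump.write_text("")
        store, report = import_backbone(dump, "gbif")
        assert report.n_nodes == 0
        assert store.is_null()

    def test_fixture_dump_counts_match_generator_truth(self, small_truth, small_backbone):
        _, report = small_backbone
        assert report.n_nodes == small_truth.summary["n_backbone_nodes"]
        assert report.n_synonyms == small_truth.summary["n_synonym_nodes"]
        assert report.n_skipped == 0

    def test_malformed_row_skipped_and_counted(self, tmp_path):
        dump = tmp_path / "bad.tsv"
        dump.write_text(
            "taxonID\tparentNameUsageID\tacceptedNameUsageID\t"
            "canonicalName\ttaxonRank\ttaxonomicStatus\n"
            "1\t\t\tAnimalia\tkingdom\taccepted\n"
            "\t\t\t\tgenus\taccepted\n"  # no id, no name
        )
        _, report = import_backbone(dump, "gbif")
        assert (report.n_nodes, report.n_skipped) == (1, 1)

    def test_unknown_dialect_is_fatal(self, tmp_path):
        dump = tmp_path / "x.tsv"
        dump.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            import_backbone(dump, "itis")

    def test_ncbi_taxdump_pair(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text(
            "1\t|\t1\t|\tno rank\t|\n"
            "2\t|\t1\t|\tkingdom\t|\n"
            "3\t|\t2\t|\tgenus\t|\n"
        )
        names.write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tMetazoa\t|\t\t|\tscientific name\t|\n"
            "2\t|\tAnimalia\t|\t\t|\tsynonym\t|\n"
            "3\t|\tApis\t|\t\t|\tscientific name\t|\n"
        )
        store, report = import_backbone(nodes, "ncbi", names_path=names)
        assert (report.n_nodes, report.n_synonyms) == (4, 1)
        (node,) = store.lookup("Animalia")
        assert node.status == "synonym"
        assert store.accepted_of(node).canonical_name == "Metazoa"


class TestLookup:
    def test_simple_genus_lookup(self, toy_store):
        store, _ = toy_store
        nodes = store.lookup("Apis", rank_hint="genus")
        assert len(nodes) == 1 and nodes[0].rank == "genus"

    def test_lookup_is_case_insensitive(self, toy_store):
        store, _ = toy_store
        assert store.lookup("apis MELLIFERA")[0].canonical_name == "Apis mellifera"

    def test_absent_name_returns_empty(self, toy_store):
        store, _ = toy_store
        assert store.lookup("Notaxon fakeus") == []

    def test_homonym_resolved_by_context(self, small_truth, small_backbone):
        store, _ = small_backbone
        homonyms = [
            line.split("\t")[0]
            for line in small_truth.homonym_list.read_text().splitlines()
            if line and not line.startswith("#")
        ]
        assert homonyms, "fixture must contain homonyms"
        name = homonyms[0]
        both = store.lookup(name, rank_hint="genus")
        assert len(both) >= 1  # homonym list itself may already disambiguate
        animal = store.lookup(name, rank_hint="genus", context="Animalia")
        assert len(animal) == 1
        assert store.lineage_of(animal[0]).kingdom == "Animalia"

    def test_all_accepted_names_findable(self, small_backbone):
        store, _ = small_backbone
        for name in store.accepted_names():
            assert store.lookup(name), f"accepted name {name!r} not found"


class TestAcceptedOf:
    def test_accepted_node_resolves_to_itself(self, toy_store):
        store, _ = toy_store
        (node,) = store.lookup("Apis mellifera")
        assert store.accepted_of(node) is node or store.accepted_of(node) == node

    def test_synonym_resolves_to_accepted(self, toy_store):
        store, _ = toy_store
        (syn,) = store.lookup("Apis mellifica")
        acc = store.accepted_of(syn)
        assert acc.canonical_name == "Apis mellifera"
        assert acc.status == "accepted"

    def test_chained_synonym_resolves_transitively(self, tmp_path):
        dump = tmp_path / "chain.tsv"
        dump.write_text(
            "taxonID\tparentNameUsageID\tacceptedNameUsageID\t"
            "canonicalName\ttaxonRank\ttaxonomicStatus\n"
            "1\t\t\tApis prima\tspecies\taccepted\n"
            "2\t\t1\tApis secunda\tspecies\tsynonym\n"
            "3\t\t2\tApis tertia\tspecies\tsynonym\n"
        )
        store, _ = import_backbone(dump, "gbif")
        (node,) = store.lookup("Apis tertia")
        assert store.accepted_of(node).canonical_name == "Apis prima"

    def test_accepted_of_is_idempotent(self, small_backbone):
        store, _ = small_backbone
        for node in store.iter_nodes():
            acc = store.accepted_of(node)
            assert store.accepted_of(acc) == acc

    def test_no_dangling_synonyms_in_fixture(self, small_backbone):
        store, _ = small_backbone
        for node in store.iter_nodes():
            if node.status == "synonym":
                assert store.accepted_of(node).status == "accepted"

    def test_dangling_reference_is_an_error(self):
        store = BackboneStore()
        store.add_node(TaxonNode("9", "Lostus", "species", "synonym", None, "404", "gbif"))
        with pytest.raises(TaxonomyError, match="404"):
            store.accepted_of(store.node("9"))


class TestLineageOf:
    def test_species_chain_fills_all_slots(self, small_backbone):
        store, _ = small_backbone
        species = [
            n for n in store.iter_nodes()
            if n.rank == "species" and n.status == "accepted"
        ]
        lin = store.lineage_of(species[0])
        assert all(lin.get(r) for r in RANKS)

    def test_root_kingdom_fills_only_kingdom(self, toy_store):
        store, _ = toy_store
        (node,) = store.lookup("Animalia")
        lin = store.lineage_of(node)
        assert lin.kingdom == "Animalia"
        assert lin.names()[1:] == (None,) * 6

    def test_nonstandard_rank_skipped(self, tmp_path):
        dump = tmp_path / "subfam.tsv"
        dump.write_text(
            "taxonID\tparentNameUsageID\tacceptedNameUsageID\t"
            "canonicalName\ttaxonRank\ttaxonomicStatus\n"
            "1\t\t\tApidae\tfamily\taccepted\n"
            "2\t1\t\tApinae\tsubfamily\taccepted\n"
            "3\t2\t\tApis\tgenus\taccepted\n"
        )
        store, _ = import_backbone(dump, "gbif")
        lin = store.lineage_of(store.lookup("Apis")[0])
        assert lin.family == "Apidae" and lin.genus == "Apis"
        assert "Apinae" not in lin.names()

    def test_parent_cycle_is_fatal(self):
        store = BackboneStore()
        store.add_node(TaxonNode("1", "A", "genus", "accepted", "2", "1", "gbif"))
        store.add_node(TaxonNode("2", "B", "family", "accepted", "1", "2", "gbif"))
        with pytest.raises(TaxonomyError, match="cycle"):
            store.lineage_of(store.node("1"))


FULL = Lineage("Animalia", "Arthropoda", "Insecta", "Hymenoptera", "Apidae",
               "Apis", "Apis mellifera")


class TestLca:
    def test_identical_lineages(self):
        assert lca(FULL, FULL) == FULL

    def test_truncated_at_genus_for_sister_species(self):
        other = FULL.with_rank("species", "Apis cerana")
        out = lca(FULL, other)
        assert out.genus == "Apis" and out.species is None

    def test_kingdom_disagreement_gives_empty(self):
        plant = Lineage(kingdom="Plantae")
        assert lca(FULL, plant).is_empty()

    lineage_strategy = st.builds(
        Lineage.from_names,
        st.lists(st.sampled_from(["Aa", "Bb", "Cc", None]), min_size=7, max_size=7),
    )

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(a=lineage_strategy, b=lineage_strategy)
    def test_commutative_idempotent_and_never_finer(self, a, b):
        ab = lca(a, b)
        assert ab == lca(b, a)
        assert lca(a, a) == a
        assert ab.resolution_index() <= min(a.resolution_index(), b.resolution_index())
        assert lca_many([a, b]) == ab
        assert is_prefix(lca_many([a, b, FULL]), ab)

    def test_from_pairs_projects_standard_ranks_only(self):
        lin = Lineage.from_pairs(
            [("Kingdom", "Animalia"), ("subfamily", "Apinae"), ("genus", "Apis")]
        )
        assert lin.kingdom == "Animalia" and lin.genus == "Apis"
        assert "Apinae" not in lin.names()
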