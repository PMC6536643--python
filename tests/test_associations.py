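"""Integration of disease-gene and disease-phenotype mapping sources."""

import pytest

from gpsim.associations import (
    DGPStore,
    MappingRecord,
    build_dgp,
    filter_phenotypes,
    hpo_source,
    parse_hpo_annotation_file,
    parse_id_gene_file,
    parse_name_gene_file,
    propagate_up,
    resolve_disease,
)

from conftest import write_obo
from gpsim.ontology import load_obo


@pytest.fixture
def annot_file(tmp_path):
    rows = [
        "#Format: disease-id<tab>gene-symbol<tab>gene-id<tab>HPO-ID<tab>HPO-term-name",
        "OMIM:104300\tAPP\t351\tHP:0000020\tmemory impairment",
        "OMIM:104300\tPSEN1\t5663\tHP:0000030\tdementia",
        "DOID:5419\tDRD2\t1813\tHP:0000040\tdelusion",
        "bad row",
        "OMIM:104300\tAPP",  # too few columns
        "DOID:5419\tCOMT\t1312\tHP:0000050\tx",
    ]
    p = tmp_path / "annot.tsv"
    p.write_text("\n".join(rows) + "\n")
    return p


class TestParsing:
    def test_triples_round_trip_and_skip(self, annot_file, caplog):
        with caplog.at_level("WARNING"):
            triples = parse_hpo_annotation_file(annot_file)
        assert triples[0] == ("OMIM:104300", "APP", "HP:0000020")
        assert len(triples) == 4  # 2 malformed rows skipped
        skips = [r for r in caplog.records if "malformed" in r.message]
        assert len(skips) == 2

    def test_comment_only_file_yields_nothing(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("# header only\n# another\n")
        assert parse_hpo_annotation_file(p) == []

    def test_two_column_parsers(self, tmp_path):
        idf = tmp_path / "id.tsv"
        idf.write_text("OMIM:104300\tAPP\nDOID:5419\tDRD2\n")
        src = parse_id_gene_file(idf)
        assert src.tag == "sidd_style"
        assert all(r.record_kind == "by_id" for r in src.records)

        nf = tmp_path / "name.tsv"
        nf.write_text("Alzheimer's disease\tAPP\nschizophrenia\tDRD2\n")
        src = parse_name_gene_file(nf)
        assert src.tag == "dancer_style"
        assert src.records[0] == MappingRecord(
            "Alzheimer's disease", "APP", "by_name", "gene"
        )


class TestResolveDisease:
    def test_doid_identity_and_alt_id(self, do_graph):
        rec = MappingRecord("DOID:10652", "APP", "by_id", "gene")
        assert resolve_disease(do_graph, rec) == "DOID:10652"
        rec = MappingRecord("DOID:24817", "APP", "by_id", "gene")
        assert resolve_disease(do_graph, rec) == "DOID:10652"

    def test_obsolete_doid_unresolved(self, do_graph):
        rec = MappingRecord("DOID:9999", "APP", "by_id", "gene")
        assert resolve_disease(do_graph, rec) is None

    def test_xref_resolves_to_unique_term(self, do_graph):
        rec = MappingRecord("OMIM:104300", "APP", "by_id", "gene")
        assert resolve_disease(do_graph, rec) == "DOID:10652"

    def test_name_matches_after_casefold_and_whitespace(self, do_graph):
        rec = MappingRecord("  ALZHEIMER'S   disease ", "APP", "by_name", "gene")
        assert resolve_disease(do_graph, rec) == "DOID:10652"

    def test_ambiguous_name_is_dropped_not_guessed(self, tmp_path):
        g = load_obo(
            write_obo(
                tmp_path / "amb.obo",
                [
                    {"id": "DOID:1", "name": "root"},
                    {"id": "DOID:2", "name": "dup disease", "is_a": ["DOID:1"]},
                    {"id": "DOID:3", "name": "other", "synonyms": ["dup disease"], "is_a": ["DOID:1"]},
                ],
            )
        )
        rec = MappingRecord("dup disease", "APP", "by_name", "gene")
        assert resolve_disease(g, rec) is None

    def test_unknown_name_unresolved(self, do_graph):
        rec = MappingRecord("no such disease", "APP", "by_name", "gene")
        assert resolve_disease(do_graph, rec) is None


class TestBuildDgp:
    def test_dedup_with_merged_provenance(self, do_graph, hpo_graph, tmp_path):
        idf = tmp_path / "id.tsv"
        idf.write_text("OMIM:104300\tAPP\n")
        nf = tmp_path / "name.tsv"
        nf.write_text("Alzheimer's disease\tAPP\n")
        store = build_dgp(
            do_graph, hpo_graph, [parse_id_gene_file(idf), parse_name_gene_file(nf)]
        )
        assert store.gene_set("DOID:10652") == {"APP"}
        assert store.provenance[("DOID:10652", "APP")] == {"sidd_style", "dancer_style"}

    def test_full_integration_counts(self, do_graph, hpo_graph, annot_file):
        store = build_dgp(
            do_graph, hpo_graph, [hpo_source(parse_hpo_annotation_file(annot_file))]
        )
        assert store.diseases == {"DOID:10652", "DOID:5419"}
        assert store.gene_set("DOID:10652") == {"APP", "PSEN1"}
        assert store.phenotype_set("DOID:5419") == {"HP:0000040", "HP:0000050"}
        assert store.report.resolved == 8
        assert store.report.unresolved == 0

    def test_unresolvable_source_yields_empty_store(self, do_graph, hpo_graph, tmp_path, caplog):
        nf = tmp_path / "n.tsv"
        nf.write_text("martian fever\tAPP\nlunar cough\tDRD2\n")
        with caplog.at_level("WARNING"):
            store = build_dgp(do_graph, hpo_graph, [parse_name_gene_file(nf)])
        assert store.diseases == set()
        assert store.report.unresolved == 2
        assert any("empty" in r.message for r in caplog.records)

    def test_invalid_phenotype_targets_counted(self, do_graph, hpo_graph, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("DOID:5419\tDRD2\t1\tHP:9999999\tnope\n")
        store = build_dgp(do_graph, hpo_graph, [hpo_source(parse_hpo_annotation_file(p))])
        assert store.phenotype_set("DOID:5419") == set()
        assert store.report.invalid_phenotypes == 1

    def test_idempotent_rebuild(self, do_graph, hpo_graph, annot_file):
        src = lambda: [hpo_source(parse_hpo_annotation_file(annot_file))]
        s1 = build_dgp(do_graph, hpo_graph, src())
        s2 = build_dgp(do_graph, hpo_graph, src())
        assert s1.gene_sets == s2.gene_sets
        assert s1.phenotype_sets == s2.phenotype_sets
        assert s1.provenance == s2.provenance

    def test_tsv_round_trip(self, do_graph, hpo_graph, annot_file, tmp_path):
        store = build_dgp(
            do_graph, hpo_graph, [hpo_source(parse_hpo_annotation_file(annot_file))]
        )
        out = tmp_path / "store.tsv"
        store.to_tsv(out)
        again = DGPStore.from_tsv(out)
        assert again.gene_sets == store.gene_sets
        assert again.phenotype_sets == store.phenotype_sets

    def test_propagation_is_opt_in(self, do_graph, hpo_graph, annot_file):
        store = build_dgp(
            do_graph, hpo_graph, [hpo_source(parse_hpo_annotation_file(annot_file))]
        )
        assert "DOID:0000002" not in store.diseases  # not propagated by default
        up = propagate_up(store, do_graph)
        assert store.gene_set("DOID:10652") <= up.gene_set("DOID:0000002")


class TestFilterPhenotypes:
    @pytest.fixture
    def store(self, do_graph, hpo_graph):
        s = DGPStore()
        # depths in hpo_graph: HP:0000020 -> 2, HP:0000030 -> 3, HP:0000040 -> 4, HP:0000050 -> 5
        for hp in ("HP:0000020", "HP:0000030", "HP:0000040", "HP:0000050"):
            s.add("DOID:10652", "phenotype", hp, "hpo_annot")
        s.add("DOID:10652", "gene", "APP", "hpo_annot")
        s.add("DOID:5419", "phenotype", "HP:0000050", "hpo_annot")
        return s

    def test_zero_filter_is_identity(self, store, hpo_graph):
        out = filter_phenotypes(store, hpo_graph, 0, 0)
        assert out.phenotype_sets == store.phenotype_sets
        assert out.gene_sets == store.gene_sets

    def test_depth_filter_removes_shallow_terms(self, store, hpo_graph):
        out = filter_phenotypes(store, hpo_graph, min_depth=4, min_count=0)
        assert out.phenotype_set("DOID:10652") == {"HP:0000040", "HP:0000050"}

    def test_min_count_drops_entry_but_keeps_genes(self, store, hpo_graph):
        out = filter_phenotypes(store, hpo_graph, min_depth=0, min_count=5)
        assert "DOID:10652" not in out.phenotype_sets
        assert out.gene_set("DOID:10652") == {"APP"}

    def test_negative_arguments_rejected(self, store, hpo_graph):
        with pytest.raises(ValueError):
            filter_phenotypes(store, hpo_graph, -1, 0)
        with pytest.raises(ValueError):
            filter_phenotypes(store, hpo_graph, 0, -1)

    @pytest.mark.parametrize("d1,d2", [(0, 2), (2, 4), (3, 5)])
    def test_raising_min_depth_never_adds_phenotypes(self, store, hpo_graph, d1, d2):
        lo = filter_phenotypes(store, hpo_graph, d1, 0)
        hi = filter_phenotypes(store, hpo_graph, d2, 0)
        for d in hi.phenotype_sets:
            assert hi.phenotype_set(d) <= lo.phenotype_set(d)
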