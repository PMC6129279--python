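"""GAF / phenotype / prediction / STRING parsing and corpus operations."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorules.annotations import (
    AnnotationCorpus,
    GeneAnnotation,
    map_ids,
    parse_gaf,
    parse_phenotype_tsv,
    parse_predicted_functions,
    parse_string_links,
    propagate,
)
from phenorules.ontology import ancestors, parse_obo

from conftest import random_dag_obo


def gaf_row(gene="P1", qualifier="", go="GO:0001783", evidence="IDA",
            aspect="P", extension=""):
    cols = ["DB", gene, gene, qualifier, go, "PMID:1", evidence, "", aspect,
            "", "", "protein", "taxon:10090", "20171215", "DB", extension, ""]
    return "\t".join(cols)


class TestGaf:
    def test_experimental_kept_electronic_dropped(self):
        corpus = parse_gaf([gaf_row(evidence="IDA"), gaf_row(gene="P2", evidence="IEA")])
        assert corpus.genes == {"P1"}

    def test_not_qualifier_dropped(self):
        corpus = parse_gaf([gaf_row(qualifier="NOT|involved_in"),
                            gaf_row(gene="P2", qualifier="involved_in")])
        assert corpus.genes == {"P2"}

    def test_annotation_extension_dropped_as_contextual(self):
        rows = [gaf_row(extension="occurs_in(CL:0000236)"), gaf_row(gene="P2")]
        assert parse_gaf(rows).genes == {"P2"}
        assert parse_gaf(rows, drop_contextual=False).genes == {"P1", "P2"}

    def test_wrong_column_count_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_gaf(["!gaf-version: 2.2", "too\tfew\tcolumns"])

    def test_duplicates_collapse(self):
        corpus = parse_gaf([gaf_row(), gaf_row()])
        assert corpus.n_annotations() == 1

    def test_row_order_is_irrelevant(self):
        rows = [gaf_row(gene=f"P{i}", go=f"GO:{i:07d}") for i in range(10)]
        shuffled = rows[:]
        random.Random(0).shuffle(shuffled)
        a, b = parse_gaf(rows), parse_gaf(shuffled)
        assert a.assignments == b.assignments


class TestPhenotypeTsv:
    def test_simple_two_column(self):
        corpus = parse_phenotype_tsv(["g1\tMP:0008782"])
        assert corpus.classes_of("g1") == {"MP:0008782"}
        assert not corpus.closed

    def test_mgi_dialect_with_duplicate_rows(self):
        row = "allele\tsym\tid\tbg\tMP:0008782\tPMID:1\tMGI:2444668"
        corpus = parse_phenotype_tsv([row, row], dialect="mgi_gene_pheno")
        assert corpus.assignments == {
            "MGI:2444668": {GeneAnnotation("MP:0008782")}}

    def test_hpo_dialect_prefix_filter(self):
        rows = ["1\tSYM\tname\tHP:0000001", "2\tSYM2\tname\tMP:0000001"]
        corpus = parse_phenotype_tsv(rows, dialect="hpo_gene_pheno")
        assert corpus.genes == {"1"}

    def test_known_pairs_round_trip(self):
        pairs = {(f"g{i}", f"MP:{i:07d}") for i in range(20)}
        rows = [f"{g}\t{c}" for g, c in sorted(pairs)]
        corpus = parse_phenotype_tsv(rows)
        assert {(g, a.class_id) for g, anns in corpus.assignments.items()
                for a in anns} == pairs

    def test_empty_file_gives_empty_corpus(self):
        assert parse_phenotype_tsv([]).genes == set()


class TestPredictedFunctions:
    def test_score_passthrough(self):
        corpus = parse_predicted_functions(["g1\tGO:0002904\t0.9"])
        (ann,) = corpus.assignments["g1"]
        assert ann.score == 0.9 and ann.evidence == "PRED"

    @pytest.mark.parametrize("bad", ["0", "0.0", "1.5", "-0.1"])
    def test_out_of_range_score_raises(self, bad):
        with pytest.raises(ValueError, match="line 1"):
            parse_predicted_functions([f"g1\tGO:0002904\t{bad}"])

    def test_scores_preserved_exactly(self):
        rng = random.Random(4)
        rows, expected = [], {}
        for i in range(50):
            score = round(rng.uniform(0.01, 1.0), 6)
            rows.append(f"g{i}\tGO:{i:07d}\t{score}")
            expected[f"g{i}"] = score
        corpus = parse_predicted_functions(rows)
        for gene, score in expected.items():
            (ann,) = corpus.assignments[gene]
            assert ann.score == score


class TestMapIds:
    def _corpus(self, **genes):
        c = AnnotationCorpus()
        for gene, classes in genes.items():
            for cls in classes:
                c.add(gene, GeneAnnotation(cls))
        return c

    def test_rename(self):
        mapped = map_ids(self._corpus(P1=["MP:0000001"]), {"P1": "MGI:1"})
        assert mapped.genes == {"MGI:1"}

    def test_on_missing_drop_and_error(self):
        corpus = self._corpus(P1=["MP:0000001"], P2=["MP:0000002"])
        assert map_ids(corpus, {"P1": "MGI:1"}, on_missing="drop").genes == {"MGI:1"}
        assert map_ids(corpus, {"P1": "MGI:1"}, on_missing="keep").genes == {"MGI:1", "P2"}
        with pytest.raises(KeyError):
            map_ids(corpus, {"P1": "MGI:1"}, on_missing="error")

    def test_collision_merges_annotation_sets(self):
        corpus = self._corpus(P1=["MP:0000001"], P2=["MP:0000002", "MP:0000003"])
        mapped = map_ids(corpus, {"P1": "MGI:1", "P2": "MGI:1"})
        union = corpus.classes_of("P1") | corpus.classes_of("P2")
        assert mapped.classes_of("MGI:1") == union


class TestPropagate:
    def _graph(self):
        return parse_obo(random_dag_obo(30, seed=8, prefix="MP").splitlines())

    def test_root_annotation_unchanged(self):
        graph = self._graph()
        corpus = AnnotationCorpus({"g1": {GeneAnnotation("MP:0000000")}})
        closed = propagate(corpus, graph)
        assert closed.classes_of("g1") == {"MP:0000000"}
        assert closed.closed

    def test_chain_leaf_propagates_to_all(self):
        text = ("format-version: 1.2\n\n[Term]\nid: A:1\nname: a\n\n"
                "[Term]\nid: A:2\nname: b\nis_a: A:1\n\n"
                "[Term]\nid: A:3\nname: c\nis_a: A:2\n\n")
        graph = parse_obo(text.splitlines())
        corpus = AnnotationCorpus({"g1": {GeneAnnotation("A:3")}})
        assert propagate(corpus, graph).classes_of("g1") == {"A:1", "A:2", "A:3"}

    def test_scores_equal_brute_force_max(self):
        graph = self._graph()
        rng = random.Random(1)
        corpus = AnnotationCorpus()
        for g in range(8):
            for _ in range(4):
                corpus.add(
                    f"g{g}",
                    GeneAnnotation(f"MP:{rng.randrange(30):07d}", "PRED",
                                   round(rng.uniform(0.1, 1.0), 3)))
        closed = propagate(corpus, graph)
        for gene, anns in corpus.assignments.items():
            expected = {}
            for ann in anns:
                for anc in ancestors(graph, ann.class_id):
                    expected[anc] = max(expected.get(anc, 0.0), ann.score)
            got = {a.class_id: a.score for a in closed.assignments[gene]}
            assert got == expected

    def test_idempotent(self):
        graph = self._graph()
        corpus = AnnotationCorpus({"g1": {GeneAnnotation("MP:0000029"),
                                          GeneAnnotation("MP:0000013")}})
        once = propagate(corpus, graph)
        twice = propagate(once, graph)
        assert once.assignments == twice.assignments

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(min_value=0, max_value=29), min_size=1, max_size=6),
           st.floats(min_value=0.1, max_value=1.0))
    def test_propagation_never_increases_scores(self, ids, score):
        graph = self._graph()
        score = round(score, 4)
        corpus = AnnotationCorpus(
            {"g": {GeneAnnotation(f"MP:{i:07d}", "PRED", score) for i in ids}})
        closed = propagate(corpus, graph)
        assert all(a.score <= score for a in closed.assignments["g"])
        again = propagate(closed, graph)
        assert again.assignments == closed.assignments


class TestStringLinks:
    def test_threshold_is_inclusive_at_300(self):
        rows = ["protein1 protein2 combined_score", "a b 299", "a c 300"]
        assert parse_string_links(rows) == {("a", "c")}

    def test_self_interactions_excluded(self):
        assert parse_string_links(["a a 900"]) == set()

    def test_unordered_dedup(self):
        assert parse_string_links(["a b 500", "b a 700"]) == {("a", "b")}

    def test_id_map_requires_both_endpoints(self):
        rows = ["x y 500", "x z 500"]
        got = parse_string_links(rows, id_map={"x": "g1", "y": "g2"})
        assert got == {("g1", "g2")}

    def test_filter_matches_brute_force_oracle(self):
        rng = random.Random(13)
        rows, expected = [], set()
        for _ in range(100):
            a, b = f"p{rng.randrange(20)}", f"p{rng.randrange(20)}"
            score = rng.randrange(0, 1000)
            rows.append(f"{a} {b} {score}")
            if score >= 300 and a != b:
                expected.add((min(a, b), max(a, b)))
        assert parse_string_links(rows) == expected
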