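import pytest

from entcite.lexicon import EntityType, build_lexicon
from entcite.ner import (
    annotate_corpus,
    chunk_text,
    cited_citation_table,
    citing_frequency_table,
    write_annotations,
)
from entcite.corpus import build_paper_citation_graph
from entcite.synthdata import SynthConfig, generate_corpus

from .conftest import eid
from .oracles import chunk_oracle


class TestChunkText:
    def test_longest_match_suppresses_shorter(self, small_lexicon):
        mentions = chunk_text("metformin reduces insulin resistance", small_lexicon)
        got = [(m.entity.entity_type, m.surface) for m in mentions]
        assert got == [
            (EntityType.DRUG, "metformin"),
            (EntityType.DISEASE, "insulin resistance"),
        ]

    def test_fig_style_gene_entry(self, small_lexicon):
        mentions = chunk_text("ACTA1", small_lexicon)
        assert len(mentions) == 1
        assert mentions[0].entity.canonical_id == "P68133"

    def test_empty_text(self, small_lexicon):
        assert chunk_text("", small_lexicon) == []

    def test_token_boundaries_respected(self, small_lexicon):
        # no match may begin or end inside an alphanumeric run
        assert chunk_text("xmetformin metforminx ametforminb", small_lexicon) == []

    def test_offsets_slice_normalized_text(self, small_lexicon):
        from entcite.lexicon import normalize_surface

        text = "Metformin  and   Insulin."
        norm = normalize_surface(text)
        for m in chunk_text(text, small_lexicon):
            assert norm[m.char_start : m.char_end] == m.surface

    def test_trailing_whitespace_invariance(self, small_lexicon):
        base = chunk_text("metformin and insulin", small_lexicon)
        padded = chunk_text("metformin and insulin   \n ", small_lexicon)
        assert [(m.surface, m.char_start) for m in base] == [
            (m.surface, m.char_start) for m in padded
        ]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        # random text built from surfaces and fillers must chunk identically
        # to brute-force enumeration + longest-leftmost greedy selection
        import numpy as np

        rng = np.random.default_rng(seed)
        lex = build_lexicon(
            [
                ("alpha", eid("G", "A")),
                ("alpha beta", eid("Z", "AB")),
                ("beta", eid("G", "B")),
                ("beta gamma delta", eid("Z", "BGD")),
                ("gamma", eid("D", "C")),
                ("delta", eid("D", "D")),
            ]
        )
        vocab = ["alpha", "beta", "gamma", "delta", "filler", "and", "x9"]
        text = " ".join(rng.choice(vocab, size=30))
        mentions = chunk_text(text, lex)
        expected = chunk_oracle(text, sorted({s for s, _ in lex}))
        assert [(m.char_start, m.char_end, m.surface) for m in mentions] == expected
        # non-overlap + sortedness invariant
        for a, b in zip(mentions, mentions[1:]):
            assert a.char_end <= b.char_start


class TestAnnotateCorpus:
    def test_multiset_vs_set_counts(self, small_lexicon, small_corpus):
        ann = annotate_corpus(small_corpus, small_lexicon, {"e"})
        counts = ann.counts("e")
        # "Obesity review" title + "Obesity and metformin." abstract
        assert counts[small_lexicon.get("obesity")] == 2
        assert ann.entity_set("e") == frozenset(
            {small_lexicon.get("obesity"), small_lexicon.get("metformin")}
        )

    def test_title_abstract_boundary_blocks_matches(self):
        from entcite.corpus import Corpus, Document

        lex = build_lexicon([("insulin resistance", eid("Z", "D007333"))])
        corpus = Corpus([Document("a", "About insulin", "resistance is discussed")])
        ann = annotate_corpus(corpus, lex, {"a"})
        assert ann.counts("a") == {}

    def test_ground_truth_recovery(self):
        corpus, truth, lex = generate_corpus(SynthConfig(n_docs=60, seed=5))
        ann = annotate_corpus(corpus, lex, corpus.ids)
        for doc_id in corpus.ids:
            assert ann.counts(doc_id) == truth.mentions[doc_id]

    def test_annotation_export(self, small_lexicon, small_corpus, tmp_path):
        ann = annotate_corpus(small_corpus, small_lexicon, {"a", "b"})
        out = tmp_path / "ann.tsv"
        write_annotations(ann, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("doc_id\t")
        assert len(lines) == 1 + sum(len(ann.mentions(d)) for d in ("a", "b"))


class TestFrequencyTables:
    def test_document_frequency(self, small_lexicon, small_corpus):
        ann = annotate_corpus(small_corpus, small_lexicon, {"a", "b", "e"})
        table = citing_frequency_table(ann, {"a", "b", "e"})
        by_name = dict(zip(table.entity_name, table["count"]))
        assert by_name["obesity"] == 3  # three docs mention it
        assert by_name["metformin"] == 2  # docs a and e, despite 2 mentions in e

    def test_mention_mode_counts_multiplicity(self, small_lexicon, small_corpus):
        ann = annotate_corpus(small_corpus, small_lexicon, {"e"})
        table = citing_frequency_table(ann, {"e"}, mode="mentions")
        by_name = dict(zip(table.entity_name, table["count"]))
        assert by_name["obesity"] == 2

    def test_empty_annotation(self, small_lexicon):
        from entcite.ner import AnnotationMap

        table = citing_frequency_table(AnnotationMap(), set())
        assert table.empty

    def test_matches_brute_force_document_recount(self):
        corpus, _, lex = generate_corpus(SynthConfig(n_docs=40, seed=9))
        ann = annotate_corpus(corpus, lex, corpus.ids)
        table = citing_frequency_table(ann, corpus.ids)
        for _, row in table.iterrows():
            expected = sum(
                1
                for d in corpus.ids
                if any(
                    e.canonical_id == row.entity_id and e.entity_type.value == row.entity_type
                    for e in ann.entity_set(d)
                )
            )
            assert row["count"] == expected

    def test_cited_table_counts_citation_events(self, small_lexicon, small_corpus):
        ann = annotate_corpus(small_corpus, small_lexicon, {"a", "b", "c", "d", "e"})
        pg = build_paper_citation_graph(small_corpus, {"a", "b", "c"})
        table = cited_citation_table(ann, pg)  # arcs: a->d, a->e, b->d, c->e
        by_name = dict(zip(table.entity_name, table["count"]))
        assert by_name["insulin"] == 2  # d cited twice
        assert by_name["obesity"] == 2  # e cited twice
        # entity only in citing docs is absent
        papers = cited_citation_table(ann, pg, mode="papers")
        assert dict(zip(papers.entity_name, papers["count"]))["insulin"] == 1

    def test_matches_nested_loop_arc_oracle(self):
        corpus, _, lex = generate_corpus(SynthConfig(n_docs=40, seed=13))
        ann = annotate_corpus(corpus, lex, corpus.ids)
        pg = build_paper_citation_graph(corpus, corpus.ids)
        table = cited_citation_table(ann, pg)
        for _, row in table.head(10).iterrows():
            expected = sum(
                1
                for _, cited in pg.arcs
                if any(
                    e.canonical_id == row.entity_id and e.entity_type.value == row.entity_type
                    for e in ann.entity_set(cited)
                )
            )
            assert row["count"] == expected
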