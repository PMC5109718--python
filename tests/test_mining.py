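"""Sentence splitting, candidate extraction, the attributive heuristic and
corpus mining against fixture ground truth."""

import pytest

from florapheno import fixtures as fx
from florapheno.lexicon import normalize
from florapheno.mining import (EQRecord, TaxonDocument, attributive_filter,
                               corpus_from_tsv, corpus_to_tsv,
                               extract_candidates, records_from_tsv,
                               records_to_tsv, split_sentences)


class TestSplitSentences:
    @pytest.mark.parametrize("text,expected", [
        ("Leaves opposite. Flowers red.", ["Leaves opposite", "Flowers red"]),
        ("Stem 2 cm. in diam., glabrous.", ["Stem 2 cm. in diam., glabrous"]),
        ("", []),
        ("Herb 1.5 m tall; leaves ovate!", ["Herb 1.5 m tall", "leaves ovate"]),
        ("See T. Smith. Petals white.", ["See T. Smith", "Petals white"]),
    ])
    def test_examples(self, text, expected):
        assert split_sentences(text) == expected

    def test_coverage_of_input(self):
        text = "Flowers red; stamens yellow. Leaves ovate."
        joined = " ".join(split_sentences(text))
        for word in ("Flowers", "stamens", "Leaves"):
            assert word in joined


class TestExtractCandidates:
    def test_single_pair(self, lexicons):
        e_lex, q_lex = lexicons["en"]
        tokens = normalize("The flowers are red", "en")
        cands = extract_candidates(tokens, e_lex, q_lex)
        assert [(e[1], q[1]) for e, q in cands] == [(fx.FLOWER, fx.RED)]

    def test_cross_product_before_filtering(self, lexicons):
        e_lex, q_lex = lexicons["en"]
        tokens = normalize("The flowers are red with yellow stamens.", "en")
        pairs = {(e[1], q[1]) for e, q in extract_candidates(tokens, e_lex, q_lex)}
        assert pairs == {(fx.FLOWER, fx.RED), (fx.FLOWER, fx.YELLOW),
                         (fx.STAMEN, fx.RED), (fx.STAMEN, fx.YELLOW)}

    def test_quality_without_entity_gives_nothing(self, lexicons):
        e_lex, q_lex = lexicons["en"]
        tokens = normalize("Mostly red throughout", "en")
        assert extract_candidates(tokens, e_lex, q_lex) == []


class TestAttributiveFilter:
    def _spans(self, lexicons, sentence):
        e_lex, q_lex = lexicons["en"]
        tokens = normalize(sentence, "en")
        ents = {cid: span for span, cid in e_lex.lookup(tokens)}
        quals = {cid: span for span, cid in q_lex.lookup(tokens)}
        return tokens, ents, quals

    def test_worked_interleaved_sentence(self, lexicons):
        tokens, ents, quals = self._spans(
            lexicons, "The flowers are red with yellow stamens.")
        all_spans = list(ents.values())
        accept = lambda e, q: attributive_filter(tokens, ents[e], quals[q],
                                                 all_spans)
        assert accept(fx.FLOWER, fx.RED)
        assert accept(fx.STAMEN, fx.YELLOW)
        assert not accept(fx.FLOWER, fx.YELLOW)   # stamen claims yellow
        assert not accept(fx.STAMEN, fx.RED)      # flower is nearer to red
    def test_pre_and_post_modifier_adjacency(self, lexicons):
        for sentence in ("red flowers", "flowers red"):
            tokens, ents, quals = self._spans(lexicons, sentence)
            assert attributive_filter(tokens, ents[fx.FLOWER], quals[fx.RED],
                                      list(ents.values()))

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError):
            attributive_filter(["a", "b"], (0, 1), (0, 2))


class TestMineCorpus:
    def test_single_document_worked_example(self, miner):
        doc = TaxonDocument("TX:0001", "Examplea", "The flowers are red", "en")
        records = miner.mine_document(doc)
        assert [(r.entity_class, r.quality_class) for r in records] == \
            [(fx.FLOWER, fx.RED)]
        assert not records[0].relational_placeholder

    def test_relational_quality_gets_placeholder(self, miner):
        doc = TaxonDocument("TX:0002", "Ex", "The stems are connected.", "en")
        (rec,) = miner.mine_document(doc)
        assert rec.quality_class == fx.CONNECTED
        assert rec.relational_placeholder

    def test_unknown_language_is_error(self, miner):
        doc = TaxonDocument("TX:0003", "Ex", "Die Blüten sind rot.", "de")
        with pytest.raises(ValueError, match="de"):
            miner.mine_document(doc)

    def test_empty_corpus(self, miner):
        records, summary = miner.mine_corpus([])
        assert records == [] and summary.n_records == 0

    def test_document_order_invariance(self, miner, default_corpus):
        docs, _ = default_corpus
        fwd, _ = miner.mine_corpus(docs)
        rev, _ = miner.mine_corpus(list(reversed(docs)))
        assert fwd == rev

    def test_no_record_pairs_two_entities_or_two_qualities(
            self, default_records, structure_ont, quality_ont):
        for rec in default_records:
            assert rec.entity_class in structure_ont.classes
            assert rec.quality_class in quality_ont.classes
            assert rec.entity_class not in quality_ont.classes

    def test_recall_and_filter_precision_on_ground_truth(
            self, miner, default_corpus):
        """All planted pairs are recovered (recall 1.0) and none of the
        construction-guaranteed negative cross-pairings appear."""
        docs, truth = default_corpus
        records, summary = miner.mine_corpus(docs)
        mined = {(r.taxon_id, r.entity_class, r.quality_class) for r in records}
        assert truth.expected_eq <= mined
        assert mined & truth.guaranteed_negatives == set()
        assert mined == truth.expected_eq  # templates plant nothing else
        assert summary.n_taxa == len({t for t, _, _ in truth.expected_eq})

    def test_french_documents_mined_via_translation(self, miner):
        doc = TaxonDocument("TX:0004", "Ex", "Les fleurs sont rouges.", "fr")
        records = miner.mine_document(doc)
        assert [(r.entity_class, r.quality_class) for r in records] == \
            [(fx.FLOWER, fx.RED)]


class TestInterchange:
    def test_corpus_tsv_round_trip(self, default_corpus):
        docs, _ = default_corpus
        assert corpus_from_tsv(corpus_to_tsv(docs)) == docs

    def test_corpus_duplicate_taxon_rejected(self):
        text = ("taxon_id\ttaxon_name\tlanguage\tdescription\n"
                "TX:1\ta\ten\tx\nTX:1\tb\ten\ty\n")
        with pytest.raises(ValueError, match="duplicate"):
            corpus_from_tsv(text)

    def test_records_tsv_round_trip(self, default_records):
        parsed = records_from_tsv(records_to_tsv(default_records))
        assert [(r.key(), r.relational_placeholder) for r in parsed] == \
            [(r.key(), r.relational_placeholder) for r in default_records]
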