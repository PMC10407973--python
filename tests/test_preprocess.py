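import pytest

from kbrelex.formats_io import Document, EntityMention
from kbrelex.preprocess import (
    MarkerVocab,
    MarkingMethod,
    SplitterContractError,
    enumerate_pairs,
    mark_entities,
    project_entities,
    split_sentences,
    unmark,
)
from kbrelex import training


def _doc(title, abstract, mentions=()):
    doc = Document(pmid="1", title=title, abstract=abstract)
    doc.mentions.extend(mentions)
    doc.validate()
    return doc


def _mention(doc, mid, etype, needle, occurrence=0):
    start = -1
    for _ in range(occurrence + 1):
        start = doc.full_text.index(needle, start + 1)
    return EntityMention(mid, etype, start, start + len(needle), needle)


class TestSplitSentences:
    def test_two_sentences(self):
        doc = _doc("T.", "A binds B. C inhibits D.")
        windows = split_sentences(doc)
        assert [w.text for w in windows] == ["T.", "A binds B.", "C inhibits D."]
        for w in windows:
            assert doc.full_text[w.start : w.end] == w.text

    def test_single_sentence_abstract(self):
        doc = _doc("Title here.", "One single sentence without breaks")
        windows = split_sentences(doc)
        assert len(windows) == 2  # title + abstract
        assert windows[1].text == "One single sentence without breaks"

    def test_windows_ordered_nonoverlapping(self, small_bundle):
        for doc in small_bundle.docset:
            windows = split_sentences(doc)
            prev_end = -1
            for w in windows:
                assert w.start >= prev_end
                assert doc.full_text[w.start : w.end] == w.text
                prev_end = w.end

    def test_overlapping_splitter_rejected(self):
        doc = _doc("T.", "Some text here.")
        with pytest.raises(SplitterContractError):
            split_sentences(doc, splitter=lambda t: [(0, 10), (5, 15)])

    def test_out_of_range_splitter_rejected(self):
        doc = _doc("T.", "Short.")
        with pytest.raises(SplitterContractError):
            split_sentences(doc, splitter=lambda t: [(0, len(t) + 5)])


class TestProjectEntities:
    def test_contained_mention_attached(self):
        doc = _doc("T.", "Aspirin binds COX2.")
        m = _mention(doc, "T1", "CHEMICAL", "Aspirin")
        doc.mentions.append(m)
        windows = split_sentences(doc)
        report = project_entities(doc, windows)
        assert report.n_attached == 1 and report.n_dropped == 0
        assert m in windows[1].mentions

    def test_straddling_mention_dropped(self):
        doc = _doc("T.", "First part. Second part.")
        straddler = EntityMention("T1", "CHEMICAL", 8, 16, doc.full_text[8:16])
        doc.mentions.append(straddler)
        windows = split_sentences(doc)
        report = project_entities(doc, windows)
        assert report.n_dropped == 1
        assert all(straddler not in w.mentions for w in windows)

    def test_identical_spans_different_types_both_attached(self):
        doc = _doc("T.", "ABC1 is ambiguous.")
        a = _mention(doc, "T1", "CHEMICAL", "ABC1")
        b = _mention(doc, "T2", "GENE", "ABC1")
        doc.mentions.extend([a, b])
        windows = split_sentences(doc)
        project_entities(doc, windows)
        assert {m.mention_id for m in windows[1].mentions} == {"T1", "T2"}


class TestEnumeratePairs:
    def test_cartesian_product(self):
        doc = _doc("T.", "A1 and A2 with G1 G2 G3 here.")
        ms = [
            _mention(doc, "C1", "CHEMICAL", "A1"),
            _mention(doc, "C2", "CHEMICAL", "A2"),
            _mention(doc, "G1", "GENE", "G1"),
            _mention(doc, "G2", "GENE", "G2"),
            _mention(doc, "G3", "GENE", "G3"),
        ]
        doc.mentions.extend(ms)
        windows = split_sentences(doc)
        project_entities(doc, windows)
        pairs = enumerate_pairs(windows[1])
        assert len(pairs) == 6
        assert all(p.chem.etype == "CHEMICAL" and p.gene.etype == "GENE" for p in pairs)

    def test_chemicals_only_yield_nothing(self):
        doc = _doc("T.", "A1 and A2 alone.")
        doc.mentions.extend(
            [_mention(doc, "C1", "CHEMICAL", "A1"), _mention(doc, "C2", "CHEMICAL", "A2")]
        )
        windows = split_sentences(doc)
        project_entities(doc, windows)
        assert enumerate_pairs(windows[1]) == []

    def test_no_cross_sentence_pairs(self):
        doc = _doc("T.", "Aspirin acts here. COX2 is elsewhere.")
        doc.mentions.extend(
            [
                _mention(doc, "C1", "CHEMICAL", "Aspirin"),
                _mention(doc, "G1", "GENE", "COX2"),
            ]
        )
        windows = split_sentences(doc)
        project_entities(doc, windows)
        assert all(enumerate_pairs(w) == [] for w in windows)

    def test_pair_count_law_on_corpus(self, small_bundle):
        for doc in small_bundle.docset:
            windows = split_sentences(doc)
            project_entities(doc, windows)
            for w in windows:
                assert len(enumerate_pairs(w)) == len(w.chemicals()) * len(w.genes())


class TestMarkEntities:
    @pytest.fixture
    def worked_example(self):
        doc = _doc("T.", "Alendronate was a slow-binding inhibitor of PTPmeg1.")
        chem = _mention(doc, "T1", "CHEMICAL", "Alendronate")
        gene = _mention(doc, "T2", "GENE", "PTPmeg1")
        doc.mentions.extend([chem, gene])
        windows = split_sentences(doc)
        project_entities(doc, windows)
        (pair,) = enumerate_pairs(windows[1])
        return windows[1], pair

    def test_method_none(self, worked_example):
        window, pair = worked_example
        seq = mark_entities(window, pair, MarkingMethod.NONE)
        assert seq.text == "Alendronate was a slow-binding inhibitor of PTPmeg1."

    def test_method_mask(self, worked_example):
        window, pair = worked_example
        seq = mark_entities(window, pair, MarkingMethod.MASK)
        assert seq.text == "CHEM was a slow-binding inhibitor of GENE."

    def test_method_wrap_type(self, worked_example):
        window, pair = worked_example
        seq = mark_entities(window, pair, MarkingMethod.WRAP_TYPE)
        assert seq.text == (
            "CHEM Alendronate CHEM was a slow-binding inhibitor of GENE PTPmeg1 GENE."
        )

    def test_method_wrap_type_se(self, worked_example):
        window, pair = worked_example
        seq = mark_entities(window, pair, MarkingMethod.WRAP_TYPE_SE)
        assert seq.text == (
            "CHEM-S Alendronate CHEM-E was a slow-binding inhibitor of "
            "GENE-S PTPmeg1 GENE-E."
        )

    def test_wrap_type_se_invertible_on_corpus(self, small_bundle):
        from kbrelex.preprocess import candidate_pairs

        for doc in list(small_bundle.docset)[:10]:
            windows = split_sentences(doc)
            project_entities(doc, windows)
            for w in windows:
                for pair in enumerate_pairs(w):
                    seq = mark_entities(w, pair, MarkingMethod.WRAP_TYPE_SE)
                    assert unmark(seq) == w.text

    def test_other_mentions_untouched(self):
        doc = _doc("T.", "Aspirin inhibited COX2 but not PTGS1 here.")
        chem = _mention(doc, "T1", "CHEMICAL", "Aspirin")
        g1 = _mention(doc, "T2", "GENE", "COX2")
        g2 = _mention(doc, "T3", "GENE", "PTGS1")
        doc.mentions.extend([chem, g1, g2])
        windows = split_sentences(doc)
        project_entities(doc, windows)
        pair = next(p for p in enumerate_pairs(windows[1]) if p.gene.mention_id == "T2")
        seq = mark_entities(windows[1], pair, MarkingMethod.WRAP_TYPE_SE)
        assert "PTGS1" in seq.text
        assert "GENE-S PTGS1" not in seq.text

    def test_identical_spans_chemical_markers_outside(self):
        doc = _doc("T.", "ABC1 does something.")
        chem = _mention(doc, "T1", "CHEMICAL", "ABC1")
        gene = _mention(doc, "T2", "GENE", "ABC1")
        doc.mentions.extend([chem, gene])
        windows = split_sentences(doc)
        project_entities(doc, windows)
        (pair,) = enumerate_pairs(windows[1])
        seq = mark_entities(windows[1], pair, MarkingMethod.WRAP_TYPE_SE)
        assert seq.text.startswith("CHEM-S GENE-S ABC1 GENE-E CHEM-E")

    def test_mention_outside_window_rejected(self):
        doc = _doc("T.", "Aspirin here. COX2 there.")
        chem = _mention(doc, "T1", "CHEMICAL", "Aspirin")
        gene = _mention(doc, "T2", "GENE", "COX2")
        doc.mentions.extend([chem, gene])
        windows = split_sentences(doc)
        project_entities(doc, windows)
        from kbrelex.preprocess import CandidatePair

        bogus = CandidatePair(pmid="1", sent_index=1, chem=chem, gene=gene)
        with pytest.raises(ValueError):
            mark_entities(windows[1], bogus, MarkingMethod.WRAP_TYPE_SE)

    def test_truncation_keeps_pair(self):
        long_tail = " filler" * 100
        doc = _doc("T.", f"Aspirin inhibited COX2{long_tail}.")
        chem = _mention(doc, "T1", "CHEMICAL", "Aspirin")
        gene = _mention(doc, "T2", "GENE", "COX2")
        doc.mentions.extend([chem, gene])
        windows = split_sentences(doc)
        project_entities(doc, windows)
        (pair,) = enumerate_pairs(windows[1])
        seq = mark_entities(
            windows[1], pair, MarkingMethod.WRAP_TYPE_SE, max_sequence_chars=80
        )
        assert len(seq.text) <= 80
        assert "Aspirin" in seq.text and "COX2" in seq.text


def test_label_candidates_matches_planted_truth(small_bundle):
    examples = training.build_examples(small_bundle.docset)
    truth = {
        (p.pmid, p.chem_mention_id, p.gene_mention_id): p.label
        for p in small_bundle.manifest
    }
    from kbrelex.formats_io import RelationLabel

    for pair, label in zip(examples.pairs, examples.labels):
        assert label == truth.get(pair.pair_key, RelationLabel.NONE)


class TestGazetteerTagger:
    def test_exact_match_with_boundaries(self):
        from kbrelex.preprocess import tag_with_gazetteer

        doc = _doc("T.", "Aspirin inhibited COX2 but Aspirinol did not.")
        gaz = {"Aspirin": ("CHEMICAL", "MESH:D001241"), "COX2": ("GENE", "NCBIGene:5743")}
        found = tag_with_gazetteer(doc, gaz)
        assert [(m.surface, m.etype) for m in found] == [
            ("Aspirin", "CHEMICAL"),
            ("COX2", "GENE"),
        ]
        for m in found:
            assert doc.full_text[m.start : m.end] == m.surface
            assert m.norm_id is not None

    def test_existing_spans_not_duplicated(self):
        from kbrelex.preprocess import tag_with_gazetteer

        doc = _doc("T.", "Aspirin here.")
        doc.mentions.append(_mention(doc, "T1", "CHEMICAL", "Aspirin"))
        found = tag_with_gazetteer(doc, {"Aspirin": ("CHEMICAL", "X")})
        assert found == []

    def test_longest_match_first(self):
        from kbrelex.preprocess import tag_with_gazetteer

        doc = _doc("T.", "COX2 inhibitor tested.")
        gaz = {"COX2": ("GENE", "g1"), "COX2 inhibitor": ("CHEMICAL", "c1")}
        found = tag_with_gazetteer(doc, gaz)
        assert [m.surface for m in found] == ["COX2 inhibitor"]
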