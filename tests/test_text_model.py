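"""Corpus model: readers, interchange stability, entity blinding."""

import pytest

from befree.text_model import (
    CANDIDATE1, CANDIDATE2, ENTITY_OTHER, CandidateInstance, PairLabel,
    attach_dependencies, blind_entities, read_conll_dependencies,
    read_euadr_corpus, read_jsonl_corpus, write_jsonl_corpus,
)
from conftest import build_sentence, make_pair


EUADR_HEADER = ("pmid,sentence_id,sentence,e1_start,e1_end,e1_type,e1_ids,"
                "e2_start,e2_end,e2_type,e2_ids,label,consensus\n")


def _euadr_csv(tmp_path, rows):
    path = tmp_path / "corpus.csv"
    path.write_text(EUADR_HEADER + "".join(rows))
    return path


class TestEuadrReader:
    def test_labelled_pairs_preserved(self, tmp_path):
        text1 = "BRCA1 is associated with breast cancer"
        text2 = "TP53 was not linked to asthma although EGFR was"
        path = _euadr_csv(tmp_path, [
            f'1,s1,{text1},0,5,GENE,672,25,38,DISEASE,C0006142,PA,1\n',
            f'2,s2,{text2},0,4,GENE,7157,23,29,DISEASE,C0004096,NA,1\n',
            f'2,s2,{text2},39,43,GENE,1956,23,29,DISEASE,C0004096,FA,1\n',
        ])
        result = read_euadr_corpus(path)
        assert len(result.sentences) == 2
        assert len(result.instances) == 3
        assert [i.label.fine for i in result.instances] == ["PA", "NA", "FA"]

    def test_fa_maps_to_binary_false(self, tmp_path):
        path = _euadr_csv(tmp_path, [
            '1,s1,GENE1 near disease1,0,5,GENE,1,11,19,DISEASE,C1,FA,1\n',
        ])
        inst = read_euadr_corpus(path).instances[0]
        assert inst.label.binary == "FALSE"

    def test_span_beyond_sentence_skipped_with_count(self, tmp_path):
        path = _euadr_csv(tmp_path, [
            '1,s1,short text,0,5,GENE,1,90,99,DISEASE,C1,PA,1\n',
        ])
        result = read_euadr_corpus(path)
        assert result.instances == []
        assert result.skipped_spans == 1

    def test_non_consensus_rows_dropped(self, tmp_path):
        path = _euadr_csv(tmp_path, [
            '1,s1,BRCA1 causes cancer,0,5,GENE,672,13,19,DISEASE,C1,PA,0\n',
        ])
        assert read_euadr_corpus(path).instances == []

    def test_malformed_row_raises_with_row_number(self, tmp_path):
        path = _euadr_csv(tmp_path, [
            '1,s1,text,notanint,5,GENE,1,6,9,DISEASE,C1,PA,1\n',
        ])
        with pytest.raises(ValueError, match="row 2"):
            read_euadr_corpus(path)


class TestJsonlInterchange:
    def test_round_trip_is_byte_stable(self, tmp_path, fig_sentence):
        pair = make_pair(fig_sentence, "g1", "d1", "PA")
        p1 = tmp_path / "a.jsonl"
        p2 = tmp_path / "b.jsonl"
        write_jsonl_corpus(p1, [fig_sentence], [pair])
        r = read_jsonl_corpus(p1)
        write_jsonl_corpus(p2, r.sentences, r.instances)
        assert p1.read_bytes() == p2.read_bytes()
        assert r.instances[0].label == PairLabel(binary="TRUE", fine="PA")

    def test_counts_partition_by_binary_label(self, tmp_path, fig_sentence):
        pairs = [make_pair(fig_sentence, "g1", "d1", "PA"),
                 make_pair(fig_sentence, "g2", "d1", "FA")]
        path = tmp_path / "c.jsonl"
        write_jsonl_corpus(path, [fig_sentence], pairs)
        insts = read_jsonl_corpus(path).instances
        n_true = sum(1 for i in insts if i.label.binary == "TRUE")
        n_false = sum(1 for i in insts if i.label.binary == "FALSE")
        assert n_true + n_false == len(insts) == 2


CONLLU = """\
# sent_id = 1
1\tEHD3\tEHD3\tNOUN\tNN\t_\t3\tnsubjpass\t_\t_
2\tis\tbe\tAUX\tVBZ\t_\t3\tauxpass\t_\t_
3\tassociated\tassociate\tVERB\tVBN\t_\t0\troot\t_\t_
4\twith\twith\tADP\tIN\t_\t3\tprep\t_\t_
5\tMDD\tMDD\tNOUN\tNN\t_\t4\tpobj\t_\t_
"""

# same parse in the older 10-column dialect (PHEAD/PDEPREL instead of DEPS/MISC)
CONLLX = """\
1\tEHD3\tEHD3\tNN\tNN\t_\t3\tnsubjpass\t_\t_
2\tis\tbe\tVBZ\tVBZ\t_\t3\tauxpass\t_\t_
3\tassociated\tassociate\tVBN\tVBN\t_\t0\troot\t_\t_
4\twith\twith\tIN\tIN\t_\t3\tprep\t_\t_
5\tMDD\tMDD\tNN\tNN\t_\t4\tpobj\t_\t_
"""


class TestConllReader:
    def test_well_formed_tree(self, tmp_path):
        path = tmp_path / "p.conllu"
        path.write_text(CONLLU)
        (graph,) = read_conll_dependencies(path)
        assert len(graph.edges) == 4
        assert graph.root == 2
        assert graph.is_connected()

    def test_dialects_give_identical_graphs(self, tmp_path):
        pu, px = tmp_path / "p.conllu", tmp_path / "p.conll"
        pu.write_text(CONLLU)
        px.write_text(CONLLX)
        (gu,) = read_conll_dependencies(pu)
        (gx,) = read_conll_dependencies(px)
        assert gu == gx

    def test_token_count_mismatch_is_alignment_error(self, tmp_path):
        path = tmp_path / "p.conllu"
        path.write_text(CONLLU)
        sent = build_sentence(["only", "four", "tokens", "here"])
        with pytest.raises(ValueError, match="alignment error.*s1"):
            attach_dependencies([sent], read_conll_dependencies(path))


class TestBlindEntities:
    def test_single_token_mentions(self):
        sent = build_sentence(
            ["EHD3", "is", "associated", "with", "MDD"],
            mentions=[("g", "GENE", 0, 0, {"30845"}),
                      ("d", "DISEASE", 4, 4, {"C1269683"})],
        )
        tokens, p1, p2 = blind_entities(make_pair(sent, "g", "d"))
        assert [t.surface for t in tokens] == \
            [CANDIDATE1, "is", "associated", "with", CANDIDATE2]
        assert (p1, p2) == (0, 4)

    def test_multi_token_mention_collapses(self):
        sent = build_sentence(
            ["EHD3", "causes", "major", "depressive", "disorder"],
            mentions=[("g", "GENE", 0, 0, {"30845"}),
                      ("d", "DISEASE", 2, 4, {"C1269683"})],
        )
        tokens, _, p2 = blind_entities(make_pair(sent, "g", "d"))
        assert [t.surface for t in tokens] == [CANDIDATE1, "causes", CANDIDATE2]
        assert tokens[p2].pos == "NN"
        assert tokens[p2].lemma == CANDIDATE2

    def test_non_candidate_same_type_mention_becomes_other(self, fig_sentence):
        tokens, _, _ = blind_entities(make_pair(fig_sentence, "g1", "d1"))
        assert [t.surface for t in tokens] == \
            [CANDIDATE1, "and", ENTITY_OTHER, "are", "associated", "with", CANDIDATE2]

    def test_overlapping_candidate_pair_rejected(self):
        sent = build_sentence(
            ["major", "depressive", "disorder"],
            mentions=[("a", "DISEASE", 0, 2, {"C1"}),
                      ("b", "DISEASE", 1, 1, {"C2"})],
        )
        with pytest.raises(ValueError, match="overlap"):
            make_pair(sent, "a", "b")
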