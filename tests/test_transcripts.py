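"""Transcript reading, question-answer pairing, merging and normalisation."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from milintv import (
    Bag,
    CanonicalRule,
    DIAGNOSIS_NO_SENTENCE,
    DIAGNOSIS_YES_SENTENCE,
    Instance,
    Speaker,
    build_bag,
    build_qa_pairs,
    canonicalize_key_answers,
    merge_answers,
    rank_instances,
    read_bags_jsonl,
    read_transcript,
    strip_interviewer_text,
    write_bags_jsonl,
)
from milintv.errors import (
    EmptyBagError,
    EmptyInputError,
    RowParseError,
    TranscriptFormatError,
)
from milintv.transcripts import QAPair, word_count


def _utt(start, speaker, text):
    from milintv import Utterance
    return Utterance(start, start + 1.0, speaker, text)


class TestReadTranscript:
    def test_reads_three_rows_in_time_order(self, toy_transcript_tsv):
        utts = read_transcript(io.StringIO(toy_transcript_tsv))
        assert [u.speaker for u in utts] == [
            Speaker.PARTICIPANT, Speaker.INTERVIEWER, Speaker.PARTICIPANT
        ]
        assert [u.text for u in utts] == [
            "hello there", "how are you doing today", "pretty good thanks"
        ]

    def test_out_of_order_rows_are_sorted_by_start_time(self):
        tsv = (
            "start_time\tstop_time\tspeaker\tvalue\n"
            "4.0\t5.0\tParticipant\tsecond\n"
            "0.0\t1.0\tParticipant\tfirst\n"
        )
        utts = read_transcript(io.StringIO(tsv))
        assert [u.text for u in utts] == ["first", "second"]

    def test_session_without_interviewer_rows_is_all_participant(self):
        tsv = (
            "start_time\tstop_time\tspeaker\tvalue\n"
            "0.0\t1.0\tParticipant\tone\n"
            "2.0\t3.0\tParticipant\ttwo\n"
        )
        utts = read_transcript(io.StringIO(tsv))
        assert all(u.speaker is Speaker.PARTICIPANT for u in utts)

    def test_missing_column_names_the_column(self):
        tsv = "start_time\tspeaker\tvalue\n0.0\tEllie\thi\n"
        with pytest.raises(TranscriptFormatError, match="stop_time"):
            read_transcript(io.StringIO(tsv))

    def test_bad_timestamp_reports_line_number(self):
        tsv = (
            "start_time\tstop_time\tspeaker\tvalue\n"
            "0.0\t1.0\tEllie\tok row\n"
            "oops\t3.0\tParticipant\tbad row\n"
        )
        with pytest.raises(RowParseError, match="line 3"):
            read_transcript(io.StringIO(tsv))

    def test_lenient_mode_drops_malformed_rows(self):
        tsv = (
            "start_time\tstop_time\tspeaker\tvalue\n"
            "oops\t3.0\tParticipant\tbad row\n"
            "0.0\t1.0\tParticipant\tgood row\n"
        )
        utts = read_transcript(io.StringIO(tsv), lenient=True)
        assert [u.text for u in utts] == ["good row"]

    def test_e_daic_csv_without_speaker_column_is_participant_only(self):
        csv_text = "start_time,stop_time,value\n0.0,1.0,answer text\n"
        utts = read_transcript(io.StringIO(csv_text), dialect="e_daic")
        assert utts[0].speaker is Speaker.PARTICIPANT

    def test_interviewer_tag_is_case_insensitive_and_overridable(self):
        csv_text = "start_time,stop_time,speaker,value\n0.0,1.0,WIZARD,hello\n"
        utts = read_transcript(
            io.StringIO(csv_text), dialect="e_daic", interviewer_tag="wizard"
        )
        assert utts[0].speaker is Speaker.INTERVIEWER


class TestBuildQaPairs:
    def test_groups_answer_runs_under_preceding_question(self):
        utts = [
            _utt(0, Speaker.INTERVIEWER, "q1"),
            _utt(1, Speaker.PARTICIPANT, "a"),
            _utt(2, Speaker.PARTICIPANT, "b"),
            _utt(3, Speaker.INTERVIEWER, "q2"),
            _utt(4, Speaker.PARTICIPANT, "c"),
        ]
        pairs = build_qa_pairs(utts)
        assert [(p.question, len(p.answers)) for p in pairs] == [("q1", 2), ("q2", 1)]
        assert [p.order_index for p in pairs] == [0, 1]

    def test_questionless_session_yields_one_pair_per_turn(self):
        utts = [_utt(i, Speaker.PARTICIPANT, f"t{i}") for i in range(3)]
        pairs = build_qa_pairs(utts)
        assert len(pairs) == 3
        assert all(p.question is None and len(p.answers) == 1 for p in pairs)

    def test_unanswered_question_produces_no_pair(self):
        assert build_qa_pairs([_utt(0, Speaker.INTERVIEWER, "q1")]) == []

    def test_empty_input_is_an_error(self):
        with pytest.raises(EmptyInputError):
            build_qa_pairs([])


class TestMergeAndRank:
    def test_merge_joins_answers_and_counts_words(self):
        inst = merge_answers(QAPair("q", ["i'm fine", "mostly"], 0))
        assert inst.text == "i'm fine mostly"
        assert inst.word_count == 3

    def test_single_answer_is_unchanged(self):
        assert merge_answers(QAPair("q", ["just this"], 0)).text == "just this"

    def test_internal_double_spaces_count_nonempty_tokens_only(self):
        inst = merge_answers(QAPair("q", ["a  b", "c"], 0))
        assert inst.word_count == 3

    @given(st.lists(st.lists(st.text(
        alphabet="abc", min_size=1, max_size=4), min_size=1, max_size=4
    ).map(lambda toks: " ".join(toks)), min_size=1, max_size=5))
    def test_merge_conserves_total_words(self, answers):
        merged = merge_answers(QAPair("q", answers, 0))
        assert merged.word_count == sum(word_count(a) for a in answers)

    def test_rank_sorts_most_to_least(self):
        instances = [
            Instance("a b c", 3), Instance("a b c d e f g", 7),
            Instance("a b c d e", 5),
        ]
        assert [i.word_count for i in rank_instances(instances)] == [7, 5, 3]

    def test_rank_is_stable_on_ties_and_a_permutation(self):
        instances = [Instance(f"w{i} x", 2, instance_id=i) for i in range(4)]
        ranked = rank_instances(instances)
        assert [i.instance_id for i in ranked] == [0, 1, 2, 3]
        assert rank_instances([]) == []

    @given(st.lists(st.integers(0, 20), max_size=10))
    def test_rank_output_word_counts_nonincreasing(self, counts):
        instances = [Instance("w " * c, c) for c in counts]
        ranked = rank_instances(instances)
        out = [i.word_count for i in ranked]
        assert sorted(out, reverse=True) == out
        assert sorted(out) == sorted(counts)


class TestCanonicalize:
    QUESTION = "have you ever been diagnosed with depression"

    @pytest.mark.parametrize(
        "answer,expected",
        [
            ("no", DIAGNOSIS_NO_SENTENCE),
            ("nope never", DIAGNOSIS_NO_SENTENCE),
            ("i haven't", DIAGNOSIS_NO_SENTENCE),
            ("yes", DIAGNOSIS_YES_SENTENCE),
            ("yeah a few years ago", DIAGNOSIS_YES_SENTENCE),
            ("i have", DIAGNOSIS_YES_SENTENCE),
        ],
    )
    def test_key_answers_become_the_canonical_sentence(self, answer, expected):
        inst = Instance(answer, word_count(answer), source_question=self.QUESTION)
        (out,) = canonicalize_key_answers([inst])
        assert out.text == expected
        assert out.word_count == word_count(expected)

    def test_unmatched_question_is_unchanged(self):
        inst = Instance("no", 1, source_question="what did you eat")
        (out,) = canonicalize_key_answers([inst])
        assert out.text == "no"

    def test_undetectable_answer_left_unchanged_with_warning(self, caplog):
        inst = Instance("well it's complicated", 3, source_question=self.QUESTION)
        with caplog.at_level("WARNING"):
            (out,) = canonicalize_key_answers([inst])
        assert out.text == "well it's complicated"
        assert any("neither yes nor no" in r.message for r in caplog.records)

    def test_matched_outputs_are_exactly_the_two_sentences(self):
        instances = [
            Instance(ans, word_count(ans), source_question=self.QUESTION)
            for ans in ("yes", "no", "yep", "never")
        ]
        outs = canonicalize_key_answers(instances)
        assert {o.text for o in outs} == {
            DIAGNOSIS_YES_SENTENCE, DIAGNOSIS_NO_SENTENCE
        }


class TestStripInterviewerText:
    BANK = {"how would your best friend describe you"}

    def test_embedded_question_is_removed(self):
        inst = Instance(
            "how would your best friend describe you kind i guess", 9
        )
        out = strip_interviewer_text(inst, self.BANK)
        assert out.text == "kind i guess"
        assert out.word_count == 3

    def test_no_match_is_identity(self):
        inst = Instance("kind i guess", 3)
        assert strip_interviewer_text(inst, self.BANK) is inst

    def test_total_removal_flags_empty(self):
        inst = Instance("How would your best friend describe you?", 8)
        out = strip_interviewer_text(inst, self.BANK)
        assert out.flagged_empty and out.text == ""


class TestBags:
    def test_build_bag_assigns_ids_and_counts(self):
        bag = build_bag("p1", [Instance("a", 1), Instance("b", 1)], label=1)
        assert bag.n == 2 and bag.label == 1
        assert [i.instance_id for i in bag.instances] == [1, 2]

    def test_empty_bag_is_an_error(self):
        with pytest.raises(EmptyBagError):
            build_bag("p1", [])

    def test_unlabeled_single_instance_bag(self):
        bag = build_bag("p2", [Instance("a", 1)])
        assert bag.n == 1 and bag.label is None

    def test_jsonl_round_trip(self, tmp_path):
        bags = [
            build_bag("p1", [Instance("hello world", 2, source_question="q")],
                      label=0),
            build_bag("p2", [Instance("a", 1), Instance("b c", 2)], label=None),
        ]
        path = tmp_path / "bags.jsonl"
        write_bags_jsonl(bags, path)
        back = read_bags_jsonl(path)
        assert [b.participant_id for b in back] == ["p1", "p2"]
        assert back[0].instances[0].text == "hello world"
        assert back[0].label == 0 and back[1].label is None


def test_pipeline_is_deterministic(session_transcript_tsv):
    """Byte-identical transcript input yields identical bags."""
    from milintv import transcript_to_bag

    bag1 = transcript_to_bag(io.StringIO(session_transcript_tsv), "p")
    bag2 = transcript_to_bag(io.StringIO(session_transcript_tsv), "p")
    assert bag1 == bag2
    assert [i.text for i in bag1.instances] == ["i'm fine mostly", "not great lately"]
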