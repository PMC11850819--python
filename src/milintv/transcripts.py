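"""Transcript reading and bag construction.

Clinical screening interviews (DAIC-WOZ style) arrive as timestamped dialogue
tables: one row per utterance with start/stop time, a speaker tag (the virtual
interviewer is conventionally "Ellie") and the spoken text.  This module turns
such a table into a *bag* of *instances* for multiple-instance learning:

1. :func:`read_transcript` parses the table into time-ordered utterances;
2. :func:`build_qa_pairs` segments them into question-answer groups;
3. :func:`merge_answers` joins a participant's consecutive answers to one
   question into a single comprehensive response (one MIL instance);
4. :func:`rank_instances`, :func:`canonicalize_key_answers` and
   :func:`strip_interviewer_text` apply the optional normalisation steps;
5. :func:`build_bag` assembles the participant's bag.

Sessions in which no interviewer rows exist at all (a known corpus quirk) are
handled by emitting one instance per participant turn, without merging.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
import string
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import (
    EmptyBagError,
    EmptyInputError,
    RowParseError,
    TranscriptFormatError,
)

logger = logging.getLogger(__name__)

#: Canonical replacement sentence for an affirmative answer to the
#: prior-diagnosis question.
DIAGNOSIS_YES_SENTENCE = "I was unfortunate enough to be diagnosed with depression."
#: Canonical replacement sentence for a negative answer to the same question.
DIAGNOSIS_NO_SENTENCE = (
    "I am healthy and have never tested positive for mental illness"
    " such as depression."
)

DEFAULT_YES_PHRASES = ("yes", "yeah", "yep", "i have")
DEFAULT_NO_PHRASES = ("no", "nope", "never", "i haven't")

DEFAULT_INTERVIEWER_TAG = "Ellie"

_REQUIRED_COLUMNS = ("start_time", "stop_time", "speaker", "value")
_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


class Speaker(str, Enum):
    INTERVIEWER = "interviewer"
    PARTICIPANT = "participant"


@dataclass(frozen=True)
class Utterance:
    """One timestamped dialogue turn."""

    start_time: float
    stop_time: float
    speaker: Speaker
    text: str


@dataclass
class QAPair:
    """One interviewer question with the participant's consecutive answers.

    ``question`` is ``None`` for participant turns with no preceding
    interviewer utterance (questionless sessions).
    """

    question: str | None
    answers: list[str]
    order_index: int


@dataclass
class Instance:
    """One merged participant response — the MIL instance."""

    text: str
    word_count: int
    source_question: str | None = None
    instance_id: int = 0
    flagged_empty: bool = False


@dataclass
class Bag:
    """One participant's ordered instances plus an optional binary label."""

    participant_id: str
    instances: list[Instance]
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1 or None, got {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class CanonicalRule:
    """Rewrite rule for a key screening question.

    ``question_pattern`` is a regex searched in the lowercased source
    question; the answer's leading tokens are matched against the yes/no
    phrase lists and the instance text is replaced by the corresponding
    canonical sentence.
    """

    question_pattern: str
    positive_sentence: str = DIAGNOSIS_YES_SENTENCE
    negative_sentence: str = DIAGNOSIS_NO_SENTENCE
    yes_phrases: tuple[str, ...] = DEFAULT_YES_PHRASES
    no_phrases: tuple[str, ...] = DEFAULT_NO_PHRASES


#: The prior-diagnosis question rewrite applied by default.
DEFAULT_CANONICAL_RULES = (CanonicalRule(r"diagnosed with depression"),)


def word_count(text: str) -> int:
    """Whitespace-token count (empty tokens never counted)."""
    return len(text.split())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_DIALECT_SEPARATORS = {"daic_woz": "\t", "e_daic": ",", "generic": None}


def _open_source(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    if isinstance(source, (bytes, bytearray)):
        return io.StringIO(source.decode("utf-8")), False
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        return io.StringIO(data), False
    raise TypeError(f"unsupported transcript source: {type(source)!r}")


def read_transcript(
    source,
    dialect: str = "daic_woz",
    interviewer_tag: str = DEFAULT_INTERVIEWER_TAG,
    lenient: bool = False,
) -> list[Utterance]:
    """Parse a delimited transcript table into time-sorted utterances.

    Parameters
    ----------
    source
        Path, file-like object, or raw bytes/str stream of the table.
    dialect
        ``daic_woz`` (tab-separated), ``e_daic`` (comma-separated, a missing
        speaker column is allowed and implies participant-only rows), or
        ``generic`` (delimiter sniffed).
    interviewer_tag
        Speaker value marking interviewer rows; matching is case-insensitive.
    lenient
        If true, malformed rows are logged and skipped instead of raising.

    Rows are returned sorted by ``start_time`` (stable: ties keep input
    order).  Blank-text rows are dropped and counted.
    """
    if dialect not in _DIALECT_SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}")
    handle, should_close = _open_source(source)
    try:
        sep = _DIALECT_SEPARATORS[dialect]
        if sep is None:
            sample = handle.read(4096)
            handle.seek(0)
            try:
                sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
            except csv.Error:
                sep = "\t" if "\t" in sample else ","
        reader = csv.reader(handle, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise TranscriptFormatError("transcript is empty (no header row)")
        columns = {name.strip().lower(): i for i, name in enumerate(header)}
        missing = [
            c
            for c in _REQUIRED_COLUMNS
            if c not in columns and not (c == "speaker" and dialect == "e_daic")
        ]
        if missing:
            raise TranscriptFormatError(
                f"missing required column(s): {', '.join(missing)}"
            )
        speaker_idx = columns.get("speaker")
        tag = interviewer_tag.strip().lower()

        utterances: list[Utterance] = []
        n_malformed = 0
        n_blank = 0
        for line_number, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                n_blank += 1
                continue
            try:
                start = float(row[columns["start_time"]])
                stop = float(row[columns["stop_time"]])
            except (ValueError, IndexError) as exc:
                if lenient:
                    n_malformed += 1
                    logger.warning("dropping malformed row at line %d: %s",
                                   line_number, exc)
                    continue
                raise RowParseError(f"non-numeric timestamp ({exc})", line_number)
            text = row[columns["value"]].strip() if len(row) > columns["value"] else ""
            if not text:
                n_blank += 1
                continue
            if speaker_idx is not None and len(row) > speaker_idx:
                speaker_value = row[speaker_idx].strip().lower()
                speaker = (
                    Speaker.INTERVIEWER if speaker_value == tag else Speaker.PARTICIPANT
                )
            else:
                speaker = Speaker.PARTICIPANT
            utterances.append(Utterance(start, stop, speaker, text))
        if n_malformed or n_blank:
            logger.info(
                "read_transcript: %d malformed row(s) dropped, %d blank row(s) dropped",
                n_malformed, n_blank,
            )
        utterances.sort(key=lambda u: u.start_time)  # timsort is stable
        return utterances
    finally:
        if should_close:
            handle.close()


# ---------------------------------------------------------------------------
# segmentation and merging
# ---------------------------------------------------------------------------


def build_qa_pairs(utterances: Sequence[Utterance]) -> list[QAPair]:
    """Group time-ordered utterances into question-answer pairs.

    Each maximal run of consecutive participant utterances following an
    interviewer utterance becomes one :class:`QAPair` whose question is that
    interviewer utterance's text.  Participant turns with no preceding
    interviewer turn each form their own pair with ``question=None`` — the
    handling used for corpus sessions that lack interviewer rows entirely.
    Questions never answered produce no pair.
    """
    if not utterances:
        raise EmptyInputError("no utterances to segment")
    pairs: list[QAPair] = []
    current_question: str | None = None
    current_answers: list[str] = []
    order = 0

    def flush() -> None:
        nonlocal current_answers, order
        if current_answers:
            pairs.append(QAPair(current_question, current_answers, order))
            order += 1
            current_answers = []

    for utt in utterances:
        if utt.speaker is Speaker.INTERVIEWER:
            flush()
            current_question = utt.text
        else:
            if current_question is None:
                # questionless turn: one pair per turn, never merged
                pairs.append(QAPair(None, [utt.text], order))
                order += 1
            else:
                current_answers.append(utt.text)
    flush()
    return pairs


def merge_answers(pair: QAPair, joiner: str = " ") -> Instance:
    """Join a pair's answers (original order) into one instance."""
    if not pair.answers:
        raise EmptyInputError("QAPair has no answers")
    text = joiner.join(pair.answers)
    return Instance(
        text=text,
        word_count=word_count(text),
        source_question=pair.question,
        instance_id=pair.order_index,
    )


def rank_instances(instances: Sequence[Instance]) -> list[Instance]:
    """Stable sort by word count, most to least (ties keep session order)."""
    return sorted(instances, key=lambda inst: -inst.word_count)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def _match_leading(tokens: list[str], phrases: Iterable[str]) -> int:
    """Longest phrase (token length) matching the leading tokens, else 0."""
    best = 0
    for phrase in phrases:
        ptoks = phrase.lower().split()
        if len(ptoks) > best and tokens[: len(ptoks)] == ptoks:
            best = len(ptoks)
    return best


def canonicalize_key_answers(
    instances: Sequence[Instance],
    rules: Sequence[CanonicalRule] = DEFAULT_CANONICAL_RULES,
) -> list[Instance]:
    """Replace answers to key screening questions by canonical sentences.

    Short yes/no answers to pivotal questions (e.g. a prior depression
    diagnosis) carry more signal than their word count suggests; they are
    rewritten into full canonical sentences so downstream ranking and scoring
    see them.  An answer matching neither the yes nor the no phrase list is
    left unchanged with a logged warning.
    """
    out: list[Instance] = []
    for inst in instances:
        rewritten = inst
        if inst.source_question is not None:
            q = inst.source_question.lower()
            for rule in rules:
                if re.search(rule.question_pattern, q):
                    tokens = inst.text.lower().split()
                    yes_len = _match_leading(tokens, rule.yes_phrases)
                    no_len = _match_leading(tokens, rule.no_phrases)
                    if yes_len == no_len == 0:
                        logger.warning(
                            "canonicalize: answer %r to key question %r matches "
                            "neither yes nor no; left unchanged",
                            inst.text, inst.source_question,
                        )
                        break
                    sentence = (
                        rule.positive_sentence
                        if yes_len > no_len
                        else rule.negative_sentence
                    )
                    rewritten = replace(
                        inst, text=sentence, word_count=word_count(sentence)
                    )
                    break
        out.append(rewritten)
    return out


def normalize_for_matching(text: str) -> str:
    """Lowercase, strip ASCII punctuation, collapse whitespace."""
    return " ".join(text.lower().translate(_PUNCT_TABLE).split())


def strip_interviewer_text(
    instance: Instance, question_bank: Iterable[str]
) -> Instance:
    """Remove known interviewer questions embedded inside an instance text.

    Matching is done on normalised tokens (lowercase, punctuation stripped);
    the matched token span is removed from the original token sequence and
    the remainder re-joined with single spaces.  If removal leaves no text,
    the instance is returned flagged empty for the caller to drop.
    """
    bank = [normalize_for_matching(q).split() for q in question_bank]
    bank = [b for b in bank if b]
    if not bank:
        return instance
    tokens = instance.text.split()
    norm = [normalize_for_matching(t) for t in tokens]

    changed = False
    i = 0
    kept: list[str] = []
    while i < len(tokens):
        span = 0
        for btoks in bank:
            m = len(btoks)
            if norm[i : i + m] == btoks:
                span = max(span, m)
        if span:
            i += span
            changed = True
        else:
            kept.append(tokens[i])
            i += 1
    if not changed:
        return instance
    text = " ".join(kept)
    return replace(
        instance,
        text=text,
        word_count=word_count(text),
        flagged_empty=not text,
    )


# ---------------------------------------------------------------------------
# bag assembly and I/O
# ---------------------------------------------------------------------------


def build_bag(
    participant_id: str,
    instances: Sequence[Instance],
    label: int | None = None,
) -> Bag:
    """Assemble a bag; instance ids are (re)assigned 1..n in the given order."""
    if not instances:
        raise EmptyBagError(
            f"participant {participant_id!r} has no instances; the decision "
            "rule is undefined on empty bags"
        )
    numbered = [
        replace(inst, instance_id=i) for i, inst in enumerate(instances, start=1)
    ]
    return Bag(participant_id=participant_id, instances=numbered, label=label)


def transcript_to_bag(
    source,
    participant_id: str,
    dialect: str = "daic_woz",
    label: int | None = None,
    interviewer_tag: str = DEFAULT_INTERVIEWER_TAG,
    lenient: bool = False,
    rules: Sequence[CanonicalRule] = DEFAULT_CANONICAL_RULES,
    question_bank: Iterable[str] | None = None,
    rank: bool = True,
    drop_empty: bool = True,
) -> Bag:
    """Full preprocessing pipeline: read -> pair -> merge -> normalise -> bag."""
    utterances = read_transcript(
        source, dialect=dialect, interviewer_tag=interviewer_tag, lenient=lenient
    )
    pairs = build_qa_pairs(utterances)
    instances = [merge_answers(p) for p in pairs]
    if question_bank is not None:
        instances = [strip_interviewer_text(i, question_bank) for i in instances]
        if drop_empty:
            instances = [i for i in instances if not i.flagged_empty]
    instances = canonicalize_key_answers(instances, rules)
    if rank:
        instances = rank_instances(instances)
    return build_bag(participant_id, instances, label=label)


def bag_to_dict(bag: Bag) -> dict:
    return {
        "participant_id": bag.participant_id,
        "label": bag.label,
        "instances": [
            {
                "id": inst.instance_id,
                "question": inst.source_question,
                "text": inst.text,
                "word_count": inst.word_count,
            }
            for inst in bag.instances
        ],
    }


def bag_from_dict(record: dict) -> Bag:
    instances = [
        Instance(
            text=item["text"],
            word_count=item.get("word_count", word_count(item["text"])),
            source_question=item.get("question"),
            instance_id=item["id"],
        )
        for item in record["instances"]
    ]
    label = record.get("label")
    return Bag(record["participant_id"], instances, None if label is None else int(label))


def write_bags_jsonl(bags: Iterable[Bag], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for bag in bags:
            fh.write(json.dumps(bag_to_dict(bag)) + "\n")


def read_bags_jsonl(path) -> list[Bag]:
    bags = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                bags.append(bag_from_dict(json.loads(line)))
    return bags
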