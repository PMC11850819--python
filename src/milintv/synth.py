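"""Synthetic interview and score-vector generators.

The clinical corpora this pipeline targets are access-restricted, so every
other module is exercised on synthetic data that reproduces the *statistical
structure* the MIL analysis assumes:

* minority-positive class balance (default prevalence 14/47, the depressed /
  non-depressed split of the reference test set);
* within a depressed participant's bag, only a fraction of instances are
  truly depressive;
* a non-depressed bag occasionally contains one high-scoring "spurious
  depressive" instance — a participant who sounds depressed on a single
  answer without being depressed;
* instance confidence scores drawn from a low and a high Beta distribution
  whose contrast mirrors the observed score heatmaps: essentially no
  non-depressed instance scores above 0.9, while depressed bags contain many
  high-scoring instances.

:func:`generate_score_bags` emits scored bags directly (for decision-rule
and sweep studies); :func:`generate_text_bags` emits lexicon-planted texts
plus raw transcript tables, so the full read -> pair -> merge path is
exercised end to end.  Same seed, byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .scoring import InstanceScore, ScoredBag
from .transcripts import Bag, Instance, build_bag, word_count

DEFAULT_DEPRESSIVE_LEXICON = (
    "sad", "tired", "hopeless", "empty", "worthless", "crying",
    "insomnia", "numb", "lonely", "despair", "guilty", "exhausted",
)
DEFAULT_NEUTRAL_LEXICON = (
    "today", "work", "music", "friend", "coffee", "weather", "walk",
    "movie", "dinner", "weekend", "book", "game", "family", "travel",
    "morning", "school", "garden", "traffic", "shopping", "sport",
)

QUESTION_TEMPLATES = (
    "how are you doing today",
    "tell me about your last trip",
    "how would your best friend describe you",
    "what do you do to relax",
    "how have you been sleeping",
    "what are you most proud of",
    "when was the last time you argued with someone",
    "how easy is it for you to get a good night sleep",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generators.

    Score distributions are Beta(a, b) parameter pairs for truly depressive
    ("high") and non-depressive ("low") instances.  Text generation plants
    depressive-lexicon tokens at ``depressive_token_rate`` inside truly
    depressive instances and leaks them at ``background_token_rate``
    elsewhere.
    """

    n_participants: int = 47
    prevalence: float = 14 / 47
    instances_per_bag: tuple[int, int] = (20, 50)
    depressive_fraction_pos: float = 0.6
    spurious_rate_neg: float = 0.15
    low_score: tuple[float, float] = (2.0, 8.0)
    high_score: tuple[float, float] = (12.0, 2.0)
    depressive_lexicon: tuple[str, ...] = DEFAULT_DEPRESSIVE_LEXICON
    neutral_lexicon: tuple[str, ...] = DEFAULT_NEUTRAL_LEXICON
    depressive_token_rate: float = 0.35
    background_token_rate: float = 0.02
    words_per_instance: tuple[int, int] = (5, 30)
    answers_per_question: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0,1), got {self.prevalence}")
        for name in ("depressive_fraction_pos", "spurious_rate_neg",
                     "depressive_token_rate", "background_token_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("low_score", "high_score"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ParameterError(f"{name} Beta parameters must be positive")
        lo, hi = self.instances_per_bag
        if lo < 1 or hi < lo:
            raise ConfigError(
                f"invalid instances_per_bag range {self.instances_per_bag}"
            )


def planted_boundary_config(
    n_participants: int = 300, seed: int = 0
) -> SynthConfig:
    """Conditions for the hyperparameter-recovery study.

    Truly depressive instances score just above 0.9 (Beta(60, 4): about 89%
    of its mass lies above 0.9 — the planted high-score boundary), while
    non-depressive scores (Beta(5, 6)) straddle the 0.5 cutoff, so the
    depressive-count criterion is noisy and the count tolerance must be
    raised while the majority criterion separates the classes only for
    high-confidence thresholds up to about 0.9.  Bags are kept compact
    (8-16 instances) so both criteria stay live within the default sweep
    grids.
    """
    return SynthConfig(
        n_participants=n_participants,
        instances_per_bag=(8, 16),
        depressive_fraction_pos=0.75,
        spurious_rate_neg=0.15,
        low_score=(5.0, 6.0),
        high_score=(60.0, 4.0),
        seed=seed,
    )


@dataclass
class ScoreBagSample:
    """Scored bags with per-instance ground truth (True = truly depressive)."""

    scored_bags: list[ScoredBag]
    instance_truth: dict[str, list[bool]]

    @property
    def bags(self) -> list[Bag]:
        return [sb.bag for sb in self.scored_bags]


@dataclass
class TextBagSample:
    """Text bags, raw transcript tables and per-instance ground truth."""

    bags: list[Bag]
    transcripts: dict[str, pd.DataFrame]
    instance_truth: dict[str, list[bool]]
    question_bank: list[str]


def _draw_structure(
    rng: np.random.Generator, config: SynthConfig
) -> list[tuple[str, int, int, np.ndarray]]:
    """Common bag skeleton: (participant_id, label, n, depressive flags)."""
    lo, hi = config.instances_per_bag
    out = []
    for k in range(config.n_participants):
        label = int(rng.random() < config.prevalence)
        n = int(rng.integers(lo, hi + 1))
        flags = np.zeros(n, dtype=bool)
        if label == 1:
            n_dep = math.ceil(config.depressive_fraction_pos * n)
            flags[rng.choice(n, size=min(n_dep, n), replace=False)] = True
        elif rng.random() < config.spurious_rate_neg:
            flags[rng.integers(0, n)] = True  # the lone spurious instance
        out.append((f"P{k + 300:03d}", label, n, flags))
    return out


def generate_score_bags(config: SynthConfig = SynthConfig()) -> ScoreBagSample:
    """Draw labeled bags of instance confidence scores.

    Positive bags draw ``ceil(depressive_fraction_pos * n)`` scores from the
    high Beta and the rest from the low Beta; negative bags draw from the
    low Beta, plus — with probability ``spurious_rate_neg`` — one high-Beta
    instance.  Reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    a_lo, b_lo = config.low_score
    a_hi, b_hi = config.high_score
    scored_bags: list[ScoredBag] = []
    truth: dict[str, list[bool]] = {}
    for pid, label, n, flags in _draw_structure(rng, config):
        scores = np.where(
            flags, rng.beta(a_hi, b_hi, size=n), rng.beta(a_lo, b_lo, size=n)
        )
        instances = [
            Instance(text=f"instance {i + 1}", word_count=2) for i in range(n)
        ]
        bag = build_bag(pid, instances, label=label)
        scored_bags.append(
            ScoredBag(
                bag=bag,
                scores=[
                    InstanceScore(i + 1, float(scores[i])) for i in range(n)
                ],
            )
        )
        truth[pid] = flags.tolist()
    return ScoreBagSample(scored_bags=scored_bags, instance_truth=truth)


def _instance_tokens(
    rng: np.random.Generator, config: SynthConfig, depressive: bool
) -> list[str]:
    lo, hi = config.words_per_instance
    length = int(rng.integers(lo, hi + 1))
    rate = (
        config.depressive_token_rate if depressive else config.background_token_rate
    )
    dep = np.asarray(config.depressive_lexicon)
    neu = np.asarray(config.neutral_lexicon)
    from_dep = rng.random(length) < rate
    tokens = np.where(
        from_dep,
        dep[rng.integers(0, len(dep), size=length)],
        neu[rng.integers(0, len(neu), size=length)],
    )
    return [str(t) for t in tokens]


def generate_text_bags(config: SynthConfig = SynthConfig()) -> TextBagSample:
    """Draw labeled text bags plus the raw transcript tables behind them.

    Each instance becomes one interviewer question row followed by 1-3
    participant answer rows (the instance's tokens split into contiguous
    chunks), with strictly increasing timestamps — so reading the emitted
    transcript and merging answers reconstructs the instance texts exactly.
    """
    if set(config.depressive_lexicon) & set(config.neutral_lexicon):
        raise ConfigError("depressive and neutral lexicons must be disjoint")
    if not config.depressive_lexicon or not config.neutral_lexicon:
        raise ConfigError("both lexicons must be nonempty")
    rng = np.random.default_rng(config.seed)
    bags: list[Bag] = []
    transcripts: dict[str, pd.DataFrame] = {}
    truth: dict[str, list[bool]] = {}
    a_lo, a_hi = config.answers_per_question
    for pid, label, n, flags in _draw_structure(rng, config):
        rows = []
        instances = []
        t = 0.0
        for i in range(n):
            tokens = _instance_tokens(rng, config, bool(flags[i]))
            question = (
                f"{QUESTION_TEMPLATES[i % len(QUESTION_TEMPLATES)]} part {i + 1}"
            )
            rows.append((t, t + 2.0, "Ellie", question))
            t += 2.5
            n_answers = int(rng.integers(a_lo, min(a_hi, len(tokens)) + 1))
            cuts = sorted(
                rng.choice(
                    np.arange(1, len(tokens)), size=n_answers - 1, replace=False
                ).tolist()
            ) if n_answers > 1 else []
            pieces = np.split(np.asarray(tokens), cuts)
            for piece in pieces:
                rows.append((t, t + 1.5, "Participant", " ".join(piece)))
                t += 2.0
            text = " ".join(tokens)
            instances.append(
                Instance(
                    text=text,
                    word_count=word_count(text),
                    source_question=question,
                )
            )
        bags.append(build_bag(pid, instances, label=label))
        transcripts[pid] = pd.DataFrame(
            rows, columns=["start_time", "stop_time", "speaker", "value"]
        )
        truth[pid] = flags.tolist()
    bank = sorted({inst.source_question for bag in bags for inst in bag.instances})
    return TextBagSample(
        bags=bags, transcripts=transcripts, instance_truth=truth,
        question_bank=bank,
    )


def write_transcript_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def transcript_tsv_text(frame: pd.DataFrame) -> str:
    """The transcript as DAIC-WOZ-dialect TSV text (for stream readers)."""
    return frame.to_csv(sep="\t", index=False)
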