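"""Per-instance depression confidence scoring.

A *scorer* maps one instance text to a confidence score in [0, 1] that the
instance carries depressive information.  The production-scale scorers in
this problem family are fine-tuned transformer classifiers; here the scorer
is a pluggable contract (:class:`Scorer`) so the MIL machinery is fully
testable at desk scale:

* :func:`fit_baseline_scorer` — a deterministic bag-of-words logistic
  scorer trained under the standard MIL weak-label assumption (every
  instance inherits its bag's label);
* :class:`LexiconScorer` — a fixed depressive-lexicon scorer;
* :class:`GaussianJitterScorer` / :class:`BernoulliScorer` — stochastic
  scorers emulating dropout-style prediction noise, used with
  :func:`mc_uncertainty`.

Two scorers are ensembled by the per-instance average vote
``v = (m + r) / 2`` (:func:`ensemble_scores`), and predictive uncertainty is
estimated by repeated stochastic scoring (:func:`mc_uncertainty`, 10 repeats
by default).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .errors import (
    AlignmentError,
    DegenerateTrainingError,
    EmptyBagError,
    ParameterError,
    ScorerContractError,
)
from .transcripts import Bag, Instance

logger = logging.getLogger(__name__)

#: Repeated stochastic forward passes used for uncertainty estimation.
DEFAULT_MC_REPEATS = 10


@dataclass(frozen=True)
class InstanceScore:
    """Confidence score for one instance, optionally with MC variance."""

    instance_id: int
    score: float
    variance: float | None = None


@dataclass
class ScoredBag:
    """A bag with one confidence score per instance (aligned by id)."""

    bag: Bag
    scores: list[InstanceScore]

    def __post_init__(self) -> None:
        if len(self.scores) != self.bag.n:
            raise AlignmentError(
                f"bag {self.bag.participant_id!r} has {self.bag.n} instances "
                f"but {len(self.scores)} scores"
            )
        for inst, sc in zip(self.bag.instances, self.scores):
            if inst.instance_id != sc.instance_id:
                raise AlignmentError(
                    f"score for instance {sc.instance_id} does not align with "
                    f"instance {inst.instance_id} in bag {self.bag.participant_id!r}"
                )

    @property
    def score_values(self) -> list[float]:
        return [s.score for s in self.scores]


def _text_of(item) -> str:
    return item.text if isinstance(item, Instance) else str(item)


class Scorer:
    """Scorer contract: ``score`` maps an instance (or text) to [0, 1].

    ``stochastic`` declares whether repeated calls on identical input may
    differ; deterministic scorers must return identical values.  Stochastic
    scorers should honour :meth:`reseed` so uncertainty estimates are
    reproducible.
    """

    stochastic: bool = False

    def score(self, instance) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def score_many(self, instances: Sequence) -> list[float]:
        return [self.score(i) for i in instances]

    def reseed(self, seed: int) -> None:
        """Reset internal randomness; no-op for deterministic scorers."""


class ConstantScorer(Scorer):
    def __init__(self, value: float):
        self.value = float(value)

    def score(self, instance) -> float:
        return self.value


class LexiconScorer(Scorer):
    """Deterministic lexicon scorer: ``sigmoid(bias + weight * n_hits)``.

    ``n_hits`` counts lowercased whitespace tokens found in the depressive
    lexicon.  With the default negative bias the base rate on neutral text
    is below 0.5 by construction.
    """

    def __init__(self, lexicon: Iterable[str], bias: float = -2.0, weight: float = 1.0):
        self.lexicon = frozenset(w.lower() for w in lexicon)
        self.bias = float(bias)
        self.weight = float(weight)

    @property
    def base_rate(self) -> float:
        return 1.0 / (1.0 + math.exp(-self.bias))

    def score(self, instance) -> float:
        hits = sum(1 for t in _text_of(instance).lower().split() if t in self.lexicon)
        return 1.0 / (1.0 + math.exp(-(self.bias + self.weight * hits)))


class LinearPresenceScorer(Scorer):
    """Scorer exactly linear in token-presence features (clipped to [0, 1]).

    Used to validate the perturbation explainer: for inputs whose scores
    stay strictly inside (0, 1) the model is exactly linear, so surrogate
    weights must converge to ``coefficients``.
    """

    def __init__(self, coefficients: dict[str, float], intercept: float = 0.5):
        self.coefficients = {k.lower(): float(v) for k, v in coefficients.items()}
        self.intercept = float(intercept)

    def score(self, instance) -> float:
        present = set(_text_of(instance).lower().split())
        raw = self.intercept + sum(
            w for tok, w in self.coefficients.items() if tok in present
        )
        return min(1.0, max(0.0, raw))


class BernoulliScorer(Scorer):
    """Stochastic scorer emitting 0/1 with probability ``p`` of 1."""

    stochastic = True

    def __init__(self, p: float = 0.5, seed: int | None = None):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"p must be in [0,1], got {p}")
        self.p = p
        self._rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def score(self, instance) -> float:
        return float(self._rng.random() < self.p)


class GaussianJitterScorer(Scorer):
    """Adds clipped Gaussian noise to a base scorer.

    Desk-scale analogue of dropout-at-inference prediction noise: repeated
    forward passes on the same input differ, and their variance quantifies
    the scorer's uncertainty on that input.
    """

    stochastic = True

    def __init__(self, base: Scorer, sd: float = 0.05, seed: int | None = None):
        self.base = base
        self.sd = float(sd)
        self._rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def score(self, instance) -> float:
        value = self.base.score(instance) + self._rng.normal(0.0, self.sd)
        return float(min(1.0, max(0.0, value)))


class BaselineTextScorer(Scorer):
    """Fitted bag-of-words logistic scorer (deterministic).

    The fitted per-token weights are exposed (:attr:`coefficients`) so the
    perturbation explainer can be checked against them.
    """

    def __init__(self, vectorizer: CountVectorizer, model: LogisticRegression):
        self._vectorizer = vectorizer
        self._model = model

    @property
    def coefficients(self) -> dict[str, float]:
        names = self._vectorizer.get_feature_names_out()
        coefs = self._model.coef_.ravel()
        return {name: float(w) for name, w in zip(names, coefs)}

    @property
    def intercept(self) -> float:
        return float(self._model.intercept_[0])

    def score(self, instance) -> float:
        return self.score_many([instance])[0]

    def score_many(self, instances: Sequence) -> list[float]:
        texts = [_text_of(i) for i in instances]
        X = self._vectorizer.transform(texts)
        return [float(p) for p in self._model.predict_proba(X)[:, 1]]


def fit_baseline_scorer(
    labeled_bags: Sequence[Bag],
    C: float = 1.0,
    max_iter: int = 1000,
) -> BaselineTextScorer:
    """Fit the baseline scorer under the MIL weak-label assumption.

    Every instance inherits its bag's label (bag-level supervision only);
    features are binary lowercased whitespace-token presence.  Training is
    deterministic: identical bags yield an identical scorer.
    """
    texts: list[str] = []
    labels: list[int] = []
    for bag in labeled_bags:
        if bag.label is None:
            continue
        for inst in bag.instances:
            texts.append(inst.text)
            labels.append(bag.label)
    if len(set(labels)) < 2:
        raise DegenerateTrainingError(
            "baseline scorer needs labeled bags from both classes"
        )
    vectorizer = CountVectorizer(
        lowercase=True, tokenizer=str.split, token_pattern=None, binary=True
    )
    X = vectorizer.fit_transform(texts)
    model = LogisticRegression(C=C, max_iter=max_iter, solver="lbfgs")
    model.fit(X, labels)
    return BaselineTextScorer(vectorizer, model)


# ---------------------------------------------------------------------------
# scoring, ensembling, uncertainty
# ---------------------------------------------------------------------------


def _check_range(value: float, bag_id: str, instance_id: int) -> float:
    if not 0.0 <= value <= 1.0 or not math.isfinite(value):
        raise ScorerContractError(
            f"scorer returned {value!r} for instance {instance_id} of bag "
            f"{bag_id!r}; scores must lie in [0, 1]"
        )
    return float(value)


def score_bag(scorer: Scorer, bag: Bag) -> ScoredBag:
    """Score every instance of a bag independently (order preserved)."""
    if bag.n == 0:
        raise EmptyBagError(f"bag {bag.participant_id!r} is empty")
    values = scorer.score_many(bag.instances)
    scores = [
        InstanceScore(inst.instance_id, _check_range(v, bag.participant_id,
                                                     inst.instance_id))
        for inst, v in zip(bag.instances, values)
    ]
    return ScoredBag(bag=bag, scores=scores)


def score_dataset(scorer: Scorer, bags: Sequence[Bag]) -> list[ScoredBag]:
    return [score_bag(scorer, bag) for bag in bags]


def ensemble_scores(a: ScoredBag, b: ScoredBag) -> ScoredBag:
    """Average vote: each output score is exactly ``(m + r) / 2``."""
    if a.bag.participant_id != b.bag.participant_id or a.bag.n != b.bag.n:
        raise AlignmentError(
            f"cannot ensemble bags {a.bag.participant_id!r} and "
            f"{b.bag.participant_id!r}"
        )
    merged = []
    for sa, sb in zip(a.scores, b.scores):
        if sa.instance_id != sb.instance_id:
            raise AlignmentError(
                f"instance ids {sa.instance_id} and {sb.instance_id} do not align"
            )
        merged.append(InstanceScore(sa.instance_id, (sa.score + sb.score) / 2.0))
    return ScoredBag(bag=a.bag, scores=merged)


def mc_uncertainty(
    scorer: Scorer,
    instance,
    repeats: int = DEFAULT_MC_REPEATS,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean and population variance over repeated independent scorings.

    For a deterministic scorer the variance is exactly 0.  ``seed`` reseeds
    stochastic scorers for reproducibility.
    """
    if repeats < 2:
        raise ParameterError(f"repeats must be >= 2, got {repeats}")
    if seed is not None:
        scorer.reseed(seed)
    draws = np.array([scorer.score(instance) for _ in range(repeats)], dtype=float)
    if draws.min() == draws.max():  # identical draws: variance is exactly 0
        return float(draws[0]), 0.0
    return float(draws.mean()), float(draws.var())  # population (ddof=0) variance


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def scored_bag_to_dict(scored: ScoredBag) -> dict:
    return {
        "participant_id": scored.bag.participant_id,
        "label": scored.bag.label,
        "scores": [
            {"id": s.instance_id, "score": s.score, "variance": s.variance}
            for s in scored.scores
        ],
    }


def scored_bag_from_dict(record: dict, bag: Bag | None = None) -> ScoredBag:
    """Rebuild a scored bag; a minimal bag is synthesised if none is given."""
    scores = [
        InstanceScore(item["id"], float(item["score"]), item.get("variance"))
        for item in record["scores"]
    ]
    if bag is None:
        label = record.get("label")
        bag = Bag(
            record["participant_id"],
            [Instance(text="", word_count=0, instance_id=s.instance_id)
             for s in scores],
            None if label is None else int(label),
        )
    return ScoredBag(bag=bag, scores=scores)


def write_scored_jsonl(scored_bags: Iterable[ScoredBag], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for scored in scored_bags:
            fh.write(json.dumps(scored_bag_to_dict(scored)) + "\n")


def read_scored_jsonl(path) -> list[ScoredBag]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(scored_bag_from_dict(json.loads(line)))
    return out
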