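"""Bag-level decision rules.

Classical MIL labels a bag positive iff it contains at least one positive
instance — too brittle for interview data, where a non-depressed participant
can produce the occasional depressive-sounding response.  The improved rule
used here combines two criteria over the per-instance confidence scores:

* **majority criterion** — more than half of the bag's instances score
  strictly above a high-confidence threshold ``alpha``;
* **count criterion** — strictly more than ``beta`` instances are
  *depressive instances*, i.e. score strictly above the 0.5 cutoff.

Under the default ``majority_or_count`` variant the bag is flagged depressed
when either criterion fires.  All inequalities are strict ("exceeds", "more
than"): equality at a boundary never fires a flag, and an exact half at even
bag size is negative.  Variants expose each criterion alone, their
conjunction, and the alternate single-instance reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import EmptyBagError, ParameterError
from .scoring import ScoredBag

VARIANTS = (
    "majority_or_count",
    "single_or_count",
    "count_only",
    "majority_only",
    "majority_and_count",
)


@dataclass(frozen=True)
class DecisionConfig:
    """Hyperparameters of the bag decision rule.

    ``alpha`` is the high-confidence score threshold; ``beta`` the tolerated
    number of depressive instances (absolute count by default, a fraction of
    the bag size when ``beta_is_fraction``).  ``alpha`` and
    ``depressive_cutoff`` are independent thresholds.
    """

    alpha: float = 0.95
    beta: float = 2
    depressive_cutoff: float = 0.5
    variant: str = "majority_or_count"
    beta_is_fraction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ParameterError(f"beta must be nonnegative, got {self.beta}")
        if self.beta_is_fraction and self.beta > 1:
            raise ParameterError(
                f"fractional beta must be in [0, 1], got {self.beta}"
            )
        if not 0.0 <= self.depressive_cutoff <= 1.0:
            raise ParameterError(
                f"depressive_cutoff must be in [0, 1], got {self.depressive_cutoff}"
            )
        if self.variant not in VARIANTS:
            raise ParameterError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )

    def beta_threshold(self, n: int) -> float:
        return self.beta * n if self.beta_is_fraction else self.beta


@dataclass(frozen=True)
class InstanceFlags:
    above_alpha: bool
    depressive: bool


@dataclass
class BagDecision:
    """The rule's verdict for one bag, with per-criterion evidence."""

    participant_id: str
    label: int
    n: int
    count_above_alpha: int
    count_depressive: int
    criterion_majority: bool
    criterion_count: bool
    per_instance_flags: list[InstanceFlags]


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def add(self, truth: int, prediction: int) -> None:
        if prediction == 1:
            if truth == 1:
                self.TP += 1
            else:
                self.FP += 1
        else:
            if truth == 1:
                self.FN += 1
            else:
                self.TN += 1


@dataclass
class DatasetDecisions:
    decisions: list[BagDecision]
    confusion: ConfusionCounts | None
    unlabeled: list[str] = field(default_factory=list)


def classical_bag_label(instance_labels: Sequence[int]) -> int:
    """Classical MIL rule: positive iff any instance label is 1."""
    if not instance_labels:
        raise EmptyBagError("classical rule is undefined on an empty bag")
    return 1 if any(int(y) == 1 for y in instance_labels) else 0


def pool(scores: Sequence[float], method: str) -> float:
    """Permutation-invariant score aggregation: ``max`` or ``mean``."""
    if not scores:
        raise EmptyBagError("cannot pool an empty score vector")
    if method == "max":
        return max(scores)
    if method == "mean":
        return sum(scores) / len(scores)
    raise ParameterError(f"unknown pooling method {method!r}")


def decide_bag(scored: ScoredBag, config: DecisionConfig) -> BagDecision:
    """Apply the improved decision rule to one scored bag."""
    n = scored.bag.n
    if n == 0:
        raise EmptyBagError(f"bag {scored.bag.participant_id!r} is empty")
    flags = [
        InstanceFlags(
            above_alpha=s.score > config.alpha,
            depressive=s.score > config.depressive_cutoff,
        )
        for s in scored.scores
    ]
    count_above = sum(f.above_alpha for f in flags)
    count_dep = sum(f.depressive for f in flags)
    criterion_majority = count_above > n / 2
    criterion_count = count_dep > config.beta_threshold(n)

    if config.variant == "majority_or_count":
        label = criterion_majority or criterion_count
    elif config.variant == "single_or_count":
        label = (count_above >= 1) or criterion_count
    elif config.variant == "count_only":
        label = criterion_count
    elif config.variant == "majority_only":
        label = criterion_majority
    else:  # majority_and_count
        label = criterion_majority and criterion_count

    return BagDecision(
        participant_id=scored.bag.participant_id,
        label=int(label),
        n=n,
        count_above_alpha=count_above,
        count_depressive=count_dep,
        criterion_majority=criterion_majority,
        criterion_count=criterion_count,
        per_instance_flags=flags,
    )


def decide_dataset(
    scored_bags: Sequence[ScoredBag], config: DecisionConfig
) -> DatasetDecisions:
    """Decide every bag; aggregate confusion counts over the labeled ones.

    Bags without labels are decided but excluded from the counts and listed
    in ``unlabeled``.
    """
    decisions: list[BagDecision] = []
    confusion = ConfusionCounts()
    unlabeled: list[str] = []
    any_labeled = False
    for scored in scored_bags:
        decision = decide_bag(scored, config)
        decisions.append(decision)
        if scored.bag.label is None:
            unlabeled.append(scored.bag.participant_id)
        else:
            any_labeled = True
            confusion.add(scored.bag.label, decision.label)
    return DatasetDecisions(
        decisions=decisions,
        confusion=confusion if any_labeled else None,
        unlabeled=unlabeled,
    )
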