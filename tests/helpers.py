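"""Shared test helpers and independent brute-force oracles."""

from milintv import Instance, InstanceScore, ScoredBag, build_bag


def scored_bag(values, label=None, pid="p"):
    bag = build_bag(pid, [Instance(f"t{i}", 1) for i in range(len(values))],
                    label=label)
    return ScoredBag(bag, [InstanceScore(i + 1, v) for i, v in enumerate(values)])


def oracle_label(scores, alpha, beta, cutoff=0.5):
    """Literal restatement of the two decision criteria, joined by OR:
    more than half the instances exceed the high threshold, or more than
    beta instances exceed the depressive cutoff."""
    n = len(scores)
    majority = sum(1 for s in scores if s > alpha) > n / 2
    count = sum(1 for s in scores if s > cutoff) > beta
    return int(majority or count)


def mann_whitney_auc(pairs):
    """AUC oracle: fraction of positive-negative score pairs ranked
    correctly, ties counted one half."""
    pos = [s for s, y in pairs if y == 1]
    neg = [s for s, y in pairs if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))
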