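"""Perturbation-based local surrogate explanations (LIME-style).

For one instance, the scorer is treated as a black box: copies of the text
with random token subsets removed are scored, each perturbed copy is
weighted by its proximity to the original (an exponential kernel on cosine
distance between presence masks), and a weighted sparse linear surrogate is
fitted.  The surrogate's coefficients attribute the prediction to tokens —
positive weights push toward the depressive class.

Tokenisation is the same lowercased whitespace scheme used throughout the
package; duplicate tokens are explained as one feature (all occurrences are
masked together).  The mask token is removal, not a placeholder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .errors import ParameterError
from .scoring import Scorer, _text_of

logger = logging.getLogger(__name__)

#: Ridge regularisation for the surrogate; kept tiny so the surrogate
#: converges to the scorer's own coefficients when the scorer is linear.
_SURROGATE_RIDGE_ALPHA = 1e-3


@dataclass
class Explanation:
    """Sparse local surrogate for one instance prediction."""

    tokens: list[str]
    weights: list[float]
    intercept: float
    n_samples: int
    local_fit_quality: float
    seed: int | None = None
    flat: bool = False

    def as_dict(self) -> dict:
        return {
            "tokens": self.tokens,
            "weights": self.weights,
            "intercept": self.intercept,
            "n_samples": self.n_samples,
            "local_fit_quality": self.local_fit_quality,
            "seed": self.seed,
        }


def _distinct_features(tokens: list[str]) -> list[str]:
    seen: dict[str, None] = {}
    for t in tokens:
        seen.setdefault(t, None)
    return list(seen)


def explain_instance(
    scorer: Scorer,
    instance,
    n_samples: int = 1000,
    kernel_width: float | None = None,
    max_features: int = 10,
    seed: int | None = None,
) -> Explanation:
    """Explain one instance score with a weighted sparse linear surrogate.

    Parameters
    ----------
    scorer
        Any scorer satisfying the contract; treated as a black box.
    instance
        Instance (or raw text) with at least one token.
    n_samples
        Number of random presence masks (>= 10).  The first sample is the
        unperturbed text.
    kernel_width
        Width of the exponential proximity kernel
        ``exp(-d^2 / kernel_width^2)`` on the cosine distance ``d`` between a
        mask and the all-ones mask.  Default ``0.75 * sqrt(n_features)``.
    max_features
        Number of highest-|weight| features retained.
    seed
        Makes the perturbation draw reproducible.
    """
    text = _text_of(instance)
    tokens = text.lower().split()
    if not tokens:
        raise ParameterError("cannot explain an instance with no tokens")
    if n_samples < 10:
        raise ParameterError(f"n_samples must be >= 10, got {n_samples}")
    features = _distinct_features(tokens)
    t = len(features)
    if kernel_width is None:
        kernel_width = 0.75 * math.sqrt(t)

    rng = np.random.default_rng(seed)
    masks = np.ones((n_samples, t), dtype=np.int8)
    sizes = rng.integers(0, t + 1, size=n_samples - 1)  # uniform over mask sizes
    for row, size in enumerate(sizes, start=1):
        masks[row] = 0
        if size:
            masks[row, rng.choice(t, size=size, replace=False)] = 1

    # cosine distance between a 0/1 mask of size s and the all-ones mask
    # reduces to 1 - sqrt(s / t); the empty mask is maximally distant.
    s = masks.sum(axis=1)
    distance = np.where(s > 0, 1.0 - np.sqrt(s / t), 1.0)
    sample_weights = np.exp(-(distance**2) / kernel_width**2)

    active = [set(np.array(features)[mask.astype(bool)]) for mask in masks]
    texts = [" ".join(tok for tok in tokens if tok in act) for act in active]
    try:
        ys = np.array(scorer.score_many(texts), dtype=float)
    except Exception as exc:
        raise RuntimeError(
            f"scorer failed on a perturbed text (first failing mask sizes: "
            f"{s[:5].tolist()}...)"
        ) from exc

    if float(ys.max() - ys.min()) == 0.0:
        logger.warning(
            "explain_instance: scorer output has zero variance across "
            "perturbations; returning a flat explanation"
        )
        top = features[:max_features]
        return Explanation(
            tokens=top,
            weights=[0.0] * len(top),
            intercept=float(ys[0]),
            n_samples=n_samples,
            local_fit_quality=0.0,
            seed=seed,
            flat=True,
        )

    surrogate = Ridge(alpha=_SURROGATE_RIDGE_ALPHA)
    surrogate.fit(masks, ys, sample_weight=sample_weights)
    coefs = surrogate.coef_
    quality = float(surrogate.score(masks, ys, sample_weight=sample_weights))

    order = sorted(range(t), key=lambda i: (-abs(coefs[i]), i))[:max_features]
    return Explanation(
        tokens=[features[i] for i in order],
        weights=[float(coefs[i]) for i in order],
        intercept=float(surrogate.intercept_),
        n_samples=n_samples,
        local_fit_quality=quality,
        seed=seed,
    )
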