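# Methods

## Problem setting

Screening interviews for depression produce long, multi-turn dialogues in
which only a minority of a participant's responses carry diagnostic signal.
`milintv` treats each participant as a *bag* of *instances* under multiple
instance learning (MIL): an instance is the participant's merged response to
one interviewer question, the bag carries the binary screening label (in the
source corpora, PHQ-8 ≥ 10), and instance labels are latent.

The classical MIL rule labels a bag positive iff it contains at least one
positive instance,

    Y_b = 0  if Σᵢ yᵢ = 0,   else 1.

That rule is brittle for interview text: a non-depressed participant can
produce a single depressive-sounding answer (a *spurious depressive
instance*), and one such instance would flip the bag. The decision rule
implemented here works on per-instance confidence scores νᵢ ∈ [0, 1] and
combines two criteria:

* **majority criterion** — strictly more than half of the bag's instances
  score strictly above a high-confidence threshold α;
* **count criterion** — strictly more than β instances are *depressive
  instances*, i.e. score strictly above the 0.5 cutoff.

The default variant (`majority_or_count`) flags the bag when either
criterion fires. All comparisons are strict: a score equal to α or to the
cutoff never counts, and an exact half at even bag size is negative. The
descriptions of the two criteria in the literature admit an alternate
reading in which a single instance above α suffices; this is exposed as the
`single_or_count` variant, along with `count_only`, `majority_only` and
`majority_and_count` for ablations. With `count_only`, β = 0 and the 0.5
cutoff defining instance labels, the rule degenerates to the classical
at-least-one-positive rule — a property test pins this limit.

β is an absolute count by default (the prose reads "more than β depressive
instances"); `beta_is_fraction` switches to β·n for studies that need a
size-relative tolerance.

## Transcript preprocessing

Transcripts are delimited tables (tab-separated with `start_time`,
`stop_time`, `speaker`, `value` columns; a comma-separated dialect allows
participant-only rows). Parsing choices, where the upstream descriptions
are silent, are:

* rows are sorted by `start_time`, ties stable by input order;
* malformed rows raise an error naming the line, or are counted, logged and
  dropped under `lenient=True` — never silently discarded;
* the interviewer tag defaults to "Ellie" and matches case-insensitively;
* "word count" is whitespace tokenisation of the raw text — the simplest
  reproducible rule;
* answers merged for one question are joined with a single space, so total
  participant words are conserved (property-tested);
* sessions with no interviewer rows yield one instance per participant turn
  with no merging, mirroring how questionless corpus sessions are handled;
* instances are ranked by word count, most to least, with a stable sort; no
  truncation is applied by default (all instances are retained);
* embedded interviewer questions inside responses are removed by matching
  normalised token spans (lowercase, ASCII punctuation stripped); an
  instance emptied by removal is flagged rather than dropped unilaterally;
* key screening questions (e.g. a prior depression diagnosis) have their
  short yes/no answers rewritten into two fixed canonical sentences.  The
  yes/no detector matches the answer's leading tokens against configurable
  phrase lists ({"yes","yeah","yep","i have"} / {"no","nope","never",
  "i haven't"}); an undetectable answer is left unchanged with a warning,
  since no documented behaviour exists for that case.

## Scoring

The scorer is a contract, not a model: any callable mapping an instance
text to [0, 1], declaring whether it is stochastic. Production-scale
scorers for this task are fine-tuned transformer classifiers; they are out
of scope here and plug in behind the same contract. The in-package
baseline is a binary bag-of-words logistic regression trained under the
standard MIL weak-label assumption (each instance inherits its bag's
label). It is deterministic, and its fitted per-token weights are exposed
so the explainer can be validated against them. "Confidence score" is the
positive-class probability; the decision thresholds (0.5, α) presuppose the
[0, 1] codomain.

Two scorers are fused by the per-instance average vote ν = (m + r)/2 —
exactly, with no weighting. The ensemble is symmetric and bounded by its
inputs (property-tested). Ensembling happens at the instance-score level,
before the bag decision; decision-level voting is not the default because
the average-vote formula indexes instances.

Uncertainty follows the Monte-Carlo-dropout protocol: 10 independent
scorings of the same input by default, reporting the mean and the
*population* (divide-by-N) variance. A deterministic scorer reports
exactly zero variance.

## Evaluation

Accuracy, precision, recall and F1 use the standard confusion-matrix
formulas; any zero-denominator entry is flagged undefined rather than
coerced to 0. ROC curves are computed over a pooled bag-level score — mean
instance score by default (max and depressive-count-fraction are
alternatives), since the decision rule itself emits no continuous bag
score — with AUC by trapezoid, which equals the Mann–Whitney pairwise
statistic with ties counted one half (tested against that oracle).

`sweep_alpha_beta` evaluates the full Cartesian grid, by default
α ∈ {0.50, 0.55, …, 1.00} and β ∈ {0, …, 10}; the fine step near 1.0
matters because useful high-confidence thresholds cluster there. Among
rows tied on the chosen metric the sweep reports the largest α, then the
largest β: the strictest thresholds attaining the observed optimum, which
is the configuration least sensitive to a lone inflated score.

## Synthetic data

The target corpora are access-restricted, so the generators reproduce the
statistical structure the analysis assumes rather than any actual content:

* class balance defaults to 14/47 positive — the depressed / non-depressed
  split of the reference test set;
* bags hold 20–50 merged instances by default (each instance backed by 1–3
  raw answer turns, i.e. roughly 40–100 utterances per session pre-merge);
* in a positive bag, a fraction (default 0.6) of instances are truly
  depressive and draw scores from a high Beta(12, 2); the rest, and all
  negative-bag instances, draw from a low Beta(2, 8). These defaults put
  essentially all mass above 0.9 on the depressed side only, matching the
  qualitative contrast observed in real score heatmaps;
* with probability 0.15 a negative bag contains exactly one high-scoring
  spurious instance — the misleading-response phenomenon that motivates β;
* text bags plant a depressive lexicon at rate 0.35 inside truly depressive
  instances and leak it at 0.02 elsewhere; transcript tables are emitted
  alongside so the full read → pair → merge path is exercised, and the
  merge provably reconstructs the generated instances exactly.

What the generator does **not** emulate: linguistic realism, topical
coherence, inter-annotator noise in labels, score calibration error of real
transformer scorers, or correlation between instance length and signal.
Green tests therefore certify the *machinery* — rule logic, recovery of
planted structure, metric identities — not clinical performance on real
interviews.

### The planted-boundary recovery study

The hyperparameter-recovery study uses a dedicated configuration
(`planted_boundary_config`): 300 participants, compact bags of 8–16
instances, 75% truly depressive instances per positive bag drawing from
Beta(60, 4) (≈ 89% of its mass above 0.9 — the planted boundary), and
non-depressive scores from Beta(5, 6) (P(score > 0.5) ≈ 0.38). These
values were fixed by a design calculation, for a reason worth recording:
under the default generator the depressive-count criterion alone separates
the classes perfectly, making accuracy flat in α — no sweep can recover a
boundary that does not constrain the optimum. The planted-boundary
conditions instead make the count criterion noisy (negative bags hold
several mildly elevated scores, pushing the optimal β to the top of its
grid) while the majority criterion separates the classes only for
α ≤ ≈ 0.9, so the sweep's best-accuracy α lands just below the planted
boundary. Compact bags keep both criteria live within the default β grid.
On these conditions max-pooling at 0.5 collapses (nearly every negative
bag contains some score above 0.5), which is what the pooling comparison
measures.

## Numerical choices

* Strict inequalities throughout the decision rule; empty bags are errors,
  never negatives.
* Population variance for MC uncertainty.
* The explainer draws presence masks uniformly over mask sizes (the empty
  mask is allowed and treated as maximally distant), weights samples by
  exp(−d²/w²) with d = 1 − √(s/t) (the cosine distance between a size-s
  mask and the all-ones mask) and default width 0.75·√t, and fits a
  weighted ridge surrogate with negligible regularisation (1e−3) so that
  for a truly linear scorer the surrogate converges to the scorer's own
  coefficients. Duplicate tokens are one feature; masking removes all
  occurrences (removal, not a placeholder token). Defaults: 1000 samples,
  10 reported features.
* Zero scorer variance across perturbations yields an all-zero "flat"
  explanation with a warning, not a spurious fit.
* Sweep determinism: no hidden randomness anywhere in evaluation.

## Problem sizes

Default study sizes were chosen so every check runs comfortably on a
laptop: 47–300 synthetic participants per dataset, 20 replicate seeds for
the pooling comparison, 5000 perturbation samples for explainer recovery,
10⁴ repeats for the Bernoulli variance check, and exhaustive decision-rule
verification over all score multisets up to bag size 6 on a 0.1 grid.

## Known limitations

* The baseline scorer is a unigram presence model; it validates the MIL
  machinery but is not a competitive instance scorer for real interviews.
* The explainer's agreement guarantee is exact only for scorers linear in
  token presence; for the logistic baseline agreement is monotone-rank,
  not coefficient-exact, and degrades if the explained instance sits in
  the saturated region of the sigmoid.
* β as an absolute count interacts with bag size; cross-corpus use with
  very different interview lengths should consider `beta_is_fraction`.
* Bags are unordered by design (the decision rule is permutation
  invariant); any temporal structure in a session is deliberately ignored.
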