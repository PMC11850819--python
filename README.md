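# milintv

Multiple-instance learning (MIL) for depression screening from clinical
interview transcripts.

Screening interviews (DAIC-WOZ-style: a virtual interviewer, timestamped
turns, a PHQ-8-derived binary label per participant) are long dialogues in
which only some responses carry diagnostic signal. `milintv` treats each
participant as a MIL *bag*: every merged answer to one interviewer question
is an *instance* xᵢ, a pluggable scorer assigns each instance a confidence
score νᵢ ∈ [0, 1] of carrying depressive information, and the bag-level
verdict combines two criteria over those scores:

* **majority** — more than half of the instances score above a
  high-confidence threshold α;
* **count** — more than β instances are *depressive* (score > 0.5).

The bag is flagged when either fires (variants expose each alone, their
conjunction, and a single-instance reading). Unlike the classical MIL rule
`Y_b = 1 ⇔ Σ yᵢ > 0`, the α/β rule tolerates the occasional
depressive-sounding answer from a non-depressed participant while still
catching bags whose signal is spread across many mildly-elevated instances.

The package provides, for researchers in clinical NLP:

* transcript preprocessing (timestamp-ordered segmentation into
  question–answer pairs, answer merging, word-count ranking, canonical
  rewriting of key yes/no screening answers, removal of interviewer text
  embedded in responses);
* the scorer contract with a deterministic bag-of-words logistic baseline,
  per-instance average-vote ensembling ν = (m + r)/2, and Monte-Carlo
  repeat uncertainty (10 stochastic scorings, population variance);
* the α/β decision rule with per-criterion evidence, plus max/mean pooling
  baselines;
* evaluation: accuracy/precision/recall/F1 with explicit undefined-value
  flags, ROC/AUC over pooled bag scores, exhaustive (α, β) grid sweeps,
  and pooling-strategy comparisons;
* LIME-style perturbation explanations of a single instance score;
* synthetic generators that reproduce the statistical structure of the
  (access-restricted) interview corpora, including the spurious-instance
  phenomenon, so the whole pipeline is testable offline.

See `docs/methods.md` for the model, its assumptions and all numerical
choices.

## Worked example

Train the baseline scorer on one synthetic cohort and screen another with
the default rule (α = 0.95, β = 2):

```python
from milintv import (SynthConfig, DecisionConfig, generate_text_bags,
                     fit_baseline_scorer, score_dataset, decide_dataset,
                     metrics, explain_instance)

train = generate_text_bags(SynthConfig(n_participants=100, seed=1))
test  = generate_text_bags(SynthConfig(n_participants=47, seed=2))

scorer = fit_baseline_scorer(train.bags)          # weak bag-level labels
scored = score_dataset(scorer, test.bags)
result = decide_dataset(scored, DecisionConfig(alpha=0.95, beta=2))

m = metrics(result.confusion)
print(f"acc={m.acc:.3f}  precision={m.precision:.3f}  "
      f"recall={m.recall:.3f}  f1={m.f1:.3f}")
```

```
acc=1.000  precision=1.000  recall=1.000  f1=1.000
```

On this synthetic test cohort (14 depressed / 33 non-depressed bags) the
planted lexicon is strong enough for a perfect split: every depressed bag
has more than β = 2 depressive instances and no healthy bag does. Real
interview text is far noisier — the synthetic conditions validate the
machinery, not clinical performance.

Explaining the highest-scoring instance of a flagged bag shows which
tokens push the score up (positive weights = toward the depressive class):

```python
sb  = next(s for s in scored if s.bag.participant_id == "P300")
top = max(sb.scores, key=lambda s: s.score)
inst = next(i for i in sb.bag.instances if i.instance_id == top.instance_id)
expl = explain_instance(scorer, inst, n_samples=1000, seed=0)
for tok, w in zip(expl.tokens[:5], expl.weights[:5]):
    print(f"{tok:>12s}  {w:+.3f}")
```

```
    hopeless  +0.145
      lonely  +0.140
        numb  +0.126
    insomnia  +0.119
       tired  +0.119
```

The same pipeline is available from the shell:

```bash
milintv simulate --kind text --n-participants 47 --seed 7 --out sim/
milintv preprocess sim/transcripts/*.tsv --labels sim/labels.csv --out prep/
milintv run --bags prep/bags.jsonl --out run/
milintv sweep --scored run/scored.jsonl --out sweep/
```

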