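# expertpool

Aggregation and scoring of structured expert probability judgements.

When several experts each give a probability that a binary claim is
true — "will this study replicate?", "will this event occur by June?" —
the group's judgements must be combined into a single probability per
claim. `expertpool` implements a full suite of mathematical aggregation
methods for three-point elicitations (lower bound `L`, best estimate
`B`, upper bound `U`, with `0 ≤ L ≤ B ≤ U ≤ 1`, read as the 5th/50th/
95th percentiles of each expert's subjective distribution), together
with the measures needed to compare them. It is aimed at researchers
running structured elicitation exercises (IDEA-style two-round panels,
forecasting tournaments) and at anyone studying which observable
behaviours predict forecasting skill.

**21 aggregation methods:**

* *Average-type pools* — arithmetic mean (`ArMean`), median, mean of
  log odds (`LOArMean`), Beta-CDF-extremised mean (`BetaArMean`,
  `p̂ = F_Beta(7,7)(mean B)`), and the median of the averaged
  three-point subjective distributions (`DistribArMean`).
* *Thirteen proxy-weighted linear pools* `p̂_c = Σ_i w̃_ic B_ic`, where
  the weights reward hypothesised proxies for skill: narrow intervals
  (`IntWAgg`, `IndIntWAgg`, `VarIndIntWAgg`), asymmetric intervals
  (`AsymWAgg` and composites `IndIntAsymWAgg`, `KitchSinkWAgg`),
  extreme best estimates (`DistLimitWAgg`), post-discussion movement
  (`ShiftWAgg`), granular estimates (`GranWAgg`), engagement
  (`EngWAgg`), breadth and diversity of coded reasons (`ReasonWAgg`,
  `ReasonWAgg2`), quiz performance (`QuizWAgg`) and self-rated
  comprehension (`CompWAgg`).
* *Two Bayesian pools* — a hierarchical logit-normal model with claim,
  participant and bounds-derived variance components (`BayTriVar`),
  optionally with externally supplied per-claim priors
  (`BayPRIORSAgg`).

**Four performance measures**, applicable to individual experts or to
any method's pooled predictions: average Brier score, ROC AUC,
the calibration term of the Brier decomposition over ten probability
bins, and response informativeness (mean KL divergence of the chosen
bin from the uniform 0.5 bin).

A seeded synthetic-panel generator produces realistic two-round panels
with proxy metadata whose correlation with expert skill is
controllable, so every method is testable without external data.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Three participants assess one claim with judgements
(60%, 70%, 99%), (38%, 58%, 60%) and (50%, 85%, 90%):

```python
from expertpool import (Assessment, ar_mean, median_pool, lo_ar_mean,
                        beta_ar_mean, distrib_ar_mean, BetaTransformSpec)

triples = [(0.60, 0.70, 0.99), (0.38, 0.58, 0.60), (0.50, 0.85, 0.90)]
best = [b for _, b, _ in triples]
a = [Assessment(f"p{i}", "c1", 2, *t) for i, t in enumerate(triples)]

print(ar_mean(best))          # 0.71
print(median_pool(best))      # 0.7
print(lo_ar_mean(best))       # 0.724765382305563
print(distrib_ar_mean(a))     # 0.654380664652568
print(beta_ar_mean([0.7], BetaTransformSpec(7, 7)))  # 0.9376247882008
```

The mean of the three best estimates is 0.71 and the median 0.70. The
log-odds mean (0.725) weighs the extreme 0.85 a little more than the
plain mean does. The distribution pool (0.654) is pulled down by the
second expert's low, tight interval, which concentrates mass below
0.6. The Beta(7,7) transform extremises a pooled 0.70 to 0.938 —
averaged probabilities tend to be under-confident, and the transform
pushes them back toward the certainty limits.

From the shell, the same pipeline end to end:

```sh
expertpool simulate --n-claims 40 --n-participants 12 --proxy-effect 0.5 \
    --seed 1 --out panel_dir
expertpool aggregate --panel panel_dir/panel.csv --quiz panel_dir/quiz.csv \
    --claim-meta panel_dir/claim_meta.csv --method all --out aggregates.csv
expertpool score --panel panel_dir/panel.csv --outcomes panel_dir/outcomes.csv \
    --quiz panel_dir/quiz.csv --claim-meta panel_dir/claim_meta.csv \
    --methods all --out scores.csv
```

`score` prints one row per runnable method with its four measures,
ordered from best to worst average Brier score; methods whose inputs
are missing from the panel (bounds, rounds, metadata) are skipped with
a named reason — a point-estimate-only panel supports exactly six of
the 21 methods.

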