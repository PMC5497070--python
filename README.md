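# crowdrasch

Rasch-weighted consensus scoring for crowdsourced binary diagnostic labels.

When many untrained graders each classify a medical image as *normal* or
*abnormal* — the motivating case is diabetic-retinopathy screening of retinal
fundus photographs by crowdsourcing workers — the simplest consensus is the
majority vote (MV): call the image abnormal if half or more graders did.
MV ignores that graders differ widely in skill and images in difficulty.
`crowdrasch` implements a consensus rule that learns those differences and
uses them:

1. On a training set of items with known gold labels, build the sparse
   worker × item **correctness matrix** (1 = graded correctly, 0 = not,
   missing = not graded).
2. Fit the dichotomous **Rasch model** by joint maximum likelihood (JMLE):
   the probability that worker *i* grades item *n* correctly is

   *P*<sub>ni</sub> = exp(*B*<sub>n</sub> − *D*<sub>i</sub>) / (1 + exp(*B*<sub>n</sub> − *D*<sub>i</sub>)),

   with item measure *B*<sub>n</sub> (higher = easier) and worker measure
   *D*<sub>i</sub> (lower = more skilled), both in logits.
3. Weight each worker's vote by **exp(−*D*<sub>i</sub>)** — the odds that
   they correctly classify an item of average difficulty — after truncating
   weights at the 1st/99th centiles for stability.
4. On test items, sum the weighted votes (abnormal = +1, normal = −1) into a
   consensus score *S* and call the item abnormal when *S* ≥ 0, or feed *S*
   into a logistic model and pick the operating point (maximum percent
   correct, minimum sensitivity, or minimum specificity) that the screening
   context demands.

The package provides scikit-learn-style estimators
(`RaschJMLE`, `RaschWeightedConsensus`, `MajorityVoteConsensus`), the data
cleaning rules such work needs (duplicate-grade removal, sparse-worker
exclusion, ordinal-grade dichotomization, reproducible train/test splits),
ROC evaluation with DeLong confidence intervals and the paired DeLong test
for correlated AUROCs, constrained cut-point selection, leave-one-item-out
jackknife validation, and a synthetic crowd simulator for benchmarking.

## Worked example

```python
import pandas as pd
from crowdrasch import (SimConfig, simulate_crowd, split_items, vote_matrix,
                        RaschWeightedConsensus, MajorityVoteConsensus,
                        auroc, compare_auroc, select_cutpoint)

crowd = simulate_crowd(SimConfig(n_items=400, n_workers=120, grades_per_item=10,
                                 ability_sd=1.5, seed=7))
gold = crowd.truth.set_index("item_id")["gold"]
split = split_items(sorted(gold.index), fraction=0.5, seed=1)
train, test = sorted(split.train_items), sorted(split.test_items)

X_train = vote_matrix(crowd.records[crowd.records.item_id.isin(train)], items=train)
X_test = vote_matrix(crowd.records[crowd.records.item_id.isin(test)], items=test)

model = RaschWeightedConsensus(missing_weight="neutral").fit(
    X_train, gold.loc[train].to_numpy())
scores = pd.Series(model.decision_function(X_test), index=test)
margin = pd.Series(MajorityVoteConsensus().fit(X_test).decision_function(X_test),
                   index=test)

weighted = auroc(scores, gold.loc[test])
unweighted = auroc(margin, gold.loc[test])
test_result = compare_auroc(scores, margin, gold.loc[test])
print(f"weighted AUROC  {weighted.auroc:.3f} "
      f"(95% CI {weighted.ci_low:.3f}-{weighted.ci_high:.3f})")
print(f"vote-margin AUROC {unweighted.auroc:.3f} "
      f"(95% CI {unweighted.ci_low:.3f}-{unweighted.ci_high:.3f})")
print(f"DeLong chi-square {test_result.chi_square:.1f}, p = {test_result.p_value:.2g}")

op = select_cutpoint(scores, gold.loc[test], "min_sensitivity", 90.0)
print(f"cut-off {op.chosen_cutoff:.2f}: sensitivity {op.summary.sensitivity:.1f}%, "
      f"specificity {op.summary.specificity:.1f}%, correct {op.summary.percent_correct:.1f}%")
```

Output:

```
weighted AUROC  0.829 (95% CI 0.770-0.888)
vote-margin AUROC 0.536 (95% CI 0.455-0.618)
DeLong chi-square 84.5, p = 3.8e-20
cut-off -23.47: sensitivity 92.9%, specificity 50.9%, correct 68.5%
```

With 10 grades per item from a crowd whose ability spread is 1.5 logits
around a chance-level mean, the unweighted vote margin barely ranks the
items (AUROC 0.54) because skilled and unskilled votes count alike, while
weighting by estimated ability recovers most of the attainable signal
(AUROC 0.83); the paired DeLong test confirms the gap. The constrained
cut-point trades specificity for ≥ 90% sensitivity, the usual screening
priority. Note the score scale is in summed odds, so cut-offs far from zero
are unremarkable.

A thin CLI wraps the same pipeline for file-based use:

```bash
crowdrasch simulate --config sim.yaml --out-dir data/
crowdrasch run --grades data/grades.csv --truth data/truth.csv --out-dir results/
```

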