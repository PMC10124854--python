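# semsel

Robust selection of word-embedding ("semantic") spaces for predicting
behavioral data, with the full stimulus-design and preprocessing toolchain
of a three-condition semantic-priming study, and a synthetic-data generator
with a planted ground truth for end-to-end validation.

## The problem

Researchers in psycholinguistics increasingly use distributional semantic
spaces — word2vec-style embeddings in which cosine similarity between word
vectors proxies semantic relatedness — to select stimuli and to model human
data. But many spaces can be trained (different corpora, hyperparameters),
and the behavioral datasets available for evaluating them in most languages
are small. Picking the space with the best fit *on the evaluation data
itself* is then largely an exercise in overfitting: with enough candidates,
one of them will fit any small dataset well by chance, and its apparent
performance will not transfer.

`semsel` implements a selection procedure that resists this failure mode:

1. **Multiple tasks.** Each candidate space is scored on several prediction
   tasks at once: primed lexical-decision log RTs (with word frequency
   [Zipf] and length of prime and target as baseline covariates), mean
   semantic-relatedness ratings, and SimLex-999-style relatedness and
   similarity norms. The score is held-out variance explained
   (R² = 1 − SS_res/SS_tot on test items) of an OLS model
   `response ~ covariates + cosine(prime, target)`.
2. **Rank aggregation.** Within each task candidates are ranked by R²
   (rank 1 best, midranks for ties); the candidate with the lowest average
   rank across tasks wins. Aggregating ranks rather than raw R² keeps tasks
   with large R² from dominating tasks with small R².
3. **Nested cross-validation.** An inner k-fold loop performs the selection
   using only the outer-training portion; the selected model is refit on
   that portion and scored on the untouched outer-test fold. The mean of
   the outer-fold scores estimates how the *selection procedure's output*
   will perform on independent data — the estimate a naive train-set
   selection always inflates. A final inner loop on the full data names the
   space to publish.

Because the behavioral datasets such a study uses are not bundled here, the
package ships a generator (`semsel.simulate`) that produces every input
with known structure: a latent true similarity, a ladder of candidate
spaces whose fidelity to the truth decreases in a planted order, triplets
(target + strongly related / weakly related / unrelated primes) whose clean
cosines fall in calibrated bands (0.69 / 0.49 / 0.12), ordinal 1–7 ratings
from a thresholded latent response, and lexical-decision RTs from a
log-normal model with a negative similarity (facilitation) effect. The test
suite uses this planted truth to verify that the selector finds the best
space and that its generalization estimates are honest.

The stimulus-design modules implement the supporting experimental
machinery: top-k cosine candidate generation, condition-band verification,
rating-threshold triplet filtering (strict bounds: strong > 4,
3 < weak < 5.5, unrelated < 2), counterbalanced 5-block survey partitioning
(no target repeated within a block), Latin-square rotation of prime
condition across six lexical-decision lists, and pseudoword generation by
same-category letter substitution with bigram/trigram legality checks
(Polish vowel inventory included, overridable).

## Worked example

```python
from semsel import GeneratorConfig, make_world, build_tasks, nested_cv

world = make_world(GeneratorConfig(seed=11))      # 264 triplets, 5 spaces
tasks, _ = build_tasks(world, seed=11)            # simulate + preprocess
result = nested_cv(tasks, world.spaces, k_outer=5, k_inner=5, seed=11)

print(result.chosen_space_id)
print(result.scores.round(3))
for task, est in result.outer_estimates.items():
    print(f"outer-loop R2 [{task}]: {est:.3f}")
```

prints (space_01 is the planted-best candidate):

```
space_01
          ldt_logrt  ratings  simlex_relatedness  simlex_similarity
space_01      0.146    0.722               0.673              0.089
space_02      0.139    0.635               0.638              0.077
space_03      0.121    0.517               0.466              0.071
space_04      0.126    0.327               0.345              0.041
space_05      0.099    0.156               0.152              0.043
outer-loop R2 [ldt_logrt]: 0.137
outer-loop R2 [ratings]: 0.721
outer-loop R2 [simlex_relatedness]: 0.671
outer-loop R2 [simlex_similarity]: 0.063
```

The score table is the full-data inner loop: held-out R² per space and
task. The planted-best space tops every task, and its margin shrinks down
the fidelity ladder. The outer-loop numbers are the nested-CV estimates of
how the *selected* model generalizes — slightly below the table's best
values, as an honest estimate should be.

The same pipeline is scriptable from the shell:

```
semsel simulate --seed 3 --out world/
semsel select-space --data-dir world/ --space world/space_*.txt --out sel/
semsel preprocess --trials world/ldt_trials.tsv --out prep/
semsel overfit-demo --data-dir world/ --space world/space_*.txt --out demo/
```

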