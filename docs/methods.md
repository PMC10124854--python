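# Methods

This note documents the models, algorithms, and numerical choices behind
`semsel`: what each component assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Evaluation model

A candidate semantic space is evaluated by how much held-out variance its
cosine similarities explain in a prediction task. For each task an OLS
model is fit:

* **ldt_logrt** — mean log lexical-decision RT per prime–target pair,
  predicted from four baseline covariates (Zipf frequency and letter
  length of prime and target) plus the cosine. Pair-level aggregation is
  the default: the per-trial noise of a lexical decision (~0.19 on the log
  scale) swamps the similarity signal at the single-trial level, while
  pair means over ~12 subjects leave a measurable effect. A per-trial
  variant is available (`build_tasks(ldt_per_trial=True)`); folds always
  split at the pair level so all trials of a pair stay on one side of any
  split (trials of one pair are exchangeable — splitting them would leak
  item identity).
* **ratings** — mean 1–7 relatedness rating per pair, cosine only.
* **simlex_relatedness / simlex_similarity** — per-pair norms from a
  SimLex-999-style table, cosine only.

Held-out R² is `1 − SS_res/SS_tot` with SS_tot about the **test-set**
mean; it may be negative. This is the honest out-of-sample definition: a
model that predicts worse than the test mean has explained nothing.

**Coverage.** Spaces differ in vocabulary. A space must cover ≥ 95% of a
task's pairs (configurable); evaluation is restricted to covered pairs and
a space below the threshold is disqualified for that task (recorded, given
the worst rank) rather than silently scored on a shrunken item set, which
would make R² values incomparable across spaces.

## Selection

Within each task, spaces are ranked by R² descending (rank 1 best,
midranks for ties; disqualified spaces get the worst rank). The winner has
the lowest average rank across tasks; winner ties break lexicographically
by space id, so selection is deterministic. Rank aggregation runs inside
the inner loop (it *is* the selection criterion); task subsets (e.g.
behavioral tasks only) are supported for reporting.

Nested cross-validation uses k_outer = 5 and k_inner = 5 by default. Per
outer fold: the inner loop scores every space on every task using only the
outer-training pairs; the rank-aggregate winner is refit on the full
outer-training portion and scored on the outer-test fold. Outer-test data
never touch selection — verified structurally in the tests. The per-task
mean of the outer-fold scores (`outer_estimates`) is the generalization
estimate; it is intentionally a likely lower bound, since each fold's
model is fit on 80% of the data and different folds may select different
spaces. A final inner loop on the full data names the single space to
publish, because the outer loop alone does not (its five iterations may
each select a different space).

Folds are balanced random partitions (sizes differ by ≤ 1), derived per
task from the root seed via named substreams, so every task keeps its own
reproducible split and adding a task never perturbs another's folds.

`overfit_demo` implements the cautionary contrast: select the space with
the best *training* R² on one task with no split, then report its
cross-validated held-out R² and its scores on the other tasks. With many
candidate spaces the training number is mostly selection bias.

## Stimulus design

* **Survey blocks.** Each triplet contributes one pair per condition, and
  all three pairs contain the same target, so they must land in three
  distinct blocks (hence ≥ 3 blocks). Per-condition block quotas are equal
  blocks rounded up to a multiple of six with the shortfall in one final
  short block (264 triplets over 5 blocks → 54/54/54/54/48 per condition,
  i.e. blocks of 162 pairs and one of 144), falling back to a balanced
  split when the rounding is infeasible. Assignment is a randomized greedy
  with retries: triplets in random order, each condition draws a block
  with remaining quota (probability proportional to remaining quota) among
  blocks unused by that triplet. This is one valid realization of the
  layout; the constraints, not the algorithm, are the contract.
* **LDT lists.** Targets are split into two sets; each set's triplets are
  divided into three groups, and list *j* of a set assigns group *g* the
  condition (g + j) mod 3 — a Latin square, so across a set's three lists
  every target meets each of its three primes exactly once. Every list
  carries the same filler pairs (so related and unrelated word trials
  balance) and all pseudoword trials, whose primes are checked never to
  occur among experimental or filler words. Trial order is shuffled per
  list from the seed.
* **Rating filter.** Thresholds are strict (ratings "above 4" / "below 2"
  fail at the boundary). Triplets whose weak prime out-rates the strong
  prime are flagged as inversions but not auto-repaired: choosing
  replacement primes is a judgment call the tool leaves to human judges.
* **Pseudowords.** One letter is replaced by a letter of the same class
  (vowel/consonant; Polish vowel inventory a ą e ę i o ó u y by default).
  Candidates are tried in seeded random order until n are valid or the
  substitution space is exhausted; a candidate fails if it is a real word
  or contains an unattested bigram or trigram (legality sets default to
  the n-grams attested in the supplied lexicon). Every tried candidate is
  returned with its rejection reason.

## Preprocessing

* Participant exclusion: |z| > 2.5 of a per-subject summary statistic
  (grand mean by default, configurable), z computed against the sample
  mean/SD (ddof = 1). Note the arithmetic bound |z| ≤ (n−1)/√n: with few
  subjects a 2.5 SD rule cannot fire.
* Trial exclusion: RT < 250 ms (anticipations), or more than 2.5 SD from
  the participant-by-condition mean or the item-by-condition mean. The
  two SD rules combine as a union by default ("or"); an intersection
  switch exists. Cells with < 2 trials are skipped for the SD rule.
  Kept + removed always partition the input.
* Inverse transform: −1000/RT, monotone increasing with speed, so
  facilitation keeps its negative sign in regression on transformed RTs.
* Contrast coding: sum-to-zero deviation coding for the three-level
  condition factor with unrelated as baseline (strong 1/0/−1,
  weak 0/1/−1); two-level factors code as ±0.5.

Mixed-effects estimation is deliberately out of scope; the module emits
model-ready tables and descriptive summaries (condition means/SDs, priming
effects, the rating–RT correlation).

## Synthetic generator

The generator is the package's ground-truth instrument. A world contains:

* a **clean embedding** of unit vectors (default dimension 50) over a
  pronounceable synthetic lexicon (consonant–vowel alternating strings,
  lengths 4–9, Zipf values clipped to 1.1–5.5);
* **triplets** whose primes are constructed as
  `cos·t̂ + √(1−cos²)·ŵ` with the cosine drawn from the condition band
  (centers 0.69 / 0.49 / 0.12, SDs 0.07 / 0.04 / 0.13, clipped to the
  observed ranges) — so the clean-space cosine of each pair is planted
  exactly;
* **candidate spaces**: clean vectors plus isotropic noise of total
  relative magnitude `noise_sds[i]` (defaults 0.10, 0.45, 0.80, 1.15,
  1.50), so cosine fidelity to the truth strictly decreases down the
  ladder; space 1 is the objectively best candidate, asserted at
  generation time on sampled pairs.

**Ratings** come from a latent-variable ordinal model (matching how such
scales are analyzed with cumulative-link models): latent =
intercept + slope·sgn(s)|s|^0.7 + subject shift + noise, discretized
through six cutpoints at 1.5…6.5. The mild convexity (power 0.7) reflects
the compression of rating scales near "completely unrelated"; the slope
and intercept are the closed-form line through the calibration anchors
(condition means 5.73 and 4.14 at cosines 0.69 and 0.49), and noise SDs
(subject 0.20, residual 0.55, pair idiosyncrasy 1.20) are set so that the
ratings task's ceiling R² lands near 0.75 rather than an unrealistically
clean 0.95 — human ratings carry stable pair-specific variance no cosine
can explain.

**Lexical decisions** come from a log-normal RT model:
log RT = 6.564 − 0.04·Zipf_target + 0.008·len_target − 0.01·Zipf_prime +
0.002·len_prime − 0.076·similarity + subject shift (SD 0.08) + item shift
(SD 0.05) + residual (SD 0.16), exponentiated and censored at the 1000 ms
response deadline (a censored trial is a timeout and counts as an error).
Errors are injected at 2.2% and 0.5% of trials become sub-250 ms
anticipations so the preprocessing rules have genuine targets. The
intercept and similarity slope are the closed-form inversion of the
lognormal mean through the calibration anchors (condition means
613 / 644 ms at cosines 0.69 / 0.12), with a small correction for the
anticipation/censoring/trimming shift; a linear-in-cosine log-RT model
cannot also place the weak condition exactly at 630 ms (it lands near
625), which is within the ±10 ms the calibration checks use. Pseudoword
trials draw from a slower baseline (log 700 ms) with no similarity term.

**SimLex tables** mix planted triplet pairs (covering the full similarity
range) with random vocabulary pairs; relatedness tracks the true
similarity closely, similarity mixes in an independent component and more
noise — mirroring how much harder similarity norms are to predict than
relatedness norms.

What the generator does **not** emulate: morphology and real lexical
statistics (words are random strings; frequency is independent of length
and similarity), associative vs. feature-based relatedness distinctions,
rater response styles beyond an additive shift, sequential/practice
effects within the LDT, and any nonlinearity between cosine and RT beyond
the log link. Passing tests therefore show that the pipeline's logic and
estimates are sound under its stated statistical assumptions, not that
those assumptions hold for any particular human dataset.

## Problem sizes and replication counts

End-to-end properties are measured on scaled-down worlds (60 triplets,
12 LDT subjects, 20 raters, 150 SimLex pairs, 5 spaces) chosen so that a
full generate–simulate–select cycle runs in ~0.2 s and hundreds of
replications are cheap; the structure (5 spaces, 3 conditions, 4 tasks,
5×5 nested folds) is identical to the full design. Parameter-recovery and
calibration-to-norms checks run at the published scale (264/216 triplets,
72 subjects). The planted-winner decay test reuses the same world seeds
across separation ladders (common random numbers), which makes the
monotonicity comparison paired and well-powered at five levels.

The ground truth for the estimate-calibration check is Monte-Carlo: the
selected model is refit on the observed tasks and scored on a fresh draw
of the same datasets from the same world (new subjects, new noise, new
pair idiosyncrasies). A strict closed form is intractable through the
ordinal discretization and the RT censoring; the fresh-draw estimate is
unbiased for the quantity the outer loop claims to estimate and is
computed by an independent code path.

## Numerical choices and degenerate inputs

* Cosines are clamped to [−1, 1] after division; neighbor ties break by
  vocabulary index (stable, documented).
* Zero-norm or non-finite vectors are excluded at load time and reported;
  duplicate words in an embedding file either raise or keep-first by flag.
* OOV lookups are legal everywhere and always flagged
  (`missing_reason`), never silently dropped.
* OLS raises on rank deficiency and names the collinear columns
  (incremental projection test at 1e−8 relative tolerance).
* `r2_heldout` refuses zero-variance test sets; fold construction refuses
  n < k; the nested loop refuses tasks too small for 2·k_inner items in
  the outer-training portion.
* Exact-match word lookup by default with an optional lowercase-fallback
  flag (off): in a cased language, silently case-folding changes meanings.
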