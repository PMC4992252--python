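# Methods

## The method in brief

Given a labeled matrix *DS* of *N* continuous features and class labels
*CL*, the package pre-evaluates all C(*N*, 2) unordered feature pairs: each
pair (*i*, *j*) receives the cross-validated accuracy *v<sub>ij</sub>* of a
classifier trained on those two columns only. The table of
(*i*, *j*, *v<sub>ij</sub>*) rows, sorted by accuracy descending (ties by
(*i*, *j*) ascending), is a reusable summary of second-order structure:
high rows are pairs that jointly separate the classes, whether because both
members are strong, because they complement each other, or because they
interact in a way no marginal statistic detects. Classic selection
algorithms are then modified to consult the top *T* rows of this table.

Only pairs are evaluated; triples and larger subsets are out of scope, as
is any redundancy-removal step inside the modified algorithms.

## Pipeline stages and defaults

**Pre-filter.** Plug-in mutual information (base 2) between each binned
feature and the class; the best *n* features are kept (*n* = 1000 by
default for full-scale data). Binning defaults to equal-frequency with 5
bins — robust for skewed expression values; equal-width is available. The
screen keeps exactly the MI arg-max set, ties broken by ascending original
index, and is idempotent: screening to *n* then to *m ≤ n* equals screening
to *m* directly.

**Pair table.** Default evaluator: linear-kernel SVC (C = 1) under LOOCV,
features standardized with training-fold statistics only. Stratified
5-fold is offered as a fast mode for large *N*; the table file records the
evaluator and CV scheme in its header so cached tables built under
different settings are never silently mixed. Pairs are enumerated in
lexicographic order, evaluated in order-preserving chunks (joblib), and
globally sorted, so the output is identical for any worker count. The
bundled experiments build tables with the KNN evaluator instead: KNN LOOCV
has a closed-form fast path (below) and responds to non-additive structure
such as an XOR pair, which a linear margin cannot express at all.

**Modified filters (reordering).** With base ranking CHOSEN and the top-*T*
rows *P*: pop the head *f* of CHOSEN and append it to MCHOSEN; scan *P* in
table order and, for each row containing *f* whose partner is still in
CHOSEN, append the partner and remove it from CHOSEN; repeat until CHOSEN
is empty. The output is a permutation of the input; *T* = 0 is the
identity. Partners are appended only if still unplaced (the popped feature
is already stored), and partner order follows table order. A feature can
therefore only be promoted by partnering an already-placed feature — a
real and consequential property discussed under Limitations.

**T, the pool size.** The reordering and the pair-driven searches consult
only the top *T* rows (default 1000). *T* should remain a small fraction
of the table: on full-scale data, 1000 of 499,500 rows (0.2%). Taken over
most of the table the procedure degenerates — the first popped feature
pulls in nearly every partner ordered by noisy two-feature accuracy and
destroys the base ranking. The bundled profile-gain study therefore uses
*T* = 50 on its 4,950-row tables (1%), the same order as the full-scale
default.

**Modified forward search.** Moves are generated from the top-*T* rows: a
row (*i*, *j*) proposes adding {*i*, *j*} \ CHOSEN — one or two new
features; rows inside CHOSEN are skipped and duplicate new-sets are
evaluated once. The best move by cross-validated accuracy is accepted while
it strictly improves on the current accuracy (empty-set baseline 0, so the
first accepted move is the best whole row). One-feature overlap moves are
admitted, so final subsets can have odd size.

**Modified backward elimination.** The initial subset is the union of
features occurring in the top-*T* rows; ordinary backward elimination then
runs restricted to it (removals accepted while accuracy does not drop,
stopping when every removal strictly hurts or one feature remains). With a
pool covering all rows this is exactly the original algorithm. The
union-initialization is an interpretation (the pseudo-code for this variant
was never published) and is isolated in one function so alternatives can be
swapped.

**Modified mRMR.** Same move generation, scored by the summed MID
criterion of the new features against the current selection,
Σ<sub>x∈move</sub> [I(x; C) − mean<sub>s∈S</sub> I(x; s)] on binned codes.
No stopping rule: moves are accepted until exactly *m* features accumulate;
a final two-feature move that would overshoot is truncated, keeping its
higher-relevance member.

**Baseline algorithms.**

* chi-squared: Pearson statistic on the binned-feature × class contingency
  table, no continuity correction; empty rows/columns are dropped.
* gain ratio: [H(C) − H(C|F)] / H(F), log base 2; 0 when H(F) = 0.
* ReliefF: deterministic full pass over all instances (no sampling),
  *k* = 3 neighbors by default, Manhattan distance on range-scaled values;
  miss contributions weighted by the class prior renormalized over the
  other classes; per-feature differences scaled by feature range. Chosen
  over sampled Relief because target data may have up to 4 classes and the
  deterministic pass removes a needless source of variance.
* FSDD (distance discriminant): on z-normalized values,
  J = Σ<sub>c</sub> p<sub>c</sub>(μ<sub>c</sub> − μ)² − β
  Σ<sub>c</sub> p<sub>c</sub>σ<sub>c</sub>², β = 2 by default; constant
  features score 0; z-normalization makes J affine-invariant.
* forward search / backward elimination: greedy wrappers driven by
  cross-validated accuracy. Forward requires strict improvement (mirroring
  "maximizes the increase"); backward accepts accuracy-preserving removals
  (mirroring "least reduces"), which lets it pass redundant features
  instead of stalling.
* mRMR (MID): first pick maximizes I(F; C); later picks maximize relevance
  minus mean redundancy; exactly *m* features, no stopping rule.

Every score tie anywhere breaks by ascending feature index; rankings with
scores are sorted descending with that tie rule, so all algorithms are
deterministic (the random forest evaluator is seeded through `EvalConfig`).

## Evaluation protocol and numerical conventions

LOOCV is the canonical reporting protocol: every reported accuracy is a
multiple of 1/n. KNN defaults to *k* = 3, Euclidean distance on
training-fold-standardized values. Tie handling: every training point tied
with the *k*-th smallest distance joins the vote (so in the all-constant
degenerate case KNN behaves as a training-set majority vote, and LOOCV on
balanced binary constants scores exactly 0 — each left-out sample's own
class is the training minority); vote ties break to the lowest class label
in sorted order.

The KNN-LOOCV fast path is exact, not approximate: standardizing with
training-fold statistics shifts all points per feature by the same amount,
so only the per-fold scale 1/σ enters test-to-train distances; per-fold
variances come from leave-one-out moment updates and all folds share one
squared-difference tensor. A unit test pins its equality with an explicit
fold loop. Fold-constant features get σ = 1 to avoid division by zero.

Equal-frequency bin edges are interpolated quantiles with lower-open
digitization; the induced partition commutes with strictly monotone
transforms. Equal-width edges are upper-inclusive. Constant features map
to a single code.

Accuracies in pair-table files are printed with 6 decimals; reading a
written table reproduces rows and order exactly at that precision.

## The synthetic generator

`SyntheticSpec` plants four roles in a Gaussian matrix: **univariate**
features (class means shifted by `effect_size` SDs, default 1.0 — a clear
but noisy marginal effect, adjacent classes one shift apart for 3+
classes); **XOR pairs** (class = sign(x·y), optionally flipped with
`label_noise_rate`; each member is exactly standard normal marginally and
independent of the class, the canonical interaction invisible to every
univariate filter in scope); **redundant** features (parent + Gaussian
copy noise, default SD 0.3, emulating co-regulated genes); and **noise**
(standard normal). Labels are balanced and shuffled; identical specs give
identical bytes.

What it does *not* emulate: platform/probe-level noise models, heavy-tailed
intensity distributions, batch effects, correlated noise, class imbalance.
Passing tests show the algorithms exploit planted second-order structure
under clean Gaussian conditions; they do not certify gains on any
particular real dataset.

## Bundled studies (sizes chosen to run in minutes on one CPU)

* **Interaction recovery** — 10 datasets: 1 XOR pair + 10 univariate
  (effect 1.0) + 40 noise features, n = 200; full 1,326-row KNN tables.
  Measured: the planted row ranks in the top 5% of the table (it is
  typically row #1), the modified forward search's first accepted move is
  the planted pair, and the original chi-squared top-10 misses at least
  one member.
* **Profile gain** — 20 datasets: 25 signals (effect 0.6) + 2 noisy copies
  each + 25 noise, n = 100; *T* = 50 of 4,950 rows. Measured: mean top-25
  LOOCV linear-SVM accuracy of the pair-reordered chi-squared ranking
  versus the original. The mechanism is diversification: parent-copy pairs
  score no better than the parent alone, while distinct-signal pairs score
  higher, so the reordering pulls complementary signals together.

## Known limitations

* **Promotion requires a placed partner.** The filter reordering can only
  pull a feature up when it pairs highly with an already-placed feature.
  A pair whose members are *both* marginally uninformative (an XOR pair)
  tops the table but is not promoted into the head of the reordered
  ranking: its row is consulted only when one member is popped, which
  happens late for buried features. Interaction rescue of fully buried
  pairs is provided by the pair-driven *searches* (forward/mRMR variants),
  not by the filter reordering.
* **The profile effect is small and condition-dependent.** The top-25 gain
  from reordering is positive on redundancy-heavy data but near zero on
  average across seed sets, and reordering *hurts* when the data carry no
  redundancy or interaction (the pair estimates then add pure variance) or
  when *T* is a large fraction of the table. Use the reordering when
  second-order structure is plausible, and keep *T* in the table's head.
* **The evaluation classifier bounds what pairs can contribute.** Features
  useful only through a non-linear interaction help KNN or random-forest
  tests but cannot help a linear SVM; table evaluator and test classifier
  should be chosen together.
* **Cost.** The table stage is O(N² · CV); it parallelizes and is cached,
  but dominates runtime for N near 1000 — hence the MI pre-filter.
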