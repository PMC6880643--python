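# Methods

This note documents the model and procedure implemented by `dgselect`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

Given a numeric matrix `X` (n samples × m attributes, typically n ≪ m) and
a class label per sample, find a small attribute subset whose expression
values discriminate the classes. The method is a *wrapper*: candidate
subsets are scored by an actual classifier rather than by a filter
statistic, and an evolutionary search proposes the candidates. Its
distinguishing feature is that the candidate pool itself (the *terminal
set*) shrinks as the search proceeds, so late generations search a space
orders of magnitude smaller than the original attribute universe.

## Chromosomes and decoding (karva notation)

A gene is a fixed-length string: a head of `h` symbols drawn from functions
∪ attributes, and a tail of `t = h(n−1) + 1` attributes, where `n` is the
maximum arity in the function set (`{+, −, *, /}` binary and `Q` unary by
default, so `n = 2`). The tail rule guarantees breadth-first decoding always
closes into a tree. Decoding is level-order: position 0 is the root, each
function consumes the next `arity` unread positions as ordered children,
and decoding stops when no slots remain open. Only the prefix actually
consumed (the K-expression) matters; a gene's *expressed* attributes are
the distinct leaves of its tree.

Terminals are allowed at the root (a one-attribute gene) — nothing in the
encoding forbids it, and with large pools it is the common case. Trees are
never evaluated arithmetically: the classifier is trained on the raw
expression values of the expressed attributes, so functions act purely as
arity-bearing connectors that determine how many and which terminals a gene
expresses. Consequently no protected-division or domain-guard rules exist.

Chromosomes serialize to a plain-text dialect (symbols space-separated,
genes joined by `|`), and the reader infers `h` from the gene length via
`g = h·n + 1`.

## Attribute weighting (gain ratio)

Each attribute is ranked exactly once, before the loop starts, by the gain
ratio of its best single binary split: sort the values, consider thresholds
at midpoints between consecutive distinct values, take the threshold with
maximum information gain (ties → lowest threshold), and divide that gain by
the split's intrinsic information. Entropies are in bits. A constant
attribute ranks 0; if every rank is 0 the table falls back to uniform
weights with a warning. Ranks are normalized to weights summing to 1.

A single binary split (C4.5 style) was chosen over multi-interval
discretization for determinism and speed; it is scale-invariant (depends
only on the value ordering) and adequate for ranking mean-shifted
attributes. Multi-interval or MDL-based discretization is out of scope.

## Fitness

```
f = (1 − r)·AC + r·(t − s)/t
```

* `AC` — mean accuracy of `SVC(kernel="linear", C=1)` under stratified
  k-fold cross-validation (k = 5 by default, reduced to the smallest class
  size when necessary) on the expressed attributes;
* `s` — number of expressed attributes; `t` — current terminal-set size;
* `r ∈ [0, 0.5)` — size-penalty weight, default 0.2. Keeping `r` below 0.5
  means accuracy always dominates; the penalty is a tiebreaker toward
  parsimony. `s > t` is permitted (a chromosome carried over from a larger
  pool); the penalty then goes negative and selection removes it.

The linear kernel with C = 1 is the no-tuning default appropriate for
n ≪ m expression data; any scikit-learn classifier can be substituted via
`RunConfig.classifier`. With the default classifier the five fold fits go
through scikit-learn's low-level libsvm binding — the same solver `SVC`
wraps — because a selection run scores thousands of subsets and the
high-level estimator API spends ~50× the solver time on input
(re)validation; a test pins exact fold-for-fold agreement between the two
routes.

Two determinism measures: (1) samples are put into a canonical order
(lexsort by class, then feature values) before folds are built, so the
estimate is invariant to input row order; (2) fold seeds derive from the
run seed and the generation index, so a run is bit-reproducible while
fold-luck cannot persist across generations (accuracies are cached per
expressed subset within a generation and re-estimated in the next one).

## Generation sizing

Head size is recomputed from the current pool size every generation:

```
h = max(h_min, round_half_away((T/CH − 1)/n)),    h_min = 3
```

derived from the coverage target `L·CH = 2T` with `N = 2` genes per
chromosome (`L = N(h + t)`): the positional content of a generation should
cover the pool about twice, so every attribute keeps a realistic chance of
being carried forward. Rounding is to the nearest integer (halves away from
zero) because nearest-integer sizing tracks the 2T target more closely than
truncation; `h_min = 3` keeps genes structurally non-trivial. The
denominator generalizes to the configured maximum arity `n`.

## The evolutionary loop

Generation 1 is drawn uniformly at random over the full attribute universe
(heads uniform over functions ∪ pool, tails uniform over the pool). Then,
each generation:

1. **Mutate** — each chromosome except the rank-0 elite triggers with
   probability `min(1, 0.044·L)` (a per-position rate folded into a
   per-chromosome trigger). A triggered chromosome has its single
   weakest-weight terminal replaced: in the head, by a function with
   probability ½ and otherwise by a uniformly chosen strictly
   higher-weight terminal from the pool; in the tail, by a stronger
   terminal only (no stronger terminal → head falls back to a function,
   tail leaves the chromosome unchanged).
2. **Recombine** — disjoint random pairs from the ranked top half, each
   used with probability 0.3. The lower-fitness parent donates its
   highest-weight-sum gene into the higher-fitness parent's
   lowest-weight-sum slot; the child is kept only if it strictly beats
   both parents, retrying with the donor's next gene otherwise.
3. **Re-rank** (descending fitness, ties → smaller subset, then stable)
   and log `T, h, best f/AC/s`.
4. **Extract** the next terminal set: the union of attributes carried by
   the top half, ordered by descending weight. By default *all* terminal
   positions count (head and tail, expressed or silent), so attributes the
   search has not yet expressed stay alive; `extraction="expressed"`
   restricts to expressed attributes and contracts much harder. Either
   way the new pool is a subset of the old one — contraction is monotone
   by construction.
5. **Terminate?** If the pool and the best chromosome's expressed subset
   are both unchanged for `patience` (3) consecutive generations, stop
   with reason `stagnation`; at `max_generations` (200), stop regardless.
   Stability of the selected set is the operative convergence signal
   because accuracy estimates are deliberately re-randomized each
   generation and their exact values fluctuate by CV noise.
6. **Reproduce** — the next population is `CH/2` fitness-proportionate
   (roulette, with replacement) copies drawn from the ranked top half,
   plus `CH/2` fresh random chromosomes over the new pool with the
   recomputed head size. Copy takeover is the mechanism that collapses
   the pool onto the best chromosomes' attributes; the fresh half keeps
   exploring inside the shrinking pool. Copies retain their structure
   even if `h` has changed (chromosome length is flexible across a
   population); gene swaps in recombination skip structurally mismatched
   donors so each chromosome stays internally uniform.

The reported selection is the expressed subset of the final generation's
best chromosome — the solution the population converged to. The best
fitness value ever observed is also reported (`RunResult.best_ever`), but
it is not the selection criterion: fitness values from early generations
are inflated relative to late ones because the penalty term is normalized
by the then-larger pool, and argmax-over-everything amplifies
cross-validation luck.

Design choices that were genuinely open, and why they fell this way:

* **Reproduction vs. fresh regeneration.** Regenerating the whole
  population from the pool each generation cannot collapse the pool below
  the positional coverage of the top half (a union of distinct random
  chromosomes over a small pool spans nearly all of it), and it re-rolls
  every discovery. Reproduction with replacement from the top half gives
  the observed deep contraction and preserved, across the synthetic
  benchmark seeds, both precision and convergence; it is also the standard
  GEP engine this method descends from.
* **All-positions extraction (default).** Expressed-only extraction
  discards most of the attribute universe in the first generations (a
  random chromosome over a large pool expresses only ~N attributes), which
  measurably loses planted attributes before they are ever tried.
* **Per-generation fold reseeding.** With folds frozen for a whole run,
  whichever subset gets lucky on those folds keeps its inflated score
  forever and wrapper argmax returns noise; reseeding makes luck
  transient while truly informative subsets keep their rank.
* **Termination on selected-set stability** rather than exact fitness
  equality, which per-generation reseeding makes unattainable; when folds
  are frozen the two are equivalent.

## Synthetic data

`SyntheticSpec` emulates the shape of a small two-class expression study:
`n_samples = 60`, `n_attributes = 500`, `n_informative = 5` attributes
shifted by `effect_size = 2` noise standard deviations in the "case"
class, `noise_sd = 1`, balanced Bernoulli labels. Background attributes
are i.i.d. Normal(0, noise_sd²) and independent of class.

The generator does **not** emulate: correlated attribute blocks
(co-expression), heavy-tailed or heteroscedastic noise, batch effects,
class-imbalanced designs, multi-class problems, or attributes informative
only in combination (interactions). Passing the benchmarks therefore shows
the search machinery recovers independent mean-shifted signal at realistic
dimensionality — not that the method handles correlated or interaction
structure in real microarray data.

## Numerical and degenerate-input choices

* Log base 2 throughout the entropy arithmetic; gain-ratio threshold ties
  resolve to the lowest threshold; weight ties order alphabetically by
  attribute ID.
* Ranking ties: equal fitness → smaller expressed subset → earlier
  position (stable).
* All randomness flows from one `numpy.random.Generator` seeded with
  `RunConfig.seed`; CV fold seeds derive from it.
* Degenerate inputs fail before the loop: a constant matrix, a single
  class, or a class with fewer than 2 samples raise immediately. A class
  smaller than the fold count reduces the fold count with a logged notice.
* Loader: delimiter sniffed from the header (comma/tab/semicolon); floats
  parsed round-trip-exactly; per-attribute missingness ≤ 5% is
  mean-imputed with a logged count, more is rejected; duplicate IDs,
  unmatched label IDs and non-numeric cells are named in errors.

## Known limitations

* **Selection bias.** The selected subset's cross-validated accuracy on
  the same samples used for selection is optimistically biased — at
  n = 60 the inflation is roughly +0.2 over chance on label-permuted data,
  simply because thousands of candidate subsets were compared. Report
  panel accuracy on held-out samples.
* **Recall is not the objective.** The size penalty and pool collapse
  favor the smallest high-accuracy subset; redundant informative
  attributes are deliberately dropped (the worked example recovers a
  2-of-5 planted panel at precision 1.0).
* Stochastic search: different seeds can return different (equally
  accurate) panels; stability across seeds is itself informative.
* Binary classification is the primary target; multi-class inputs work
  (accuracy generalizes; confusion counts are binary-only) but are not
  benchmarked.
* Runtime scales with `CH × generations ×` (CV cost of small SVMs); the
  60 × 500 reference setting runs in a few seconds per run on one CPU.
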