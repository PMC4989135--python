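# Methods

## The problem

Expression studies routinely produce matrices with tens of samples and
thousands of genes, of which only a handful separate the sample classes.
Wrapper feature selection searches the space of gene subsets directly,
scoring each candidate by the cross-validated accuracy of a classifier
restricted to it. The search space is `2^n` and each score costs a full
cross-validation, so the search strategy and the evaluation budget are
the whole game.

## The algorithm

HICATS is a hybrid of a binary imperialist competition algorithm (a
multi-population evolutionary search) with tabu search (a short-memory
local search applied to each sub-population's leader).

**Encoding.** A candidate solution ("country") is a bit vector over the
genes; bit `i` set selects gene `i+1`. Countries are repaired to select
at least one gene, since the fitness is undefined on an empty subset.

**Fitness.** A subset `X` with `D` selected genes out of `n` scores

    fitness(X) = w1 * A(X) + w2 * (n - D) / n,      w2 = 1 - w1

where `A(X) ∈ [0, 1]` is the cross-validated accuracy of the classifier
on the selected columns. `w1 = 0.8` weighs accuracy four times as
heavily as parsimony. Accuracy is leave-one-out by default; a stratified
k-fold mode trades a little estimator variance for a k/n-fold cost
reduction and is what the test-suite experiments use (`k = 5`).
Evaluations are memoised by exact bit pattern (the search revisits
patterns constantly), the number of true classifier-fit passes is
logged, and the best country ever evaluated is archived so reported
results cannot regress.

**Empire initialisation.** `n_pop = 15` random countries are drawn with
initial selection density 0.1 per gene, evaluated, and ranked. The top
`n_imp = 4` become imperialists; the other `n_col = 11` are dealt to
them as colonies in proportion to min-shifted, normalised imperialist
fitness, `round(p_m * n_col)` each. Two repairs make this well defined:
rounding surpluses/deficits are settled against the entries with the
largest fractional remainder, and every empire is floored at one colony
(the min-shift otherwise guarantees the weakest imperialist starts with
zero colonies and dies on the first competition step, collapsing the
multi-population structure immediately). When all imperialists tie,
powers fall back to uniform rather than 0/0.

**Assimilation.** Each generation every colony moves toward its
imperialist: the asymmetric difference (genes the imperialist has and
the colony lacks) is computed; a learning rate `beta ~ U(0,1)`, redrawn
per colony per generation, sets the transfer count `round(beta * |diff|)`
(halves up), sampled uniformly from the difference; a fair-coin template
of length `max(|IM|, |CO|)` is drawn and its complement masks which of
the colony's own genes are kept (ascending gene order against template
positions). The new colony is the union of transferred and kept genes.
In expectation the colony keeps half its genes and gains `beta * |diff|`,
so subsets shrink toward small informative cores — this, not the fitness
size term alone, is the main dimension-reduction mechanism. The template
family also defines an imperialist-side mask (IMBT); it is constructed
but deliberately unused, because the operator's published worked
arithmetic is fully explained by the transfer plus the colony mask.

**Tabu refinement.** Each imperialist is refined by `ts_iters = 5` tabu
steps per generation. A step samples `ts_neighbors = 20` distinct
single-bit flips (full neighbourhoods are hopeless at microarray
dimension), evaluates them, and moves to the best admissible neighbour
even when it is worse than the current point; a flipped position is
tabu for `ts_tenure = 7` subsequent steps unless the move would beat the
best fitness seen so far (aspiration). The best visited country is
returned, so refinement is monotone at the imperialist level. With
tenure 0 and a full neighbourhood a step reduces exactly to steepest
ascent, which the tests exploit as an oracle. Neighbourhood size, inner
iterations and tenure are tuning knobs with no canonical values; the
defaults are sized so refinement costs ~100 evaluations per imperialist
per generation.

**Competition.** After assimilation, a colony that out-scores its
imperialist swaps roles with it. Empire total power is
`imperialist fitness + xi * mean(colony fitness)` with `xi = 0.1`
(colonies matter, but weakly). The weakest empire's weakest colony is
transferred to a winner drawn with probability proportional to
min-shifted total power, the loser excluded; empires left without
colonies are dissolved and their imperialist demoted to a colony of the
strongest survivor. Demotion rather than deletion keeps the population
at exactly `n_pop` for the whole run, which the per-generation log
asserts. The empire count is therefore non-increasing and the search
anneals from multi-population exploration to single-population
exploitation.

**Stopping.** A fixed budget of 50 generations; no early stop. The
result is the archived best country, its accuracy, subset size and the
per-generation convergence log (elitist best fitness/accuracy/size,
population mean fitness, cumulative classifier fits, population and
empire counts).

## Classifier choice

The default evaluator is a linear support-vector machine
(`sklearn.svm.SVC(kernel="linear")`, C = 1), i.e. libsvm with its
pairwise multiclass scheme. A one-vs-rest linear variant (`svm-ovr`),
3-nearest-neighbours and nearest-centroid are selectable. The pairwise
scheme is the deliberate default for multiclass data: when class means
are ordered along a shared direction — exactly the structure of graded
biological signals and of this package's synthetic generator — the
one-vs-rest argmax has no hyperplane that isolates interior classes and
its accuracy saturates below 1 even on cleanly separable data, while
pairwise voting separates every class pair. Features are standardised
per fold with training-fold statistics only; no other preprocessing is
applied. No classifier hyperparameter tuning or nested cross-validation
is performed: the accuracy is a relative ranking signal for the search,
and the selection-bias caveat below applies to its absolute value
regardless.

## Synthetic data

`make_synthetic` emulates the regime of the public microarray
benchmarks this family of methods is evaluated on: tens of samples,
hundreds to thousands of genes, 2–11 classes, very few genes carrying
signal. Samples are split across classes as evenly as possible. Each
informative gene gets an additive ladder of class means
(`class c` mean `= c * effect_size * noise_sd`); everything else is
`N(0, noise_sd^2)` noise. The default spec — 40 samples, 200 genes, 5
informative, 3 classes, `effect_size = 3`, `noise_sd = 1` — keeps a
full 10-run experiment around ten minutes on one core while preserving
the defining difficulty (far more genes than samples, sparse signal).

What the generator does *not* emulate: gene–gene correlation and
co-regulated blocks, heavy-tailed and heteroscedastic expression noise,
batch effects, class imbalance beyond the remainder, and redundant
informative genes. Passing the recovery experiments therefore shows the
search machinery works on a clean sparse-signal landscape; it does not
certify accuracy numbers on real microarray data, where LOOCV-inside-
the-wrapper is also an optimistically biased estimate of generalisation
(the subset is selected to maximise exactly that statistic).

## Numerical and design notes

- All randomness flows from one `numpy.random.Generator` seeded by the
  run seed; identical seeds give bit-identical results, including the
  convergence log.
- Ranking ties (initial ranking, best colony, weakest empire, best
  neighbour) break toward the lower index, for determinism.
- `beta` is redrawn until nonzero so it lies in the open interval (0,1);
  the transfer count never exceeds the difference size.
- Stratified k-fold clamps the fold count to the smallest class size
  and falls back to leave-one-out when a class is a singleton; a
  training fold containing a single class predicts that class.
- Fold loops and train-fold standardisation are implemented directly in
  numpy around the scikit-learn estimator: the generic scoring wrappers
  spend ~3x the time per evaluation in bookkeeping, and evaluation is
  >95% of a run's cost.
- Zero-variance columns standardise to zero instead of dividing by zero.
- A flip that empties a country is repaired to a random single gene, so
  neighbourhoods never contain invalid solutions.

## Known limitations

- Wrapper accuracy is an in-search statistic, not an unbiased estimate
  of out-of-sample accuracy; use a held-out set for honest assessment.
- The tabu list is recency-only (no frequency memory, no restarts); the
  outer imperialist-competition loop is the only diversification.
- LOOCV at realistic microarray dimension is expensive; the k-fold mode
  or the `centroid` classifier are the practical choices for
  exploration, LOOCV+SVM for final reporting.
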