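# Methods

## Problem setting and model

Given a labelled matrix of n samples by p features (n ≪ p, ≥ 2 classes,
possibly strongly imbalanced), the package searches for a feature subset that
classifies held-out samples at least as well as the full feature set. The
search space is decomposed by a supervised discretization step: features for
which entropy/MDL partitioning accepts at least one cut-point are encoded as
integer cut indices and evolved by a genetic algorithm; features without
cut-points are encoded as selection bits and evolved by a binary PSO. The two
subpopulations coevolve — member i of each is combined with member i of the
other for every fitness evaluation — because cut-free features can carry
class signal only jointly, which a per-feature discretizer cannot see.

## Discretization

Candidate thresholds are midpoints between adjacent distinct sorted values
whose value-groups contain differing class labels (boundary points; the best
information gain is provably attained there, which a property test asserts
against an exhaustive midpoint scan). Per partition the maximal-gain
candidate is accepted iff

    Gain > [log2(N−1) + log2(3^k − 2) − (k·E − k1·E1 − k2·E2)] / N,

and recursion continues in both halves. Conventions fixed for
reproducibility: samples with value ≤ T go left; gain ties choose the
smallest threshold; recursion stops on partitions that are pure or smaller
than two samples. The table is built once per training fold, before the
search. A brute-force oracle (plain-Python exhaustive recursion, no shared
code) reproduces the table exactly on hundreds of random small instances.

## Fitness

fitness = β·balanced_error + (1−β)·distance, β = 0.5 by default. Balanced
error is the mean per-class misclassification rate of a 1-NN classifier fit
on the inner-training representation and evaluated on one designated
validation portion (see protocol). The representation binarizes each selected
discrete feature at its chosen cut (lower bin 0, upper bin 1) and keeps the
normalized value of each selected continuous feature; distances sum the
Hamming count over bits and the Euclidean norm over continuous values — both
parts are in comparable normalized units, which is why summation (the one
combination the method description leaves open) is used. The distance term
squashes DW − DB through 1/(1+e^{−5(DW−DB)}), where DB is the mean over
samples of the nearest different-class distance and DW the mean farthest
same-class distance, both on the inner-training samples only (a deliberate
choice; the validation samples are reserved for the error term). A solution
selecting no features receives the worst fitness (1) rather than an error.
1-NN ties resolve to the lowest training-sample index; the whole evaluation
is deterministic given a split and a solution.

## Search

* Population size N = clamp(p/20, 100, 300). Discrete codes initialize
  uniformly in [0, #cuts_f]; bits are Bernoulli(1/2); velocities uniform in
  [−Vmax, Vmax].
* GA: per-gene operation probability from the fitness rank,
  Lmin + Lmax(t)·(e^{10(r−1)/(S−1)}−1)/(e^{10}−1), Lmin = 0.25, Lmax
  decaying linearly from 0.5 to 0 over the iteration budget. Mutation draws,
  per gated gene and with probability 1/2, from N(μ, σ) with μ the mean and σ
  the absolute gap between the parent gene and the gene of the
  better-fitness one of two distinct random other individuals, rounded and
  clamped to the valid code range (σ = 0 degenerates to a copy); otherwise
  the parent gene is kept. Crossover copies each gated gene from the
  better-ranked of two distinct random others. Each parent yields one mutant
  and one crossover child; the 2N offspring are halved by the distance
  measure on their discrete-only representations (ties keep input order),
  and the gbest discrete part displaces the worst-scored survivor if
  selection would drop it, so the gbest trace is monotone.
* BPSO: v ← w·v + c1·r1·(pbest − x) + c2·r2·(cbest − x) with fresh uniform
  draws per dimension and term, clipped to ±Vmax; bits resample from
  Bernoulli(sigmoid(v)) — the position does not integrate the velocity.
* Stagnation: after 3 iterations without strict gbest improvement, a fair
  coin picks a reset — GA individuals recombine against an all-zero mate
  (pulling codes toward deselection) or the cbest attractor is zeroed for
  one velocity update. After 11 stagnant iterations the search stops; the
  stop counter is not cleared by resets (the two windows are independent;
  treating a reset as an improvement would let a stalled search run
  forever). Improvement means strictly smaller aggregate fitness; an
  absolute tolerance is exposed and defaults to 0.

## Parameters

| parameter | default | origin |
|---|---|---|
| population N | p/20, clamped to [100, 300] | published setting |
| max iterations It | 100 | published setting |
| c1 = c2 | 1.49445 | published setting |
| β | 0.5 | published setting |
| Lmin / Lmax | 0.25 / 0.5 | published setting |
| stop window | 11 iterations | published setting |
| reset window | 3 iterations | published setting |
| inertia w | 0.7298 | package choice: the Clerc–Kennedy constriction companion of c = 1.49445 |
| Vmax | 6.0 | package choice: sigmoid(±6) ≈ [0.0025, 0.9975], the conventional BPSO saturation range |

All values live in `RunConfig`; serialized reports embed the effective
config with a `source` tag (`published` / `artifact`) per field, and
re-loading a report's config reproduces the run byte-identically.

## Protocol

Two-layer stratified 10-fold cross-validation. Min-max normalization and the
cut-point table are fitted on each outer training fold only (held-out values
are clamped to [0, 1]); a `normalize_globally` escape hatch exists because
some published pipelines normalize once. Within each outer training fold one
stratified tenth is designated as the validation portion for every fitness
evaluation of that fold's search — a full inner cross-validation per
evaluation would multiply the cost by an order of magnitude for no change in
the selection signal. When the smallest class has fewer samples than the
fold count, folds fall back to non-strict stratification (per-class
round-robin dealing into the currently smallest folds) with a logged
warning.

## Synthetic data

The generator emulates the shape of public expression benchmarks without
copying any: 100 samples × 1000 features by default, four classes with
linearly increasing weights (expected 10/20/30/40 — matching the strong
imbalance and multi-class structure typical of such benchmarks, and leaving
the all-features baseline measurably below ceiling so improvements are
visible), and three planted feature kinds:

* threshold-informative (10): Gaussian class-conditionals with adjacent
  means 5 noise-sd apart — above the ~4-sd margin at which MDL acceptance
  becomes near-certain at this sample size;
* jointly-informative pairs (4 features): a class signal of 3 noise-sd along
  a 45°-rotated direction plus a shared class-free component of 8 noise-sd,
  so each marginal is ~0.37 sd-separated (MDL rejects it) while the pair is
  cleanly separable (leave-one-out 1-NN on the pair alone: 94–100%);
* pure noise elsewhere, identical across classes by construction.

What this does **not** emulate: gene–gene covariance, batch effects,
heavy-tailed counts, or weak many-gene signals. Passing the recovery study
therefore shows the search machinery works as designed on separable planted
structure, not that it matches published accuracies on real benchmarks —
those require the external matrices (the `benchmark` CLI mode runs the full
protocol on any such file).

## Numerical and degenerate-input conventions

Entropy treats 0·log 0 as 0. Constant features normalize to 0. A sample with
no same-class partner contributes 0 to DW (logged). Datasets with no
discrete or no continuous features degrade to a single-population search
with a warning. All randomness flows from one seeded NumPy generator;
same-seed runs produce byte-identical JSON reports.

## Known limitations

* With mostly cut-free features the BPSO half carries the search; its only
  selection pressure is the aggregate fitness of the combined solution, so
  bit pruning is slow and final subsets can stay large when iteration
  budgets are small (the scaled studies here use 30 iterations; stagnation
  typically stops runs after 20–45).
* The validation portion is small (a tenth of a training fold), so the error
  term is coarse for minority classes; this is inherent to the protocol at
  these sample sizes and drives early stagnation stops.
* Binarizing a discrete feature at a single cut merges classes that the
  feature's other cuts would separate; multi-class discrimination relies on
  different individuals choosing different cut indices.

## Problem sizes used in the test suite

Unit and property tests run on toy instances and 60×120 planted matrices;
the oracle-equivalence check uses 200 random instances of ≤ 40 samples and
≤ 5 distinct values. The recovery study runs 20 searches at 100×1000 with
N = 100 and a 30-iteration cap, and the acceptance script repeats a
10-dataset version of the same study; these sizes keep a full run to a few
minutes on one CPU while preserving the n ≪ p regime the method targets.
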