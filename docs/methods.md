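# Methods

## Model

`mirmeta` treats miRNA target meta-prediction as binary classification
of (miRNA, gene) pairs from up to four heterogeneous predictor scores.
Its assumptions, in decreasing order of importance:

* **Scores are monotone evidence.** After mapping each predictor's
  native range affinely onto [−1, 1] (negating miRDB first), a lower
  score always means a more probable interaction. Out-of-range raw
  scores — common in real dumps, whose extremes drift between releases
  — are clamped rather than rejected.
* **Availability is informative structure, not noise.** Which
  predictors scored a pair defines eleven disjoint strata (one
  4-predictor, four 3-predictor, six 2-predictor); each stratum gets
  its own thresholds and network. Pairs with fewer than two scores are
  out of scope.
* **Complementarity is the payoff.** The ensemble can only beat its
  parts if different predictors recover different true interactions;
  the pairwise overlap/coverage statistics in `mirmeta.metrics`
  quantify exactly this, per class.

## The voting tree

Per predictor, four cutoffs with t¹ₜ ≤ t²ₜ < t²f ≤ t¹f. Votes are
strict inequalities ("true" below the true cutoff, "false" above the
false cutoff, abstain between). Decision order: step-1 majority,
step-2 majority, then significance (aggregate distance of scores
beyond the step-2 cutoffs). Numerical conventions, all configurable:

* Aggregate distance is the **Euclidean norm** of the per-predictor
  positive margins; a plain sum is selectable (`aggregate="sum"`) since
  both readings of "distance" are defensible and differ only in rare
  multi-predictor ties.
* An exact distance tie, including the all-abstain case 0 = 0,
  resolves to **negative** — the majority class in every realistic
  stratum, so the uninformative outcome defaults to the safer call.
* Abstaining predictors contribute zero to both distances.
* The network's feature vector is the n scaled scores followed by
  (N_T1, N_F1, N_T2, N_F2, d_T2, d_F2) — n + 6 features; the
  per-predictor signed margins are exposed for diagnostics but not fed
  to the network, which would break the fixed 10/9/8 input widths.

## Threshold selection

Information gain of the split at x (groups score > x and score ≤ x) is
computed in bits, with 0·log₂0 = 0 and empty groups contributing zero.
The curve is evaluated on a 1000-point even grid over the observed
range, plus every midpoint of consecutive distinct scores when the set
has under 5000 samples, so no attainable split is missed. Spikes are
strict local maxima after merging equal-value plateaus (represented by
their lower-score end); ties rank toward the smaller score. The top
four spikes per predictor seed the initial threshold quartet (sorted
ascending → t¹ₜ, t²ₜ, t²f, t¹f), with score quantiles (10/40/60/90%)
filling in when a predictor yields fewer than four distinct spikes.

Tuning is a fixed-order coordinate walk (step-1 true → step-2 true →
step-1 false → step-2 false, predictors in canonical order miranda,
mirdb, pita, targetscan). Candidates are the spike scores plus one
grid step either side of the current value, tried nearest-first. A
move is kept when overall tree accuracy does not decrease; two
consecutive strict decreases freeze the cutoff. A step-1 move that
crosses its step-2 partner drags the partner to the nearest admissible
candidate; a step-2 move that would violate the ordering is skipped.
Consequences worth knowing:

* The returned set never scores below the initial one, and always
  satisfies the ordering invariants.
* The tuning objective is the **tree-only** accuracy: thresholds are
  fixed before any network training, keeping them cheap and
  network-independent (per-branch accuracies are available in the
  tuning state for inspection).
* For an uninformative predictor the four "largest spikes" are noise
  clustered wherever the IG wiggles; the walk cannot move its cutoffs
  far from there. This is a real limitation of spike-based candidate
  pools and the main reason the tree-only variant underperforms — the
  network stage absorbs most of it.

## The network

Fixed architecture 10/20/2 hidden/output tanh nodes. The output nodes
are tanh-activated *and then* exponential-normalized
(Oᵢᵀ = exp(Oᵢ)/Σ exp(Oⱼ)): a softmax over (−1, 1)-bounded logits.
This caps p_true at e²/(e²+1) ≈ 0.88 per component pair — an unusual
choice kept deliberately, as the bounded-logit transform is part of the
method's definition; it does not affect the 0.5 decision threshold.
Training is plain (mini-)batch gradient descent on cross-entropy of
the transformed outputs, defaults: full batch, learning rate 0.01, at
most 2000 epochs, early stopping on validation accuracy with patience
50, Glorot-uniform init, all deterministic under the seed. Class
weighting defaults to inverse frequency because realistic strata run
near 1:10 positives:negatives; without it the net happily predicts the
majority class. Targets are [1, 0] for positives, [0, 1] for
negatives; exact p_true = 0.5 is called negative.

## Data preparation

* **Labels**: a pair is positive iff it appears in the (pre-unioned)
  validated-interaction list; everything else in a score dump is
  treated as negative. This is the field's standard, and noisy:
  unvalidated true interactions count as negatives.
* **Deduplication**: two same-mask records are duplicates when every
  shared scaled score differs by < 0.04 (2% of the scaled range
  width; the raw-score reading would make the rule depend on each
  predictor's units). One member survives, chosen at random under the
  run seed; the operation is idempotent and never compares records
  across masks.
* **Splits**: stratified 80/20 train/test and stratified 5-fold CV for
  strata of ≥ 1000 records, 3-fold below (the size cutoff is a
  configurable default; only "by sample count" is inherent to the
  method). Stratification is used even though plain random splitting
  would be faithful, because at 1:10 imbalance unstratified small
  folds frequently lose a class entirely.
* Cross-subset evaluation projects richer records onto a module's
  predictor set; merging is only allowed from richer strata into
  poorer ones (the reverse would manufacture missing scores).
* Threshold tuning runs once per module on the full training stratum,
  not per CV fold — matching the pipeline order in which thresholds
  precede network training; per-fold tuning is a flag away.

## The synthetic generator

`mirmeta.simulate.generate` draws, per record: an availability mask
from a probability table (defaults: 30% fully scored, 30% spread over
the 3-predictor masks, 40% over the 2-predictor masks); a label
(positive fraction 0.08, the ~1:10 imbalance of realistic strata); and
per-predictor scores as truncated Gaussians on the scaled axis,
converted back to native units for output. Negatives sit at a
background mean of +0.3 (sd 0.3); a positive is shifted by the
per-predictor effect size (default 1.0) on the predictors that detect
it. The `complementarity` parameter (default 0.5) is the fraction of
positives detected by exactly one randomly chosen available predictor
— the knob that makes coverage exceed overlap. Unimodal score
densities were chosen for lack of any published distributional form;
a mixture mode is the natural extension when spike-rich IG curves are
needed.

What the generator does **not** emulate: sequence-level structure
(seed matches, UTR context, conservation), correlations between
predictors beyond shared detection, miRNA- or gene-specific effects,
and the heavy inter-stratum size disparities of real dumps. A green
test on synthetic data therefore establishes that the machinery is
correct and that the ensemble gain appears whenever its statistical
precondition (complementarity) holds — not that any particular
accuracy will be reached on a real compendium.

`worked_fixture()` is a hard-coded 24-row table (not sampled) spanning
all eleven masks, with one fully-scored row engineered to tie at both
vote steps (d_T2 = 0.067 vs d_F2 = 0.069 under the packaged
4-predictor thresholds) so the significance stage is exercised
deterministically.

## Known limitations

* Coordinate-wise threshold tuning has no optimality guarantee; it is
  greedy by design and the candidate pool is only as good as the IG
  spikes (see above).
* Equal-accuracy moves are accepted, so tuning can drift along
  accuracy plateaus; the walk remains deterministic (no seeds in the
  tuning path).
* The bounded-logit softmax compresses confidence scores toward 0.5;
  rank-based downstream use is unaffected.
* Negative labels are presumed, not validated — inherent to the
  problem formulation, and the main reason reported specificity should
  be read as an upper bound on the real false-positive behaviour.
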