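# Methods

## Model

The predictor treats each entity class — small molecules and miRNAs — as a
weighted similarity network and describes the relationship between two
nodes by the 28 graphlet-interaction isomers: connected graphlets of 2–4
nodes with an ordered (source, target) pair placed on them, placements
identified under automorphisms that permute only the auxiliary nodes.  The
catalog is generated at first use by exhaustive enumeration (all connected
role-labeled edge configurations, deduplicated under the swap of the two
auxiliary roles: 1 two-node + 4 three-node + 23 four-node = 28) and is
validated in the test suite against an independent route — orbit counting
of ordered pairs under the full automorphism group of each non-isomorphic
connected graph.

The weighted count of an isomer for an ordered pair (i, j) is a sum over
**ordered** assignments of **distinct** auxiliary nodes outside {i, j} of a
product of edge factors: the edge weight where the isomer has an edge, one
minus the weight where it does not.  Three choices deserve note:

* *Ordered auxiliary pairs.*  The double sum is taken literally over
  ordered (l, m); symmetric templates are therefore counted twice per
  unordered assignment.  This constant factor cancels in the per-source
  normalization and is otherwise absorbed by the learned weights, so no
  symmetry correction is applied.  Any convention applied uniformly across
  pairs yields identical normalized features.
* *Reduced products for small templates.*  The product form is stated for
  four nodes; three-node templates drop the factors and the sum involving
  the second auxiliary role, and the two-node template is the single
  (i, j) factor.  This is the only reading under which 2- and 3-node
  isomers are computable.
* *No self-edges.*  Auxiliary roles never take the values i or j, the two
  auxiliaries are distinct, and diagonal entries never enter any product
  or normalization denominator.  One-node graphlets cannot host an
  interaction between two nodes, so the catalog spans 2–4 nodes.

Counting is fully vectorized: per template, the double sum collapses to
batched matrix contractions (zeroing factor-matrix diagonals implements
the auxiliary exclusions; an explicit diagonal subtraction removes l = m),
chunked over sources to bound memory.  Complexity is O(n^4) per four-node
template in BLAS; a 300-node network is counted in about a minute, the
60-node networks used in the tests in well under a second.  Counts are
exact to float precision against the brute-force oracle.

Normalization divides each (source, isomer) row over targets by its sum;
rows whose total mass is below 1e-12 stay zero (an isolated source has no
interaction mass to distribute).

## Scoring and regression

A candidate pair (i, j) gets one 28-vector of features per network:
miRNA-side features sum normalized interactions from the miRNAs known for
i toward j (excluding p = j, which is automatic since the tensor diagonal
is zero); small-molecule-side features mirror this.  Isomer weights are
fitted by least squares of the feature matrix against the binary
known-association indicator over **all** pairs — regressing on positives
alone is degenerate (constant target), so unknowns are treated as 0, the
closed-world convention of this literature.  The explicit normal-equation
inverse fails off-design (28 features with few informative columns is
routinely rank-deficient), so the fit uses minimum-norm least squares,
which coincides with the normal-equation solution at full rank; the
condition number and residual are reported, and an all-zero feature matrix
returns zero weights with a warning.  The final score is the plain average
of the two sides.  Pairs that are new on both sides have all-zero features
and score 0 — the method's documented blind spot.  When only one side is
new, the average halves the informative score; the formula is followed
rather than special-cased.

The integrated similarity input is a weighted mean of any number of
per-measure matrices (weights default to 1); it is passed through without
renormalization or thresholding.  The diagonal is set to 1 after
integration but never participates in counting.

## Cross-validation

Global LOOCV removes each known pair in turn, retrains **both** regressions
on the reduced association matrix, and ranks the held-out score against all
pairs with no known association; the local variants restrict candidates to
the held-out pair's miRNA column (ranking small molecules) or small-
molecule row (ranking miRNAs).  k-fold CV partitions known pairs into
near-equal folds (sizes differ by ≤ 1) from a seeded permutation, retrains
per fold, and repeats over replicates, reporting mean ± sd of AUC across
replicates (the replicate dimension is repeated random splits, not folds
of a single split).  Interaction tensors depend only on the similarity
networks and are computed once per evaluation; features and regressions
are rebuilt per holdout, so the held-out pair contributes to neither
feature sums nor targets (asserted by instrumentation in the tests).

AUC is the Mann–Whitney statistic — the probability a held-out positive
outranks a random candidate, ties counted one half.  For pooled score
lists the threshold-sweep ROC is computed in integer count units so its
trapezoidal area equals the pair-ordering statistic bitwise.  For CV
schemes, each test pair is reduced to its percentile within its own
candidate set and the AUC is the mean percentile; the ROC curve sweeps a
rank-ratio threshold (x = fraction of candidates admitted, y = fraction of
test pairs reaching it).  The standard axis convention (x = FPR, y = TPR)
is used.  A held-out pair with an empty candidate set (e.g. a miRNA
associated with every small molecule in the local scheme) is recorded but
excluded from the AUC.

Per-holdout retraining is cheap because the expensive tensor step is
cached; the 90-association default runs a full LOOCV in a fraction of a
second.

## Synthetic data

The generator emulates the structure the model assumes: both entity
classes are partitioned into the same number of blocks (contiguous,
near-equal), similarity is a two-valued block baseline plus symmetric
Gaussian noise clipped to [0, 1] (clipping slightly biases the extremes;
irrelevant to rank-based evaluation), and associations are sampled without
replacement, a Binomial(n, p) share from matched-block pairs and the rest
from cross-block pairs.  Defaults: 30 small molecules, 60 miRNAs, 3
blocks, 90 associations, within-block probability 0.9, block contrast
0.8/0.2, noise sd 0.1 — a small, strongly structured problem that runs in
seconds.  The contrast and noise values were fixed once as a plausibly
strong planted signal; the five-fold AUC turns out to be insensitive to
the contrast (0.9/0.1 performs identically), because of the ceiling
described below.  Optional fractions of association-free entities emulate
datasets mixing annotated with completely new entities, and a decoupling
switch scrambles one side's blocks before placing associations to probe
one-sided prediction.

**What passing tests do and do not show.**  Because similarity is
block-constant (noise is label-independent), known and unknown pairs are
exchangeable within a block: no predictor can beat the block-membership
oracle, whose AUC under the default conditions measures ≈ 0.80 (≈ 30 % of
pairs are within-block candidates, ≈ 92 % of positives are within-block).
The model reaches ≈ 0.73 of that ceiling; the gap is estimation noise
(least squares over 28 collinear features, degree variance, positives
with an empty known-set on one side scoring through the other side only).
Real similarity data carries within-block gradients the generator does
not emulate, so absolute synthetic AUCs understate — and say nothing
quantitative about — performance on curated datasets; the synthetic study
establishes signal recovery above chance, null calibration at AUC 0.5,
monotonicity in the planted coupling, and the mechanics of all four
validation schemes.

## Numerical choices and limitations

* Zero-denominator rows in normalization stay zero (tolerance 1e-12).
* Symmetry tolerance on input matrices: 1e-8 (then exact symmetrization);
  file readers reject asymmetries beyond that naming the worst pair.
* Ill-conditioning is flagged above condition number 1e12; the solver is
  minimum-norm least squares regardless.
* Ranked outputs break score ties by (sm_id, mirna_id) lexicographically;
  ranking statistics count ties one half.
* All matrices are dense; at the scales this method targets (hundreds of
  entities per side) sparsity buys nothing.
* The model cannot score pairs new on both sides, averaging biases pairs
  predictable on only one side, and graphlets are capped at 4 nodes, so
  similarity information beyond 3 hops is invisible.
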