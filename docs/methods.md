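# Methods

## Information measures under the Gaussian model

All measures are computed under a joint-Gaussian working model on the
sample correlation matrix (variables standardized to zero mean, unit
variance, covariance denominator m − 1), in natural-log units (nats).
Standardization is harmless — MI, CMI and PMI are invariant under
per-variable affine rescaling — and improves the conditioning of the
determinant ratios. The threshold ε is therefore in nats as well; the
useful range on expression-scale problems is roughly 0.016–0.05
(ε = 0.03 corresponds to pruning pairs whose |correlation| < 0.24).

MI and CMI are the usual log-determinant forms. PMI replaces the
conditional densities p(x|z), q(y|z) of CMI with partial-dependence
functions p\*(x|z) = ∫ p(x|y,z) p(y) dy (and symmetrically q\*). For
Gaussians this compound is again Gaussian: writing the regression of X on
(Y, Z) as x = b·y + c'z + e with residual variance s², integrating over the
*marginal* of Y gives mean c'z + b·E[Y] and variance s² + b² Var(Y).
PMI then reduces to expectations of log-Gaussian quadratic forms:

PMI(X,Y|Z) = ½ ln( v\*_x v\*_y / det Σ_xy|z ) + E[(x − c'z)²]/(2 v\*_x)
             + E[(y − c'z)²]/(2 v\*_y) − 1,

with every moment read off the joint covariance. The expression reduces
exactly to MI when Z is empty (then p\* is the marginal), and vanishes
under conditional independence (then b = 0 and p\* = p(x|z), so PMI = CMI
= 0). The population value is an expected Kullback–Leibler divergence and
hence nonnegative; the implementation clamps tiny negative numerical noise
at zero. Covariances with condition number above 1e12 raise an
infinite-information error rather than returning a meaningless float.

Because the derivation above is easy to get subtly wrong, a definitional
oracle (`numeric_information_oracle`, ≤ 3 variables) evaluates the
defining integrals directly: tensorized Gauss–Hermite quadrature for the
outer expectation, and — for p\* — an inner trapezoid rule on a fine fixed
grid over y, because the integrand p(x|y,z)p(y) can be a narrow Gaussian
spike that a p(y)-weighted Hermite rule under-resolves. The trapezoid rule
is spectrally accurate for Gaussians, and the closed forms agree with the
oracle to ~1e-14 across random models up to condition number 1e4 (the test
suite asserts the documented 1e-5 / 1e-4 tolerances with a large margin).
Only the Gaussian estimation route is implemented; histogram/bin and
kernel estimators are out of scope, with the quadrature oracle serving as
the independent check instead.

## Path-consistency pruning

`run_pcapmi` starts from the complete graph. Stage 0 tests every pair with
MI. Stage L ≥ 1 visits each surviving edge e(i, j); with K the common
neighbours of i and j and T = |K|, the edge is kept untested when T < L
(the conditioning sets do not exist), otherwise the maximal PMI over all
C(T, L) size-L subsets of K is compared against ε. T = L counts as
testable with its single subset. Per pair the algorithm records the most
recent score tested (`last_score`) and its order — MI for pairs settled at
order 0, the failing PMI_max for removed edges, the surviving PMI_max for
kept ones. These scores are what the ensemble aggregates and what ROC
ranking uses, so every pair carries a finite ranking statistic.

Sequential mode deletes immediately; edges are visited in lexicographic
order of the variable labels *after* applying the configured permutation,
which makes the permutation the single source of order dependence and
every run exactly reproducible. Stable mode tests all edges of a stage
against the stage-start graph and applies removals afterwards, which makes
the result provably order independent (the tested subsets, and hence the
kept set, no longer depend on the visit sequence) — verified exhaustively
over all permutations for small n in the tests.

`max_order` defaults to `auto`: stages continue until a stage removes no
edge and no surviving edge has enough common neighbours for the next
order. Experiments in this repository pin `max_order = 2`, which settles
all but degenerate cases on the benchmark sizes used while keeping the
subset enumeration small. The diagonal of the adjacency matrix is 0:
self-edges are never tested and carry no meaning here.

Information values depend only on which variables are involved, never on
their order, so the MI matrix is computed once per dataset and a PMI value
cache keyed by (i, j, subset) is shared across ensemble runs. This changes
no result bit; it removes the N-fold redundancy of the ensemble.

## The SPCA ensemble

`run_ensemble` draws N variable orders uniformly from a seeded generator
and runs sequential PCA-PMI once per order (a stable-mode ensemble would
collapse to N identical runs). Aggregation follows the three criteria
MW/APMI/MPMI; per-pair case labels mark edges present in all (Case 1),
some (Case 2) or none (Case 3) of the runs. For MPMI, runs in which an
edge was removed contribute their failing score (the recorded PMI_max
below ε): the maximal-PMI criterion has no presence factor, for any
surviving edge the maximum is dominated by a surviving run anyway, and
this keeps a complete, informative ranking over all pairs. A flag
(`aggregate(..., absent_scores="zero")`) scores removed runs as 0 instead,
for comparison. Ties in top-M selection break by descending score, then
ascending index pair — deterministic by construction.

ε should be chosen so the Case-1 count stays below the expected edge
number while Cases 1 + 2 exceed it (then ranking Case-2 edges is what
decides the network); `check_threshold_guidance` warns when that fails.
N defaults to 1000 in the CLI; the test suite and acceptance script use
N = 30–100, past which the aggregate scores change negligibly at the
benchmark sizes used here. When the top-M network leaves nodes
disconnected, `mst_completion` first takes a maximum-weight spanning tree
under the criterion scores and then fills the remaining slots with the
best non-tree pairs, guaranteeing a connected output of exactly M edges.

## Synthetic benchmarks

The generator emulates DREAM4-scale benchmarks (100 genes × 100 samples,
~170–240 edges, heavy-tailed degrees) with a Gaussian graphical model:
gold edges are exactly the nonzero off-diagonals of a precision matrix Ω,
and the data are i.i.d. draws from N(0, Ω⁻¹). Edges therefore coincide
with the model's conditional dependencies — precisely what PMI pruning
tests — giving an exact ground truth. Graph topologies: `erdos_renyi`
(uniform G(n, m)) and `preferential_attachment` (Barabási–Albert grown,
then adjusted by uniform edge insertions/deletions to hit the target edge
count while keeping hub genes).

Ω is built with unit diagonal so that each off-diagonal entry is (minus)
the edge's partial correlation, drawn from `partial_correlation_range`
(default 0.3–0.6) with random signs. Hub nodes can make such a matrix
indefinite — many strong partial correlations cannot coexist — so the
magnitudes are uniformly shrunk by bisection until the minimum eigenvalue
reaches 0.1, but never below lo/2, keeping every edge detectable; the
diagonal is boosted only if even the floored weights are too strong. The
unit diagonal matters: boosting the diagonal of a strongly-weighted Ω
instead drives it toward singularity, and the implied covariance then
shows near-global marginal correlation — nothing like the sparse
zero-order networks real expression data produce. With the shrinkage
construction, a typical n = 50, density 0.05 instance has a median
marginal |correlation| of ~0.28 on gold edges and ~0.02 off them.

What the generator does *not* emulate: kinetic/ODE dynamics of the
DREAM simulators, multifactorial perturbation designs, non-Gaussian
marginals (beyond an optional monotone `sigmoidal` observation transform
for robustness checks), time delays, and missing values (a hard input
error — impute externally first). Passing benchmarks here demonstrate
correct recovery of conditional-independence structure from Gaussian
data, not performance on any particular real dataset.

The pinned documentation fixture (`worked_fixture`) is a 5-gene,
500-sample chain-with-fork (G1–G2–G3, G3 branching to G4, G5; 4 edges)
with partial correlations 0.35–0.45. At this strength indirect
correlations die at order 0 or 1, and pruning at ε = 0.05, max order 2
recovers the skeleton exactly under every variable order — verified, not
assumed, in the tests.

## Benchmark conditions and what they show

The recovery benchmark uses n = 50 genes, m = 100 samples (the sample
count of the reference benchmark datasets), density 0.05,
preferential-attachment topology, ε = 0.03, max order 2, ensemble N = 30,
over 20 seeded replicates. Mean ROC-AUC of the MPMI ranking is ~0.92–0.93,
above the APMI and MW criteria in essentially every replicate, and above a
single-order sequential run on average. The variation ratio of per-run
edge counts is ~9–25% depending on the instance, matching the magnitude of
order dependence the method is designed to absorb.

One regime sensitivity is worth recording: with substantially more samples
(e.g. m = 200) the per-run skeletons become so accurate that MPMI's
max-over-runs slightly inflates borderline *non*-edge scores, and the
ensemble's AUC can trail a single run's by ~0.001. The ensemble earns its
keep in the noisy, order-unstable regime — which is the regime the method
targets — not in the asymptotic one.

## Evaluation

Counts are over all n(n−1)/2 unordered pairs; directed gold standards are
symmetrized because the output is a skeleton. Standard definitions of
ACC, TPR, FPR, PPV and F1 are used; zero denominators yield 0 with a
warning rather than an error. The ROC groups tied scores into single
curve steps, and its trapezoidal AUC is checked in the tests to equal the
Mann–Whitney statistic (probability that a random gold edge outscores a
random non-edge, ties counted ½) exactly, as well as scikit-learn's
implementation.

## Known limitations

* The Gaussian closed forms are a working model; heavy-tailed or strongly
  nonlinear dependence will be mis-measured (rank-transform inputs first
  if needed).
* Output is an undirected skeleton: no edge orientation or v-structure
  discovery.
* The subset enumeration at order L costs C(T, L) PMI evaluations per
  edge; on dense graphs with hub nodes, `max_order="auto"` can be
  expensive — pin `max_order` to 1–2 for large dense problems.
* Automatic selection of ε and M is out of scope; the threshold-guidance
  warning is advisory only.
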