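# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of the pipeline, in the order the stages
run.

## Preprocessing

Genes are kept when their fraction of missing timepoints is at most
`max_rate` (default 0.15, the screening rule used for the motivating
8-gene module).  Missing values are filled by cubic-spline interpolation
over time with **not-a-knot** boundary conditions, so data lying exactly
on a cubic polynomial are reproduced exactly; genes with fewer than four
observed points fall back to linear interpolation, and masked points
outside the observed range take the nearest observed value — splines and
lines are not trusted to extrapolate.  A gene with fewer than two observed
points is an error, named explicitly.

Normalization is a per-gene z-score (sample sd, ddof = 1); min–max
scaling is available.  Constant genes are an error rather than silently
producing zeros.

Discretization maps each value onto three states relative to the gene's
mean μ and sample standard deviation s.  The default `symmetric` rule is
low (< μ−s) / mid / high (> μ+s).  A `literal` mode assigns the middle
state only on exact equality with μ+s; with continuous data that code is
effectively binary, which contradicts the three-state arity the scoring
stage assumes, so it is not the default.  The spread parameter is used
additively with the mean, which is only dimensionally consistent for a
standard deviation, and that is what is implemented.

Whether normalization precedes the computation of the discretization
thresholds is immaterial here: both thresholds are affine-equivariant, so
the state matrix is invariant under per-gene affine maps (property-tested).

## Segmentation

The series is cut into base windows of `window` minutes (default 20).
Adjacent intervals merge when no gene rejects a two-sample
Kolmogorov–Smirnov test (Mann–Whitney optional) between its values in the
two intervals; passes run left-to-right and repeat to a fixpoint, so the
result is deterministic.  The test runs on the raw (post-imputation,
pre-discretization) values: distribution equality on the measured scale
is the operational meaning of joint stationarity used here.

`alpha` (default 0.01) is the level of each **merge decision**.  A
decision aggregates one test per gene under an AND rule, so each gene is
tested at the Šidák-corrected threshold 1 − (1 − α)^(1/n_genes); without
the correction (available as `correction="none"`) the realized decision
level grows to roughly n_genes · α and pure-noise series are split far too
often.  No correction is applied across the different boundaries: each
boundary decision stands alone.

The RB ratio (in-interval over whole-series mean absolute deviation) is
the descriptive stationarity statistic and is exposed directly; the merge
decision uses the distribution test, which is the only operational
criterion available.

Small windows make the exact KS test strongly discrete: with two
observations per window no rejection at α = 0.01 is possible at all, and
the realized per-test level only approaches α for windows of ten or more
points.  The level/power simulations in the acceptance suite therefore
sample the 0–160 min span at 2-minute spacing (10 observations per
20-min window), where a 5-sd mean shift yields a complete-separation
p ≈ 10⁻⁵ while the null rejection rate stays well below α.

## K2 structure learning

Scores are Cooper–Herskovits marginal likelihoods with a uniform Dirichlet
prior, computed entirely in log space via log-gamma; raw factorials
overflow at modest sample counts.  Parent-state configurations are counted
only when observed — unobserved configurations contribute empty products
and thus factor out identically.  The node arity r defaults to 3 to match
the three-state code (r = 2 suits the literal binary code).

The greedy search visits genes in a fixed ordering (default: the matrix
row order, i.e. the case-study numbering CLN1 … SIC1) and repeatedly adds
the predecessor with the largest strict score gain, stopping at
`max_parents` (default 3, keeping parent-configuration tables tractable
for an 8-gene module).  Ties break toward the lowest gene index; a gain
must exceed 1e-12 in log space to count as an improvement, which makes
exact ties stable against floating-point noise.  Per-interval graphs are
acyclic by construction; the union across intervals may contain cycles,
and records per-edge interval provenance plus a confirmed/unconfirmed
status against an optional prior edge list.

## Entropy screening

Correlations use Pearson when both series pass a Shapiro–Wilk test at
0.05, Spearman otherwise, and enter the entropy as absolute values
normalized over the node's undirected neighborhood (in- plus out-edges).
The natural log is the default (entropies in nats; base 2 available).
Network entropy is the sum of node entropies: it is the simplest aggregate
for which node-removal and edge-addition deltas are well defined.
Entropies are computed over the whole post-imputation series, not per
interval, matching a single global normality screen.

Screening enumerates, for each unconfirmed edge, all subsets of the other
unconfirmed edges in its group (sizes 1 … group−1, lexicographic order,
optionally capped by `max_context_size`; groups above 20 edges without a
cap are refused as combinatorially infeasible).  A context is a violation
when adding the edge raises total entropy by more than `a` (default 0.3);
the edge is accepted while violations stay below `b` (default 100, set
per group).  A `semantics="literal"` mode reproduces the published
pseudocode verbatim — whose counter is never incremented, so every edge is
accepted — and exists purely for fidelity; the counting semantics above is
the only reading under which `a` and the group-specific `b` values have
any effect.  Acceptance is monotone in `b` by construction.

How unconfirmed edges should be partitioned into groups is
data-set-specific knowledge; the partition (and each group's `b`) is a
configuration input, e.g. `--groups 8:100,9:200` over the sorted edge
list.

## Sensitivity ranking

g_i = c − d_i with full recomputation after node deletion: surviving
nodes' neighbor distributions are renormalized on the reduced adjacency,
not frozen.  Isolated nodes score exactly 0; ties rank the earlier gene
first, making output deterministic.  Automorphic nodes under equal
correlations provably receive equal scores (tested).

## PLS validation

Per-gene PLS regressions are restricted to network parents (components =
min(2, parent count)); non-parents have exactly zero coefficients, so
permuting a non-parent's series can never change a gene's predictions
(tested).  Parentless genes carry the constant training-mean model.  The
intercept is recomputed on the raw scale from training means rather than
taken from the library fit, which centers internally.

Simulation draws each gene from its fitted marginal normal distribution.
With **independent** draws (the default, and the plainest reading of
"generate data from the normal distribution"), parent-based predictions
are uncorrelated with the drawn targets, so richer models always score
*worse* — the comparison between candidate networks is then structurally
biased toward sparser graphs and cannot reward a correct structure.  The
`joint=True` mode draws from a multivariate normal with the empirical
correlation matrix, under which the fitted dependency structure predicts
the draws and network comparisons become meaningful; all network-vs-
network comparisons in the acceptance suite use joint draws.  Relative
error uses an ε = 1e-8 denominator guard: z-scored expression crosses
zero routinely and the raw ratio is otherwise undefined.

The normality screen is per-gene Shapiro–Wilk at 0.05, reported as
p-values plus pass flags.

## Synthetic data

The generator produces piecewise-stationary, contemporaneous
linear-Gaussian data: per segment, root genes draw independent N(0, 1)
around a per-segment baseline, children are weighted parent sums plus
N(0, noise_sd), and missingness is uniform at a configurable rate.  The
default shape mirrors the motivating study — 8 genes, 17 timepoints at
10-minute spacing — and is deliberately too short for reliable structure
learning; the dense two-segment profile (200 one-minute points per
segment, three planted strong edges of weight 0.9 per segment,
noise sd 0.3, baseline shift 2.0) exists for recovery benchmarks, where
the pipeline reaches mean recall ≈ 0.9–1.0 and precision ≈ 0.9.

What the generator does *not* emulate: dye/probe effects, heteroscedastic
microarray noise, autocorrelated dynamics (the model is contemporaneous by
design, matching the PLS validation's own assumption), or cyclic
regulation within a segment.  Passing tests therefore demonstrate
correctness of the algorithms under the model's assumptions, not
performance on raw microarray data.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the acceptance script
derives all of its seeds from a single root.  Monte-Carlo problem sizes —
50 replicates for segmentation level/power and the PLS comparison, 20
seeds for recovery, 50 random datasets for the exact-score oracle — were
chosen to give stable rates at a few seconds of runtime each.

## Known limitations

- The K2 result depends on the node ordering; the default is the
  case-study numbering, and reproducing any particular published edge set
  additionally depends on that study's (unstated) ordering and parent cap.
- The screening thresholds `a` and `b` are free parameters with no
  internal calibration; `b` only has meaning relative to the total context
  count of an edge's group (2^(g−1) − 1 for a group of g).
- Entropy is correlation-based and undirected: it cannot distinguish edge
  directions, only attachment patterns.
- With very short series (two points per segmentation window) the exact
  KS test cannot reject at usual levels, so every window merges; plateau
  detection at the motivating study's 10-minute sampling necessarily rests
  on external evidence.
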