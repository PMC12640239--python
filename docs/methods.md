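# Methods

## The generative model

The ground truth is an open reaction network over `n` metabolites. A random
spanning tree is grown by attaching each new metabolite to a uniformly
chosen earlier one; `n_extra_edges` additional reactions between
non-adjacent pairs create cycles. All reactions are oriented away from a
designated root ("core") metabolite, mimicking a degradation cascade fed by
one upstream species. Each internal reaction is Michaelis–Menten
(`v = Vmax·S/(Km+S)`) with probability `mm_fraction`, otherwise mass action
(`v = k·S`). The undirected projection of the internal reactions — with a
multi-substrate reaction inducing edges among *all* its participants — is
the reference adjacency used by every evaluation.

Openness is what makes the steady state informative. The core metabolite
receives a constant-rate influx, and every terminal (degree-1) metabolite
and every directed sink (a node with no outgoing reaction) carries a
first-order efflux. Without the influx the only fixed point of such a
drained system is identically zero; without efflux at *all* directed sinks,
interior dead-end metabolites accumulate without bound and no steady state
exists. Both facts were observed directly during development and drove the
design.

Parameter ranges (log-uniform draws, concentration/hour units):

| parameter | range | role |
|---|---|---|
| k (mass action) | [0.5, 5] | first-order conversion rate |
| Vmax | [1, 5] | enzymatic capacity |
| Km | [0.5, 5] | half-saturation concentration |
| k_out (efflux) | [0.2, 0.5] | removal rate at sinks |
| k_in (influx) | [0.05, 0.2] | constant supply at the core |

These ranges are coupled: the total influx (≤ 0.2) is below every
reaction's capacity, so no Michaelis–Menten step can saturate into unbounded
accumulation, and every relaxation rate (k, Vmax/Km, k_out) is at least
0.2 h⁻¹, so transients decay by many e-folds inside the simulation horizon.

## Simulation

Samples are steady states under parameter perturbation: for each sample
every kinetic parameter is independently multiplied by a uniform draw from
`[1−perturb, 1+perturb]` (default ±10%) and the mass-balance ODEs are
integrated with LSODA (rtol 1e−8, atol 1e−12) from fixed initial
concentrations (1.0 everywhere, 10.0 at the core). Integration runs in six
segments up to a hard stop of 90 simulated hours; after the first (burn-in)
segment it stops early once
`max_i |dC_i/dt| / max(C_i, 1e−12) < 1e−6`. Negative transients smaller in
magnitude than 1e−9 are clipped to zero; anything larger raises a
simulation error naming the sample. The tight integrator tolerances are
deliberate: with looser settings the numerical derivative floor sits above
the steady-state criterion and the early stop can never fire.

Condition shifts multiply Vmax and Km of selected Michaelis–Menten
reactions (the benchmark's "aged" condition uses Vmax×1000, Km×2.5),
returning a new network and leaving the original untouched.

## Inference algorithms

All algorithms map a samples×metabolites table to a symmetric association
matrix with zero diagonal. Signed outputs (the correlation family) are
absolute-valued before any thresholding, ranking, CLR or PCLRC step; the
signed matrix itself is preserved for reporting.

* **Correlations** — Pearson (numpy), Spearman and Kendall (scipy), and an
  in-package vectorized biweight midcorrelation (median/MAD weights
  `w = (1−u²)²·1[|u|<1]`, `u = (x−med)/(9·MAD)`; zero-MAD columns yield 0,
  logged).
* **Partial correlation** — `pcor(i,j) = −P_ij/√(P_ii·P_jj)` from the
  Moore–Penrose pseudoinverse of the sample covariance, which stays defined
  when n ≤ p; an optional Ledoit–Wolf shrinkage flag (default off) trades
  bias for conditioning.
* **Mutual information** — the continuous kNN estimator (scikit-learn,
  k = 3 by default, seeded tie-breaking jitter), one estimate per unordered
  pair, negatives clipped to zero. Nats throughout.
* **CLR** — each entry re-expressed against its row backgrounds:
  `out_ij = √(max(0,z_i)² + max(0,z_j)²)` with z-scores over the
  off-diagonal row entries; zero-variance rows get z = 0. Applicable to any
  association matrix.
* **MRNET** — greedy maximum-relevance/minimum-redundancy per target using
  the *difference* criterion (relevance minus mean association to already
  selected features), pairwise score frozen at selection time and floored
  at 0, directions merged by elementwise max. The difference form is used
  rather than the quotient because it is stable as redundancy → 0.
* **Tree importances (GENIE3-style)** — each metabolite in turn predicted
  from the rest by a seeded random forest (default 100 trees — a desk-scale
  default below the 1000 commonly used — sqrt feature subsampling, no
  depth cap); normalized impurity importances give directed scores, merged
  by max.
* **PCLRC** — per iteration, 75% of samples drawn *without* replacement,
  base association (default Pearson; pluggable, so an MI base is available)
  CLR-transformed, and the top 30% of off-diagonal pairs marked globally
  (a per-node flag exists). The output is each pair's selection frequency
  over (default) 1000 iterations. Because each iteration marks exactly the
  top fraction, the *mean* output frequency equals that fraction — a
  ceiling that caps how well PCLRC can match references whose density
  differs from the marking fraction.

## Evaluation

All edge scoring works on the n(n−1)/2 unordered off-diagonal pairs. An
edge is predicted when `|A(x,y)| > τ` (strict). F1 = 2TP/(2TP+FP+FN),
MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), FDR = FP/(TP+FP).
Degenerate denominators return defined values (0) and are logged, never
raised. The optimal threshold scans midpoints between consecutive sorted
unique magnitudes, plus one candidate below the minimum and one above the
maximum, computed incrementally from the descending pair ranking; ties take
the smallest τ. AUROC uses the Mann–Whitney rank statistic with averaged
ties; AUPR is the step-wise (non-interpolated) precision–recall area, the
conservative convention that avoids interpolation bias.

## Centrality comparison

Degree is normalized by N−1 (switchable to N). Betweenness follows the
unnormalized pair-fraction sum with endpoints excluded, computed from
BFS-derived distance and shortest-path-count matrices via the identity
σ_jk(i) = σ_ji·σ_ik when d_ji+d_ik = d_jk. Closeness is the *harmonic*
form — mean inverse distance with 1/∞ := 0 — which needs no special-casing
on disconnected graphs. PageRank (α = 0.85, tol 1e−10, max 1000 iterations)
is a plain power iteration that redistributes the rank mass of isolated
nodes uniformly, keeping the vector summing to 1 at every step; the L1
residual trace is observable and non-convergence raises an error carrying
the last residual. Comparisons report per-node residuals
(inferred − reference, positive = overestimate) and their MAE; repetition
summaries use 95% percentile intervals (2.5th–97.5th).

## Aspirational sweep

Each unordered pair receives one U[0,1] draw (mirrored, so the matrix is
exactly symmetric — the one-draw convention keeps symmetry exact rather
than approximate) plus `signal·Adj(x,y)`. The default sweep covers fifty
levels 0.02…1.00 (a flag includes 0) with 100 matrices per level. At
signal 1 every true edge scores ≥ 1 and every non-edge < 1, so all pairwise
metrics attain their optima and centrality MAEs vanish; at signal 0 the
matrix is pure noise and AUROC centers on 0.5.

## Bootstrap differentiation

Per condition: 100 bootstraps of 100 samples (with replacement — unlike
PCLRC's without-replacement subsampling, and deliberately kept distinct),
each inferred with a configurable algorithm (default Pearson+CLR) and
binarized. Binarization uses the per-bootstrap F1-optimal threshold when a
reference adjacency is supplied; without one, a fixed τ from the
configuration or a rank rule keeping the top-k pairs (a fixed τ such as the
conventional 0.6 is meaningless on CLR z-score outputs, hence the
reference- or rank-based defaults). Reliable edges are those in strictly
more than 50% of bootstrap networks; differential edges are the symmetric
difference of two conditions' reliable sets, and the split-half check
partitions the already-generated networks by index (larger first half when
odd) and counts disagreements between the two halves' reliable sets.

## Experiment grid

The grid runs methods × sample sizes (default 5, 10, 20, 50, 100, 200) ×
repetitions (default 100) over a fixed sample pool, drawing n samples
without replacement per repetition. Per-cell seeds are SHA-256 hashes of
`(master seed, method, n, repetition)` folded to 31 bits, so every row is
regenerable in isolation and cell order never matters. Methods whose
preconditions need more samples than a cell offers are skipped with a
logged reason (PCLRC over MI drops out at the smallest sizes because its
75% subsample must still satisfy the kNN estimator's minimum). Per-cell
failures are recorded and skipped, never aborting the grid; a manifest
makes reruns resumable. Concentrations are used raw by default; a
`log_transform` switch applies a positive-shifted log first.

## What the generator does and does not emulate

The synthetic networks reproduce the *class* of the motivating system —
sparse, tree-like degradation cascades with a few cycles, mixed kinetics,
flux from a core metabolite to terminal sinks, sample-to-sample variation
from ±10% parameter perturbation. They do not reproduce any specific
biochemical pathway's topology or optimized kinetic constants, metabolite
aggregation conventions, measurement noise, compartmentalization, or
regulatory (non-mass-balance) couplings. Passing benchmarks here therefore
show that an algorithm can recover kinetically coupled steady-state
structure under ideal sampling — not that it will recover a real pathway
from experimental data.

## Problem sizes in the shipped runs

The test suite and the acceptance script run the same machinery at desk
scale as the package's standard configuration for routine verification: a
20-node, 24-reaction network with a 220-sample pool, grid sizes 10/50/200
with 10 repetitions, 30 aspirational matrices per level over six levels,
200 PCLRC iterations, and the full 100×100 bootstrap differentiation. All
defaults for full-scale studies (100 repetitions, fifty signal levels,
1000 PCLRC iterations) remain the documented configuration values.

## Known limitations

* The simulator integrates to a steady state; oscillatory or multistable
  kinetic regimes are out of scope (the generator's parameter coupling
  avoids them by construction).
* Mutual information estimates at very small n (≲ 10) are noisy and
  clipped at zero, which biases small true MI upward.
* Betweenness is reported unnormalized; comparisons are only meaningful
  between same-size graphs (the package always compares same-node-set
  networks, where the scale cancels).
* Directed inference is not attempted: all evaluations relax reference
  edges to undirected.
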