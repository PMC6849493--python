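# Methods

This note documents the models and procedures implemented in `netattack`,
the parameters that matter, and the choices made where the design was
genuinely open.

## The attack protocol

A symptom network is an undirected, signed-weighted graph; edge existence
means a nonzero weight. An *attack* removes nodes one at a time and records
three state characteristics after every removal:

- **connectivity** — the count of interactions present. A weighted variant
  (summed |w|) is provided as a first-class alternative because "number of
  interactions" and "total interaction mass" can rank attacks differently on
  weighted networks; the count is the default.
- **components** — connected components, isolated nodes included
  (`scipy.sparse.csgraph`).
- **average path length** — mean shortest-path distance over connected
  *ordered* pairs only; disconnected pairs are excluded rather than given an
  infinite or imputed distance. Hop counts are the default metric; `1/|w|`
  edge lengths are available. When no edges remain the value is NaN, and
  downstream peak searches skip NaN steps.

Trajectories run to full depletion — N−1 removals, N recorded states — so
peak searches always see the whole removal process. The stopping point is a
design choice: stopping earlier could only hide late peaks.

Targeted attacks come in two modes. `initial` (default) ranks nodes once on
the intact network and removes them in that fixed order — this mirrors how
treatment targets are normally chosen, from a single network estimate.
`recalculated` (cascading) re-ranks the surviving subnetwork before every
removal. Ranking ties break by ascending label, making every run
deterministic; a seeded uniform tie-break is available.

Random attacks draw uniformly random removal orders. Each replicate uses an
independent child of a `SeedSequence`, so enlarging `n_sims` extends the
replicate set without reordering earlier replicates. The default
`n_sims = 2000`.

The per-step all-pairs distances are computed with a frontier BFS expressed
as boolean matrix products (O(diameter) matrix multiplications per step),
which keeps a 2,000-replicate campaign on a 120-node network to tens of
seconds on one CPU; the per-step values are tested to agree exactly with
independent whole-network recomputation.

## Outcome measures

Per network and condition, five outcomes:

- impact magnitude for components and path length: peak value along the
  trajectory minus the initial value (step 0 is included in the peak search,
  so magnitudes are nonnegative);
- attack extent for components and path length: (first step index attaining
  the peak) / N, with N the initial node count — peak ties resolve to the
  first attainment;
- connectivity extent: (first step with connectivity ≤ ½ of initial) / N.

N (rather than N−1) as the denominator reads the extent as "proportion of
the original network's symptoms". Random-condition outcomes are computed per
replicate and then averaged (the mean of a nonlinear functional, not the
functional of the mean trajectory); the alternative — reducing the
pointwise-mean trajectory — is available behind a flag for sensitivity
analysis and is not the default because it systematically flattens peaks.

## Module measures

Two bridge-symptom roles are distinguished: *overlapping* symptoms belong to
several modules; *bridging* symptoms belong to one module but connect to
others. Both are scored as effective numbers (inverse participation ratio
`1/Σp²`) of a probability vector over modules:

1. A hard base partition is obtained by greedy modularity maximization on
   |w| (networkx's deterministic implementation, communities re-indexed by
   smallest member so module ids are reproducible).
2. Fuzzy membership is produced by random-walk smoothing
   `q ← (1−α)·onehot(base) + α·P q`, with `P` the |w| row-normalized
   adjacency, iterated to a fixed point (α = 0.5, ≤ 50 iterations,
   tolerance 1e−6). Row-stochasticity is preserved exactly at every
   iteration. Isolated nodes keep their one-hot anchor via a self-loop in P.
3. The connection profile `ĉ(i, m) ∝ Σ_j |w_ij| q(j, m)` distributes a
   node's edge mass over modules.

Modular overlap is the effective number of `q(i, ·)`; modular bridgeness the
effective number of `ĉ(i, ·)`. Both lie in [1, M]. Note that the one-hot
anchor keeps memberships asymmetric even for perfectly symmetric shared
nodes (a node shared between two 6-cliques converges to membership
(0.75, 0.25), overlap 1.6, not (0.5, 0.5)): the measures are *ordinal*
scores, and the tests assert ordinal fidelity — on planted fixtures the
shared node attains the network maximum of overlap and a bridge-edge
endpoint the maximum of bridgeness. No numerical equivalence with any
specific published overlapping-community tool is claimed; the backend is
pluggable behind the `ModuleAssignment` contract. Planted fixtures carry
either shared nodes or bridge edges, not both: a node holding full
membership in two modules necessarily also has the most balanced connection
profile, so it would dominate both measures in a mixed fixture.

Signed weights enter all module computations as |w|, consistent with
strength summing absolute weights.

## Network estimation

**Continuous data.** Graphical lasso over a log-spaced penalty grid
(100 points from λ_max — the largest absolute off-diagonal sample
correlation, the smallest penalty giving the empty graph — down to
λ_max/100). For each candidate support, EBIC
`−2L + k ln n + 2γk ln p` (γ = 0.5 by default) is scored on the
*support-constrained Gaussian MLE*, computed by iterative proportional
scaling (nodewise regressions restricted to each node's neighborhood,
cached per distinct support). Scoring on the penalized estimate itself was
tried first and rejected: the likelihood then improves with smaller λ partly
because shrinkage of the *true* edges relaxes, which conflates edge count
with edge magnitude and systematically over-selects (F1 ≈ 0.67 instead of
≥ 0.8 on the 15-node recovery benchmark). Edge weights of the selected
model are the partial correlations `ρ_ij = −κ_ij/√(κ_ii κ_jj)` of the
refitted precision.

**Binary data.** Nodewise L1-penalized logistic regression (liblinear),
per-node penalty grid from just above the zero-solution boundary, per-node
EBIC with γ = 0.25 and k = active neighbors. liblinear's penalized intercept
is neutralized with a large `intercept_scaling` so the penalty does not
couple to the node's base rate. Directed coefficients are reconciled by the
AND rule (edge kept only if both directions are nonzero; weight = mean of
the two coefficients); OR is available.

## Robust statistics

Outcome distributions across networks are skewed with extreme values, so
conditions are compared on 20%-trimmed means with bootstrap-t calibration
(defaults: trim 0.2, B = 2000, α = 0.05).

- Omnibus: the dependent-groups trimmed-means ANOVA statistic
  `F_t = [Q_c/(J−1)] / [Q_e/((h−1)(J−1))]` with `h = n − 2g`,
  `g = ⌊trim·n⌋`, Q_c the between-condition trimmed sum of squares and Q_e
  the residual sum of squares of the double-centered Winsorized data. The
  critical value is the empirical (1−α) quantile of the statistic over B
  resamples of complete rows from column-centered data (each column minus
  its trimmed mean), which imposes the null while preserving the dependence
  across conditions. Empirical type-I error over 500 null simulations
  (3 exchangeable conditions, n = 50, B = 599) is verified to land in
  [0.03, 0.08] by the test suite.
- Post hoc: marginal trimmed-mean differences (psihat), studentized with
  `SE² = (w_jj + w_kk − 2w_jk)(n−1)/(h(h−1))` from the Winsorized
  covariance. One familywise critical value per family — the (1−α) quantile
  of the bootstrap max-|T| over all pairs — yields the constant
  "critical value" column; CI = psihat ± crit·SE, so significance and the
  CI excluding zero coincide by construction. Degenerate zero-SE pairs are
  reported as T = 0 when psihat = 0 and ±∞ otherwise.
- Missing values: rows (networks) with any missing condition are dropped
  listwise; at least 10 complete rows are required.

## Synthetic data

The generator reproduces the statistical footprint of the published sample
the analysis was designed for, not any particular disorder network:

- node counts from a log-normal (μ = 2.75, σ = 0.85, giving mean ≈ 22 and
  SD ≈ 22) truncated to [5, 120] by resampling — the published sample
  reports only a mean of ~23, SD ~21, and that range, so a right-skewed
  two-parameter family matching those moments is the natural choice;
- densities uniform on [0.067, 0.861]; edge support uniform at the target
  density (realized edge count within one edge of rounding);
- edge-weight magnitudes uniform on (0.05, 1], signs 90% positive / 10%
  negative — typical of partial-correlation symptom networks, configurable;
- connectedness not forced (published networks show up to 5 components).

Ground-truth Gaussian models draw a sparse symmetric precision matrix and
load the diagonal on a deterministic retry ladder until positive definite
with condition number ≤ 1e4. Ising models draw couplings near a unit scale
and negative thresholds (uniform on [−1.5, −0.5]) so activation
probabilities stay away from 0 and 1; sampling is by systematic-scan Gibbs
with configurable burn-in and thinning, validated against exact Boltzmann
enumeration on two-node models.

What the generator does *not* emulate: empirical degree heterogeneity
(support is uniform, not hub-dominated), community structure in ensemble
networks, and the dependence between size and density seen in real
published networks. Passing tests therefore demonstrate correctness of the
machinery and direction-level replication on controlled topologies
(stars, preferential-attachment graphs), not numerical reproduction of any
published table — which would require the original adjacency matrices.

## Problem sizes and determinism

The full study configuration (51 networks, five conditions,
n_sims = 2000, B = 2000) completes in roughly 3 minutes on one CPU and is
byte-reproducible for a fixed seed: every random draw flows from explicit
integer seeds through `numpy.random.SeedSequence` substreams, and all
tie-breaks are deterministic. Smaller grids and replicate counts used in
individual unit tests are stated in the tests themselves; they exercise the
same code paths.

## Known limitations

- The module backend is a specified stand-in with the required contract
  (fuzzy membership + connection profile); absolute overlap/bridgeness
  values are backend-dependent even though orderings are stable on planted
  structure.
- The Ising EBIC uses the nodewise pseudo-likelihood, as is standard; no
  joint-likelihood refit is attempted.
- Mixed continuous/binary data, edge-removal (interaction-inhibition)
  attacks, and betweenness/closeness centralities are out of scope — the
  latter deliberately, given their known instability on symptom networks.
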