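# Methods

## Connectome construction and thresholding

Connectivity is the Pearson correlation between parcel time series,
Fisher-z transformed (`z = atanh(r)`, clipped at |r| = 1 − 1e−7 so unit
correlations stay finite). Matrices are symmetric with a zero diagonal;
asymmetric input files are symmetrized as `(M + Mᵀ)/2` with a warning.

Proportional thresholding keeps the `floor(d·N(N−1)/2)` largest
upper-triangle weights at density `d` and zeroes the rest. Ranking is by
*signed* weight — the simplest reading of "connection density" on Fisher-z
matrices, where at the primary density of 0.10 essentially all retained
edges are positive anyway — with `absolute=True` (CLI `--abs-threshold`)
as the alternative. Ties are broken deterministically by lexicographic
(i, j) node-pair order, lower indices first, so the retained edge set at a
lower density is always a subset of the set at a higher density. The
diagonal never counts toward density or degree.

## Targeted attack and network reliance

Weighted degree is `k_i = Σ_j w_ij` over retained edges. The attack
removes the surviving node with maximal degree, recomputing degrees on the
surviving subgraph after *every removal* (not once per stage): the
procedure is explicitly iterative, and per-removal recomputation is the
reading consistent with it. Degrees are maintained incrementally
(subtracting the removed node's incident weights); a from-scratch
recomputation serves as the test oracle. Two numerical guards keep the
incremental path exactly equivalent to the oracle:

- nodes whose surviving edge count reaches zero have their degree snapped
  to exactly 0, so float residue cannot perturb the degree-0 tie pool;
- the running maximum is selected with a 1e−8 tolerance band, so genuinely
  tied degrees (e.g. two nodes whose only surviving edge is their mutual
  one) resolve by the lowest-node-index rule rather than by rounding noise.

Ties — including isolated nodes, which are common at 10% density — are
broken by lowest node index; they still receive stage labels normally.

The removal order is partitioned into `S` equal consecutive stages
(default 8; for N = 264 each stage is exactly 33 nodes, a 12.5% reduction
per stage). When `N mod S ≠ 0` the earlier stages receive the extra node.
Per-network node-loss counts per stage satisfy two exact conservation laws
(checked in tests): column sums equal stage sizes, row sums equal network
sizes. **Reliance** of a network is its mean node loss over stages 1–4 —
the first half of the degradation, where hub loss is most informative.
Note that reliance is only informative when `S` exceeds the averaging
range: with `S = 4` the stage-1..4 mean is the network size divided by 4
for every subject, a constant.

## Stage-wise EF association

Each (network, stage) node-loss count is regressed on the three EF factors
plus a binary scanner indicator (reference level TRIO). Twin dependence is
handled with family-clustered sandwich standard errors on OLS rather than
a random-intercept mixed model: clustered OLS is deterministic,
assumption-light, and targets exactly the dependence structure (two
correlated observations per family). Cells with a constant response yield
undefined p-values; they are reported as p = 1 (no evidence). The BH FDR
family is the 8 stages within one network, applied per predictor
(`fdr_scope="global"` pools all cells instead). Significance is α = 0.05
throughout. VIF diagnostics (`1/(1−R²)` of each factor on the other two)
guard against EF factor collinearity; with the default intercorrelations
(0.31, 0.38, −0.28) VIFs sit near 1.4.

When every family contributes a single subject, clustered sandwich SEs
agree with classical OLS SEs only asymptotically (a singleton-cluster
sandwich is an HC-type estimator, not the homoskedastic formula); the test
suite checks agreement to 5% at n = 2000 on homoskedastic data.

## Twin models

Twin correlations are double-entered Pearson (each pair enters as (A, B)
and (B, A)), making the estimate exactly invariant to within-pair order.
Falconer's `H² = 2(r_MZ − r_DZ)` is reported unclipped — values above 1 or
below 0 are legitimate moment estimates.

The SEMs maximize the bivariate-normal pair likelihood with per-zygosity
covariances `Cov_MZ = a² + c²`, `Cov_DZ = a²/2 + c²`, total variance
`V = a² + c² + e²`, and a single common mean (no covariates). Components
are kept nonnegative by optimizing path coefficients (a, c, e) whose
squares are the variances; `e² > 0` is enforced by the likelihood itself
(a singular covariance has −∞ likelihood on non-identical twins).
Optimization is Nelder-Mead from three deterministic starts (equal thirds,
twin-correlation-informed, E-dominant); `fit_all()` additionally feeds
each nested solution forward as a start for the richer models, which
guarantees the nesting inequality `−2LL(ACE) ≤ −2LL(nested)` up to 1e−6.
The E model has a closed form (grand mean, ML variance) used both as a
start and as an independent test oracle.

Model selection follows the chi-square + AIC rule: each nested model is
tested against ACE by likelihood ratio (df = parameter difference), and
the lowest-AIC model among those with p > 0.05 is selected; ACE is
selected only when every nested model is significantly worse. The AIC
convention is `AIC = −2LL − 2·df` with
`df = (observed values) − (free parameters)` — the bookkeeping under which
published twin-model tables are internally consistent row by row. Only the
identity, not any absolute df, is meaningful across datasets. At the
`c² = 0` boundary the likelihood-ratio chi-square is conservative; the
selection rule inherits that conservatism by design.

## Synthetic data generator

The generator defines the study conditions for every simulation-based
check:

- **Cohort scale.** 115 MZ + 108 DZ pairs by default (≈230/216
  individuals), scanner labels assigned per family (twins share a
  session) as Bernoulli(0.5) over {TRIO, PRISMA}.
- **Traits.** Twin similarity is parameterized *directly* by per-trait
  (rMZ, rDZ) targets — cEF (0.81, 0.22), SHI (0.55, 0.15), UPD
  (0.65, 0.31) — rather than by (a², c², e²), because targets with
  rDZ < rMZ/2 (as for cEF) are unreachable by any purely additive
  generator. A pair's 2K trait values are drawn from the joint covariance
  `[[R, D], [D, R]]` with `R` the cross-trait correlation matrix
  (defaults 0.31, 0.38, −0.28) and `D_ij = √(r_i r_j)·R_ij`: per-trait
  pair correlations and within-subject cross-trait correlations are then
  exact in expectation. The matrix is eigen-clipped to the nearest PSD
  matrix (with a warning) for pathological configurations.
  `TraitSpec.from_ace(a2, c2, e2)` maps components to targets
  (rMZ = a²+c², rDZ = a²/2+c²) for recovery tests.
- **Connectomes.** Block matrices in Fisher-z units: within-network mean
  0.45, between-network 0.10, i.i.d. Gaussian edge noise (sd 0.12) drawn
  on the upper triangle and mirrored, so symmetry is exact. The 0.35
  within/between gap with 0.12 noise makes >80% of edges retained at 10%
  density within-network — the hub structure the attack expects. A
  `CouplingSpec(trait, network, effect)` shifts the coupled network's
  within-block edges by `effect` z-units per SD of the trait (this alone
  raises those nodes' degree, which is the only quantitative contract the
  coupling carries); an optional pair-shared matrix component
  (`pair_shared_sd`) adds family-level similarity. MZ pairs are more
  similar than DZ pairs whenever a coupled trait is heritable.
- **Atlas.** 264 nodes in 10 contiguous label blocks (58 DMN, 50 SUB,
  35 SMN, 31 VIS, 25 FPN, 18 SN, 14 CING, 13 AUD, 11 DAN, 9 VAN). These
  block sizes are a synthetic stand-in for a Power-style parcellation
  collapsed to 10 networks (the unassigned/cerebellar/memory parcels
  folded into SUB); the true parcel table is not redistributable.
- **BOLD.** `simulate_bold` inverts the Fisher transform, restores the
  unit diagonal, projects to the nearest PSD correlation matrix if
  needed, and samples a zero-mean multivariate normal; sample correlations
  converge to the target at the usual 1/√T rate.

What the generator does *not* emulate: spatial autocorrelation and
distance-dependent connectivity, head-motion artefacts, scanner noise
spectra, heavy-tailed edge distributions, or any mechanistic origin of
network reliance (couplings are a test harness, not a claim about how
reliance arises). Passing recovery tests therefore demonstrate that the
*estimators* are correct and calibrated under the assumed structure, not
that real data satisfy that structure.

## Problem sizes and determinism

Simulation-based tests use sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances at single-CPU-friendly cost: twin-trait
recovery at 1000–2000 pairs (sampling SE of r ≈ 0.02), ACE recovery at
5000 pairs per zygosity (component SE ≈ 0.015), model-selection
consistency over 50 replicates of 500+500 pairs, association null
calibration over 200 replicate 80-cell scans at n = 450, and
planted-effect recovery at n = 1000. All randomness derives from explicit
integer seeds through `numpy.random.SeedSequence` spawning; identical
config + seed reproduces outputs byte-for-byte (tested).

## Known limitations

- Degree is the only centrality; no betweenness/eigenvector attack and no
  random-failure baseline.
- No mixed-model or GEE alternative for the association step; no
  interaction or nonlinear terms.
- Univariate twin models only: no ADE (dominance), bivariate, or
  sex-limitation models. The "AC" variant (dropping E) is degenerate —
  zero unique variance makes the pair likelihood singular — so the
  implemented set is ACE, AE, CE, E.
- Tie-break and isolated-node ordering rules in the attack are this
  package's own deterministic conventions; other implementations may
  order exact ties differently.
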