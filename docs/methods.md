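# Methods

This note documents the statistical models implemented in `evomorph`, their
assumptions, the defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Model assumptions

All comparative machinery assumes multivariate Brownian motion (BM) on a
rooted phylogeny with branch lengths: trait values at the tips are jointly
Gaussian with covariance R ⊗ C, where C is the N×N matrix of shared
root-to-MRCA path lengths and R the trait (coordinate- or landmark-level)
rate/covariance matrix. No other evolutionary models (OU, early-burst,
branch-specific shifts) are implemented anywhere. Polytomies and
non-ultrametric trees are handled naturally through C; zero-length branches
are allowed (C is PSD-repaired by eigenvalue clipping at 1e-12·λmax with a
warning when numerically indefinite).

Expected values E(X) are always the GLS root-state estimates
a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X, including inside the landmark rate matrix and the BM
likelihood — never arithmetic means. C⁻¹ is applied through a cached
Cholesky factor; no explicit inversion.

Two divisor conventions coexist deliberately: the coordinate-level
evolutionary rate matrix uses N−1 (sample-covariance convention; with C = I
it reduces exactly to the ordinary covariance matrix), while the
landmark-level rate matrix uses 1/N. Both are exposed where relevant and
the bookkeeping identity diag_landmark = trace(coordinate block)·(N−1)/N is
covered by a test.

## Procrustes alignment

Full generalized Procrustes: translation removal, scaling to unit centroid
size (sizes recorded in original units before scaling), and per-iteration
optimal rotation via the Kabsch solution with reflections disallowed
(det +1) — biological configurations must never be mirrored. Convergence
when the consensus moves < `tol` (default 1e-10 RMS, max 100 iterations).
After convergence the whole sample is rotated into a canonical
principal-axes frame of the consensus (axis signs fixed by the
largest-magnitude coordinate; the last axis sign keeps the frame proper), so
the output is invariant (≤1e-8 RMS) to arbitrary rigid motions and global
rescaling of the inputs. Semilandmarks are treated as fixed points — no
sliding is performed. Bilateral averaging is expressed through the
specimen→species map given to `species_means`; sizes average on the
original (not log) scale.

## Congruence and module detection

The congruence coefficient between landmarks is the trace-ratio of the d×d
blocks of the coordinate-level rate matrix; with a star phylogeny it equals
the classical centered-dot-product congruence exactly (oracle-tested to
1e-10). Landmarks with zero variance trace get undefined (NaN) rows and are
excluded from clustering with a warning.

Open choices, resolved as follows:

* **Correlation → dissimilarity**: d = √(2(1−r)), the Euclidean-embedding
  metric, monotone in −r. Signed r is used by default (the congruence
  definition produces signed coefficients and no folding instruction
  exists); `fold_abs=True` folds to |r|.
* **Broken-stick count**: the number of *leading, contiguous* eigenvalue
  proportions exceeding b_i = (1/k)Σ_{j≥i}1/j; counting stops at the first
  failure. If no axis exceeds its expectation the floor is m = 1 (no
  modularity), with a warning.
* **Constrained Ward**: hierarchical agglomeration minimizing
  (1−α)·ΔI(D0) + α·ΔI(D1) at each merge, with D0 (congruence) and D1
  (consensus-geometry distances) each rescaled by its maximum so α is
  comparable across datasets; α defaults to 0.5. α = 0 and α = 1 reduce to
  plain Ward on either matrix (verified against scipy's Ward linkage).
  Merge ties are broken by the lowest original landmark index pair, making
  the dendrogram deterministic. `choice_alpha` reports explained
  pseudo-inertia curves per matrix across an α grid for the operator.

## Confirmatory tests

**Covariance ratio.** CR is computed from the phylogenetically corrected
coordinate covariance: for module pair (a,b),
CR_ab = √( tr(R_ab R_abᵀ) / √(tr(R̃_aa R̃_aaᵀ)·tr(R̃_bb R̃_bbᵀ)) ) with the
within-block diagonals zeroed; the overall statistic averages over module
pairs. The permutation unit is the whole landmark (its d coordinates move
together), module sizes are preserved, the test is left-tailed (low CR =
modularity), and p uses the +1 estimator, so it is conservative-exact.
Note an intrinsic floor: with few landmarks a non-negligible fraction of
permutations reproduces the tested partition exactly (≈3% at k = 8 split
4/4), bounding the attainable p from below.

**EMMLi-style likelihoods.** Each model assigns one correlation parameter ρ
per cell of unique off-diagonal congruence coefficients (single pooled ρ;
pooled within + pooled between; per-module within + pooled between;
per-module within + per-pair between). ρ̂ is the back-transformed mean of
Fisher z(r) (floored at 0), which maximizes the z-normal likelihood with
variance 1/(n_eff−3); the closed form is grid-verified in tests. AICc uses
the number of ρ cells as the parameter count and the number of unique
coefficients as the sample size. Defaults: coefficients folded to |r|
(sign-free covariation strength; signed variant behind a flag), and
n_eff = number of species, since the correlations are across-species
evolutionary correlations — both are configurable because the effective
sample size of correlation likelihoods on derived matrices is debatable,
and conclusions should be checked for sensitivity to it.

## Allometry

Sequential (Type I) decomposition in the fixed order size → group →
size×group, matching the conventional ANOVA-table layout; shape is the
flattened Procrustes data, size the natural log of centroid size (the base
affects coefficients only). Significance by RRPP: residuals of the
reduced model for each term are permuted, the term's F recomputed against
the full-model residual, p = (1+#{F* ≥ F})/(n_perm+1) with 999 permutations
by default (minimum reportable p = 1/(n_perm+1)). The PGLS variant
premultiplies response and design (including the intercept) by L⁻¹ from
C = LLᵀ and permutes whitened residuals; with C = I it equals the ordinary
fit to machine precision (tested). The homogeneity-of-slopes test is the
size×group interaction F from this engine.

The common allometric component is the pooled within-group regression
vector of shape on log size, unit-normalized; scores project grand-mean
centered shape onto it; predicted end-member shapes evaluate the full
linear model at the observed size extremes with group dummies at their
grand-mean coding (one configuration per extreme).

## Rate heterogeneity

The landmark rate matrix sums per-dimension GLS quadratic forms and divides
by N; its diagonal is the multivariate BM rate of each landmark. The BM
log-likelihood uses the Kronecker identities (quadratic form
tr(C⁻¹(X−E)R⁻¹(X−E)ᵀ) per dimension; log|R⊗C| = N log|R| + k log|C|), with
the Gaussian constant written per dimension as N·k·log 2π so values are
proper log-densities; constants are identical across candidate models and
cancel in comparisons.

**Degenerate Procrustes input.** Aligned configurations are centered, so
the all-ones landmark vector is an exact null vector of the landmark rate
matrix and the full k-dimensional Gaussian is degenerate. `bm_loglik`
detects centroid-free data and evaluates the proper degenerate-Gaussian
density on the (k−1)-dimensional Helmert (centroid-free) subspace,
identically for every candidate R, so model comparisons remain valid;
uncentered data (e.g. simulated shape-space data) use the full space. An
eigenvalue floor of 1e-10·λmax (with warning) repairs residual
near-singularity, e.g. from duplicated landmarks.

**Candidate models.** One shared rate (grand mean of observed diagonal),
one rate per module (module means), and all rates free (observed diagonal).
The off-diagonals are rescaled to preserve the observed correlation matrix
under each candidate diagonal, R_c = D_c^{1/2}·corr(R_obs)·D_c^{1/2},
keeping the candidates nested in their diagonal parameterization. AIC =
−2 logL + 2q with q = number of distinct diagonal values; GLS root states
are identical across candidates and excluded from q.

*Calibration caveat, measured on synthetic data*: with strongly correlated
within-module landmarks (ρ_w = 0.7) the per-module vs one-rate likelihood
gain under a single-rate truth is overdispersed relative to χ²₁/2 (mean
≈1.5 instead of 0.5 at N = 100, k = 12), because the plug-in correlation
matrix is estimated from the same data; the one-rate model then falls more
than 2 AIC behind the best model in roughly 30% of null replicates.
Replacing the plug-in diagonals by MLE scaling does not change this; with
near-independent landmarks the gain calibrates cleanly (mean ≈0.4). AIC
differences between rate models should therefore be read cautiously when
trait correlations are strong — a margin of 2 AIC is not a calibrated
null threshold there.

**Q-mode test.** Statistic: ratio of fastest to slowest per-module (or
per-landmark) rate. Null draws simulate constant-rate BM (grand-mean rate,
observed inter-landmark correlations, coordinate covariance R₀ ⊗ I_d/d) on
the same tree via Cholesky factors and recompute the statistic; the +1
estimator gives a conservative-exact p. Both module-level and
landmark-level units are supported.

## Synthetic data generator

`simulate_shapes` draws species shape deviations matrix-normally with row
covariance C and column covariance Λ^{1/2}(Ψ ⊗ I_d)Λ^{1/2}: Ψ is the block
landmark correlation matrix (ρ_w within, ρ_b between planted modules,
positive-definiteness checked at construction) and Λ assigns per-coordinate
variance σ²_m/d so each landmark's multivariate BM rate is exactly σ²_m.
Log centroid size evolves as univariate BM (rate `size_rate`), and an
allometric component β·(logCS − mean) along a fixed random unit direction
is added, making both β and the direction sharply identifiable. The mean
configuration places each module's landmarks around a separate center
(jitter `module_spread`), so planted modules are spatially contiguous — the
regime the geometric clustering constraint assumes, as in real anatomy.
Raw coordinates are produced by scaling each configuration to its centroid
size and applying a random rotation and translation, so the Procrustes
stage is exercised end to end. Groups are ~balanced contiguous blocks of
the tree's leaf order (clade-like; boundaries jittered by the seed).
Everything is bit-reproducible from (config, seed).

Defaults describe the emulated study system: a ~200-tip Yule clade
(birth rate 1), 3D landmarks, two equal modules with ρ_w = 0.7 and
ρ_b = 0.1, unit per-landmark rates, three clade-based groups, and no
allometry unless requested.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: measurement error and within-species
variation (species values are drawn directly), semilandmark sliding,
bilateral symmetry, missing landmarks, non-Brownian evolution, and
realistic anatomical geometry (module centers are abstract). One
interaction it does expose faithfully: Procrustes translation removal
subtracts each configuration's centroid, which redistributes part of any
module-common variation — with few modules this measurably attenuates
planted between-landmark correlations in the aligned data (and is why
analyses of aligned data are run at study-like landmark counts, k ≈ 30,
in the worked example), while analyses run directly on the simulated shape
space see the planted values exactly.

Rates are in squared shape units per unit branch length; when simulating
raw coordinates for the alignment stage they should be small relative to
the unit-size mean configuration (e.g. σ² ≈ 0.001–0.01 over a depth-~5
tree) so that shape variation stays in the tangent-space regime, as in real
morphometric data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate on: 50-instance oracle
sweeps (congruence at N=20, k=6; dense-likelihood at N≤8, k≤5), 20
replicates for each recovery experiment (module detection at N=64, k=12;
rate-model selection and allometry recovery at N=100, k=12), and 200
replicates × 99 permutations/simulations for each calibration experiment
(CR and allometry nulls at N=50; Q-mode null at N=50, k=10). Allometry
recovery uses a deliberately high signal-to-noise condition (σ² = 0.01 per
landmark, size BM rate 1, β = 1), chosen by an a priori standard-error
analysis so the true direction is recoverable to a few degrees at N = 100;
it measures estimator correctness, not field-realistic power. The whole
suite runs in well under a minute on one CPU.

## Known limitations

* Brownian motion only; no rate shifts along branches, no OU attraction.
* The congruence→cluster pipeline is exploratory; module counts from the
  broken stick are conservative, especially on Procrustes-aligned data
  with few modules (see above).
* EMMLi-style AICc inherits the arbitrariness of n_eff; rankings, not
  absolute weights, are the robust output.
* AIC among constrained rate models is anti-conservative under strong
  trait correlation (see calibration caveat).
* The CR permutation p has a combinatorial floor at small k.
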