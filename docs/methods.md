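# Methods

This note records the statistical model implemented by `kgreg`, the numerical
choices behind it, what the synthetic-data generator does and does not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and estimators

### Prior and KGR solution

A graph signal matrix F ∈ ℝ^(N×T) carries one value per node per time. The
prior is the zero-mean matrix normal `vec(F) ~ N(0, γ⁻¹ K ⊗ H²)`: the Gram
matrix K (Gaussian kernel, bandwidth σ, over the feature columns of X) sets
the correlation between times, and the squared graph filter H² = U η(Λ)² Uᵀ
sets the correlation between nodes. η is decreasing with η(0) = 1, so the
prior concentrates on signals that are smooth over the graph; γ is an overall
precision. The likelihood is `Y = S_N F S_Tᵀ + E` with selection matrices
realised as index sets (no physical reordering is ever performed, so
reordering caveats under autocorrelation never arise).

With white noise, the MAP estimate is

    F* = H² S_Nᵀ Ū (J ∘ (Ūᵀ Y V̄)) V̄ᵀ S_T K,
    S_T K S_Tᵀ = V̄ Λ̄_K V̄ᵀ,   S_N H² S_Nᵀ = Ū Λ̄_H Ūᵀ,
    J_ij = 1 / (λ̄H_i λ̄K_j + γ).

Rows of J index node eigenpairs and columns time eigenpairs, matching the
shape of ŪᵀYV̄. Dense eigendecompositions touch only N′×N′ and T′×T′ blocks.
The brute-force solution — inverting the NT×NT normal-equation matrix with a
1e-10 jitter on K and H² — is retained as a guarded oracle (`fit_kgr_naive`,
N·T ≤ 2000) and the two are asserted equal to relative 1e-8 throughout the
test suite. Jitter appears *only* in the oracles; the efficient path never
inverts K or H², so singular filters (cut-off, ReLU) are handled without
regularisation.

### Product-graph reconstruction

When times themselves live on a graph (a time-vertex problem), K is replaced
by a second squared graph filter H_T², giving the prior
`vec(F) ~ N(0, γ⁻¹ H_T² ⊗ H_N²)` — the spectral prior of the Cartesian
product graph whenever the filter family is separable
(η(λ_T + λ_N) = η(λ_T)η(λ_N), e.g. the exponential family; a numeric
separability check is provided). We use the squared filters on both axes so
the product prior is exactly "filter applied to white noise on the product
graph"; the solver algebra is unchanged.

### GLS extension

Real residuals are serially and cross-sectionally correlated, so the GLS
variant models `vec(E) ~ N(0, Σ_T(θ) ⊗ Σ_N)`. Σ_T is constrained to an AR(1)
*correlation* matrix (unit diagonal), which removes the Kronecker scale
ambiguity; Σ_N is a free SPD covariance. Given the covariances, the BLUE
solution whitens the observed blocks by the covariance eigenfactors and
applies the same Hadamard solve; the whitened matrices are symmetric by
construction, so all spectra are real without appeal to non-symmetric
eigentheory. Identity covariances reduce the GLS estimator to plain KGR
exactly (asserted to 1e-10).

Given F, the covariances are estimated from E = Y − S_N F* S_Tᵀ:

- **θ**: the negative log posterior
  `N′(T′−1)ln(1−θ²) + (a − θb + θ²c)/(1−θ²) + N′T′α/(1−θ²)` with
  a = tr(EᵀΣ_N⁻¹E), b = tr(EᵀΣ_N⁻¹E B₁), c = tr(EᵀΣ_N⁻¹E B₂) is stationary at
  the real roots of a cubic. The implementation takes all real roots in
  (−1, 1) and keeps the one with lowest cost (uniqueness is not guaranteed
  for every input); if none is feasible it falls back to a 1e-4-spaced grid
  minimisation with a warning. The traces use the banded structure of the
  tridiagonal AR(1) inverse, O(N′²T′), never forming Σ_T⁻¹.
- **Σ_N**: the autocorrelation-corrected ML estimate
  `Σ_ML = E Σ_T⁻¹(θ) Eᵀ / T′` shrunk toward its scaled-identity target with
  the Rao-Blackwell Ledoit-Wolf weight ρ ∈ [0, 1]. When Σ_ML is proportional
  to the identity the RBLW denominator vanishes; ρ = 1 is returned (target
  and estimate coincide, so the value is immaterial). After shrinkage,
  eigenvalues are floored at 1e-10·tr/N′ to protect the downstream Λ^(−1/2).

The **flip-flop** loop alternates these two closed forms from Σ_N = I, θ = 0
until |Δθ| and the relative Frobenius change of Σ_N both fall below 1e-8
(max 100 iterations). The **outer** loop alternates the BLUE fit and the
flip-flop until the relative Frobenius change of F* falls below 1e-6 (max 50
iterations); iteration counts are reported as outer + summed inner. The
stationarity-prior strength defaults to α = 0.1, the midpoint (in log space)
of the 10⁻³–10¹ range over which the algorithm's convergence behaviour is
commonly explored; it is exposed in the config.

**Divergence guard.** The GLS objective
`tr((Y−S_NFS_Tᵀ)ᵀ Σ_N⁻¹ (Y−S_NFS_Tᵀ) Σ_T⁻¹) + γ tr(K⁻¹FᵀH⁻²F)` is evaluated
each outer iteration *at the freshly updated covariances*, so small increases
occur even on healthy runs as the cost asymptotes. A step counts as
diverging only when the cost rises **and** the F-update norm grows; three
consecutive such steps stop the loop early, flagged `converged=False` with a
diagnostic message in the result (a warning, not an exception, so sweeps can
record the failure).

### Laplace marginal variance

The posterior covariance of vec(F) at the MAP point is
`Σ_F = (S_TᵀΣ_T⁻¹S_T ⊗ S_NᵀΣ_N⁻¹S_N + γK⁻¹⊗H⁻²)⁻¹` — exact for plain KGR,
a plug-in approximation when estimated covariances are substituted. Only its
diagonal, re-stacked into the N×T matrix Ω_F, is exposed:

    Ω_F = (Ũ⁻ᵀ ∘ (H²Ũ)) J̃ (Ṽ⁻¹ ∘ (ṼᵀK)),
    S_NᵀΣ_N⁻¹S_N H² = Ũ Λ̃_H Ũ⁻¹,   S_TᵀΣ_T⁻¹S_T K = Ṽ Λ̃_K Ṽ⁻¹,
    J̃_ij = 1/(γ + λ̃H_i λ̃K_j)  (N×T; rows index node eigenpairs).

The two matrix products are non-symmetric but are products of PSD matrices,
hence have real non-negative spectra. Rather than calling a non-symmetric
eigensolver, the implementation diagonalises them through symmetric
congruences — whitening by H on the node side and by the symmetric square
root K^(1/2) on the time side — which collapses the two Hadamard factors to
elementwise squares, (HQ)∘² and (QᵀK^(1/2))∘², making positivity of Ω_F
explicit and keeping all arithmetic real. This requires H to be invertible;
for filter families whose response reaches zero (cut-off, ReLU, cosine at
λ_max) the code falls back to the literal non-symmetric route (eigenvalue
imaginary parts are asserted below 1e-8 of the spectral radius, then
clipped) and warns. The literal route is also kept as a cross-check in the
tests, and Ω_F is asserted equal to the diagonal of the dense Σ_F oracle to
relative 1e-6 on random partially observed instances. Full Σ_F is available
only through the guarded test oracle; it is impractical at real sizes and is
deliberately not part of the public surface.

Credible bands are `F* ± k√Ω_F` (default k = 2). Under estimated covariances
Ω_F ignores hyperparameter and covariance uncertainty, so it is a lower
bound on the true predictive uncertainty.

## Synthetic-data generator

The generator reproduces the reference simulation design used throughout the
tests: a chain graph of N = 100 nodes over T = 120 times; a latent signal
F = HW with W i.i.d. standard normal and H the exponential diffusion filter
(β = 1) on the chain; 80% of nodes and times observed (so 64% of node-times
are in the train set); matrix-normal errors at the observed block with AR(1)
θ and node covariance either identity or squared-exponential
`exp(−(i−j)²) + 0.05δ_ij`; and M = 12 i.i.d. Gaussian feature columns. The
baseline fit configuration is γ = 1, β = 1, σ = 4, α = 0.1. All generators
are pure functions of (parameters, seed).

Two deliberate properties of this design matter for interpreting test
results:

- **The features carry no information about the signal.** F is generated
  independently of X, so the kernel K is uninformative and predictions at
  *hidden times* come essentially from the prior. Passing tests therefore
  demonstrate masking, estimation and uncertainty machinery — not that
  feature-driven prediction works on real data where X is informative.
- **F = HW is not a draw from the model prior** γ⁻¹K⊗H². Calibration of the
  credible bands is therefore checked on a separate well-specified design in
  which F is drawn from the model's own prior (F = HW·chol(K)ᵀ/√γ, K built
  from the generated features) with known-θ matrix-normal noise; the
  flip-flop covariances are still *estimated*, so the check exercises the
  Laplace plug-in. The coverage assertion (≥ 85% at 2σ, averaged over seeds)
  leaves room below the nominal ~95% for plug-in slack.

What the generator does not emulate: real sensor layouts (graphs other than
the chain are accepted but not defaulted), informative or autocorrelated
features, non-Gaussian or heteroscedastic noise, and time-varying
missingness (the observed node set is constant over time by construction,
matching the model's assumption).

Problem sizes in the automated checks are chosen to keep each experiment in
the seconds-to-minutes range on one CPU: oracle comparisons run at N ≤ 10,
T ≤ 12 (the dense oracle is O((NT)³)); θ-recovery at N′ = 50, T′ = 400 ×
200 replicates; full-pipeline comparisons at the reference 100×120 design
with 12–50 replicates; coverage at 60×80 × 50 replicates.

## Numerical choices

- Eigendecompositions of symmetric matrices use `numpy.linalg.eigh`
  (ascending eigenvalues); spectra are compared as sorted multisets, never
  eigenvectors (sign/rotation ambiguity). Tiny negative eigenvalues from
  rounding are clipped at zero.
- Connected components are counted as eigenvalues below 1e-8·λ_max.
- The cosine filter needs λ_max; it uses the decomposed graph's largest
  Laplacian eigenvalue (computed once and cached) and clips λ into
  [0, λ_max] so the response never goes negative.
- SPD inputs to the GLS whitening are rejected when the smallest eigenvalue
  is below 1e-12·trace.
- Degree-zero nodes are allowed: they contribute zero Laplacian rows,
  decouple in the prior, and their posterior at unobserved times is the
  prior itself.
- AR(1) assumes consecutive observed time columns are consecutive, regularly
  spaced steps. The kernel side needs no such assumption (times may be
  irregular); when both are used together the AR(1) assumption governs.
  These two conventions are not reconciled further.
- CSV output uses 12 significant digits, making repeated runs byte-identical.

## Design choices made where the design was open

- **Cubic root selection**: "the" MAP estimator of θ is taken as the
  feasible real root minimising the exact cost, since uniqueness in (−1, 1)
  is not guaranteed for arbitrary residuals.
- **Initialisation**: Σ_N = I, θ = 0 for both loops — the white-noise model
  is the natural neutral starting point and makes the first outer iterate
  exactly the plain KGR fit.
- **Squared-exponential node covariance**: the generator uses
  `exp(−(i−j)²) + 0.05δ_ij`. A positive exponent would grow without bound
  off-diagonal and could not be a covariance; the negated form is the
  standard squared-exponential kernel.
- **Tuning**: cross-validation partitions the observed times uniformly at
  random into folds; grids for γ, β, σ are log-spaced, with optional
  Nelder-Mead polish in log space from the best grid point. A temporal
  (first-80%/last-20%) split is available through the selection interface.
- **Interface scope**: the coordinate-based graph builder offers a plain
  Euclidean MST or symmetric kNN union with weights exp(−d/median d); it is
  plumbing for users without a given graph, not a recommended construction.

## Limitations

- Missingness must be a constant node subset over a time subset; arbitrary
  per-entry missingness is out of scope.
- One scalar observation per node-time (d = 1); no multi-channel signals.
- The AR(1)-with-scalar-θ noise model cannot express node-specific
  autocorrelation (Θ ≠ θI) or higher-order AR(p) structure.
- Hyperparameters (γ, β, σ, α) are point-tuned; no uncertainty over them or
  over (θ, Σ_N) propagates into Ω_F.
- Dense H² and K are formed explicitly, so memory is O(N² + T²); no
  low-rank/Nyström or sparse-polynomial-filter approximations are provided.
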