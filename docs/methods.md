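# Methods

This note documents the models, estimators, default parameters and design
decisions behind `dyngrad`, and what the synthetic-data experiments do and
do not establish about real data.

## Gradient estimation

Functional connectivity is the Pearson correlation of region time courses;
scan-wise FC matrices are averaged into a study FC. The embedding chain is:

1. **Row thresholding.** Per row, the ⌈density·(N−1)⌉ largest off-diagonal
   entries are kept (default density 0.10), ties broken toward the lower
   column index; the result is asymmetric. A matrix-wide threshold is a
   one-line variant but row-wise is the default because it guarantees every
   region keeps a profile.
2. **Normalized-angle affinity.** `A_ij = 1 − arccos(ρ_ij)/π` with ρ the
   cosine similarity of thresholded row profiles, clipped to [−1, 1].
   Identical profiles give 1, orthogonal 0.5, antiparallel 0. The
   thresholded matrix is symmetrized through this step (cosine of row
   pairs), as the diffusion kernel must be symmetric.
3. **Diffusion embedding.** Anisotropic normalization `W = D^−α A D^−α`
   with α = 0.5, transition matrix `P = D_w^−1 W`, eigendecomposition via
   the symmetric conjugate; the trivial constant eigenvector is dropped;
   components are scaled by λ/(1−λ) (diffusion time 0). Explained variance
   is λ_k²/Σλ² over the retained spectrum with negative eigenvalues clipped
   to zero, so the vector is probability-like and nonincreasing. α and the
   time-0 scaling are the community defaults; both are arguments.
4. **Alignment.** Orthogonal Procrustes without isotropic scaling, so
   explained variance keeps its meaning across arousal bins. Fingerprinting
   reports the k×k |Pearson| matrix between two gradient sets and an
   order-match score (mean diagonal − mean off-diagonal), invariant to sign
   flips.

Two properties of this chain matter for interpretation. It is
**scale-invariant**: multiplying all off-diagonal connectivity by a
constant leaves the affinity, hence the gradients and their explained
variance, unchanged — uniform connectivity-strength changes are invisible,
only *relative* structure changes register. And the explained-variance
fraction is **not monotone** in simple structure dilution: mixing an
unstructured correlation matrix into the connectivity can raise or lower
the first gradient's share depending on which tail eigenvalues it inflates.
Both were verified numerically at population level and shape what the
synthetic experiments can assert (see "Dynamics" below).

## Arousal indices

The behavioral index is the per-TR median of valid pupil samples (blinks
are missing samples; frames with no valid sample are linearly interpolated
and flagged) divided by the per-scan maximum, making it scale-invariant and
confined to [0, 1]. The eye-open ratio is the fraction of frames with at
least half their samples valid. The arousal template correlates each
region's BOLD course with the canonical double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6) convolution of the behavioral index, computed
per scan and Fisher-z averaged; the fMRI index is the spatial correlation
of each frame with that template, without frame z-scoring (region courses
are already zero-mean after demeaning). Equal-sample binning ranks frames
by index and drops remainder frames symmetrically from the rank extremes,
so every bin has exactly the same degrees of freedom.

## Dynamic connectivity

DCC is the standard two-stage quasi-maximum-likelihood estimator:
GARCH(1,1) per region (ω > 0, α, β ≥ 0, α+β < 1; three deterministic
starts, L-BFGS-B, likelihood tolerance 1e-12) on demeaned series, then
scalar DCC(1,1) on the standardized residuals with correlation targeting
(`Q_t = (1−a−b)S + a z_{t−1}z_{t−1}ᵀ + b Q_{t−1}`, S the unconditional
correlation). Parameters at the stationarity boundary are clamped to
1 − 1e-4 with a warning. The recursions are numba-compiled when numba is
present; the pure-NumPy fallback is identical.

Validation uses simulation from the *same model family* (known GARCH/DCC
generator): (a, b) are recovered with absolute bias well under 0.05 at
T = 3000–4000, and a step change in correlation is tracked. On the
generator's arousal-modulated cohorts at reduced scan lengths, the DCC QMLE
correctly concludes that conditional-correlation dynamics are weak
(a ≈ b ≈ 0): the planted modulation moves individual correlations by only
a few hundredths, below the innovation noise at those lengths. For this
reason the arousal-binned analyses in the acceptance experiments estimate
bin-level connectivity by equal-sample binning of frames (the sample
correlation of each bin's members), which is statistically sufficient for
bin means; the DCC route remains the frame-resolved estimator in the
pipeline and is validated separately.

Bin-mean matrices are re-projected to the nearest correlation matrix
(Higham alternating projections, tolerance 1e-8) before embedding. Flow in
gradient space is summarized per network as the least-squares linear drift
of the (G1, G2) centroid across ordered bins; its magnitude is tested
against a scan-level arousal-shuffle null with the +1-corrected permutation
p-value. FC entropy is the Shannon entropy (bits) of the upper-triangle
histogram over 64 fixed bins spanning [−1, 1]. Quadratic trends are OLS
fits `y = c₂x² + c₁x + c₀` classified by the 95% CI of c₂ (inverted-U/U)
or, failing that, of c₁ (monotone) — otherwise flat.

## Variance partitioning

The pair-level model `FC = b0 + b1·SC + b2·NS` is solved with a small ridge
penalty on the slopes (trace-scaled, default 1e-6, intercept unpenalized);
at the default the solution coincides with OLS on well-conditioned data and
the "norm-constrained least squares" reading is preserved for collinear
predictors. Cross-validation leaves one scan out, fits on the mean FC of
the rest, and scores 1 − SSE/SST on the held-out scan (squared Pearson is
also reported). Single-variable models upper-bound a predictor's
contribution; the reduced model lower-bounds its unique contribution:
ΔR² = cvR²(full) − mean cvR² over shuffles of that predictor. Shuffles
permute *region identities* (rows and columns jointly), keeping the
shuffled predictor a valid similarity matrix and its degrees of freedom
intact; independent pair permutation is available as an option. 1000
shuffles by default; the experiments here use 50–200 and record the count.

Receptor contributions replace one receptor's expression map by surrogate
maps, rebuild the neuromodulatory similarity and refit the arousal-binned
GLM. Significance does **not** use the similarity-slope correlation test as
the decision rule: for a truly inert receptor, the surrogate-similarity →
surrogate-R² regression has a nonzero cohort-level true slope of random
sign (a map's direction within the similarity matrix aligns by chance with
the fit residual), making the right-tailed t-test structurally
anti-conservative (~25% false positives at 200 surrogates in our
experiments). Decisions instead use the exchangeability-based rank test:
p = (1 + #{surrogate R² ≥ empirical R²})/(1 + M), which is calibrated by
construction and retains full power for loaded receptors. The slope
statistic is still computed and reported as a diagnostic, and behaves as
documented when the independence assumption actually holds. FDR control is
Benjamini–Hochberg at q = 0.05.

## Spatial-autocorrelation-preserving surrogates

Semivariograms use equal-count lag bins (default 15) and, for surrogate
fitting, only pairs below the 25th percentile of the distance distribution:
the long-range semivariance of a single smooth realization is dominated by
realization-specific drift that no sill-bounded surrogate can match, and
the short range is where spatial autocorrelation biases map-level tests.
Each surrogate permutes the map, smooths it with an exponential
distance-kernel truncated at k nearest neighbors (k ∈ {2, 3, 5, 8, 13, 21,
34, 55}), and fits `γ_target ≈ β·γ_smooth + α` by per-lag relative least
squares, α ≥ 0 acting as a white-noise nugget; the k with the smallest
relative residual wins. Ensemble-mean variograms match the target within
15% at every lag on smooth maps; the surrogate-correlation null is centered
and the resulting p-values are uniform under independence, while the naive
parametric test rejects ~40% of independent smooth-map pairs at α = 0.05 —
the reason the correction exists.

## The synthetic cohort generator

The generator emulates, at region scale, the statistical structure the
analysis assumes. Regions are uniform points in the unit square; smooth
maps are Gaussian random fields with covariance exp(−d/0.3). The frame
model is

    x_t = L(a_t) ε_t + g·(a_t − ā)·template + σ_obs η_t,

where `L(a)L(a)ᵀ = w_SC·SC + w_NS(a)·NS + (1 − w_SC − w_NS(a))·I` is a
convex combination of correlation matrices (valid by construction; the
Higham projection is applied as a safeguard), `w_NS(a) = c·4(a−½)²`
(U-shape; the inverted-U variant flips it), and `a_t` is a logistic-squashed
AR(1) (persistence 0.95 per 2-s frame). An optional mixing toward an
unstructured correlation matrix (`ev_mod`) plants arousal-dependent
dilution of gradient structure. The pupil trace is a sample-and-hold
upsampling of `a` at 6 fps with Gaussian noise and Poisson blink gaps
(< 0.5 s). Tracing weights are log-normal with distance-decaying means;
expression maps are loadings on the planted maps plus *spatially smooth*
noise fields (histology-derived maps are smooth; smoothness is also what
makes surrogate ensembles exchangeable with empirical maps). Null receptors
have exactly zero loading and never enter the generative neuromodulatory
similarity — they are genuinely inert, which is what a null-receptor
discrimination experiment requires.

**Chain-consistent ground truth.** The planted gradient maps are *defined*
as the connectivity gradients of the expected static correlation of the
full generative model (including the mean arousal modulation, the template
covariance and observation noise), computed once per cohort
(`refine_gradient_maps`). Without this, the threshold/angle chain's
nonlinearity displaces the estimator's noiseless fixed point from the raw
generating fields by enough to cap recovery correlations near 0.87, which
would conflate estimator error with a convention mismatch. Gradient maps
are unit-normalized but not forced to Euclidean orthogonality (diffusion
components are orthogonal in the stationary measure); the receptor-specific
and template maps are orthogonalized against the gradient subspace.

**Default conditions.** 116 regions (55 tracing targets), TR 2 s, 6 fps
pupil sampling, 10 scans × 500 frames, w_SC = 0.45, NS modulation amplitude
0.35, σ_obs = 0.2, 16 receptors (4 null) with noise SD 0.5, template gain
1.0, structural eigenweights (0.48, 0.44). The eigenweights give two strong
planted gradients whose chain eigenvalues sit well above the non-planted
floor — with a weaker second gradient the chain's gap compression makes the
second component ill-conditioned and its recovery a coin flip, which tests
nothing about the estimator.

**Per-experiment regimes.** The acceptance experiments prescribe their own
cohort configurations, as experiments do: gradient recovery runs in a
weak-global-artifact regime (template gain 0.8, N = 100, 5000 frames),
arousal readout in a strong-arousal regime (gain 1.2, 4 × 512-frame scans,
N = 100) — the template's rank-1 covariance forms its own connectivity
gradient at high gain, so the two properties have genuinely conflicting
optimal regimes and are measured where each is well-posed. The opposing
ΔR²-trend experiment uses 30-region, 3 × 400-frame cohorts with 50 shuffles
per bin; receptor discrimination uses 60-region, 3 × 500-frame cohorts with
8 receptors (3 null), w_SC = 0.40, modulation amplitude 0.45, expression
noise 0.3, and 200 surrogates per receptor. All sizes appear in
`tests/test_acceptance.py` and `scripts/acceptance.py`.

## What the synthetic experiments do and do not show

Passing tests establish that the estimators recover what the generator
plants: gradient maps under sampling noise, a latent arousal process behind
a noisy pupil and a hemodynamic template, DCC parameters from its own model
family, unique-contribution bounds with correct ordering and null behavior,
opposing arousal modulation of predictor contributions, receptor
discrimination at controlled false-positive rates, and calibrated spatial
nulls. They do not establish that real cortex satisfies the generative
assumptions: real BOLD has hemodynamic temporal autocorrelation, motion and
physiological artifacts, non-Gaussian tails, geodesic rather than Euclidean
geometry, and arousal dynamics richer than a one-dimensional AR(1). The
generator also leaves one documented gap: a planted *explained-variance*
arousal modulation is not reliably recoverable end-to-end, because the
embedding chain is scale-invariant and its explained-variance fraction is
non-monotone in structure dilution; the per-bin EV machinery is therefore
validated on directly planted eigenweight courses, and the arousal story is
carried by the ΔR² trends, which are robust.

## Numerical choices

Nearest-correlation projection: Higham alternating projections, tolerance
1e-8, 200 iterations, final eigenvalue clip. Threshold ties: lower column
index. Degenerate inputs raise informative errors (constant region series,
isolated affinity nodes, disconnected graphs, constant maps, single scans).
Permutation p-values always use the +1 correction. All randomness flows
from explicit integer seeds; one global seed fans out to stage seeds by a
crc32-based hash, and identical seeds reproduce every artifact bit-exactly
across processes.
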