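# Methods

## The measurement model

A molecule carries two differently colored fluorophores separated by a true
distance `d`. Each fluorophore is localized with per-axis Gaussian error
(`σ_loc1`, `σ_loc2`, in nm), and mapping the two camera channels onto each
other leaves a residual registration error `σ_reg`. The measured separation
vector is therefore the true separation plus isotropic Gaussian noise with
per-axis SD

    σ_d = sqrt(σ_reg² + σ_loc1² + σ_loc2²)

and the measured Euclidean distance `r` follows the 2D radial density

    p(r | μ, σ_d) = (r/σ_d²) exp(−(μ²+r²)/(2σ_d²)) I₀(rμ/σ_d²),

the Rice distribution with location `μ` and scale `σ_d`. Two limits shape
everything downstream. For `μ = 0` it is exactly Rayleigh. For `μ/σ_d → 0`
the density becomes independent of `μ` (the leading `μ` dependence can be
absorbed into the scale; what distinguishes `μ > 0` from `μ = 0` is an
O((μ/σ_d)⁴) correction). Quantitatively, the Kullback–Leibler divergence
between the density at (μ, σ) and the best-matching Rayleigh is ≈ 1.9·10⁻⁵
per observation at μ/σ = 0.5, i.e. several hundred thousand observations are
needed before the data distinguish a distance of half the uncertainty from
zero. This is the identifiability cliff that the estimators below are
designed around.

All distances and errors are in nm everywhere in the package; pixels exist
only inside the localization module (converted at 159 nm/px by default).

## Estimators

**P2D (two-parameter MLE).** Reference method: maximize the likelihood over
(μ, σ_d) jointly. Near and beyond σ_d ≈ μ this fit is driven by σ_d and
collapses toward μ = 0. Two findings from this implementation are worth
recording. First, on *homogeneous* data (every pair sharing one σ_d) a
careful multi-start MLE is consistent and does not collapse at ratio
σ_d/d = 1 with thousands of points — the likelihood's μ = 0 stationary point
is exactly marginal (the Rayleigh-profile condition Σr² = 2nσ̂² is an
identity at the optimum), and the quartic term decides, in favor of the
truth for large n. Second, the reproducible collapse appears as soon as the
per-pair uncertainties are heterogeneous (as they always are in real data
and in the Gamma-mixture generator below): the pooled two-parameter model is
then misspecified, its fitted σ̂ inflates to cover the mixture tails, and the
μ basin at the truth loses to μ ≈ 0. The often-reported "underestimates by
almost 100%" behavior of this estimator is that misspecification effect, not
an optimizer artifact.

**Sigma-P2D (one-parameter MLE).** Fix each observation's σ_d to its
measured value and maximize over μ only:

    μ̂ = argmax_μ Σᵢ log p(rᵢ | μ, σ_d,ᵢ)

The per-observation σ_d,ᵢ form generalizes the pooled write-up and reduces
to it for constant σ_d. This removes the degeneracy: the benchmark suite
recovers d within ~10% of truth with only 100 particles up to σ_d/d = 3, and
within ~0.6% with 10,000 particles at σ_d/d ≤ 2 (mean over 100 simulated
datasets; single-dataset estimates at high ratios remain bimodal, which is
visible as large SDs across repeats).

**Vector / Vector-P2D (population averages over frames).** With F frames per
molecule, average dx and dy separately and take the norm of the mean vector;
coherent averaging shrinks the noise scale to σ_vec = RMS(σ_d)/√F, while
frame-by-frame distance averaging would rectify the noise instead. Vector
fits a (untruncated) Gaussian to the averaged distances — its mean is biased
upward by ≈ σ_vec²/2μ and badly so once σ_vec ≳ μ. Vector-P2D fits the P2D
CDF (numeric integration of the density) to the empirical CDF of the
averaged distances by nonlinear least squares, evaluating the model CDF at
every sorted sample point (Hazen plotting positions (i−½)/n; no histogram,
no bin-size choices). NLLSQ on the ECDF degrades gracefully with background
outliers where MLE does not; with 5% uniform background the two agree, and
beyond that NLLSQ is the safer default. An optional high distance cutoff
(several times the expected distance) may drop gross outliers.

**SEMs.** Sigma-P2D and P2D report the Wald SEM from the observed Fisher
information — the numerical second derivative of the log-likelihood in μ at
μ̂, computed on the *exact* log-density (the approximation switch below makes
the fitting objective minutely discontinuous, which a finite-difference
curvature would amplify catastrophically). In the well-posed regime
(σ_d ≲ d/2) the 2-SEM interval covers the truth at its nominal ~95%; in the
weakly identified regime Wald intervals undercover, as they do for any
estimator near an identifiability boundary. Vector and Vector-P2D use a
particle-level bootstrap (default 1,000 resamples, seed required);
non-positive curvature triggers a bootstrap fallback.

## Numerical choices

- All densities are evaluated in log space with the exponentially scaled
  Bessel function: log I₀(z) = log i0e(z) + z turns the product into
  exp(−(r−μ)²/2σ²) times a slowly varying factor, finite far beyond the
  naive overflow point (z ≈ 700). A clamp to the floating-point extremes
  remains as a final guard on the linear scale.
- The Gaussian approximation
  p ≈ (2πσ_d²)^{−1/2} √(r/μ) exp(−(r−μ)²/2σ_d²) replaces the exact form in
  the fitters whenever the current σ_d estimate is below μ̂/2. It agrees with
  the exact density within 2% for σ_d ≤ μ/4 and within ~13% at the switch
  boundary; the switch lives in the fitters, not in the density functions.
- The CDF is computed by adaptive quadrature of the density on
  [max(0, μ−12σ), μ+12σ] (requested tolerance 1e−10; mass outside that
  interval is < 1e−30 and treated as an analytic tail bound). The NLLSQ
  fitter uses a cumulative-Simpson grid at resolution σ/10 instead, which is
  orders of magnitude cheaper and accurate far below ECDF noise.
- Likelihoods and the ECDF objective are near-flat in μ below the scale of
  σ_d and can be bimodal (a basin at the truth and one at zero), so every
  fitter scans a coarse scale-covariant grid (built from data quantiles)
  before polishing the best basins locally; ties break to the higher
  likelihood, then the smaller μ. This makes all estimators exactly
  equivariant under rescaling of the data.
- Degenerate inputs: zero-variance samples are returned flagged
  non-converged for the two-parameter fits (the scale is unidentified) and
  handled exactly by the one-parameter fit (μ̂ = r₀ as σ → 0).

## Registration

Channel 2 is mapped onto channel 1 in two stages. A global affine transform,
least-squares fit to mutual-nearest-neighbor bead pairs (centered
coordinates for conditioning; pairs re-derived once after the first fit and
pruned by an iterated 5×median residual rule, since a few accidental
mispairings otherwise leverage the fit), brings the channels close enough
for reliable pairing. A piecewise-affine stage then corrects each point with
a local affine fit to the nearest control beads — at most 100, within 2 µm,
at least 10, ties broken by index — which removes the smooth nonlinear
distortion a single affine cannot. Queries with too few neighbors are
uncorrectable regions and raise (or are excluded from TRE statistics);
a control point never votes on its own correction, so evaluating the map on
its own beads is a leave-one-out TRE. Registration quality on independent
test beads is summarized by the mean residuals (μ_x, μ_y), their SDs, and
σ_reg = √(μ_x²+μ_y²); maps with σ_reg < 1 nm are accepted for distance
analysis. On simulated 80×80 µm fields with a 20 nm quadratic warp and
realistic bead density (~8,000 beads), the piecewise stage reduces the TRE
residual spread several-fold relative to the global affine and reaches
σ_reg well below 1 nm.

## Localization

Spots are local maxima exceeding the surrounding ROI ring mean by a noise
tolerance, resolved greedily by brightness into non-overlapping odd-sized
boxes. Each ROI is fit by Poisson MLE of a symmetric integrated-Gaussian PSF
(pixel-area erf integrals, not point samples) over a constant background,
started from the centroid, width 0.9 px, ring-mean background, and
sum-minus-background intensity. (The starting-condition convention of
"summing the outermost pixels" for the background is ambiguous between sum
and per-pixel mean; the per-pixel mean is used as the background parameter.)
Photometry for downstream use comes from the aperture method — ring-mean
background, background-subtracted ROI sum — which tracks measured variances
better than the MLE amplitudes; the MLE photometry is kept as a diagnostic.

The per-spot localization variance fed into σ_d is the Cramér–Rao bound of
the same imaging model, evaluated directly from the Fisher information of
the pixelated Gaussian + constant Poisson background lattice (spot centered
on a pixel, lattice wide enough to hold all mass):
var(x) = 1 / Σ_k (∂μ_k/∂x)²/μ_k. This choice is deliberate: the widely
transcribed closed form with the 16/9 prefactor is the *least-squares*
variance of the underlying theory and overshoots what an efficient MLE fit
actually achieves at low background by ~78%. The package therefore computes
the bound itself (a few hundred erf evaluations) and validates it by the
repeat-simulation calibration test: predicted SD within 30% of the empirical
SD of repeated fits across N ∈ {500, 2,000, 10,000} photons and backgrounds
∈ {1, 10, 50} photons/px (measured agreement is a few percent at typical
conditions). EM gain is not modeled (conventional CCD acquisition).

## The Monte Carlo generator

`simulate_pairs` draws, per particle, a true separation vector
(d + g₁, g₂) with g ~ N(0, σ_con²) per axis — conformational heterogeneity
as an isotropic 2D displacement. This convention (rather than a scalar
truth) is what makes population averaging well-defined: the vector-averaged
distances of a heterogeneous sample are then *exactly* P2D-distributed with
location d and scale √(σ_con² + σ_vec²), so Vector-P2D estimates the
population center d no matter how broad the heterogeneity. The truth SD
equals σ_con to first order (within 2% for σ_con ≤ d/2) and saturates below
it for σ_con ≳ d, where no non-negative-distance convention can keep them
equal.

Per frame and channel, a localization *variance* is drawn from a Gamma
distribution with mean σ_loc² and SD 2·σ_loc·σ_σ(loc) (shape (m/s)², scale
s²/m — any mean/SD-matched Gamma would do; this is a recorded convention),
and the observed positions add iid per-axis Gaussian noise of that variance.
Registration error adds per-axis Gaussian noise with SD σ_reg to the
channel-2 position, so the empirical per-axis SD of the separation equals
the σ_d composition rule by construction. An `outlier_fraction` of
observations is replaced by background points with distance uniform on
[0, outlier_range_max] (default 5d) in a uniform random direction. A seed is
mandatory and datasets are byte-for-byte reproducible.

The benchmark condition used throughout the suite is: equal channel errors
sized to the target ratio σ_d/d, with a relative Gamma spread of
σ_σ(loc) = 0.25·σ_loc (per-frame precision varying with CV ≈ 0.5 in
variance — typical of real single-molecule data, where intensity varies
spot to spot). What the generator deliberately omits: stage/focus drift,
camera EM-gain noise, dye-orientation (polarization) effects, and
non-Gaussian PSF tails. Passing benchmarks therefore validate the estimators
under the stated noise structure, not the acquisition pipeline itself.

## Benchmark protocol and problem sizes

The benchmark metric is the normalized distance discrepancy
(measured − expected)/expected; −1.0 means the estimator returned 0 nm. For
each condition (estimator × ratio × particles × frames) 100 independent
datasets are simulated and the *mean* discrepancy and its SD across repeats
are reported; a condition is "reliable" when |mean| < 20% with SD < 30%.
Within a condition all estimators see the same datasets, so comparisons are
paired. Non-converged fits are counted and excluded; a cell with > 20%
failures is flagged.

Problem sizes used by the test suite and the acceptance script (chosen as
the smallest sizes at which each claim is statistically meaningful):
Sigma-P2D accuracy at 100 and 10,000 particles and Vector-P2D at 100 and
1,000 particles × 20 frames, 100 repeats per ratio; ordering comparisons at
300–500 particles with 10 repeats; the σ_con = 2d population-average
recovery at 100,000 particles × 20 frames (below ~10⁵ particles the
population center is not identifiable at that heterogeneity — see the KL
number above — and single-dataset estimates are bimodal); localization
calibration with 250 repeated fits per condition.

## Known limitations

- Wald SEMs undercover once σ_d/d ≳ 1 at small n; bootstrap or repeated
  simulation is the honest error bar there.
- Single-dataset estimates near the identifiability cliff are bimodal
  (truth vs zero); only averages over many datasets, or more particles, are
  meaningful, and the large error bars in benchmark grids flag exactly this.
- The Vector estimator's Gaussian fit is untruncated; for σ_vec ≳ μ its
  positive bias is structural, which is the reason Vector-P2D exists.
- 2D only: no axial (z) distances, no astigmatic PSFs, no polarization or
  fluorophore-orientation corrections, no drift correction (assumed handled
  at acquisition).
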