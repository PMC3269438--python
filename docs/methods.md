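# Methods

## Model

Pixel intensities within one spot's target mask are modelled as i.i.d. draws
from a K-component Gaussian mixture, K ≤ 3, whose last (brightest) component
is right-censored at the scanner saturation threshold S (65535 ADU for
16-bit images):

f(y; θ) = Σ_{k=1}^{K−1} π_k φ(y; μ_k, σ_k) + π_K φ_S(y; μ_K, σ_K),

with mixing weights π_k summing to one and means ordered μ₁ < … < μ_K for
identifiability. φ_S mixes a density and an atom: φ(y; μ_K, σ_K) for y < S
and the survival mass 1 − Φ((S − μ_K)/σ_K) at y = S. Saturation is detected
by exact equality y == S after clamping, because scanner saturation is an
exact ceiling in 16-bit TIFF data.

The assumptions worth stating explicitly:

* pixels within a mask are exchangeable — no spatial structure is modelled;
* each population of pixels (background, optional intermediate, foreground)
  is approximately normal on the raw ADU scale;
* only the brightest component can saturate; the background never reaches S.

K = 1 is interpreted as a blank or weak spot, K = 2 as a clean
background/foreground spot, and the middle component of K = 3 as the fuzzy
edge of a bright spot or the inner hole of a donut-shaped spot. K is capped
at 3 because brighter structure than that is not interpretable at the level
of one target mask.

## Estimation

The observed-data likelihood is maximized by EM. Responsibilities are
computed in log space (log-sum-exp), so extreme scale ratios between
components cannot underflow. The M-step uses the closed-form weighted-moment
updates for every uncensored component. For the censored component the
weighted MLE has no closed form; it is found by Newton–Raphson on
(μ, log σ) with analytic gradient and Hessian. Working in log σ keeps the
scale positive without projections. When the Hessian is indefinite the step
is stabilized by a Levenberg shift (H − λI with λ escalated until the step
points uphill), each step is backtracked until the likelihood increases, and
if Newton stalls while the scaled gradient is still large the point is
polished by Nelder–Mead. Convergence requires both a likelihood change below
1e−8 and a small scaled gradient. The solver warm-starts from the previous
EM iterate, so each M-step can only increase the component likelihood
(generalized EM) and the observed-data likelihood ascends monotonically.

Components are re-sorted by mean after every M-step to enforce the ordering
constraint continuously. One subtlety is documented here as the package's
own choice: if the re-sort hands the censored role to a *different*
component, the likelihood function itself changes meaning and the recorded
log-likelihood may drop at that single iteration. `fit_mixture` treats this
as a restart of the monotone ascent — the trace resets and EM continues
under the new labeling — so the reported trace is always non-decreasing and
the final parameters satisfy the ordering. In practice this occurs only on
small, weakly structured masks.

### Numerical safeguards

* **Scale floor.** All σ are floored at 1e−6·S. A component that *converges
  onto* the floor away from S has collapsed onto a handful of identical
  pixels — a spurious likelihood singularity, not a cluster — and the fit is
  rejected (`ComponentCollapseError`), which `select_K` treats as a failed
  candidate. A floored component sitting *at* S is kept: that is the regular
  model's well-known point-mass response to saturated ties, and retaining it
  is essential for honest comparison between the censored and regular fits.
* **Degenerate foreground.** If all of the censored component's mass lies on
  saturated pixels its location is not identifiable (the likelihood increases
  without bound in μ); the component is pinned at S and the fit flagged
  `degenerate_fg`; quantification then reports the foreground as S with the
  flag set.
* **Initialization** is deterministic: sorted pixel values are split into K
  contiguous blocks with sizes proportional to the starting weights
  (K=2 → 0.8/0.2, K=3 → 0.7/0.1/0.2, reflecting typical background /
  intermediate / foreground shares of a target mask), and block moments seed
  the parameters. No random restarts are needed, and fits are exactly
  reproducible.
* **EM stopping rule:** relative likelihood increase below 1e−6 or 500
  iterations; non-convergence is flagged on the result, never silently
  dropped.

## Model selection

AIC/BIC use the standard definitions −2ℓ + 2p and −2ℓ + p·log n with
p = 3K − 1 free parameters. The selected model is the *smallest* K whose
criterion exceeds the best one by less than a relative threshold (default
0.001): a simpler model within 0.1% of the best is preferred. The rule is
deliberately ordered by K so that parsimony wins ties.

## Target masks

Spot centers (from any gridding tool) define the masks. Every image pixel is
assigned to its nearest center in Euclidean distance — the Voronoi
tessellation of the center lattice — which yields hexagonal cells on an
orange-crate (hexagonally offset) layout and rectangles on a rectangular
lattice, with no explicit polygon rasterization. Pixels farther than one
grid pitch from every center stay unassigned so that distant background
cannot bleed into edge cells; cells cut by the image border are clipped and
flagged. Coordinates are 0-based (row, col); centers are supplied in
scanner (x, y) = (col, row) order. GenePix-style tables in microns are
converted by an explicit `microns_per_pixel` scalar — scanner resolution is
metadata the file may lack, so it is never guessed.

Extracted pixel values are clamped to [0, S]. Simulated masks are *not*
clamped below: the generating mixture is a plain normal mixture, unbounded
below, and truncating it at zero would distort the background-parameter
recovery study.

## Simulation design

The generator reproduces the validation study's conditions. Masks hold
n = 500 pixels. The fixed parameters are, for K = 2: π = (0.8, 0.2),
background N(8000, 2000²); for K = 3: π = (0.7, 0.1, 0.2), background
N(2000, 1000²), intermediate N(15000, 6000²). The foreground scale is fixed
at σ_K = 6000 and its location is derived from the target saturated
fraction p_sat ∈ {0.10, 0.40, 0.70} of foreground pixels via
μ_K = S − σ_K·Φ⁻¹(1 − p_sat), so the stated saturation fractions hold in
expectation (at p_sat = 0.5, μ_K = S exactly). Three analysis arms see the
identical data in every trial (per-trial RNG streams spawned from one master
seed): GMM0 fits regular mixtures to the uncensored data, CGMM fits censored
mixtures to the censored data, GMM1 fits regular mixtures to the censored
data. Selection rates count trials with correctly selected K; relative bias
(mean estimate − truth)/truth is computed only over correctly selected
trials, as in the original study. Summaries are byte-identical across reruns
with the same seed.

What the generator does *not* emulate: spatial spot shape (donuts, peaks,
fuzzy edges appear only through the intensity histogram, not geometry),
integer quantization of ADU values, optical flare correlations between
neighboring spots, and any departure from within-component normality.
Passing the simulation study therefore validates the estimator and the
selection rule under the model's own assumptions, not robustness to
real-image artifacts.

The foreground truth convention matters for one comparison: with σ_K = 6000
the three populations remain well separated even at 70% saturation, so the
regular-mixture-on-censored-data arm still identifies K = 3 essentially
always, whereas with a much wider foreground (as the original study's
unprinted truth appears to have been) it frequently drops to K = 2. The
naive arm's qualitative failures — foreground mean biased downwards,
monotonically worse with saturation; foreground scale collapsing — are
reproduced at all design points regardless of the convention. A second
knife-edge quantity is the intermediate component's scale: with only ~50
pixels its ML estimate carries an inherent small-sample bias of about −3%,
visible identically in the uncensored gold-standard arm, so it reflects ML
shrinkage rather than anything censoring-related.

## Problem sizes used by the test suite and acceptance script

The test suite reruns the study at 200 trials per design point and the
acceptance script at 1000 trials (the study's own protocol); both complete
in minutes on one CPU. Monte-Carlo standard errors of the bias estimates are
reported alongside the biases and used for 3×SE agreement checks.

## Known limitations

* Left or interval censoring and non-normal (e.g. Cauchy) components are out
  of scope.
* Automatic spot-center finding is not provided; centers come from external
  gridding software.
* Dual-channel ratio analysis is not defined here — the model is strictly
  per-channel.
* When nearly all foreground information is censored (saturated fractions
  well above 70%), the corrected estimates remain unbiased only on average;
  individual spots can under- or overshoot substantially because the
  likelihood becomes very flat in (μ_K, σ_K).
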