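# Methods

This note documents the modeling assumptions, parameter conventions and
numerical choices behind `frfnet`, and what the simulation-based tests do
and do not establish.

## Stimuli

A stimulus is `w · (1 + m·E) · carrier`, held in memory as zero-mean
luminance contrast (background = 0; 8-bit quantization with 128 = zero
contrast happens only when PNGs are written).

**Carrier.** A dense field of odd-phase (sine) Gabor micropatterns placed
at uniformly random integer positions in an oversize image (margin = one
micropattern on each side) and cropped centrally. The micropattern's
Gaussian envelope s.d. is size/4, so the nominal size spans ±2 s.d., and
its carrier wavelength equals the nominal size; elongated micropatterns
(aspect 2:1) stretch the envelope along the stripe axis. Defaults follow
the experimental designs: 256×256 images with 2048 vertical 32-px
micropatterns (identification and discrimination), 8192 8-px micropatterns
(high-frequency-carrier control), or 512 elongated micropatterns at two
orthogonal orientations (the two-channel design). The accepted carrier is
rescaled to exactly 14% global rms contrast.

**Uniformity.** Carriers are rejection-sampled until every block of a 4×4
partition has rms contrast within ±25% of the global rms. The block size
must exceed the carrier's speckle correlation length (≈ the micropattern
size) for such a criterion to be satisfiable at all: with 32-px blocks a
32-px-micropattern carrier has ~1 speckle cell per block and essentially
every sample fails, while 64-px blocks contain several cells and accept
about a third of draws. Both the partition and the tolerance are
configurable.

**Envelope and window.** The boundary envelope E ramps from −1 to +1 by a
half-cosine over 0.2 of the image width, along the normal of a line
through the image center at the boundary orientation (degrees clockwise
from vertical; +45° is right-oblique). At phase 0 the high-contrast side
is the side toward the bottom of the image (the +x side for an exactly
vertical boundary); phase 180 negates E. This sign convention makes the
+θ and −θ envelopes exact mirror images about the vertical midline; since
phase is randomized across trials it has no behavioral consequence. The
circular window w (radius = half the image size) decays from 1 to 0 at
the rim by a half-cosine over the same taper width; outside it the image
is mean-luminance gray. Modulation depth m is the Michelson modulation of
contrast: the two sides carry contrast c₀(1 ± m).

**Designs.** `exp1_var` uses levels {0} ∪ 9 log-spaced in [0.08, 0.32]
(geometric center 16%) with ±45° boundaries; `exp2_var` uses {0} ∪ 9
log-spaced in [0.16, 0.64] with the boundary perturbed ±JND (default 7°,
configurable per observer) about vertical; the `_fix` variants hold a
single level; `exp3` pairs `exp1_var` levels with the two-orientation
carrier. Trials are exactly balanced over levels, and balanced-random over
category and phase within level. Every trial draws a fresh carrier whose
seed is spawned from the set seed and the trial index, so any single
stimulus is reproducible in isolation and no carrier repeats.

## Front end

One energy channel per carrier orientation: a quadrature Gabor pair with
wavelength matched to the micropattern size and circular Gaussian envelope
s.d. = wavelength/2, applied by FFT convolution with symmetric (reflective)
boundary padding; energy = even² + odd². The even-phase kernel is
DC-corrected so a constant image elicits exactly zero energy.

Normalization is global divisive: each energy map is divided by the mean
energy pooled over the image and all channels (guard constant 10⁻⁶ of the
pooled mean), making features invariant to overall stimulus contrast. The
normalization of the underlying physiological model is not uniquely
determined; a local divisive pool is a plausible alternative but would
cancel the region-wide contrast-modulation signal itself whenever the pool
is smaller than the half-disc, so the global form is the default and the
scheme is kept swappable. One consequence, discussed under Limitations, is
that window-attenuated rim features keep their relative signal-to-noise
ratio while shrinking in scale, which MAP fits compensate with large rim
weights.

Pooling tiles the map into grid×grid blocks (maps whose side is not a
multiple of the grid are first padded symmetrically to the next multiple,
split evenly with the extra pixel at the trailing edge): AVG = block mean,
MAX = block max, SUB = the element at index `block_size // 2` along each
axis. Channel blocks are concatenated in ascending-orientation order
(0° first) for serialization stability.

## Model and estimation

Hidden units compute sᵢ = |wᵢᵀx|^α, evaluated as (|z| + 10⁻¹²)^α so
gradients stay finite near zero for α < 1. Output weights are fixed at ±1
(v‖w‖^α is constant along the scale degeneracy), the decision variable is
u = Σvᵢsᵢ + v₀, and P(R) = γ/2 + (1−γ)σ(βu) with the lapse rate γ fixed
at 0 (retained only as a forward-simulation constant) and β = 1 by default
(absorbed into the filter norms; `fit_internal_noise` offers the explicit
1-D maximum-likelihood search, bounded to [10⁻³, 10³]). DET classification
breaks the measure-zero tie P(R) = 0.5 toward L. Architectures: `single`/
`early_sum` (one L/R pair over the full feature vector) and `late_sum`
(one L/R pair per channel, summed at the output; filters cycle L1, R1,
L2, R2 in coordinate ascent).

The MAP objective is the Bernoulli log-likelihood (computed via
log-sum-exp, equivalent to clipping probabilities at 10⁻¹²) plus
−(1/2λ)Σᵢⱼwᵢⱼ² and, when the smoothness prior is on, −(1/2ω)wᵢᵀS₂ᵀS₂wᵢ per
channel block, with S₂ the 2-D discrete Laplacian stencil at every grid
location and Dirichlet (zero-padded) edges. Smaller λ or ω means a
stronger penalty.

Coordinate ascent optimizes one filter at a time jointly with the bias
(L-BFGS with analytic gradients; a step is only accepted if it does not
decrease the posterior), then α by a 0.05-step grid search over
[0.1, 4.0] refined by bounded scalar minimization. After the first round
the smaller-norm filter is re-initialized to the left-right mirror image
of the larger one — the even rectifier makes filter sign arbitrary, and
this escapes the common one-nonzero-filter local maximum — and the ascent
continues for up to `n_rounds` (default 6; ideal-observer fits, whose α
drifts to the top of the range, profit from 16–20) with early stopping on
relative improvement < 10⁻⁶. Random initialization draws weights with
s.d. 0.01; 3 restarts by default, best posterior wins. Cross-validation
folds are contiguous blocks in trial order (experimental sessions come in
blocks), with a randomized option; degenerate single-class folds are
re-split randomly with a warning.

Because the rectifier is even, refitted filters come back with arbitrary
sign; `weight_map_stats` sign-aligns every bootstrap replicate to the
first before averaging, otherwise ensemble means cancel.

## Simulated observers

The ideal-observer dataset is the true category labels. Ground-truth
observers implement alternative spatial strategies as linear templates on
the feature grid — compass-quadrant "pizza slices" of the inscribed
circle (adjacent pair; a three-sector W-vs-N+E template; a per-trial
random choice among the four informative adjacent pairs), single or
paired ±45° step templates, and whole-field ±20° step templates. Since
envelope phase is randomized, every strategy reads the *magnitude* of its
template projection; thresholds are set at the median statistic over the
presented set (balancing responses) and responses are sampled through a
logistic whose gain is calibrated so the expected accuracy hits a target
(default 0.8, the classification-image convention of near-threshold
performance). The three-slice and slice-pair observers are parameterized
as 90° compass quadrants; the exact sector geometry is a documented
assumption.

For double-pass simulations the package's tests additionally use blended
observers: a task template plus a stimulus-frozen random-strategy
component shared across both passes (weight 0.7 after standardizing both
statistics), emulating the repeatable idiosyncratic structure of human
observers. Without such a hidden component a fitted model predicts a
simulated observer's majority response almost perfectly and DET-mode
agreement sits systematically above the observer's own self-consistency,
which is not the human pattern.

## Evaluation and comparison

Psychometric curves and proportion comparisons use Wald 95% intervals
(p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0, 1], no continuity correction).
Double-pass agreement scores the model against each pass and averages the
two. Decision-variable correlation fixes the two criteria from the
marginal response rates (probit) and maximizes the multinomial likelihood
of the 2×2 agreement counts under bivariate-normal orthant probabilities,
per stimulus category, with 200 trial-bootstrap resamples for SEMs;
degenerate marginals are flagged as undefined. 1-D profiles collapse a
square weight map along the matrix main diagonals (left-oblique),
anti-diagonals (right-oblique) or columns (near-vertical boundaries);
profile positions run in ascending diagonal offset, and a unit-norm
variant divides by the profile's Euclidean norm.

Model comparison uses natural logarithms throughout. For equal-dimension
models ΔBIC = ln p₂(D) − ln p₁(D) at the MAP (the complexity terms
cancel; unequal parameter counts are refused because the shortcut is then
invalid), with 2 ln B₂₁ > 10 reported as "very strong". The closed-form
binomial Bayes factor ln B₂₁ = n·(D_KL(p*‖p₁) − D_KL(p*‖p₂)) is an exact
rearrangement of the Bernoulli likelihood ratio and is tested against it
to 10⁻⁹. Generalization comparison refits both architectures on random
train/test splits and summarizes held-out log-likelihoods.

## Simulation scales used in the tests

The test suite runs on proportionally scaled stimuli: 96-px images with
proportionally smaller and fewer micropatterns, which preserves the
number of independent texture cells per image (and hence task
difficulty), with 8- or 12-fold pooling grids. Two deliberate departures
from pure proportional scaling, used where the scaled geometry would
otherwise destroy the effect under study:

- a *finer carrier* variant (6-px micropatterns at matched density) keeps
  several speckle cells per pooling block, the regime needed for clean
  filter recovery and for edge-localization measurements; the full-size
  designs' own high-frequency-carrier control shows the scientific
  conclusions are invariant to carrier scale;
- the fine-discrimination perturbation is enlarged (10–14° instead of
  6–7°) because at 96 px the ±7° wedge is smaller than one pooling block —
  at reduced acuity the just-noticeable difference is genuinely larger.

Edge-based concentration is measured on weight maps averaged over fits to
independent stimulus replicates (the fold-averaging the full-size analyses
use), because a single MAP fit's ideal-observer weights also contain an
inverse-covariance component: carrier speckle is spatially correlated at
the pooling scale, so the whitening part of the optimal readout spreads
weight beyond the boundary and onto window-attenuated rim cells. That
component is systematic, not sampling noise; replicate averaging removes
the sampling part and the central columns then carry ≥ 60% of the mass.

What the passing tests show: the estimation machinery recovers the
structure that generated the data (templates, localization, expansive α)
under the stated noise and trial counts, and the diagnostic estimators
are calibrated on data satisfying their own assumptions. What they do not
show: that human observers behave like any of these simulated observers,
or that the specific normalization and pooling conventions match the
visual system — human trial data would be needed for both.

## Known limitations

- The first stage is energy-only (no half-wave-rectified or
  center-surround channels, single scale per carrier), so carrier phase
  and polarity cues are invisible to the model by construction.
- Global divisive normalization leaves a scale gradient across the
  windowed image; MAP weights on rim cells are correspondingly inflated,
  and localization metrics should be read on replicate-averaged maps.
- Trial-bootstrap weight SEMs measure response-resampling stability on a
  fixed stimulus sample; they do not distinguish a structured observer
  from a random-strategy one (both yield similar SEMs at matched accuracy
  and n) — template-similarity statistics do.
- MAP point estimates only; no posterior sampling, and the α line search
  is bounded at 4.0, where ideal-observer fits saturate.
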