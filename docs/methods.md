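# Methods

This note documents the models and procedures implemented in scanstorm,
the parameters that matter, the numerical choices, and what the synthetic
data does and does not capture.

## Acquisition model and simulator

A confocal line scanner rasterizes the field of view one horizontal line
per time step. The simulator reproduces this on a sub-lattice `S` of
`N x N` cells, `N = s_px * s_im`, with `s_px = 100` cells per 100 nm
camera pixel (1 nm cells) and a line period `dt = 6 ms`.

Emitter kinetics per scanned line:

* new emitters arrive with rate `lambda_on` (default 0.12 per line, chosen
  so a 9x9-pixel field carries ~2-3 active emitters on average);
* each emitter draws a switch-ON countdown and an ON lifetime from
  Poisson distributions with mean 90 ms (15 lines — an ON span of roughly
  1.7 frames at 9 lines/frame, which produces the characteristic mid-PSF
  truncation);
* position is uniform on `S`; the PSF is an Airy disk with first zero
  drawn uniformly from [525, 555] nm; brightness is an integer uniform in
  [800, 1500] detector units, re-jittered each frame with Gaussian noise
  of sigma = 0.2 x brightness (floored at 1).

While an emitter's countdown is positive it is decremented by `dt` and the
emitter is dark; afterwards each line subtracts `dt` from the lifetime and
the emitter contributes the slice of its Airy kernel that overlaps the
currently scanned band of `s_px` rows. Emitters switching ON/OFF mid-scan
therefore leave top- or bottom-truncated PSFs. An emitter enters a frame's
ground truth only if it was rendered in at least 40 % of the lines in
which it was ON during that frame (per frame; an emitter that was never ON
is rejected).

**Amplitude convention.** Rendering uses the peak-normalized Airy kernel:
an emitter of brightness `ph` contributes a PSF with peak `ph` on the
sub-lattice. Camera frames are the area mean over each pixel's
`s_px x s_px` cells, so the noiseless frame peak is ~`ph` detector units.
This is the only convention under which the configured read-noise range
(sigma in [175, 185] detector units) gives a workable peak SNR of ~5-8;
normalizing the kernel to unit mass instead would bury the signal three
orders of magnitude below the noise. The standalone `airy_psf` function
still returns a unit-mass kernel (the natural convention for the
measurement operator).

**Noise model.** Poisson shot noise on the noiseless signal followed by
additive Gaussian read noise with per-batch sigma drawn from [175, 185];
both stages can be disabled in `ScanConfig`. This is the standard
sCMOS-style two-stage model; no per-pixel gain maps, no axial PSF, no
bidirectional scanning, and no photon-arrival (lifetime) simulation.

**What the generator does not emulate.** Real FLIMbee data additionally
shows line-to-line intensity fluctuations within one PSF, detector
afterglow, sample drift, and structured background from out-of-focus
fluorophores. Passing tests on simulated crops therefore demonstrates the
algorithmic contract (detection, fitting, calibration of the extraction
rule), not parity with any specific instrument.

## Trainable wavelet detection

A two-tap filter bank (Haar initialization) with shared
analysis/synthesis weights. Orthogonality of the high-pass `hp` and
low-pass `lp` taps is enforced by Gram-Schmidt coupling
`lp_n = lp - (<hp, lp>/<hp, hp>) hp`, re-applied on every forward pass, so
it holds after every training update. Synthesis divides each coupled tap
vector by its squared norm; for two-tap banks the stride-2 transform is
block-orthogonal and reconstruction is exact to machine precision for any
non-degenerate taps (verified over random initializations). Longer taps
are supported but exact inversion is only guaranteed for the two-tap
default.

A per-subband bias followed by ReLU acts as a learned soft threshold on
the decomposed frequency images. Taps and biases are trained with Adam on
the MSE between the reconstructed central frame and the noise-free
simulated target (default 40 epochs, lr 1e-2); the bank records the
intensity scale it was trained at and rescales inputs accordingly at
inference. Candidate emitters are strict 8-neighborhood local maxima of
the denoised frame above a threshold (default: median + 3 robust standard
deviations, MAD-based); plateau ties are resolved row-major. Candidates
are cropped to 9x9x3 patches (previous/current/next frame, zero-padded at
borders and sequence ends).

## Compressed sensing layer

The measurement operator `A` maps a super-resolved lattice with `u` cells
per pixel (default `u = 8`, i.e. a 72x72 lattice for a 9x9 crop — the
1 nm simulation lattice would make a dense `A` infeasible) to the crop by
placing the unit-mass Airy kernel at each lattice cell, clipping to the
crop and sum-binning. `min_b 1/2||Ab-y||^2 + lambda||b||_1, b >= 0` is
solved with FISTA; the step size is `1/L` with `L` estimated by 20 power
iterations on `A^T A`. Non-negativity is folded into the shrinkage step
(`relu(z - (grad + lambda)/L)`), reflecting non-negative emitter
intensities. The solver exists twice with one shared contract: a plain
numpy version with optional tolerance-based early stopping (and a
guarantee never to return an iterate worse than b = 0 — FISTA is not
monotone), and an unrolled fixed-iteration version built from autodiff
primitives so gradients reach the per-crop lambda estimator.

The lambda estimator is a three-conv / three-dense CNN with a sigmoid
output scaled by `lambda_max = 0.025`. Its dense weights are initialized
from N(0.5, 0.3) scaled by 1/fan-in with truncated-normal biases: the
unscaled variant saturates the sigmoid (lambda pinned at the bound with a
dead gradient), while the fan-in-scaled form keeps lambda strictly inside
(0, 0.025). The optional CS sparsity objective (L1 on `b` plus the squared
residual of `s = Ab` against the noise-free frame) is implemented and
exposed but not part of the default training loss.

## Fitter architectures

All four models map a 9x9x3 crop (scaled by 1/1000 so inputs share units
with the intensity channel) to 8 raw channels, then apply the output
activations: sigmoid for `p`, tanh for `dx, dy`, 3 x sigmoid for the
sigmas, softplus for `N` and `B` (positivity is physically required; the
printed activations only cover `p`, sigma and the offsets). The raw `p`
bias is initialized to -3 so the initial probability mass matches typical
emitter counts instead of 40.5 (= 0.5 x 81).

* **cs_cnn** — FISTA (20 iterations) on the central frame as a prior,
  lattice binned back to 9x9, concatenated with the crop, four 3x3 conv
  layers (width 64).
* **cs_inception** — two stacked inception blocks (paths: lambda-CNN +
  FISTA, asymmetric 1x3/3x1 filters, 1x1 bottleneck, activation
  pass-through); the first block runs FISTA at 5 iterations, the second at
  20, then a convolutional head.
* **cs_unet** — FISTA prior, then a two-level encoder-decoder (width 16,
  9 padded to 12, pooling to 6 and 3, skip connections).
* **rec_unet** — no explicit FISTA. An encoder U-Net produces `F(0)`;
  each recursion decodes `F` to image space, adds a background head,
  batch-normalizes the sum with the input image, encodes the residual and
  updates `F <- F + F_update`. Weights are shared across recursions
  (parameter count independent of their number; default 2 recursions).
  Batch normalization uses batch statistics in training and running
  statistics at inference.

Exact layer dimensions are not prescribed by the underlying method; the
widths above are this package's defaults, chosen to train in minutes on
one CPU core, and are configurable.

## Loss

For ground-truth emitter `t` the localisation term is a Gaussian mixture
over pixels `i` with weights `p_i / sum_m p_m`, means
`(x_px + dx_i, y_px + dy_i, N_i)` and per-axis spreads
`(sx_i, sy_i, sN_i)`:

    mix_t = sum_i p_i exp(-[(x_i-x_t)^2/sx_i^2 + (y_i-y_t)^2/sy_i^2
                             + (N_i-N_t)^2/sN_i^2])
            / ((2 pi)^{3/2} sx_i sy_i sN_i) / sum_m p_m

The normalizer keeps the sigmas outside the square root (per-component
Gaussian normalization — doubling `sx` halves the density), and the
exponent carries no factor 1/2; `N` is supervised in units of 10^3
detector counts. The *evaluator* `localisation_mixture` returns these
densities (higher = better); the *trained* loss is
`-sum_t log(mix_t)`, computed with a log-sum-exp over components so the
gradient stays finite when every component is far from the truth.

The count term compares `sum_i p_i` to the true count `c_t` with variance
`sigma_c = sum_i p_i(1-p_i)`. Two sign conventions of its log term are
exposed: the `printed` form `(...)^2/(2 sigma_c) - ln sqrt(2 pi sigma_c)`
(with `sigma_c` guarded at 1e-6) and the Gaussian negative log-likelihood
(`+ ln`). Training uses the NLL form: minimizing the `-ln` variant rewards
*large* `sigma_c`, i.e. pushes probabilities toward 0.5, the opposite of
the intended "confident 0/1" behavior. The training form additionally
floors `sigma_c` at 1e-2: once probabilities saturate, a single
miscounted crop otherwise contributes a quadratic term scaled by
1/(2e-6) whose (even clipped) gradient direction dominates whole batches
and can collapse the model into a degenerate mixture optimum — all mass
at a fixed corner with maximal spread. The background term is the mean absolute
deviation of `B` from the noise-free frame (`sqrt((B_i - n_i)^2)`,
epsilon-smoothed at 1e-12 for differentiability). The total loss is the
sum of the three terms.

## Training

Datasets follow the 40 x (4 x 1000) crop layout with a per-batch read
noise sigma in [175, 185] and a 3:1 train/eval split, scalable down
through `TrainConfig`. The optimizer is Adam; every `eval_every` steps the
validation loss, Jaccard index and RMSE are logged and the best-validation
state is checkpointed (the returned model is the final state — detection
metrics keep improving after the validation loss plateaus, a known
property of this loss family). Two numerical safeguards: gradients are
clipped to a global norm of 10 (as probabilities saturate, `sigma_c` in
the count term shrinks and single miscounted crops otherwise produce
destabilizing spikes), and the learning rate drops tenfold at 70 % of the
step budget.

Two reference runs are bundled. The desk-scale experiment
(`scanstorm.pipeline.desk_scale_experiment`) trains the recursive U-Net
on 4000 standard noisy crops (four noise batches) for 7500 steps at batch
16 with lr 1e-3 and validates on 1000 held-out crops; the full-scale
recipe of the underlying method (120k crops, lr 1e-4, GPU epochs) is out
of desk scope, and the tenfold-higher learning rate compensates for the
much smaller step budget (dropped tenfold for the final 30 % of
training). The pipeline health check
(`scanstorm.pipeline.smoke_recovery_experiment`) trains on 4000
noise-free crops that each contain one *fully rendered* emitter at least
half a pixel from the border, and evaluates the complete detection →
fitting → extraction pipeline on held-out clips. Fully rendered matters:
the 40 %-rendered ground-truth rule also accepts emitters whose ON window
never coincided with the scanner passing their rows, leaving only a faint
off-center PSF tail in the frame — such "ghosts" are unfittable from a
single frame by construction and are excluded from the health-check
distribution (they remain present in the standard training crops).

## Extraction and evaluation

Pixels with `p > t_cls` (default 0.3 — a low gate; the decision is made
by the cross rule, and the value is configurable) are convolved with the
cross filter [[0,1,0],[1,1,1],[0,1,0]]. If the cross sum exceeds
`t_re = 0.7` the highest-p pixel of the formation is accepted; above
`2 t_re` the second highest as well (ties row-major; each pixel emits at
most one localization, which also deduplicates overlapping formations).
Coordinates are `(col + 0.5 + dx, row + 0.5 + dy)` plus the crop origin;
pixel `(i, j)` spans `[i, i+1)` so centers sit at half-integers, 0-based.

Matching between predictions and truth is a per-frame Hungarian
assignment within 250 nm (2.5 px — a common SMLM-challenge radius;
configurable). JI = TP/(TP+FP+FN) (defined as 1 when all are zero); RMSE
is over matched pairs in nm (NaN with a warning when nothing matched).
FRC splits the table at the median frame, renders both halves as 10 nm
histograms zero-padded to a power of two, and correlates ring-wise; the
summary coefficient is the mean over rings up to Nyquist, with the full
curve always returned so other reductions remain computable. Only a
user-supplied global linear drift can be applied; no correlation-based
drift estimation.

## Known limitations

* The CS lattice (`u = 8`) is coarser than the simulation lattice; CS
  candidates are at best 12.5 nm quantized.
* The measurement operator assumes the full Airy PSF; for truncated PSFs
  it acts as a prior only, and its maximum can be displaced along the
  scan axis — position accuracy for chopped emitters comes from the
  trained network, not from CS.
* Two-tap wavelets give exact reconstruction but limited frequency
  selectivity; longer trained taps lose the exact-inversion guarantee.
* Desk-scale training budgets leave the fitters short of their achievable
  accuracy; all reported numbers are produced by the bundled runs, not by
  the full-scale recipe.
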