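# Methods

## The problem

Spectral-domain OCT reconstructs a depth profile (A-scan) as the Fourier
transform of a spectral interferogram.  Chromatic dispersion in the sample
arm adds a wavelength-dependent phase to the fringes; the quadratic
(group-velocity) and cubic terms broaden the axial point-spread function and
wash out layer boundaries.  A single numerical phase correction

    phi_bar(k) = -a2 (k - k0)^2 - a3 (k - k0)^3

applied to the complex analytic spectrum cancels the distortion — but only
for the depth whose dispersion the coefficient matches.  In layered tissue
the effective dispersion varies with depth, so each correction coefficient
sharpens only one depth band.  The pipeline in this package (i) manufactures
all-depth-compensated "ground truth" images by stitching the best band from
each member of a ladder of single-coefficient reconstructions, and (ii)
trains a multichannel encoder–decoder network that maps the whole ladder to
the stitched target in one shot, so that at inference time no per-depth
coefficient search is needed.

## Signal model (sim)

The simulated interferogram on a uniform wavenumber grid k (rad/um) is

    S(k) = I_r(k) + sum_n 2 sqrt(r_n) I_r(k) cos(k dz_n + a2_n u^2 + a3_n u^3) + noise

with I_r the source envelope (Gaussian, peak-normalized), r_n the layer
reflectivity, dz_n the *total* optical pathlength difference (round trip
included — no hidden factor of two), and u the offset from the spectral
centroid k0.  The constant and group-delay terms of the full dispersive
phase expansion only translate the peak, so they are absorbed into dz_n
rather than carried as free parameters.  Matching this sign convention,
correcting the analytic spectrum with coefficient a2 exactly cancels a layer
simulated with the same a2; the per-band coefficient search therefore
recovers +a2 of the layer it sharpens.

Dispersion coefficients default to **pixel-index mode**: the phase at
detector pixel j is `a2 * ((j - j0)/(P/2))^2`, i.e. a2 is the phase in
radians accumulated at the edge of the grid.  This makes sweep ranges
instrument-independent (a full 2048-pixel instrument and the desk-scale one
share the same +/-30 rad ladder).  Physical-k mode (coefficients multiplying
(k - k0)^2 in rad/um units) is a switch.

Noise: additive white Gaussian on the fringe plus optional shot noise
(variance proportional to the local intensity).  Speckle is realized
geometrically, as sub-resolution scatterers jittered around each layer;
repeated frames at one location share the scatterer geometry and differ only
in detector noise, which is what makes repeat averaging meaningful.

Aliasing: a layer beyond the unambiguous range pi/dk logs a warning and the
simulation proceeds (the wrapped signal is itself physically faithful).

## Reconstruction (recon)

Chain: per-detector-pixel background subtraction across A-lines -> analytic
signal (Hilbert construction: negative depth frequencies zeroed, needed
because the complex phase correction cannot act on a real signal) ->
multiplication by exp(i phi_bar(k)) -> FFT -> magnitude -> positive-depth
half (Z = P/2 rows, row 0 = zero delay, depth increasing downward).  No
apodization beyond the Gaussian source envelope, which self-apodizes.
k-linearization from a wavelength-uniform detector uses a cubic spline
(linear interpolation as fallback); the simulator already emits k-uniform
fringes, so this step is exercised separately.

Because the correction is a pure spectral phase, total image energy is
independent of the coefficient (Parseval) — used as an invariant test at
1e-8 relative.  On the *real-valued fringe* the analogous energy statement
holds only to ~1e-2 relative (the chirped cos^2 residual does not vanish),
so that check lives at the reconstruction level.

The display transform is 20*log10(I/max I), clipped at a floor (default
-50 dB at desk scale), rescaled to [0, 1].  Network inputs/targets and image
metrics all use this log-compressed normalized representation (dynamic
range L = 1); a linear-scale switch exists for the metrics.

## Ground truth (gtruth)

Per-depth sharpness is scored by the normalized intensity concentration
`sum(I^4)/sum(I^2)^2` over a depth band — 1 for an impulse, 1/M for a
uniform band of M pixels, scale-invariant, and maximized when the band's PSF
is narrowest.  The per-band optimal coefficient is the argmax of this score
over a brute-force coefficient sweep, refined by parabolic interpolation of
the top three scores; a flat landscape (max/min < 1 + 1e-6) returns the
sweep midpoint with a warning.  This automates a selection that is done
empirically on real instruments; the metric choice is this package's own.

Stitching copies band i of the image reconstructed with coefficient C_i
(ascending coefficient <-> increasing depth).  Bands default to equal-height
partitions (remainder rows to the last band); a layer-aware mode places
boundaries at midpoints between detected layer peaks.  Hard stitching is the
default; optional linear feathering over w rows exists because hard seams
are visible in noise-free synthetic images.

Datasets: the stitched target is always built from the N-coefficient stack
with N = number of bands (5 in the benchmark), regardless of how many
channels the network input uses; splits are assigned volume-wise so no
volume leaks across train/test.

## Network (nn + adcnet)

The restoration model is a modified UNet: encoder stages of dense blocks
(concatenative 3x3 convolution stages with intra-block skips) each followed
by a 1x1 channel-halving transition block and 2x2 max pooling; a bottleneck
dense block; a decoder of 2x nearest-neighbour upsampling, concatenation
with the corresponding transition output, and two 3x3 convolutions; batch
normalization + ReLU after every convolution; terminal 1x1 convolution with
a sigmoid.  SoftMax over a single output channel is degenerate (constant
one) and is kept only as a config option; sigmoid preserves the [0, 1]
image range while remaining trainable.  The loss is the soft dice form

    L = 1 - (2 sum(p g) + eps) / (sum p + sum g + eps),   eps = 1e-6,

evaluated on continuous [0, 1] images (an MAE option exists for plain
regression problems).  Optimizer: Adam, default learning rate 1e-4.

The engine underneath is a purpose-built reverse-mode autodiff on NumPy
arrays (channels-last, float32, convolutions as k^2 shifted GEMMs so the
BLAS operands stay contiguous).  It is single-threaded and fully
deterministic given the seed — two runs with the same seed produce identical
training histories to float precision; graph memory is released
deterministically after each backward pass.  Encoder pretraining at
ImageNet scale is replaced by seeded He-normal initialization; a hook loads
externally pretrained encoder weights when supplied.

## Evaluation (quality)

* MSE, and PSNR = 10 log10(s^2/MSE).  In the default "auto" mode s is the
  maximum pixel of the *reconstructed* image, which makes PSNR asymmetric in
  its arguments; this literal reading is kept, with a fixed-dynamic-range
  mode for conventional comparisons.  Identical images return +inf with a
  warning.
* SSIM with C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2/2, K1 = 0.01, K2 = 0.03,
  local statistics under the conventional 11x11 Gaussian window (sigma 1.5),
  mean over valid window positions.
* MS-SSIM over a dyadic pyramid (2x2 mean-pool between scales):
  contrast x structure at every scale, luminance only at the coarsest —
  entering through the full similarity map there, so a single scale reduces
  exactly to plain SSIM.  Canonical 5-scale exponents
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), renormalized when the image
  supports fewer scales (128x128 images support 4; the benchmark uses the
  auto-reduced count).
* Repeat averaging (group-wise pixel mean), absolute difference images with
  jet rendering, and axial intensity profiles (B-scan and A-line averaging,
  peak detection by prominence, FWHM by linear interpolation at half
  height) reproduce the remaining evaluation procedures.

## The synthetic benchmark (benchmark)

Clinical OCT volumes of the kind this method targets are not freely
redistributable, so the fixed study conditions here are synthetic retina-like samples on a desk-scale
instrument:

* detector P = 256 pixels (reconstructions 128 rows), 128 A-lines/B-scan;
  840 nm centre, 50 nm FWHM Gaussian source sampled over +/-2 FWHM
  (transform-limited magnitude PSF ~12.4 um FWHM, depth pitch ~3.46 um);
* five layers, one near the centre of each of five equal depth bands
  (depth jitter +/-12 um), reflectivities uniform in [0.3, 0.9], smooth
  parabolic curvature (20 um bow) plus random tilt;
* second-order dispersion increasing with depth: layer n carries
  a2 ~ the n-th rung of the [-30, +30] rad ladder +/- 3 rad jitter — the
  depth-varying dispersion that motivates the whole method;
* speckle: 8 sub-resolution scatterers per layer per A-line within
  +/-8 um; additive noise sigma = 0.02; display floor -50 dB;
* datasets of 9 volumes x 22 B-scans split 7/2 by volume (198 pairs),
  mirroring a typical nine-volume, seven-train acquisition design at
  desk scale.

What the generator does *not* emulate: motion between repeats, vignetting/
sensitivity roll-off, polarization effects, vessel shadows, pathology.
Passing tests therefore demonstrate the mechanics of the method — coefficient
recovery, stitching optimality, learnability of the ladder-to-stitched
mapping and the channel-count ordering — not clinical image quality;
absolute metric values measured on human retinas are out of reach by
construction.

## Desk-scale training conditions

CPU training uses a deliberately small instance of the architecture
(2 encoder stages, 8 base filters, dense-block growth 8, two convolution
stages per block; ~18k parameters).  The learning rate for these desk-scale
runs is Adam 2e-3, raised from the 1e-4 default because the tiny network /
few-epoch regime underfits badly at 1e-4; the default is untouched.
Mini-batches of 8; best-validation checkpointing; training is deterministic
per seed.  The end-to-end run trains on the noise-free benchmark (198
pairs, 16 epochs) and is scored by the MS-SSIM uplift over the
uncompensated mid-channel.  The optimization-descent property (loss more
than halves within 20 epochs) is asserted on a 48-train-pair noise-free
run, where the first epoch — six mini-batches — is a genuine baseline; at
~200 pairs the first epoch already contains ~20 learning steps, which
halves the recorded baseline itself, and on the noisy benchmark the dice
loss saturates near the detector-noise mismatch floor (~0.25) regardless
of capacity.  The channel-count
experiment trains {1, 3, 5}-channel models over 3 seeds on a reduced noisy
dataset (5 volumes x 12 B-scans, 4/1 volume split, 10 epochs) — sized at
the smallest scale where the 5-channel model reliably converges past the
uncompensated baseline.

## Numerical choices and degenerate inputs

* Background subtraction requires >= 2 A-lines (the mean would annihilate a
  single A-line).  A B-scan whose A-lines are *identical* loses its signal
  to background subtraction; realistic samples always carry lateral
  structure.
* estimate_optimal_coeff on a signal-free band returns the sweep midpoint
  with a degenerate-landscape warning rather than an arbitrary argmax.
* PSNR of identical images returns +inf (sentinel, with warning).
* MS-SSIM contrast/structure means are clipped at zero before the
  fractional-power combination (negative means are possible on adversarial
  inputs and would otherwise produce complex values).
* FWHM measurements on the ~1.8-pixel transform-limited PSF use 16x
  zero-padded reconstructions for sub-pixel resolution.
* Dice on continuous images uses eps = 1e-6 in numerator and denominator;
  the loss is bounded in [0, 1] for inputs in [0, 1].

## Known limitations

* At desk scale the channel-count comparison resolves the large effects —
  the uncompensated baseline is lowest and the 5-channel model highest —
  but the 1-vs-3-channel gap is of the same order as the seed-to-seed
  standard deviation. The 3-channel input strictly contains the 1-channel
  input's information, so its advantage must appear at convergence, and
  longer noise-free runs show the two curves crossing near 24 epochs; the
  short desk-scale runs stop before that point, so the 1 <= 3 leg of the
  ordering is not reliably resolved there.

* Only second-order dispersion is exercised end to end (third order is
  implemented and tested at the operator level); standard practice
  likewise compensates a2 only.
* The simulator's layers are discrete reflectors, not continuous scattering
  media; speckle statistics are approximate.
* The NumPy training engine is single-threaded and desk-scale; it is not a
  general deep-learning framework and provides exactly the operators this
  architecture needs.
* Band boundaries for stitching are geometric (equal or peak-midpoint), not
  anatomical segmentation.
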