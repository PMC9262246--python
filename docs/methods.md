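# Methods

`usdenoise` benchmarks multilevel 2-D wavelet soft-threshold denoising on
B-mode-like ultrasound images. This note records the models implemented,
the parameter choices that matter, and the limits of what the synthetic
benchmark can show.

## Synthetic phantoms

Clinical B-mode images are not shipped; the benchmark's "gold standard"
natives are synthetic phantoms built from the standard fully-developed
speckle model:

1. a complex circular-Gaussian scatterer field (per-pixel variance
   proportional to `scatterer_density`, default 2.0 scatterer-energy
   units/pixel, shaped by a piecewise echogenicity map);
2. convolution with a separable Gaussian point-spread function
   (`psf_sigma_axial` = 2.0 px along rows, `psf_sigma_lateral` = 1.5 px
   along columns by default — axial resolution in B-mode is finer than
   lateral, but pixel grids are usually closer-sampled axially, so the
   defaults keep the speckle cell mildly anisotropic);
3. envelope detection (magnitude), which over homogeneous tissue is
   Rayleigh-distributed — the canonical speckle statistic;
4. logarithmic compression to a displayed dynamic range `R`
   (`log_compression_db`, default 50 dB): `x -> (20*log10(x/x_max) + R)/R`
   clipped to [0, 1]. Passing `None` keeps the linear envelope, which is
   what the Rayleigh goodness-of-fit checks use.

Anatomy is painted as echogenicity multipliers relative to background
tissue (1.0): anechoic fluid 0.03–0.05, parenchyma ~1.5, specular
interfaces (vessel wall, tendon, bone) 2.2–3.2, acoustic shadows
multiplying everything beneath them by 0.12–0.25. Four templates mimic
the benchmark's exam categories: carotid (anechoic lumen with bright
double-line wall), abdominal (parenchyma block with anechoic vessels),
neck (two thyroid-like lobes flanking a tracheal shadow column), and
musculoskeletal (near-horizontal tendon and bone lines with shadow below
the bone). These values were chosen once so that the standard
radiological contrast relations hold with margin (e.g. lumen mean
intensity below a quarter of the wall mean after 50 dB compression);
they are not fitted to any data.

The default dataset is 100 abdominal / 40 neck / 80 carotid / 72
musculoskeletal natives (292 total) at 512x512. Per-image seeds are a
stable SHA-256 hash of `(master_seed, category, index)`, so one
category's count can change without reshuffling the others.

What the phantoms do *not* model: beamforming geometry, depth-dependent
attenuation and focusing, RF-domain correlation, scan-conversion
interpolation, or the tissue-texture diversity of real exams. Passing
benchmarks on phantoms therefore supports *relative* statements (which
wavelet ranks where, how scores trend with noise level), not clinical
absolute scores.

## Noise models

Twenty-level parameter ladders, fixed by construction:

| kind         | parameters                                  | ladder                |
|--------------|---------------------------------------------|-----------------------|
| gaussian     | additive, variance 0.01, mean `mu`          | `mu = 0.01..0.20`     |
| salt_pepper  | corrupted-pixel fraction `d`, salt:pepper ½:½ | `d = 0.001..0.02`   |
| speckle      | multiplicative `img + n*img`, `Var n = s²`  | `s² = 0.1..2.0`       |

Outputs are clipped to [0, 1] after corruption so 8-bit export stays
well-defined. The speckle multiplier is uniform on
`[-sqrt(3 s²), +sqrt(3 s²)]` by default — the convention the variance
parameterization comes from — with a Gaussian option recorded in every
result row. Per-cell seeds hash `(run_seed, image_id, kind, level)`;
the wavelet configuration deliberately does not enter the hash, so every
filter sees the identical degraded image.

## Filter banks

Daubechies (db2–db30) and Symlet (sym2–sym29) orthonormal banks are
constructed at run time by spectral factorization of the Daubechies
half-band polynomial, with root finding and polynomial assembly in
80-digit arithmetic (mpmath) before rounding to float64. This keeps the
invariants (sum √2, unit energy, even-shift orthogonality, QMF relation,
N vanishing moments) at the 1e-8–1e-10 level even for length-60 filters,
where double-precision root finding alone degrades badly.

Daubechies banks retain all zeros inside the unit circle (minimum
phase) and match the conventional tables exactly. Symlets select, among
all conjugate-group inside/outside assignments, the one minimizing the
L2 norm of the nonlinear part of the phase response (evaluated on a
257-point frequency grid after least-squares removal of the linear
phase), with ties broken by the lexicographically smallest coefficient
sequence. Because reflection negates the nonlinear phase, the minimizer
is found up to mirror image, and different toolboxes publish different
representatives; magnitude responses are factorization-invariant and are
what the cross-check tests compare. The exhaustive mask search is done
in float (per-group phase vectors, all 2^m sign combinations by one
matrix product), and only the winner is assembled in extended precision.

## 2-D transform

Separable DWT with symmetric half-point boundary extension: each 1-D
step extends by `filter_len - 1` samples per side, correlates with the
analysis filter and keeps odd-indexed outputs, so band shapes follow
`floor((n + 2N - 1)/2)` per axis and the representation is expansive.
Reconstruction upsamples, correlates with the time-reversed filters and
crops using recorded per-level shapes. The alignment convention is fixed
by an explicit matrix-operator oracle (extension, correlation and
decimation built as matrices from unit vectors) rather than by prose;
round-trip error is at machine precision, asserted below 1e-8 across the
full 16-bank x J∈{3,4} grid.

## Thresholding

Birge-Massart level-dependent budgets: level `l` (1 = finest) keeps
`n_l = max(1, round(M / (J + 2 - l)^alpha))` coefficients per detail
band, with `alpha = 1.5` (the standard denoising setting; compression
uses 3) and `M` defaulting to the coarsest approximation band's
coefficient count. Each band's soft threshold is the magnitude of its
`(n_l + 1)`-th largest coefficient — zero when the budget covers the
band. Thresholds are computed per orientation (H/V/D) within each
level; a pooled per-level variant (shared threshold, budget `3 n_l`) is
available for sensitivity analysis. Rounding is half-away-from-zero with
a floor of one; tie-breaks between equal-magnitude coefficients at the
budget boundary do not matter under soft thresholding, because the
threshold equals that shared magnitude either way. The approximation
band is never thresholded, and outputs are clipped to [0, 1] before
metric evaluation.

## Metrics

Five full-reference scores on the 0–255 scale: Pearson correlation, MSE,
PSNR (`10 log10(D²/MSE)`, `D = 255` by default with `D = 256` available
for gray-level-count conventions — every report records D), the
Wang-Bovik Q-index (correlation x luminance x contrast factors), and
SSIM with stabilizers `c1 = (0.01 D)²`, `c2 = (0.03 D)²`. Variances and
covariances use unbiased `L - 1` divisors. Q-index and SSIM default to
global whole-image statistics, which is what the closed-form identities
in the tests are stated for; windowed modes (8x8 uniform windows for Q,
11x11 Gaussian sigma 1.5 windows for SSIM, normalized weights without
sample-size correction) implement the original local formulations, and
the windowed SSIM is cross-checked against scikit-image to 1e-6.
Correlation is genuine Pearson on [-1, 1] and is not clamped.
Degenerate pairs (zero variance in a denominator) yield a NaN sentinel
rather than an exception; identical images give PSNR `+inf`, serialized
literally in CSV.

## Benchmark grid

`run_grid` walks images x noise kinds x levels x wavelets x J, scoring
both the noisy and the denoised stage against the native (two rows per
cell). Results are a long-format CSV (versioned column order in a header
comment) from which all summaries derive: pooled medians per category
and noise kind (median over images and levels jointly, even counts
averaging the two central values, plus a Mean row over the four category
aggregates), mean ± sample standard deviation of PSNR per wavelet /
category / kind, and per-wavelet metric-vs-level trend curves. Runs are
resumable (existing keys skipped) and scheduling-invariant (rows sorted
by key; per-cell seeds independent of worker count).

Directional checks — db2 first among Daubechies on mean speckle PSNR,
db30 first on salt-&-pepper PSNR, SSIM higher at level 1 than level 20
for every wavelet — are warn-level: on synthetic phantoms the low-order
versus high-order ordering reproduces robustly, but the gap between db2
and db5 on speckle is within a fraction of a dB and can flip with the
phantom seed set, which is exactly why these are reported as findings
rather than asserted.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations so a
single CPU finishes comfortably: the dataset-count check runs the full
292-native x 3 x 20 grid at 512x512 (noise only); the denoising-benefit
check uses 20 phantoms at 512x512 (256x256 in the unit tests); the
directional grid uses 24 phantoms at 128x128 with all 16 wavelets, 20
levels and 3 kinds. Rayleigh goodness-of-fit subsamples the envelope at
a 5-pixel stride (beyond the PSF correlation length) so the KS test's
iid assumption holds approximately; the fit uses the moment estimator
`scale = sqrt(mean(x²)/2)`.

Known limitations: no biorthogonal or stationary (undecimated)
transforms; no alternative threshold rules (universal, SURE); phantom
realism limits noted above; absolute runtimes are logged but never
asserted, since they are hardware-dependent.
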