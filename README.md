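# usdenoise

A benchmark pipeline for wavelet-domain denoising of B-mode ultrasound
images. Speckle, sensor noise and impulse dropouts degrade ultrasound
reads and downstream segmentation; wavelet soft-thresholding is a
standard remedy, but its efficacy depends strongly on the mother
wavelet, the decomposition depth and the noise actually present. This
package makes that dependence measurable: it generates seeded synthetic
B-mode phantoms for four exam categories, corrupts them on controlled
noise ladders, denoises with a grid of Daubechies/Symlet filter banks,
and scores every configuration with five full-reference quality metrics.

Intended users: medical-imaging researchers and software developers
choosing a wavelet configuration for ultrasound preprocessing, and
anyone needing a reproducible, no-download testbed for denoising
experiments.

## The method

For an image $g$ and its degraded version $f$, the denoiser computes a
$J$-level separable 2-D DWT (orthonormal Daubechies db2–db30 or Symlet
sym2–sym29 banks, symmetric half-point boundary extension), applies
soft thresholding $\eta_t(c) = \mathrm{sign}(c)\max(|c|-t, 0)$ to every
detail band, and reconstructs. Thresholds follow the Birgé–Massart
level-dependent rule: level $\ell$ (finest $=1$) keeps

$$n_\ell = \max\!\bigl(1,\ \mathrm{round}\,M/(J+2-\ell)^{\alpha}\bigr)$$

coefficients per band ($\alpha = 1.5$, $M$ = coarsest approximation
size by default), and each band's $t$ is its $(n_\ell+1)$-th largest
coefficient magnitude. The approximation band is never thresholded.

Quality is scored on the 0–255 scale with correlation,
$\mathrm{MSE} = \frac{1}{MN}\sum (g_{ij}-f_{ij})^2$,
$\mathrm{PSNR} = 10\log_{10}(D^2/\mathrm{MSE})$, the Wang–Bovik
Q-index $Q = \frac{\sigma_{xy}}{\sigma_x\sigma_y}\cdot
\frac{2\bar x\bar y}{\bar x^2+\bar y^2}\cdot
\frac{2\sigma_x\sigma_y}{\sigma_x^2+\sigma_y^2}$, and
$\mathrm{SSIM} = \frac{(2\bar x\bar y + c_1)(2\sigma_{xy} + c_2)}
{(\bar x^2+\bar y^2+c_1)(\sigma_x^2+\sigma_y^2+c_2)}$
with unbiased ($L-1$) moment estimators.

Noise ladders (20 levels each): additive Gaussian ($\sigma^2=0.01$,
$\mu = 0.01\ldots0.20$), salt-&-pepper (density $d=0.001\ldots0.02$),
and multiplicative speckle ($f = g + n\,g$, $\sigma_n^2 = 0.1\ldots2.0$).

## Worked example

```python
from usdenoise import (PhantomSpec, render_phantom, apply_speckle,
                       DenoiseConfig, denoise_image, evaluate_pair)

native = render_phantom(PhantomSpec("msk", seed=7))          # 512x512 phantom
noisy = apply_speckle(native, sigma2=1.0, seed=0)            # heavy speckle
denoised = denoise_image(noisy, DenoiseConfig("daubechies", 2, levels=3))

for stage, img in [("noisy", noisy), ("denoised", denoised)]:
    r = evaluate_pair(native, img)
    print(f"{stage:9s} corr={r.corr:.3f} mse={r.mse:7.1f} "
          f"psnr={r.psnr:5.2f} q={r.q_index:.3f} ssim={r.ssim:.3f}")
```

prints

```
noisy     corr=0.301 mse= 9105.7 psnr= 8.54 q=0.223 ssim=0.227
denoised  corr=0.707 mse= 1028.5 psnr=18.01 q=0.645 ssim=0.652
```

Speckle at variance 1 destroys most of the structural similarity of the
musculoskeletal phantom (SSIM 0.23); db2 shrinkage at three levels
recovers the large-scale anatomy, cutting MSE by ~9x (+9.5 dB PSNR) and
nearly tripling SSIM. Full grids, summary tables and trend curves are
driven either from Python (`run_grid`, `aggregate_median`,
`aggregate_mean_std`, `trend_curves`) or from the CLI:

```bash
usdenoise phantoms generate --counts msk=4 --seed 1 --out natives/
usdenoise noise apply --in natives/ --kind speckle --levels 1..20 --seed 1 --out noisy/
usdenoise denoise --in noisy/ --family db --order 2 --levels 3 --out clean/
usdenoise bench run --config run.yaml
```

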