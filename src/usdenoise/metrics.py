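"""Full-reference image quality metrics.

Five scores compare a processed image against its native gold standard:
Pearson correlation, MSE, PSNR, the Wang-Bovik universal quality index
(Q-index) and SSIM.  All are computed on the 8-bit intensity scale
(pixels in [0,1] are mapped to 0..255; the PSNR peak ``D`` defaults to
255 and is recorded in every report).

Q-index and SSIM are evaluated globally (whole-image moments with
unbiased ``L-1`` divisors) by default, which is how the closed-form
identities in the test suite are stated; windowed variants (8x8 uniform
sliding windows for Q, 11x11 Gaussian sigma=1.5 windows for SSIM, as in
the original formulations) are available via ``MetricConfig.mode``.

Metrics that are undefined for a pair (zero-variance denominators) return
the ``UNDEFINED`` NaN sentinel rather than raising, so a large benchmark
grid never aborts; identical images give PSNR ``+inf``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import DataError, ParameterError, UltrasoundImage

#: Sentinel for metrics whose defining ratio is 0/0 for the given pair.
UNDEFINED = float("nan")


def is_undefined(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)


@dataclasses.dataclass(frozen=True)
class MetricConfig:
    """Shared metric parameters.

    ``dynamic_range`` is the PSNR peak D (255 for standard 8-bit; 256
    matches conventions that count gray levels).  ``ssim_c1``/``ssim_c2``
    default to ``(0.01*D)**2`` and ``(0.03*D)**2``.
    """

    dynamic_range: float = 255.0
    ssim_c1: float | None = None
    ssim_c2: float | None = None
    mode: str = "global"
    q_window: int = 8
    ssim_window: int = 11
    ssim_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ParameterError("dynamic_range must be > 0")
        if self.mode not in ("global", "windowed"):
            raise ParameterError("mode must be 'global' or 'windowed'")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ParameterError("SSIM stabilizers must be > 0")

    @property
    def c1(self) -> float:
        return self.ssim_c1 if self.ssim_c1 is not None else (0.01 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return self.ssim_c2 if self.ssim_c2 is not None else (0.03 * self.dynamic_range) ** 2


@dataclasses.dataclass(frozen=True)
class ImagePairMoments:
    """First and second moments of an image pair (unbiased divisors)."""

    x_mean: float
    y_mean: float
    x_var: float
    y_var: float
    xy_cov: float
    L: int


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DataError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def pair_moments(x, y) -> ImagePairMoments:
    """Means, unbiased variances and covariance of a same-shape pair."""
    x, y = _as_arrays(x, y)
    L = x.size
    if L < 2:
        raise DataError("need at least 2 pixels for pair moments")
    xm, ym = float(x.mean()), float(y.mean())
    dx, dy = x - xm, y - ym
    return ImagePairMoments(
        x_mean=xm,
        y_mean=ym,
        x_var=float((dx * dx).sum() / (L - 1)),
        y_var=float((dy * dy).sum() / (L - 1)),
        xy_cov=float((dx * dy).sum() / (L - 1)),
        L=L,
    )


def mse(x, y) -> float:
    """Mean squared difference over the M*N pixel domain."""
    x, y = _as_arrays(x, y)
    d = x - y
    return float((d * d).mean())


def psnr(x, y, cfg: MetricConfig = MetricConfig()) -> float:
    """``10*log10(D**2 / MSE)`` in dB; +inf for identical images."""
    m = mse(x, y)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(cfg.dynamic_range**2 / m))


def corr_coeff(x, y) -> float:
    """Pearson correlation; UNDEFINED when either image is constant."""
    mom = pair_moments(x, y)
    denom = math.sqrt(mom.x_var * mom.y_var)
    if denom == 0.0:
        return UNDEFINED
    return float(mom.xy_cov / denom)


def _q_from_moments(mom: ImagePairMoments) -> float:
    corr_den = mom.x_var * mom.y_var
    lum_den = mom.x_mean**2 + mom.y_mean**2
    con_den = mom.x_var + mom.y_var
    if corr_den == 0.0 or lum_den == 0.0 or con_den == 0.0:
        return UNDEFINED
    sx, sy = math.sqrt(mom.x_var), math.sqrt(mom.y_var)
    return float(
        (mom.xy_cov / (sx * sy))
        * (2.0 * mom.x_mean * mom.y_mean / lum_den)
        * (2.0 * sx * sy / con_den)
    )


def q_index(x, y, cfg: MetricConfig = MetricConfig()) -> float:
    """Wang-Bovik universal quality index: correlation x luminance x contrast.

    Windowed mode averages the same statistic over all ``q_window``-sized
    sliding windows, skipping windows where a factor is undefined; images
    smaller than one window fall back to the global statistic.
    """
    x, y = _as_arrays(x, y)
    if cfg.mode == "global" or min(x.shape) < cfg.q_window:
        return _q_from_moments(pair_moments(x, y))
    w = cfg.q_window
    L = w * w
    xw = np.lib.stride_tricks.sliding_window_view(x, (w, w)).reshape(-1, L)
    yw = np.lib.stride_tricks.sliding_window_view(y, (w, w)).reshape(-1, L)
    mx, my = xw.mean(axis=1), yw.mean(axis=1)
    dx, dy = xw - mx[:, None], yw - my[:, None]
    vx = (dx * dx).sum(axis=1) / (L - 1)
    vy = (dy * dy).sum(axis=1) / (L - 1)
    cov = (dx * dy).sum(axis=1) / (L - 1)
    num = 4.0 * cov * mx * my
    den = (vx + vy) * (mx * mx + my * my)
    valid = den != 0.0
    if not np.any(valid):
        return UNDEFINED
    return float((num[valid] / den[valid]).mean())


def _ssim_global(x, y, cfg: MetricConfig) -> float:
    mom = pair_moments(x, y)
    c1, c2 = cfg.c1, cfg.c2
    num = (2.0 * mom.x_mean * mom.y_mean + c1) * (2.0 * mom.xy_cov + c2)
    den = (mom.x_mean**2 + mom.y_mean**2 + c1) * (mom.x_var + mom.y_var + c2)
    return float(num / den)


def _ssim_windowed(x, y, cfg: MetricConfig) -> float:
    # Gaussian-weighted local statistics (normalized weights, no sample-size
    # correction), cropped to windows fully inside the image.
    sigma, win = cfg.ssim_sigma, cfg.ssim_window
    truncate = (win - 1) / 2 / sigma
    kw = dict(sigma=sigma, truncate=truncate, mode="nearest")
    ux = gaussian_filter(x, **kw)
    uy = gaussian_filter(y, **kw)
    vx = gaussian_filter(x * x, **kw) - ux * ux
    vy = gaussian_filter(y * y, **kw) - uy * uy
    cov = gaussian_filter(x * y, **kw) - ux * uy
    c1, c2 = cfg.c1, cfg.c2
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def ssim(x, y, cfg: MetricConfig = MetricConfig()) -> float:
    """Structural similarity: luminance, contrast and structure terms with
    stabilizers c1, c2; global moments by default, 11x11 Gaussian windows
    in windowed mode.  Images smaller than one window use the global form."""
    x, y = _as_arrays(x, y)
    if cfg.mode == "global" or min(x.shape) <= cfg.ssim_window:
        return _ssim_global(x, y, cfg)
    return _ssim_windowed(x, y, cfg)


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """The five objective scores for one (native, processed) pair, plus the
    identifying tuple of the processed image within the benchmark grid."""

    corr: float
    mse: float
    psnr: float
    q_index: float
    ssim: float
    image_id: str = ""
    category: str = ""
    noise_kind: str = ""
    level_index: int = 0
    family: str = ""
    order: int = 0
    levels: int = 0
    stage: str = ""
    dynamic_range: float = 255.0
    mode: str = "global"


def evaluate_pair(
    native: UltrasoundImage,
    processed: UltrasoundImage,
    cfg: MetricConfig = MetricConfig(),
) -> MetricReport:
    """Score a processed image against its native on the 0..255 scale."""
    if native.role != "native":
        raise ParameterError("first argument must have role 'native'")
    if native.pixels.shape != processed.pixels.shape:
        raise DataError("native and processed shapes differ")
    x = native.pixels * 255.0
    y = processed.pixels * 255.0
    noise = processed.meta.get("noise_spec", {})
    den = processed.meta.get("denoise", {})
    return MetricReport(
        corr=corr_coeff(x, y),
        mse=mse(x, y),
        psnr=psnr(x, y, cfg),
        q_index=q_index(x, y, cfg),
        ssim=ssim(x, y, cfg),
        image_id=native.image_id,
        category=native.category,
        noise_kind=noise.get("kind", ""),
        level_index=int(noise.get("level_index", 0) or 0),
        family=den.get("family", ""),
        order=int(den.get("order", 0) or 0),
        levels=int(den.get("levels", 0) or 0),
        stage=processed.role,
        dynamic_range=cfg.dynamic_range,
        mode=cfg.mode,
    )
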