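"""Level-dependent Birge-Massart threshold selection and soft shrinkage.

The denoiser decomposes an image with :func:`usdenoise.wavelets.wavedec2`,
soft-thresholds every detail band with a level-dependent threshold, and
reconstructs.  The approximation band is never touched.

The Birge-Massart strategy allocates a per-level budget of detail
coefficients to keep,

    n_l = max(1, round(M / (J + 2 - l)**alpha)),   l = 1 (finest) .. J,

with ``alpha > 1`` a sparsity exponent (default 1.5, the standard
denoising choice) and ``M`` a budget scale defaulting to the coefficient
count of the coarsest approximation band.  The finest level therefore
keeps the fewest coefficients.  Each band's threshold is the magnitude of
its ``(n_l + 1)``-th largest coefficient (0 when the budget exceeds the
band), computed per orientation by default; a pooled single-threshold-
per-level variant is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .image import ParameterError, UltrasoundImage
from .wavelets import Decomposition2D, FilterBank, build_filter_bank, wavedec2, waverec2

ORIENTATIONS = ("horizontal", "vertical", "diagonal")


def soft_threshold(values: np.ndarray, t: float) -> np.ndarray:
    """Soft shrinkage ``sign(c) * max(|c| - t, 0)`` (elementwise)."""
    if t < 0:
        raise ParameterError("threshold must be >= 0")
    values = np.asarray(values)
    return np.sign(values) * np.maximum(np.abs(values) - t, 0.0)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _band_threshold(magnitudes: np.ndarray, keep: int) -> float:
    if keep >= magnitudes.size:
        return 0.0
    # (keep+1)-th largest magnitude
    flat = np.partition(magnitudes.ravel(), magnitudes.size - keep - 1)
    return float(flat[magnitudes.size - keep - 1])


@dataclasses.dataclass(frozen=True)
class ThresholdPlan:
    """Keep-counts and per-(level, orientation) thresholds for one image.

    ``keep_counts[l-1]`` is the per-band coefficient budget at level ``l``
    (level 1 = finest); ``thresholds[(l, o)]`` is the soft threshold for
    orientation ``o`` at level ``l``.
    """

    alpha: float
    M: int
    keep_counts: tuple[int, ...]
    thresholds: dict[tuple[int, str], float]


def birge_massart_keep_counts(levels: int, M: int, alpha: float) -> tuple[int, ...]:
    """The per-level keep budget, finest (l=1) to coarsest (l=J)."""
    if alpha <= 1:
        raise ParameterError("alpha must be > 1")
    return tuple(
        max(1, _round_half_away(M / (levels + 2 - l) ** alpha))
        for l in range(1, levels + 1)
    )


def birge_massart_plan(
    dec: Decomposition2D,
    alpha: float = 1.5,
    M_override: int | None = None,
    per_orientation: bool = True,
) -> ThresholdPlan:
    """Compute the threshold plan for a decomposition.

    With ``per_orientation=True`` each of the three detail bands at a level
    gets its own order-statistic threshold with budget ``n_l``; with
    ``False`` the three bands are pooled and share one threshold with
    budget ``3 * n_l``.
    """
    M = int(M_override) if M_override is not None else int(dec.approx.size)
    keep = birge_massart_keep_counts(dec.levels, M, alpha)
    thresholds: dict[tuple[int, str], float] = {}
    for lvl in range(1, dec.levels + 1):
        bands = dec.details[lvl - 1]
        if per_orientation:
            for o in ORIENTATIONS:
                thresholds[(lvl, o)] = _band_threshold(
                    np.abs(bands[o]), keep[lvl - 1]
                )
        else:
            pooled = np.concatenate([np.abs(bands[o]).ravel() for o in ORIENTATIONS])
            t = _band_threshold(pooled, 3 * keep[lvl - 1])
            for o in ORIENTATIONS:
                thresholds[(lvl, o)] = t
    return ThresholdPlan(alpha=alpha, M=M, keep_counts=keep, thresholds=thresholds)


@dataclasses.dataclass(frozen=True)
class DenoiseConfig:
    """Wavelet shrinkage configuration: bank identity, depth and budget knobs."""

    family: str = "daubechies"
    order: int = 5
    levels: int = 3
    alpha: float = 1.5
    M_override: int | None = None
    per_orientation: bool = True
    force_zero_threshold: bool = False  # debug hook: disables shrinkage

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ParameterError("alpha must be > 1")
        build_filter_bank(self.family, self.order)  # validates (family, order)

    @property
    def bank(self) -> FilterBank:
        return build_filter_bank(self.family, self.order)


def apply_plan(dec: Decomposition2D, plan: ThresholdPlan) -> Decomposition2D:
    """Soft-threshold every detail band; the approximation passes through
    untouched (bit-identical)."""
    new_details = []
    for lvl in range(1, dec.levels + 1):
        bands = dec.details[lvl - 1]
        new_details.append(
            {o: soft_threshold(bands[o], plan.thresholds[(lvl, o)]) for o in ORIENTATIONS}
        )
    return dataclasses.replace(dec, details=new_details)


def denoise_image(img: UltrasoundImage, cfg: DenoiseConfig) -> UltrasoundImage:
    """Full shrinkage pipeline: decompose, threshold details, reconstruct, clip."""
    bank = cfg.bank
    dec = wavedec2(img, bank, cfg.levels)
    plan = birge_massart_plan(dec, cfg.alpha, cfg.M_override, cfg.per_orientation)
    if cfg.force_zero_threshold:
        plan = dataclasses.replace(
            plan, thresholds={k: 0.0 for k in plan.thresholds}
        )
    dec = apply_plan(dec, plan)
    rec = np.clip(waverec2(dec, bank), 0.0, 1.0)
    return img.with_pixels(
        rec,
        "denoised",
        {
            "denoise": {
                "family": bank.family,
                "order": bank.order,
                "levels": cfg.levels,
                "alpha": plan.alpha,
                "M": plan.M,
                "per_orientation": cfg.per_orientation,
            }
        },
    )
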