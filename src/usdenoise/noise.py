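"""Controlled noise injection for the benchmark grid.

Three corruption models typical for B-mode ultrasound, each on a fixed
20-level parameter ladder:

* additive Gaussian — constant variance 0.01, mean 0.01·level;
* impulse salt & pepper — corrupted-pixel fraction 0.001·level,
  salt/pepper split 1/2 each;
* multiplicative speckle — ``out = img + n·img`` with zero-mean ``n`` of
  variance 0.1·level (uniform multiplier by default, Gaussian optional).

All outputs are clipped back to ``[0, 1]`` and are bit-reproducible under
a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .image import ParameterError, UltrasoundImage

NOISE_KINDS = ("gaussian", "salt_pepper", "speckle")


class ContractError(RuntimeError):
    """A pipeline-internal contract was violated (e.g. a seed left unset)."""


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """One cell of the noise ladder.

    ``level_index`` runs 1..20; the model parameters are fully determined
    by ``(kind, level_index)``.  ``seed`` is filled in by the benchmark
    layer (per grid cell) and may be ``None`` on a bare grid.
    """

    kind: str
    level_index: int
    mu: float = 0.0
    sigma2: float = 0.0
    density: float = 0.0
    seed: int | None = None
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if not 1 <= self.level_index <= 20:
            raise ParameterError("level_index must be in 1..20")

    def with_seed(self, seed: int) -> "NoiseSpec":
        return dataclasses.replace(self, seed=seed)


def noise_spec(kind: str, level_index: int, seed: int | None = None) -> NoiseSpec:
    """Build the canonical spec for one (kind, level) cell of the ladder."""
    if kind == "gaussian":
        return NoiseSpec(kind, level_index, mu=0.01 * level_index, sigma2=0.01, seed=seed)
    if kind == "salt_pepper":
        return NoiseSpec(kind, level_index, density=0.001 * level_index, seed=seed)
    if kind == "speckle":
        return NoiseSpec(kind, level_index, mu=0.0, sigma2=0.1 * level_index, seed=seed)
    raise ParameterError(f"unknown noise kind {kind!r}")


def noise_level_grid(kind: str) -> list[NoiseSpec]:
    """The full 20-level ladder for one noise kind (seeds unset)."""
    return [noise_spec(kind, level) for level in range(1, 21)]


def apply_gaussian(
    img: UltrasoundImage, mu: float, sigma2: float, seed: int
) -> UltrasoundImage:
    """Additive Gaussian noise: ``clip(img + N(mu, sigma2), 0, 1)``."""
    if sigma2 < 0:
        raise ParameterError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    n = mu + np.sqrt(sigma2) * rng.standard_normal(img.pixels.shape)
    out = np.clip(img.pixels + n, 0.0, 1.0)
    return img.with_pixels(out, "noisy", {"noise": ("gaussian", mu, sigma2)})


def apply_salt_pepper(img: UltrasoundImage, density: float, seed: int) -> UltrasoundImage:
    """Impulse noise: each pixel independently corrupted with probability
    ``density``; corrupted pixels become 1.0 ("salt") or 0.0 ("pepper")
    with equal probability."""
    if not 0.0 <= density <= 1.0:
        raise ParameterError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(img.pixels.shape)
    out = img.pixels.copy()
    out[u < density / 2.0] = 0.0
    out[(u >= density / 2.0) & (u < density)] = 1.0
    return img.with_pixels(out, "noisy", {"noise": ("salt_pepper", density)})


def apply_speckle(
    img: UltrasoundImage, sigma2: float, seed: int, distribution: str = "uniform"
) -> UltrasoundImage:
    """Multiplicative noise: ``clip(img + n*img, 0, 1)`` with zero-mean ``n``
    of variance ``sigma2``.  The default multiplier is uniform on
    ``[-sqrt(3*sigma2), +sqrt(3*sigma2)]``, matching the convention the
    level ladder's variance parameter comes from; ``distribution="gaussian"``
    draws ``n ~ N(0, sigma2)`` instead."""
    if sigma2 < 0:
        raise ParameterError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        half = np.sqrt(3.0 * sigma2)
        n = rng.uniform(-half, half, img.pixels.shape)
    elif distribution == "gaussian":
        n = np.sqrt(sigma2) * rng.standard_normal(img.pixels.shape)
    else:
        raise ParameterError(f"unknown speckle multiplier distribution {distribution!r}")
    out = np.clip(img.pixels + n * img.pixels, 0.0, 1.0)
    return img.with_pixels(out, "noisy", {"noise": ("speckle", sigma2, distribution)})


def apply_noise(img: UltrasoundImage, spec: NoiseSpec) -> UltrasoundImage:
    """Dispatch to the matching generator; the spec (with seed) is recorded
    in the output metadata."""
    if spec.seed is None:
        raise ContractError("NoiseSpec.seed must be set before applying noise")
    if spec.kind == "gaussian":
        out = apply_gaussian(img, spec.mu, spec.sigma2, spec.seed)
    elif spec.kind == "salt_pepper":
        out = apply_salt_pepper(img, spec.density, spec.seed)
    elif spec.kind == "speckle":
        out = apply_speckle(img, spec.sigma2, spec.seed, spec.distribution)
    else:  # pragma: no cover - NoiseSpec validates kind
        raise ParameterError(f"unknown noise kind {spec.kind!r}")
    return dataclasses.replace(
        out, meta={**out.meta, "noise_spec": dataclasses.asdict(spec)}
    )
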