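"""Synthetic B-mode phantom generation.

The benchmark needs native ("gold standard") images for four anatomical
categories — abdominal, carotid, neck and musculoskeletal — without any
clinical data.  The phantoms emulate the two features that drive wavelet
denoising behaviour on B-mode data:

* fully developed speckle: a complex circular-Gaussian scatterer field
  convolved with a separable Gaussian point-spread function; the envelope
  (magnitude) of the result is Rayleigh-distributed over homogeneous
  tissue, which is the standard statistical model of B-mode speckle;
* macroscopic anatomy: piecewise echogenicity maps built from simple
  geometric primitives (ellipses and bands) — anechoic vessel lumens,
  bright wall/tendon/bone interfaces, acoustic shadows.

Envelopes are log-compressed to a configurable dynamic range (default
50 dB) and rescaled to ``[0, 1]``, mimicking scan-converter display
mapping.  Everything is bit-reproducible under a fixed spec.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._seeds import stable_seed
from .image import ParameterError, UltrasoundImage, write_image

#: Default per-category image counts for the generated benchmark dataset.
DEFAULT_COUNTS: dict[str, int] = {"abdominal": 100, "neck": 40, "carotid": 80, "msk": 72}


# ---------------------------------------------------------------------------
# Geometric primitives


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """Elliptical region; coordinates and radii are fractions of the image size.

    ``mode="set"`` paints the region's echogenicity; ``mode="mul"`` scales
    whatever is already there (used for acoustic shadows).
    """

    cx: float
    cy: float
    rx: float
    ry: float
    echogenicity: float
    mode: str = "set"

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        u = (xx / width - self.cx) / self.rx
        v = (yy / height - self.cy) / self.ry
        return u * u + v * v <= 1.0


@dataclasses.dataclass(frozen=True)
class Band:
    """Straight band (thick line).  ``orientation`` is "h" or "v"; ``tilt``
    offsets the band centre linearly across the image, giving near-horizontal
    (or near-vertical) interfaces such as tendons."""

    orientation: str
    center: float
    half_width: float
    echogenicity: float
    tilt: float = 0.0
    extent: tuple[float, float] = (0.0, 1.0)
    mode: str = "set"

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        if self.orientation == "h":
            along, across = xx / width, yy / height
        elif self.orientation == "v":
            along, across = yy / height, xx / width
        else:
            raise ParameterError(f"unknown band orientation {self.orientation!r}")
        center = self.center + self.tilt * (along - 0.5)
        inside = np.abs(across - center) <= self.half_width
        return inside & (along >= self.extent[0]) & (along <= self.extent[1])


Structure = Ellipse | Band


def _validate_structures(structures: Sequence[Structure]) -> None:
    for s in structures:
        if s.echogenicity < 0:
            raise ParameterError("echogenicity multipliers must be >= 0")
        if s.mode not in ("set", "mul"):
            raise ParameterError(f"unknown structure mode {s.mode!r}")


# ---------------------------------------------------------------------------
# Category templates

def category_structures(category: str) -> tuple[Structure, ...]:
    """Anatomy templates for the four emulated exam categories.

    Echogenicity is relative to background tissue (1.0): anechoic fluid is
    near zero, specular interfaces (vessel wall, bone, tendon) are several
    times brighter, acoustic shadows multiply everything beneath them.
    """
    if category == "carotid":
        # Longitudinal carotid: anechoic lumen with a bright double-line
        # (intima/adventitia) wall above and below.
        return (
            Band("h", 0.42, 0.012, 3.0, tilt=0.02),
            Band("h", 0.46, 0.008, 2.2, tilt=0.02),
            Ellipse(0.5, 0.565, 0.52, 0.085, 0.03),
            Band("h", 0.67, 0.012, 3.0, tilt=0.02),
            Band("h", 0.71, 0.008, 2.2, tilt=0.02),
        )
    if category == "abdominal":
        # Liver-like parenchyma block with anechoic vessels.
        return (
            Ellipse(0.5, 0.55, 0.55, 0.45, 1.5),
            Ellipse(0.38, 0.45, 0.10, 0.045, 0.04),
            Ellipse(0.66, 0.62, 0.065, 0.03, 0.04),
        )
    if category == "neck":
        # Thyroid lobes flanking the tracheal air shadow.
        return (
            Ellipse(0.28, 0.45, 0.17, 0.22, 1.5),
            Ellipse(0.72, 0.45, 0.17, 0.22, 1.5),
            Band("v", 0.5, 0.055, 1.0, extent=(0.25, 1.0), mode="mul"),
            Band("v", 0.5, 0.055, 0.12, extent=(0.25, 1.0)),
        )
    if category == "msk":
        # Tendon over bone: two bright near-horizontal interfaces, acoustic
        # shadow below the (brightest) bone surface.
        return (
            Band("h", 0.35, 0.02, 2.2, tilt=0.06),
            Band("h", 0.60, 0.015, 3.2, tilt=0.03),
            Band("h", 0.82, 0.21, 0.25, tilt=0.03, mode="mul"),
        )
    if category == "synthetic-other":
        return ()
    raise ParameterError(f"unknown phantom category {category!r}")


# ---------------------------------------------------------------------------
# Phantom spec and rendering


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; identical specs render identical pixels.

    ``scatterer_density`` scales the scatterer field variance (echo energy
    per pixel); ``psf_sigma_axial``/``psf_sigma_lateral`` are the Gaussian
    point-spread widths in pixels along image rows/columns;
    ``log_compression_db`` is the displayed dynamic range R in dB
    (``None`` selects linear/envelope mode, mainly for statistical checks).
    """

    category: str
    seed: int
    height: int = 512
    width: int = 512
    scatterer_density: float = 2.0
    psf_sigma_axial: float = 2.0
    psf_sigma_lateral: float = 1.5
    log_compression_db: float | None = 50.0
    structures: tuple[Structure, ...] | None = None

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ParameterError("phantom dimensions must be at least 32x32")
        if self.scatterer_density < 0:
            raise ParameterError("scatterer_density must be >= 0")
        if self.psf_sigma_axial <= 0 or self.psf_sigma_lateral <= 0:
            raise ParameterError("psf sigmas must be > 0")
        if self.log_compression_db is not None and self.log_compression_db <= 0:
            raise ParameterError("log_compression_db must be > 0 (or None for linear)")
        if self.structures is not None:
            _validate_structures(self.structures)

    def resolved_structures(self) -> tuple[Structure, ...]:
        if self.structures is not None:
            return tuple(self.structures)
        return category_structures(self.category)


def _echogenicity_map(spec: PhantomSpec) -> np.ndarray:
    emap = np.ones((spec.height, spec.width))
    for s in spec.resolved_structures():
        m = s.mask(spec.height, spec.width)
        if s.mode == "set":
            emap[m] = s.echogenicity
        else:
            emap[m] *= s.echogenicity
    return emap


def _envelope(spec: PhantomSpec, emap: np.ndarray) -> np.ndarray:
    """Envelope of the PSF-filtered complex scatterer field."""
    rng = np.random.default_rng(spec.seed)
    scale = np.sqrt(spec.scatterer_density / 2.0) * emap
    re = rng.standard_normal((spec.height, spec.width)) * scale
    im = rng.standard_normal((spec.height, spec.width)) * scale
    sig = (spec.psf_sigma_axial, spec.psf_sigma_lateral)
    return np.hypot(gaussian_filter(re, sig), gaussian_filter(im, sig))


def _compress(env: np.ndarray, log_compression_db: float | None) -> np.ndarray:
    peak = env.max()
    if peak == 0.0:
        return np.zeros_like(env)
    if log_compression_db is None:
        return env / peak
    r = log_compression_db
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.clip((db + r) / r, 0.0, 1.0)


def render_speckle_base(spec: PhantomSpec) -> UltrasoundImage:
    """Render the speckle texture alone (no anatomy), role ``native``.

    In linear mode (``log_compression_db=None``) the pixel values over a
    uniform region follow a Rayleigh distribution up to normalization.
    ``scatterer_density=0`` is a degenerate debug mode yielding all zeros.
    """
    emap = np.ones((spec.height, spec.width))
    env = _envelope(spec, emap)
    px = _compress(env, spec.log_compression_db)
    return UltrasoundImage(
        pixels=px,
        category=spec.category,
        image_id=f"{spec.category}-base-{spec.seed}",
        role="native",
        meta={"phantom_seed": spec.seed, "speckle_base": True},
    )


def render_phantom(spec: PhantomSpec) -> UltrasoundImage:
    """Render the full phantom: speckle modulated by the category anatomy."""
    emap = _echogenicity_map(spec)
    env = _envelope(spec, emap)
    px = _compress(env, spec.log_compression_db)
    return UltrasoundImage(
        pixels=px,
        category=spec.category,
        image_id=f"{spec.category}-{spec.seed}",
        role="native",
        meta={"phantom_seed": spec.seed},
    )


def generate_dataset(
    counts: Mapping[str, int] | None = None,
    master_seed: int = 0,
    height: int = 512,
    width: int = 512,
    **spec_kwargs,
) -> list[UltrasoundImage]:
    """Generate the native benchmark set (default 100/40/80/72 = 292 images).

    Per-image seeds are a stable hash of ``(master_seed, category, index)``,
    so changing one category's count never reshuffles another category.
    """
    if counts is None:
        counts = DEFAULT_COUNTS
    images: list[UltrasoundImage] = []
    for category, n in counts.items():
        if n < 0:
            raise ParameterError(f"negative image count for {category!r}")
        for index in range(n):
            seed = stable_seed(master_seed, category, index)
            spec = PhantomSpec(
                category=category, seed=seed, height=height, width=width, **spec_kwargs
            )
            img = render_phantom(spec)
            img = dataclasses.replace(img, image_id=f"{category}-{index:04d}")
            images.append(img)
    return images


def save_dataset(images: Sequence[UltrasoundImage], out_dir: str | Path) -> Path:
    """Write images as 8-bit PNGs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        fname = f"{img.image_id}.png"
        write_image(img, out_dir / fname)
        rows.append(
            {
                "image_id": img.image_id,
                "category": img.category,
                "seed": img.meta.get("phantom_seed", ""),
                "path": fname,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[UltrasoundImage]:
    """Load a dataset written by :func:`save_dataset`."""
    from .image import read_image

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    return [
        read_image(base / row["path"], category=row["category"], image_id=row["image_id"])
        for _, row in df.iterrows()
    ]
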