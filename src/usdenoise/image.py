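"""Core image container and 8-bit grayscale I/O.

The pipeline works on linear gray intensities in ``[0, 1]``.  Disk formats
are lossless 8-bit grayscale PNG or single-plane TIFF; RGB inputs are
collapsed to luma before any processing, because every downstream stage is
defined on single-channel B-mode data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np

CATEGORIES = ("abdominal", "carotid", "neck", "msk", "synthetic-other")
ROLES = ("native", "noisy", "denoised")

#: Rec. 601 luma weights used to collapse RGB inputs to a single channel.
_LUMA = np.array([0.299, 0.587, 0.114])


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class DataError(ValueError):
    """Input data violates a structural precondition (shape, finiteness)."""


@dataclasses.dataclass(frozen=True)
class UltrasoundImage:
    """A 2-D intensity field with provenance metadata.

    ``pixels`` is a float array with values in ``[0, 1]``; ``category``
    names the anatomical template the image emulates; ``role`` tracks the
    stage of the pipeline that produced it.  Instances are immutable —
    stages return new instances via :meth:`with_pixels`.
    """

    pixels: np.ndarray
    category: str = "synthetic-other"
    image_id: str = ""
    bit_depth: int = 8
    role: str = "native"
    meta: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise DataError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise DataError(f"image must be at least 32x32, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise DataError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise DataError("pixel intensities must lie in [0, 1]")
        if self.category not in CATEGORIES:
            raise ParameterError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.role not in ROLES:
            raise ParameterError(f"unknown role {self.role!r}; expected one of {ROLES}")
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(
        self, pixels: np.ndarray, role: str, extra_meta: Mapping[str, object] | None = None
    ) -> "UltrasoundImage":
        """Return a copy carrying new pixel data and role; identity fields kept."""
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        return dataclasses.replace(self, pixels=pixels, role=role, meta=meta)


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize ``[0,1]`` intensities to 8 bits (round half to even via rint)."""
    return np.rint(np.clip(pixels, 0.0, 1.0) * 255.0).astype(np.uint8)


def from_uint8(raw: np.ndarray) -> np.ndarray:
    return raw.astype(np.float64) / 255.0


def write_image(img: UltrasoundImage, path: str | Path) -> None:
    """Write as lossless 8-bit grayscale PNG or single-plane TIFF."""
    path = Path(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ParameterError(f"unsupported image format: {path.suffix}")
    iio.imwrite(path, to_uint8(img.pixels))


def read_image(
    path: str | Path,
    category: str = "synthetic-other",
    image_id: str | None = None,
    role: str = "native",
) -> UltrasoundImage:
    """Read a PNG/TIFF image; RGB(A) planes are collapsed by luma weights."""
    path = Path(path)
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        rgb = raw[..., :3].astype(np.float64)
        raw = rgb @ _LUMA
    if raw.dtype == np.uint8 or raw.max() > 1.0:
        px = np.clip(raw.astype(np.float64) / 255.0, 0.0, 1.0)
    else:
        px = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return UltrasoundImage(
        pixels=px,
        category=category,
        image_id=image_id if image_id is not None else path.stem,
        role=role,
    )
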