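"""Image I/O, JPEG distortion-set construction and synthetic pool-scene fixtures.

Coordinate convention everywhere in this package: row-major, 0-based
``(row, col)``; ``height`` counts rows, ``width`` counts columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ImagePlane:
    """A 2-D grid of real luminance values with a known dynamic range.

    Parameters
    ----------
    pixels
        2-D float array, values in ``[0, dynamic_range]``, finite.
    dynamic_range
        Upper bound of the representable intensity (default 255 for 8-bit).
    """

    pixels: np.ndarray
    dynamic_range: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D array")
        h, w = self.pixels.shape
        if h < 3 or w < 3:
            raise ValidationError(f"image must be at least 3x3, got {h}x{w}")
        if self.dynamic_range <= 0:
            raise ValidationError("dynamic_range must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels must be finite (no NaN/Inf)")
        if self.pixels.min() < 0 or self.pixels.max() > self.dynamic_range:
            raise ValidationError(
                "pixel values must lie in [0, dynamic_range]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class DistortionSet:
    """One reference image and its JPEG-compressed versions, one per level."""

    reference_id: str
    reference: ImagePlane
    levels: list[int]
    distorted: list[ImagePlane]

    def __post_init__(self) -> None:
        if len(self.distorted) != len(self.levels):
            raise ValidationError("one distorted plane per level required")
        for d in self.distorted:
            if (d.height, d.width) != (self.reference.height, self.reference.width):
                raise ValidationError("distorted plane dimensions must match reference")
        _check_levels(self.levels)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic pool-scene reference image.

    Identical specs yield bit-identical images.
    """

    seed: int = 0
    height: int = 288
    width: int = 512
    tile_period: int = 32
    n_swimmers: int = 3
    ripple_amplitude: float = 2.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.height < 3 or self.width < 3:
            raise ValidationError("fixture must be at least 3x3")
        if self.tile_period < 2:
            raise ValidationError("tile_period must be >= 2")
        if self.n_swimmers < 0:
            raise ValidationError("n_swimmers must be nonnegative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


def _check_levels(levels: Sequence[int]) -> None:
    if len(levels) == 0:
        raise ValidationError("level list must be nonempty")
    if len(set(levels)) != len(levels):
        raise ValidationError("levels must be distinct")
    for q in levels:
        if not (1 <= int(q) <= 100):
            raise ValidationError(f"JPEG quality {q} outside [1, 100]")


def load_image_gray(path: str | Path) -> ImagePlane:
    """Load an 8-bit raster (PNG/JPEG/BMP) as a grayscale plane.

    RGB input is converted with the Rec. 601 luma weighting
    ``0.299 R + 0.587 G + 0.114 B`` and rounded half-up to integers;
    grayscale input passes through unchanged.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode == "L":
                arr = np.asarray(im, dtype=np.float64)
            elif im.mode in ("RGB", "RGBA"):
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
                arr = np.floor(luma + 0.5)  # round half-up
            else:
                raise ValidationError(
                    f"unsupported format: mode {im.mode!r} in {path}"
                )
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    return ImagePlane(np.clip(arr, 0, 255), dynamic_range=255.0)


def save_image_gray(plane: ImagePlane, path: str | Path, quality: int | None = None) -> None:
    """Write a plane as an 8-bit grayscale raster; format from the extension."""
    arr = np.clip(np.round(plane.pixels), 0, 255).astype(np.uint8)
    im = Image.fromarray(arr, mode="L")
    kwargs = {}
    if quality is not None:
        kwargs["quality"] = int(quality)
    im.save(Path(path), **kwargs)


def jpeg_compress(image: ImagePlane, quality: int) -> ImagePlane:
    """Encode with a standard JPEG codec at the given quality and decode back."""
    quality = int(quality)
    if not (1 <= quality <= 100):
        raise ValidationError(f"JPEG quality {quality} outside [1, 100]")
    arr = np.clip(np.round(image.pixels), 0, 255).astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(arr, mode="L").save(buf, format="JPEG", quality=quality)
    buf.seek(0)
    with Image.open(buf) as im:
        out = np.asarray(im.convert("L"), dtype=np.float64)
    assert out.shape == arr.shape
    return ImagePlane(out, dynamic_range=image.dynamic_range)


def build_distortion_set(
    reference: ImagePlane, levels: Sequence[int], reference_id: str = "ref"
) -> DistortionSet:
    """Compress one reference at every quality level, order preserved."""
    _check_levels(levels)
    levels = [int(q) for q in levels]
    distorted = [jpeg_compress(reference, q) for q in levels]
    return DistortionSet(
        reference_id=reference_id,
        reference=reference,
        levels=levels,
        distorted=distorted,
    )


def generate_pool_fixture(spec: FixtureSpec) -> ImagePlane:
    """Render a deterministic synthetic pool scene.

    The scene composes, in order: a periodic tile grid (period
    ``tile_period``), vertical high-contrast lane stripes, ``n_swimmers``
    elliptical bright blobs at seeded positions, a smooth sinusoidal
    coordinate warp of amplitude ``ripple_amplitude``, and seeded Gaussian
    noise with sd ``noise_sd``; the result is clipped to [0, 255] and
    rounded to integers.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, t = spec.height, spec.width, spec.tile_period
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    # tile field: bright tiles separated by dark grout lines
    grout = max(1, t // 8)
    img = np.full((h, w), 150.0)
    img[(rows % t < grout) | (cols % t < grout)] = 80.0

    # lane stripes: dark vertical bands, constant over rows so that the
    # noise/ripple-free fixture stays exactly row-periodic with period t
    lane_every = 4 * t
    lane_width = max(2, t // 4)
    img[:, (np.arange(w) % lane_every) < lane_width] = 30.0

    # swimmers: compact elliptical Gaussian blobs, brighter than the tiles
    for _ in range(spec.n_swimmers):
        cr = rng.uniform(0.1 * h, 0.9 * h)
        cc = rng.uniform(0.1 * w, 0.9 * w)
        ar = rng.uniform(0.03, 0.07) * h
        ac = rng.uniform(0.05, 0.12) * w
        blob = np.exp(-(((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2))
        img += 105.0 * blob

    # smooth sinusoidal coordinate warp (water ripple)
    if spec.ripple_amplitude != 0:
        amp = spec.ripple_amplitude
        rr = rows + amp * np.sin(2 * np.pi * cols / (4.0 * t))
        cc_ = cols + amp * np.sin(2 * np.pi * rows / (5.0 * t))
        coords = np.broadcast_arrays(rr, cc_)
        img = ndimage.map_coordinates(
            img, np.stack(coords), order=1, mode="reflect"
        )

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))

    return ImagePlane(np.clip(np.round(img), 0, 255), dynamic_range=255.0)
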