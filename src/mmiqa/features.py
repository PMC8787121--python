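"""Per-pixel feature maps and the shared similarity transform.

Luminance, contrast and gradient maps are compared between reference and
distorted planes through the same stabilized ratio
``s(a, b) = (2ab + C) / (a^2 + b^2 + C)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_fixtures import ImagePlane, ValidationError

# Scharr masks, 1/16 normalization; S_v is the transpose of S_h.
SCHARR_H = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=np.float64) / 16.0
SCHARR_V = SCHARR_H.T.copy()


@dataclass(frozen=True)
class WindowSpec:
    """Local neighborhood used for the mean/std maps.

    ``kind`` is ``"gaussian"`` (default 11x11, sigma 1.5 — the SSIM
    convention), ``"box"`` (unweighted, with the 1/(N-1) small-sample
    correction on the variance), or ``"global"`` (degenerate mode: one
    global mean/std broadcast over the image, the literal whole-image
    reading). Borders are padded symmetrically.
    """

    kind: str = "gaussian"
    size: int = 11
    sigma: float = 1.5
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "box", "global"):
            raise ValidationError("window kind must be gaussian, box or global")
        if self.size < 1 or self.size % 2 == 0:
            raise ValidationError("window size must be odd and positive")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValidationError("gaussian window needs sigma > 0")
        if self.padding != "symmetric":
            raise ValidationError("only symmetric padding is supported")

    def weights(self) -> np.ndarray:
        """Normalized 2-D kernel (sums to 1)."""
        if self.kind == "box":
            k = np.ones((self.size, self.size))
        else:
            half = self.size // 2
            g = np.exp(-(np.arange(-half, half + 1) ** 2) / (2.0 * self.sigma**2))
            k = np.outer(g, g)
        return k / k.sum()


@dataclass
class SimilarityMap:
    """Map of the stabilized similarity ratio; values in (0, 1] for
    nonnegative operands, exactly 1 where the operands are equal."""

    values: np.ndarray
    stabilizer: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def mean(self) -> float:
        return float(self.values.mean())


def similarity_map(a: np.ndarray, b: np.ndarray, C: float) -> SimilarityMap:
    """Pixelwise ``(2ab + C) / (a^2 + b^2 + C)``; symmetric in (a, b)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("similarity operands must be finite")
    if not (C > 0):
        raise ValidationError("stabilizer C must be positive")
    values = (2.0 * a * b + C) / (a * a + b * b + C)
    return SimilarityMap(values=values, stabilizer=float(C))


def _check_window(image: ImagePlane, window: WindowSpec) -> None:
    if window.size > 2 * min(image.height, image.width):
        raise ValidationError("window larger than twice the image extent")


def local_mean_map(image: ImagePlane, window: WindowSpec | None = None) -> np.ndarray:
    """Weighted local average under the window at every pixel."""
    if window is None:
        window = WindowSpec()
    _check_window(image, window)
    x = image.pixels
    if window.kind == "global":
        return np.full_like(x, x.mean())
    return ndimage.correlate(x, window.weights(), mode="reflect")


def local_std_map(image: ImagePlane, window: WindowSpec | None = None) -> np.ndarray:
    """Square root of the locally weighted second central moment.

    The unweighted box mode applies the N/(N-1) small-sample correction;
    the Gaussian mode uses the plain weighted moment.
    """
    if window is None:
        window = WindowSpec()
    _check_window(image, window)
    x = image.pixels
    if window.kind == "global":
        return np.full_like(x, x.std(ddof=1) if x.size > 1 else 0.0)
    w = window.weights()
    xc = x - x.mean()  # centering tames the E[x^2]-E[x]^2 cancellation
    m = ndimage.correlate(xc, w, mode="reflect")
    m2 = ndimage.correlate(xc * xc, w, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    if window.kind == "box":
        n = window.size**2
        if n > 1:
            var = var * (n / (n - 1.0))
    return np.sqrt(var)


def scharr_gradient_magnitude(image: ImagePlane) -> np.ndarray:
    """Gradient magnitude from the 3/10/3 Scharr masks, symmetric padding."""
    if image.height < 3 or image.width < 3:
        raise ValidationError("image smaller than the 3x3 Scharr mask")
    x = image.pixels
    gh = ndimage.correlate(x, SCHARR_H, mode="reflect")
    gv = ndimage.correlate(x, SCHARR_V, mode="reflect")
    return np.sqrt(gh * gh + gv * gv)
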