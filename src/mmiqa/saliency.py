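"""Spectral-residual main-target extraction and positional pooling weights.

The saliency map is built in the frequency domain: the log-amplitude
spectrum minus its local (box-filtered) average is the "residual"; the
inverse transform of the residual spectrum, combined with the untouched
phase, concentrates energy on unexpected — salient — structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .io_fixtures import ImagePlane, ValidationError


@dataclass(frozen=True)
class SaliencyParams:
    """Free constants of the spectral-residual pipeline.

    Attributes
    ----------
    working_width
        The image is resized (bilinear, aspect-preserving) so its width is
        at most this before the FFT; classic spectral residual operates on
        small images. Clamped to the native width for narrower inputs.
    gamma
        Amplitude-stretch exponent applied to the (shifted, nonnegative)
        log-amplitude spectrum. The default 1.0 makes the stretch a no-op.
    residual_filter_size
        Side of the square box (averaging) filter subtracted from the
        log-amplitude spectrum; must be odd.
    smooth_sigma
        Gaussian smoothing scale for the spatial saliency map and for the
        positional weight map.
    log_epsilon
        Additive guard inside the logarithm so zero-amplitude bins stay
        finite.
    stretch_domain
        ``"log"`` stretches the log-amplitude spectrum (default);
        ``"amplitude"`` stretches the raw amplitude before the log.
    """

    working_width: int = 256
    gamma: float = 1.0
    residual_filter_size: int = 7
    smooth_sigma: float = 3.0
    log_epsilon: float = 1e-12
    stretch_domain: str = "log"

    def __post_init__(self) -> None:
        if self.working_width < 3:
            raise ValidationError("working_width must be >= 3")
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.residual_filter_size < 1 or self.residual_filter_size % 2 == 0:
            raise ValidationError("residual_filter_size must be odd and positive")
        if self.smooth_sigma <= 0:
            raise ValidationError("smooth_sigma must be positive")
        if self.log_epsilon <= 0:
            raise ValidationError("log_epsilon must be positive")
        if self.stretch_domain not in ("log", "amplitude"):
            raise ValidationError("stretch_domain must be 'log' or 'amplitude'")


@dataclass
class SaliencyMap:
    """Nonnegative map on [0, 1]; max is exactly 1 unless identically 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("saliency values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("saliency values must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("saliency values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def _stretched_log_amplitude(amplitude: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """A-bar: energy-renormalized, gamma-stretched log-amplitude spectrum."""
    eps = params.log_epsilon
    if params.stretch_domain == "amplitude":
        a = np.log(amplitude ** params.gamma + eps)
        return a
    a = np.log(amplitude + eps)
    if params.gamma == 1.0:
        return a
    shifted = a - a.min()  # the log-amplitude may be negative; stretch a
    aprime = shifted ** params.gamma  # nonnegative copy, then renormalize
    denom = aprime.sum()
    if denom == 0:
        return a
    return (a.sum() / denom) * aprime


def spectral_residual_map(pixels: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Pre-normalization spectral-residual map at the input's own scale.

    No resizing is performed here; this is the FFT core shared by
    :func:`spectral_residual_saliency` and exposed for oracle comparison.
    """
    f = np.fft.fft2(pixels)
    abar = _stretched_log_amplitude(np.abs(f), params)
    phase = np.angle(f)
    residual = abar - ndimage.uniform_filter(
        abar, size=params.residual_filter_size, mode="nearest"
    )
    sal = np.abs(np.fft.ifft2(np.exp(residual + 1j * phase))) ** 2
    return ndimage.gaussian_filter(sal, params.smooth_sigma, truncate=4.0, mode="nearest")


def spectral_residual_saliency(image: ImagePlane, params: SaliencyParams | None = None) -> SaliencyMap:
    """Main-target saliency of one image, max-normalized to [0, 1].

    Pipeline: bilinear resize to the working width; 2-D DFT; log-amplitude
    (with ``log_epsilon`` guard) and phase; gamma stretch and energy
    renormalization; subtraction of the box-filtered spectrum (the
    residual); squared magnitude of the inverse transform; Gaussian
    smoothing; resize back to native resolution; max-normalization.
    Deterministic.
    """
    if params is None:
        params = SaliencyParams()
    h, w = image.height, image.width
    ww = min(params.working_width, w)
    if ww < w:
        wh = max(3, int(round(h * ww / w)))
        small = resize(
            image.pixels, (wh, ww), order=1, mode="edge",
            anti_aliasing=True, preserve_range=True,
        )
    else:
        small = image.pixels

    sal = spectral_residual_map(small, params)

    if sal.shape != (h, w):
        sal = resize(
            sal, (h, w), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    sal = np.maximum(sal, 0.0)
    peak = sal.max()
    if peak > 0:
        sal = sal / peak
    return SaliencyMap(np.clip(sal, 0.0, 1.0))


def positional_weight_map(
    sal_ref: SaliencyMap, sal_dist: SaliencyMap, smooth_sigma: float
) -> np.ndarray:
    """Pooling weights: smoothed reference/distorted saliency, combined by max.

    Each map is Gaussian-smoothed with ``smooth_sigma`` (0 disables
    smoothing), then the two are united pixelwise by the maximum — the
    set-union analogue for fuzzy memberships.
    """
    if sal_ref.values.shape != sal_dist.values.shape:
        raise ValidationError("saliency maps must share dimensions")
    if smooth_sigma < 0:
        raise ValidationError("smooth_sigma must be nonnegative")
    if smooth_sigma > 0:
        a = ndimage.gaussian_filter(sal_ref.values, smooth_sigma, truncate=4.0, mode="nearest")
        b = ndimage.gaussian_filter(sal_dist.values, smooth_sigma, truncate=4.0, mode="nearest")
    else:
        a, b = sal_ref.values, sal_dist.values
    return np.maximum(a, b)
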