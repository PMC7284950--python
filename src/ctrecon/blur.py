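"""Linear motion-blur simulation.

Uniform linear motion during exposure degrades an image by convolution with a
line-shaped point spread function (PSF): the blurred image is

    I_b = P * I_c + N

where ``P`` is the PSF (parameterized by the motion angle and amplitude),
``*`` is 2D convolution and ``N`` an optional noise term.  This module
builds the PSF, applies the degradation, and produces clear/blurred pair
sets for evaluating deblurring.

PSF rasterization: the line segment of length ``amplitude`` through the
kernel center at the given angle is rasterized with symmetric sub-pixel
coverage weighting — a pixel whose center lies within half a pixel
(perpendicular distance) of the segment receives weight proportional to the
segment length it covers — then the kernel is normalized to unit mass.
Axis-aligned angles (0°, 90°) yield exactly uniform 1xL kernels; oblique
angles are an approximation to anti-aliased line rendering.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .core_io import GrayImage

__all__ = ["MotionBlurPSF", "NoiseModel", "motion_psf", "apply_blur", "make_pair_set"]


@dataclasses.dataclass
class MotionBlurPSF:
    """Normalized line-shaped convolution kernel.

    ``angle`` is in degrees counter-clockwise from horizontal (reduced
    modulo 180) and ``amplitude`` is the blur length in pixels.  The kernel
    has odd side lengths so its center is well defined, and its weights sum
    to one.
    """

    kernel: np.ndarray
    angle: float
    amplitude: int


@dataclasses.dataclass
class NoiseModel:
    """Additive noise attached to the degradation model.

    ``kind`` is ``"none"`` or ``"additive-gaussian"``; ``sigma`` is the
    standard deviation in intensity units (ignored for ``"none"``).
    """

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def motion_psf(angle: float, amplitude: int) -> MotionBlurPSF:
    """Build the PSF of uniform linear motion.

    Parameters
    ----------
    angle:
        Motion direction, degrees counter-clockwise from horizontal.  The
        PSF depends on the angle only modulo 180°.
    amplitude:
        Blur length in pixels (integer >= 1).  Amplitude 1 means no motion
        and yields the 1x1 identity kernel.
    """
    amplitude = int(amplitude)
    if amplitude < 1:
        raise ValueError(f"amplitude must be >= 1, got {amplitude}")
    if amplitude == 1:
        return MotionBlurPSF(np.array([[1.0]]), angle % 180.0, 1)

    theta = math.radians(angle % 180.0)
    dx, dy = math.cos(theta), math.sin(theta)
    # The motion path is a segment of total length `amplitude` centered on
    # the kernel center, so axis-aligned kernels come out exactly uniform.
    half = amplitude / 2.0

    # Generous odd-sized grid; zero border rows/columns are trimmed below.
    cx = int(math.ceil(abs(dx) * half + 0.5))
    cy = int(math.ceil(abs(dy) * half + 0.5))
    nx, ny = 2 * cx + 1, 2 * cy + 1

    # Pixel center relative to the kernel center, with +y up so a positive
    # angle is counter-clockwise in image convention.
    cols = np.arange(nx) - cx
    rows = cy - np.arange(ny)
    px, py = np.meshgrid(cols, rows)

    # Decompose each pixel center into along-segment (t) and perpendicular
    # (d) coordinates; coverage = length of the segment chord within the
    # unit-width band of the pixel, clipped to the segment extent.
    t = px * dx + py * dy
    d = -px * dy + py * dx
    near = np.abs(d) <= 0.5
    lo = np.maximum(t - 0.5, -half)
    hi = np.minimum(t + 0.5, half)
    coverage = np.clip(hi - lo, 0.0, 1.0)
    kernel = np.where(near, coverage, 0.0)

    # Trim symmetric all-zero borders, keeping the side lengths odd.
    while kernel.shape[0] > 1 and not kernel[0].any() and not kernel[-1].any():
        kernel = kernel[1:-1]
    while kernel.shape[1] > 1 and not kernel[:, 0].any() and not kernel[:, -1].any():
        kernel = kernel[:, 1:-1]

    total = kernel.sum()
    if total <= 0:  # pragma: no cover - cannot happen for amplitude >= 2
        raise RuntimeError("degenerate PSF rasterization")
    return MotionBlurPSF(kernel / total, angle % 180.0, amplitude)


def apply_blur(
    clear: GrayImage,
    psf: MotionBlurPSF,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    *,
    padding: str = "replicate",
) -> GrayImage:
    """Degrade ``clear`` by the motion-blur model.

    The image is convolved with the PSF kernel (same-size output).  Border
    handling defaults to replicate padding, which preserves constant images
    and avoids dark frames on CT; pass ``padding="zero"`` for strict
    zero-padded convolution semantics.  Noise (if any) is added after the
    convolution and the result is clipped to the representable range.
    """
    noise = noise or NoiseModel()
    kh, kw = psf.kernel.shape
    h, w = clear.pixels.shape
    if kh > h or kw > w:
        raise ValueError(
            f"PSF kernel {kh}x{kw} does not fit within image {h}x{w}"
        )
    mode = {"replicate": "nearest", "zero": "constant"}.get(padding)
    if mode is None:
        raise ValueError(f"unknown padding mode {padding!r}")
    # ndimage.convolve computes true convolution (kernel flipped), matching
    # the degradation model.
    blurred = ndimage.convolve(clear.pixels, psf.kernel, mode=mode, cval=0.0)
    if noise.kind == "additive-gaussian" and noise.sigma > 0:
        rng = np.random.default_rng(seed)
        blurred = blurred + rng.normal(0.0, noise.sigma, size=blurred.shape)
    blurred = np.clip(blurred, 0, clear.max_value)
    return GrayImage(blurred, bit_depth=clear.bit_depth)


#: Experimental blur grids: angles swept at fixed amplitude 15, and
#: amplitudes swept at fixed angle 45°.
DEFAULT_ANGLE_SWEEP = ((0.0, 15), (30.0, 15), (60.0, 15), (90.0, 15))
DEFAULT_AMPLITUDE_SWEEP = ((45.0, 5), (45.0, 15), (45.0, 20), (45.0, 25))


def make_pair_set(
    images: list[GrayImage],
    angles: list[float],
    amplitudes: list[int],
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> list[tuple[GrayImage, GrayImage, float, int]]:
    """Degrade every image at every (angle, amplitude) combination.

    Returns the Cartesian product as ``(clear, blurred, angle, amplitude)``
    tuples, reproducible given ``seed``.
    """
    if not images:
        raise ValueError("empty image list")
    if not angles or not amplitudes:
        raise ValueError("angle and amplitude lists must be non-empty")
    rng = np.random.default_rng(seed)
    pairs = []
    for image in images:
        for angle in angles:
            for amplitude in amplitudes:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                psf = motion_psf(angle, amplitude)
                blurred = apply_blur(image, psf, noise, seed=sub_seed)
                pairs.append((image, blurred, float(angle), int(amplitude)))
    return pairs
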