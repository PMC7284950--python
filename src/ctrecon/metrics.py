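"""Image-restoration and reconstruction quality metrics.

Implements the evaluation quantities used throughout the toolkit:

* Shannon entropy of an image histogram, ``E = sum_i p_i log2(1/p_i)`` with
  ``p_i = Num_i / (W*H)`` over ``N`` equal-width bins spanning the
  representable intensity range.  Blurring spreads intensity mass over more
  histogram bins, so entropy grows with blur.
* the Shannon entropy ratio ``E_r = E_d / E_p`` of a degraded or restored
  image against the clear image (closer to 1 from above = better
  restoration),
* MSE and PSNR (``10*log10((2**n - 1)**2 / MSE)``),
* overlap accuracy of a reconstructed binary mask against a reference.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core_io import BinaryMask, GrayImage

__all__ = [
    "MetricReport",
    "shannon_entropy",
    "entropy_ratio",
    "mse",
    "psnr",
    "reconstruction_accuracy",
]


@dataclasses.dataclass
class MetricReport:
    """A named scalar result together with the parameters that produced it."""

    name: str
    value: float
    parameters: dict

    def as_dict(self) -> dict:
        return {"name": self.name, "value": self.value, **self.parameters}


def _histogram(image: GrayImage, bins: int) -> np.ndarray:
    """Counts over ``bins`` equal-width bins spanning [0, 2**n - 1]."""
    counts, _ = np.histogram(
        image.pixels, bins=bins, range=(0.0, float(image.max_value))
    )
    return counts


def shannon_entropy(image: GrayImage, bins: int = 256) -> float:
    """Shannon entropy of the intensity histogram, in bits.

    Terms with ``p_i = 0`` contribute zero.  A constant image has entropy 0;
    a perfectly uniform histogram over ``bins`` bins has entropy
    ``log2(bins)``.
    """
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    if image.pixels.size == 0:
        raise ValueError("empty image")
    counts = _histogram(image, bins)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_ratio(test: GrayImage, clear: GrayImage, bins: int = 256) -> float:
    """Entropy of the test (blurred or restored) image over that of the clear.

    Both images must share a bit depth so the histograms span the same
    intensity range.  Undefined (error) when the clear image has zero
    entropy.
    """
    if test.bit_depth != clear.bit_depth:
        raise ValueError("bit depths differ between test and clear images")
    e_clear = shannon_entropy(clear, bins)
    if e_clear == 0.0:
        raise ValueError("clear image has zero entropy; ratio undefined")
    return shannon_entropy(test, bins) / e_clear


def mse(image_i: GrayImage, image_k: GrayImage) -> float:
    """Mean squared error over all pixel pairs."""
    if image_i.pixels.shape != image_k.pixels.shape:
        raise ValueError(
            f"shape mismatch {image_i.pixels.shape} vs {image_k.pixels.shape}"
        )
    diff = image_i.pixels - image_k.pixels
    return float(np.mean(diff * diff))


def psnr(image_i: GrayImage, image_k: GrayImage, bit_depth: int | None = None) -> float:
    """Peak signal-to-noise ratio in dB.

    ``10*log10(peak**2 / MSE)`` with ``peak = 2**n - 1``.  Identical images
    yield ``math.inf`` (a flagged sentinel, not an exception).
    """
    n = image_i.bit_depth if bit_depth is None else bit_depth
    if n < 1:
        raise ValueError("bit depth must be >= 1")
    err = mse(image_i, image_k)
    if err == 0.0:
        return math.inf
    peak = float((1 << n) - 1)
    return 10.0 * math.log10(peak * peak / err)


def reconstruction_accuracy(recon: BinaryMask, reference: BinaryMask) -> MetricReport:
    """Overlap of a reconstructed mask with a reference annotation.

    The primary value is the fraction of the reference covered by the
    reconstruction, ``|recon ∩ reference| / |reference|``; the report also
    carries the Jaccard index ``|∩| / |∪|`` as a stricter companion (it
    additionally penalizes over-segmentation).
    """
    if recon.shape != reference.shape:
        raise ValueError(f"lattice mismatch {recon.shape} vs {reference.shape}")
    ref_count = reference.count()
    if ref_count == 0:
        raise ValueError("empty reference mask")
    inter = int(np.logical_and(recon.inside, reference.inside).sum())
    union = int(np.logical_or(recon.inside, reference.inside).sum())
    return MetricReport(
        name="reconstruction_accuracy",
        value=inter / ref_count,
        parameters={
            "jaccard": inter / union if union else 0.0,
            "reference_voxels": ref_count,
            "reconstruction_voxels": recon.count(),
        },
    )
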