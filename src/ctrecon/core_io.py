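"""Domain containers and readers/writers for the formats the toolkit touches.

The toolkit works with three kinds of gridded data:

* :class:`GrayImage` — a single-channel 2D image with an explicit bit depth,
  the unit of the blur-simulation and metric computations.
* :class:`VolumeGrid` — a 3D scalar field on a regular lattice with physical
  voxel spacing, the input to segmentation and surface reconstruction.
* :class:`BinaryMask` — an inside/outside labelling on the lattice of a
  parent grid, used for segmentation output and reference annotations.

Conventions: indexing is 0-based and voxel ``(i, j, k)`` sits at world
position ``(i*sx, j*sy, k*sz)``; ``i`` runs along x, ``j`` along y and ``k``
along z.  RGB inputs are collapsed to luminance with ITU-R 601 weights since
CT data is grayscale.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "VolumeGrid",
    "BinaryMask",
    "read_dicom_series",
    "read_image",
    "write_image",
    "read_raw_volume",
    "write_raw_volume",
]

#: ITU-R 601 luminance weights used to collapse RGB inputs.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Tolerance (in the slice-position unit, mm for CT) on the consistency of
#: consecutive slice gaps when slice spacing has to be derived.
SLICE_GAP_TOL = 1e-3


@dataclasses.dataclass
class GrayImage:
    """Single-channel image with pixel values in ``[0, 2**bit_depth - 1]``.

    ``pixels`` is stored as float64 so that intermediate arithmetic (blurring,
    noise) does not silently wrap; quantization happens only at file output.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2D pixel array, got {self.pixels.ndim}D")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.bit_depth < 1:
            raise ValueError("bit depth must be >= 1")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside representable range "
                f"[0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**n - 1``."""
        return (1 << self.bit_depth) - 1


@dataclasses.dataclass
class VolumeGrid:
    """3D scalar field indexed ``(i, j, k)`` with physical voxel spacing."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D value array, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclasses.dataclass
class BinaryMask:
    """Inside/outside labelling on the lattice of a parent grid."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.inside.shape

    def count(self) -> int:
        return int(self.inside.sum())


# ---------------------------------------------------------------------------
# DICOM series reading
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | Path) -> VolumeGrid:
    """Read a single-frame DICOM series from ``directory`` into a volume.

    Slices are sorted by their position along the slice axis (the projection
    of ImagePositionPatient on the slice normal, falling back to
    SliceLocation, then InstanceNumber), so the result is independent of
    filename order.  Stored values are rescaled with the per-slice
    RescaleSlope/RescaleIntercept.  Slice spacing is taken from
    SpacingBetweenSlices when present and otherwise derived from consecutive
    slice positions; inconsistent gaps (> ``SLICE_GAP_TOL``) are an error.
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for path in paths:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:  # noqa: BLE001 - report offending file
            raise ValueError(f"unreadable DICOM file {path}: {exc}") from exc
        slices.append((path, ds))
    if len(slices) < 2:
        raise ValueError(
            f"directory {directory} holds {len(slices)} DICOM slice(s); need >= 2"
        )

    first = slices[0][1]
    series_uid = getattr(first, "SeriesInstanceUID", None)
    shape = (int(first.Rows), int(first.Columns))
    for path, ds in slices[1:]:
        if getattr(ds, "SeriesInstanceUID", None) != series_uid:
            raise ValueError(f"mixed series: {path} belongs to a different series")
        if (int(ds.Rows), int(ds.Columns)) != shape:
            raise ValueError(
                f"inconsistent dimensions: {path} is "
                f"{int(ds.Rows)}x{int(ds.Columns)}, expected {shape[0]}x{shape[1]}"
            )

    def slice_position(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        iop = getattr(ds, "ImageOrientationPatient", None)
        if ipp is not None and iop is not None:
            row = np.array(iop[:3], dtype=float)
            col = np.array(iop[3:], dtype=float)
            normal = np.cross(row, col)
            return float(np.dot(normal, np.array(ipp, dtype=float)))
        if ipp is not None:
            return float(ipp[2])
        loc = getattr(ds, "SliceLocation", None)
        if loc is not None:
            return float(loc)
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=lambda item: slice_position(item[1]))
    positions = [slice_position(ds) for _, ds in slices]

    planes = []
    for path, ds in slices:
        try:
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"cannot decode pixel data in {path}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)

    # DICOM pixel_array is (row, col) = (y, x); transpose to (i=x, j=y).
    values = np.stack([p.T for p in planes], axis=2)

    ps = getattr(first, "PixelSpacing", [1.0, 1.0])
    sy, sx = float(ps[0]), float(ps[1])  # PixelSpacing is (row, col)
    sbs = getattr(first, "SpacingBetweenSlices", None)
    if sbs is not None:
        sz = float(sbs)
    else:
        gaps = np.diff(positions)
        if np.any(np.abs(gaps - gaps[0]) > SLICE_GAP_TOL):
            raise ValueError(
                f"inconsistent slice gaps {gaps.tolist()} in {directory}; "
                "cannot derive slice spacing"
            )
        sz = float(abs(gaps[0])) if gaps[0] != 0 else 1.0
    return VolumeGrid(values, spacing=(sx, sy, sz))


# ---------------------------------------------------------------------------
# 2D image reading/writing (PNG / TIFF, 8- and 16-bit gray)
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF image as grayscale.

    8-bit and 16-bit single-channel images round-trip losslessly; RGB(A)
    inputs are collapsed to luminance with ITU-R 601 weights.
    """
    path = Path(path)
    with Image.open(path) as im:
        mode = im.mode
        if mode in ("L", "P"):
            arr = np.asarray(im.convert("L"), dtype=np.float64)
            depth = 8
        elif mode in ("I;16", "I;16B", "I;16L", "I"):
            arr = np.asarray(im, dtype=np.float64)
            depth = 16
        elif mode in ("RGB", "RGBA"):
            rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
            r, g, b = LUMA_WEIGHTS
            arr = r * rgb[..., 0] + g * rgb[..., 1] + b * rgb[..., 2]
            depth = 8
        else:
            raise ValueError(f"unsupported sample format {mode!r} in {path}")
    return GrayImage(np.clip(arr, 0, (1 << depth) - 1), bit_depth=depth)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write ``image`` as PNG or TIFF (by extension), 8- or 16-bit gray."""
    path = Path(path)
    quantized = np.rint(np.clip(image.pixels, 0, image.max_value))
    if image.bit_depth <= 8:
        pil = Image.fromarray(quantized.astype(np.uint8), mode="L")
    elif image.bit_depth <= 16:
        pil = Image.fromarray(quantized.astype(np.uint16))
    else:
        raise ValueError(f"cannot write bit depth {image.bit_depth} to {path.suffix}")
    pil.save(path)


# ---------------------------------------------------------------------------
# Self-describing raw volume container
# ---------------------------------------------------------------------------

def write_raw_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume to a self-describing ``.npz`` container (bit-exact)."""
    path = Path(path)
    if not path.name:
        raise ValueError("empty path")
    np.savez(
        path,
        values=volume.values,
        spacing=np.asarray(volume.spacing, dtype=np.float64),
        format_version=np.int64(1),
    )


def read_raw_volume(path: str | Path) -> VolumeGrid:
    """Read a volume written by :func:`write_raw_volume`."""
    path = Path(path)
    try:
        with np.load(path) as data:
            values = data["values"]
            spacing = tuple(data["spacing"])
    except KeyError as exc:
        raise ValueError(f"corrupted volume container {path}: missing {exc}") from exc
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read volume container {path}: {exc}") from exc
    return VolumeGrid(values, spacing=spacing)
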