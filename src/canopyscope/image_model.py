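"""Domain types and file I/O for co-registered multispectral image sets.

A sample is a folder of 8-bit grayscale frames, one per waveband, taken by a
monochrome camera under different LED colors. Pixel intensity (0-255) is the
reflectance proxy every downstream computation consumes. The chlorophyll
fluorescence frame (band label ``cfi``, taken under blue excitation through a
long-pass filter) is mandatory: it drives segmentation.

Conventions fixed project-wide: row-major pixel grids, origin top-left,
0-based (row, col) indexing. Intensities are stored as integers (uint8) so
histograms are bit-exact; index math promotes to floats elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np

from .errors import (
    DimensionMismatchError,
    ImageFormatError,
    MissingBandError,
)

#: Wavebands the instrument knows about. ``cfi`` is the chlorophyll
#: fluorescence frame used for plant/background separation.
KNOWN_BANDS = ("blue", "green", "red", "nir", "cfi")

FLUORESCENCE_BAND = "cfi"

#: Default band -> filename map; extension may be png/tif/tiff.
DEFAULT_BAND_FILES = {band: f"{band}.png" for band in KNOWN_BANDS}

_ALLOWED_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class WavebandImage:
    """One co-registered 8-bit grayscale frame for a named waveband."""

    pixels: np.ndarray
    waveband: str
    exposure_ms: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError(
                f"waveband image must be a 2-D grid, got shape {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageFormatError(
                f"waveband image must hold integer intensities, got {px.dtype}"
            )
        if px.min() < 0 or px.max() > 255:
            raise ImageFormatError("intensities must lie in [0, 255]")
        if self.exposure_ms is not None and self.exposure_ms <= 0:
            raise ImageFormatError("exposure_ms must be positive when given")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class IntensityHistogram:
    """Exact per-intensity pixel tally of one 8-bit frame (256 bins)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if (c < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryMask:
    """Foreground (plant, True) / background (False) partition of a frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", px.astype(bool, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class MultispectralImageSet:
    """The per-sample bundle of waveband frames plus scale metadata.

    Invariants: all frames share identical dimensions and the fluorescence
    band is present (segmentation is impossible without it).
    """

    images: dict[str, WavebandImage]
    set_id: str
    cm_per_pixel: float
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if FLUORESCENCE_BAND not in self.images:
            raise MissingBandError(
                f"no fluorescence image: set {self.set_id!r} lacks the "
                f"{FLUORESCENCE_BAND!r} band"
            )
        shapes = {band: img.shape for band, img in self.images.items()}
        if len(set(shapes.values())) > 1:
            raise DimensionMismatchError(
                f"set {self.set_id!r}: waveband dimensions differ: {shapes}"
            )
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(self.images)

    def __getitem__(self, band: str) -> WavebandImage:
        try:
            return self.images[band]
        except KeyError:
            raise MissingBandError(
                f"set {self.set_id!r} has no {band!r} band"
            ) from None


def _read_grayscale_8bit(path: Path) -> np.ndarray:
    """Read one frame, enforcing the single-channel 8-bit contract.

    16-bit and color files are rejected, not silently rescaled: the
    instrument is monochrome and 8-bit, so anything else signals an
    acquisition error.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageFormatError(f"cannot read image file {path.name}: {exc}") from exc
    if arr.ndim == 3:
        raise ImageFormatError(
            f"{path.name}: multi-channel (color) image; expected 8-bit grayscale"
        )
    if arr.ndim != 2:
        raise ImageFormatError(f"{path.name}: unsupported image layout {arr.shape}")
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path.name}: {arr.dtype} depth not supported; expected 8-bit"
        )
    return arr


def load_waveband_image(path: str | Path, waveband: str) -> WavebandImage:
    """Load a single 8-bit grayscale PNG/TIFF as a :class:`WavebandImage`."""
    return WavebandImage(pixels=_read_grayscale_8bit(Path(path)), waveband=waveband)


def load_image_set(folder_path: str | Path, config) -> MultispectralImageSet:
    """Read one sample folder into a :class:`MultispectralImageSet`.

    ``config`` is any object exposing ``band_files`` (band label -> filename)
    and ``cm_per_pixel``; in practice a
    :class:`canopyscope.config.PipelineConfig`. Bands whose file is absent are
    simply not loaded — except the fluorescence band, which is required.

    An optional ``timestamp.txt`` in the folder provides the acquisition
    timestamp recorded in the results.
    """
    folder = Path(folder_path)
    band_files: Mapping[str, str] = config.band_files
    images: dict[str, WavebandImage] = {}
    for band, filename in band_files.items():
        path = folder / filename
        if not path.exists():
            # allow alternate extensions for the same stem
            for ext in _ALLOWED_EXTENSIONS:
                alt = path.with_suffix(ext)
                if alt.exists():
                    path = alt
                    break
        if not path.exists():
            continue
        images[band] = load_waveband_image(path, band)
    if FLUORESCENCE_BAND not in images:
        raise MissingBandError(
            f"no fluorescence image: {folder} has no readable "
            f"{band_files.get(FLUORESCENCE_BAND, FLUORESCENCE_BAND + '.png')!r}"
        )
    ts_file = folder / "timestamp.txt"
    timestamp = ts_file.read_text().strip() if ts_file.exists() else None
    return MultispectralImageSet(
        images=images,
        set_id=folder.name,
        cm_per_pixel=config.cm_per_pixel,
        timestamp=timestamp,
    )


def compute_histogram(image: WavebandImage) -> IntensityHistogram:
    """Tally pixel intensities: counts[v] = number of pixels with value v."""
    counts = np.bincount(image.pixels.ravel(), minlength=256)
    return IntensityHistogram(counts=counts)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG, foreground 255 / background 0."""
    out = np.where(mask.pixels, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_mask(path: str | Path) -> BinaryMask:
    """Read back a mask PNG written by :func:`write_mask` (any nonzero = True)."""
    arr = _read_grayscale_8bit(Path(path))
    return BinaryMask(pixels=arr > 0)


def write_waveband_image(image: WavebandImage, path: str | Path) -> None:
    iio.imwrite(Path(path), image.pixels)
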