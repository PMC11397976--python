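"""Plant segmentation from the chlorophyll fluorescence image.

Under blue excitation through a >650 nm long-pass filter, chlorophyll
fluoresces: plant pixels are bright, background pixels dark, so the
fluorescence intensity histogram is bimodal. The mask is obtained by
thresholding at the valley (minimum) between the two leftmost modes —
background mode first, plant mode second — and then removing small connected
components (despeckling).

The valley search runs on a moving-average-smoothed histogram within bounds
that are either set manually or found automatically from the two leftmost
sufficiently prominent peaks. Two deterministic conventions, recorded in the
returned :class:`ThresholdResult` for auditability:

* the comparison at the threshold is strict (``intensity > t`` is plant;
  the threshold bin itself is background);
* ties between equal minima break toward the lowest intensity, biasing
  toward larger plant masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigurationError, NotBimodalError
from .image_model import (
    BinaryMask,
    IntensityHistogram,
    MultispectralImageSet,
    WavebandImage,
    compute_histogram,
)


@dataclass(frozen=True)
class ThresholdResult:
    """Diagnostics of one valley-threshold computation."""

    threshold: int
    bounds: tuple[int, int]
    smoothed_counts: np.ndarray
    peaks: tuple[int, ...] = ()
    method: str = "bounded_valley"  # or "auto_peaks"

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo <= self.threshold <= hi:
            raise ValueError("threshold must lie within its bounds")


@dataclass(frozen=True)
class DespeckleParams:
    """Size-based despeckling parameters.

    Connected components strictly smaller than ``min_component_px`` are
    dropped. ``median_prefilter`` applies a 3x3 median to the fluorescence
    frame before thresholding (a grayscale despeckle at intensity-extraction
    time, off by default).
    """

    min_component_px: int = 50
    connectivity: int = 8
    median_prefilter: bool = False

    def __post_init__(self) -> None:
        if self.min_component_px < 1:
            raise ConfigurationError("min_component_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class SegmentationConfig:
    """Full segmentation recipe.

    Manual bounds (``lo``, ``hi``) take precedence when both are given;
    otherwise, with ``auto_bounds`` enabled, the two leftmost histogram peaks
    supply the valley-search bounds.
    """

    lo: int | None = None
    hi: int | None = None
    auto_bounds: bool = True
    smooth_window: int = 5
    min_prominence_frac: float = 0.05
    despeckle: DespeckleParams = field(default_factory=DespeckleParams)


def smooth_histogram(hist: IntensityHistogram, window: int) -> np.ndarray:
    """Centered moving average of the 256 histogram counts.

    Edges are padded by replicating the boundary bin; ``window=1`` returns
    the counts unchanged (as floats).
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"smoothing window must be odd and >= 1, got {window}")
    counts = hist.counts.astype(float)
    if window == 1:
        return counts
    half = window // 2
    padded = np.pad(counts, half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def find_valley_threshold(
    hist: IntensityHistogram,
    lo: int,
    hi: int,
    window: int = 5,
) -> ThresholdResult:
    """Valley threshold: argmin of the smoothed histogram over [lo, hi].

    Ties break to the lowest intensity. ``lo``/``hi`` are the manually or
    automatically chosen bracketing positions of the background and plant
    modes.
    """
    if not (0 <= lo <= hi <= 255):
        raise ConfigurationError(f"need 0 <= lo <= hi <= 255, got lo={lo}, hi={hi}")
    smoothed = smooth_histogram(hist, window)
    # np.argmin returns the first minimum -> lowest-intensity tie-break
    t = lo + int(np.argmin(smoothed[lo : hi + 1]))
    return ThresholdResult(
        threshold=t, bounds=(lo, hi), smoothed_counts=smoothed, method="bounded_valley"
    )


def find_histogram_peaks(
    smoothed: np.ndarray, min_prominence_frac: float
) -> tuple[int, ...]:
    """Positions of local maxima with prominence >= frac * max(smoothed).

    The array is padded with -1 at both ends so modes sitting at bin 0 or
    255 (e.g. a clipped dark background) still register as peaks.
    """
    if not 0 < min_prominence_frac < 1:
        raise ConfigurationError("min_prominence_frac must be in (0, 1)")
    peak_floor = min_prominence_frac * float(smoothed.max())
    padded = np.concatenate(([-1.0], smoothed, [-1.0]))
    idx, _ = signal.find_peaks(padded, prominence=peak_floor)
    return tuple(int(i) - 1 for i in idx)


def auto_bounds(
    hist: IntensityHistogram,
    window: int = 5,
    min_prominence_frac: float = 0.05,
) -> tuple[int, int]:
    """Bounds for the valley search: the two leftmost prominent modes.

    The first mode from the left is the background, the second the plant;
    the valley between them is the segmentation threshold.
    """
    smoothed = smooth_histogram(hist, window)
    peaks = find_histogram_peaks(smoothed, min_prominence_frac)
    if len(peaks) < 2:
        raise NotBimodalError(
            "histogram not bimodal: fewer than two prominent peaks found; "
            "supply manual threshold bounds (lo, hi) in the segmentation config"
        )
    return peaks[0], peaks[1]


def threshold_mask(image: WavebandImage, t: int) -> BinaryMask:
    """Binarize: a pixel is plant iff its intensity strictly exceeds ``t``."""
    if not 0 <= t <= 255:
        raise ConfigurationError(f"threshold must be in [0, 255], got {t}")
    return BinaryMask(pixels=image.pixels > t)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def despeckle_mask(mask: BinaryMask, params: DespeckleParams) -> BinaryMask:
    """Drop connected components smaller than ``min_component_px``.

    Output foreground is a subset of the input foreground, and the operation
    is idempotent.
    """
    labels, n = ndimage.label(mask.pixels, structure=_STRUCTURES[params.connectivity])
    if n == 0:
        return BinaryMask(pixels=np.zeros_like(mask.pixels, dtype=bool))
    sizes = np.bincount(labels.ravel())
    keep = sizes >= params.min_component_px
    keep[0] = False  # background label
    return BinaryMask(pixels=keep[labels])


def segment(
    image_set: MultispectralImageSet, config: SegmentationConfig
) -> tuple[BinaryMask, ThresholdResult]:
    """Full fluorescence segmentation pipeline for one sample.

    Steps: optional 3x3 median prefilter on the fluorescence frame ->
    intensity histogram -> manual or automatic valley-search bounds ->
    valley threshold -> strict binarization -> size-based despeckle.
    """
    cfi = image_set["cfi"]
    if config.despeckle.median_prefilter:
        cfi = WavebandImage(
            pixels=ndimage.median_filter(cfi.pixels, size=3),
            waveband=cfi.waveband,
            exposure_ms=cfi.exposure_ms,
        )
    hist = compute_histogram(cfi)
    manual = config.lo is not None and config.hi is not None
    if manual:
        lo, hi = int(config.lo), int(config.hi)
        peaks: tuple[int, ...] = ()
        method = "bounded_valley"
    elif config.auto_bounds:
        smoothed = smooth_histogram(hist, config.smooth_window)
        peaks = find_histogram_peaks(smoothed, config.min_prominence_frac)
        if len(peaks) < 2:
            raise NotBimodalError(
                "histogram not bimodal: fewer than two prominent peaks found; "
                "supply manual threshold bounds (lo, hi) in the segmentation config"
            )
        lo, hi = peaks[0], peaks[1]
        method = "auto_peaks"
    else:
        raise ConfigurationError(
            "segmentation needs manual bounds (lo, hi) or auto_bounds = true"
        )
    result = find_valley_threshold(hist, lo, hi, config.smooth_window)
    result = ThresholdResult(
        threshold=result.threshold,
        bounds=result.bounds,
        smoothed_counts=result.smoothed_counts,
        peaks=peaks,
        method=method,
    )
    mask = threshold_mask(cfi, result.threshold)
    mask = despeckle_mask(mask, config.despeckle)
    return mask, result
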