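"""Normalized-difference index computation on canopy pixels.

An index pairs two wavebands a, b and assigns each foreground pixel
(R_a - R_b) / (R_a + R_b), a value in [-1, 1]. NDVI (a = near-infrared,
b = red) tracks chlorophyll ("greenness"); NDAI (a = red, b = green) tracks
anthocyanin pigmentation. Background pixels never enter the arithmetic —
index images, statistics and histograms describe canopy properties only.

Pixels where both bands read 0 have an undefined ratio and are excluded from
statistics rather than assigned 0, so index means are never diluted by
undefined pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib as mpl
import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingBandError
from .image_model import BinaryMask, MultispectralImageSet

#: Built-in index definitions. The NDAI band order / sign convention is the
#: one under which anthocyanin-rich tissue scores positive; it is fully
#: configurable, so users can match any published variant.
BUILTIN_INDICES = {
    "ndvi": ("nir", "red"),
    "ndai": ("red", "green"),
}

#: Fixed index-histogram binning: 200 bins of width 0.01 on [-1, 1].
HISTOGRAM_BIN_EDGES = np.linspace(-1.0, 1.0, 201)


@dataclass(frozen=True)
class IndexDefinition:
    """A normalized-difference index (R_a - R_b)/(R_a + R_b)."""

    name: str
    band_a: str
    band_b: str

    def __post_init__(self) -> None:
        if self.band_a == self.band_b:
            raise ConfigurationError(
                f"index {self.name!r}: band_a and band_b must differ"
            )

    @classmethod
    def builtin(cls, name: str) -> "IndexDefinition":
        a, b = BUILTIN_INDICES[name]
        return cls(name=name, band_a=a, band_b=b)


@dataclass(frozen=True)
class IndexImage:
    """Per-pixel index values, defined only where ``valid`` is True.

    ``valid`` marks foreground pixels with a defined ratio (band sum > 0);
    everywhere else ``values`` holds NaN.
    """

    values: np.ndarray
    valid: np.ndarray
    index_name: str

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass(frozen=True)
class CanopyStats:
    """Summary of one index over the canopy: mean, population std, histogram.

    ``mean``/``std`` are NaN markers when no valid pixel exists. The std is
    the population standard deviation: the canopy pixels are the full
    population of interest, not a sample from it.
    """

    index_name: str
    mean: float
    std: float
    n_pixels: int
    counts: np.ndarray
    fractions: np.ndarray

    @property
    def bin_edges(self) -> np.ndarray:
        return HISTOGRAM_BIN_EDGES


def compute_index(
    image_set: MultispectralImageSet, mask: BinaryMask, defn: IndexDefinition
) -> IndexImage:
    """Evaluate an index over the masked canopy.

    For each mask-true pixel with intensities a, b: value = (a-b)/(a+b) when
    a+b > 0; the pixel is invalid when a+b = 0. Mask-false pixels are invalid.
    """
    if mask.shape != image_set.shape:
        raise ValueError("mask dimensions do not match the image set")
    for band in (defn.band_a, defn.band_b):
        if band not in image_set.images:
            raise MissingBandError(
                f"index {defn.name!r} needs band {band!r}, absent from set "
                f"{image_set.set_id!r}"
            )
    a = image_set[defn.band_a].pixels.astype(np.float64)
    b = image_set[defn.band_b].pixels.astype(np.float64)
    total = a + b
    valid = mask.pixels & (total > 0)
    values = np.full(a.shape, np.nan)
    np.divide(a - b, total, out=values, where=valid)
    return IndexImage(values=values, valid=valid, index_name=defn.name)


def index_stats(img: IndexImage) -> CanopyStats:
    """Mean, population std and the fixed 200-bin histogram of an index image.

    The last bin [0.99, 1.00] is right-inclusive so the value 1.0 is counted.
    """
    vals = img.valid_values
    n = vals.size
    counts, _ = np.histogram(vals, bins=HISTOGRAM_BIN_EDGES)
    if n == 0:
        return CanopyStats(
            index_name=img.index_name,
            mean=float("nan"),
            std=float("nan"),
            n_pixels=0,
            counts=counts,
            fractions=np.zeros_like(counts, dtype=float),
        )
    return CanopyStats(
        index_name=img.index_name,
        mean=float(vals.mean()),
        std=float(vals.std(ddof=0)),
        n_pixels=int(n),
        counts=counts,
        fractions=counts / n,
    )


def canopy_area(mask: BinaryMask, cm_per_pixel: float) -> float:
    """Projected canopy area in cm²: foreground pixel count x scale²."""
    if cm_per_pixel <= 0:
        raise ConfigurationError("cm_per_pixel must be positive")
    return mask.n_foreground * cm_per_pixel**2


def histogram_frame(stats: CanopyStats) -> pd.DataFrame:
    """Index histogram as a DataFrame: bin_left, bin_right, count, fraction."""
    edges = stats.bin_edges
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": stats.counts,
            "fraction": stats.fractions,
        }
    )


def write_histogram_csv(stats: CanopyStats, path: str | Path) -> None:
    histogram_frame(stats).to_csv(path, index=False, float_format="%.6g")


def render_false_color(
    img: IndexImage, colormap_name: str, out: str | Path
) -> None:
    """Write a false-color PNG of an index image plus a color-bar legend.

    Valid pixels map [-1, 1] linearly onto the named matplotlib colormap;
    invalid/background pixels are black. The legend is written alongside as
    ``<stem>_legend.png``.
    """
    try:
        cmap = mpl.colormaps[colormap_name]
    except KeyError:
        available = ", ".join(sorted(mpl.colormaps)[:20])
        raise ConfigurationError(
            f"unknown colormap {colormap_name!r}; available include: {available}, ..."
        ) from None
    out = Path(out)
    rgb = np.zeros(img.values.shape + (3,), dtype=np.uint8)
    if img.valid.any():
        normed = (img.values[img.valid] + 1.0) / 2.0
        colored = cmap(normed)[:, :3]
        rgb[img.valid] = np.round(colored * 255).astype(np.uint8)
    import imageio.v3 as iio

    iio.imwrite(out, rgb)
    _write_legend(cmap, img.index_name, out.with_name(out.stem + "_legend.png"))


def _write_legend(cmap, index_name: str, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.4, 4.0))
    norm = mpl.colors.Normalize(vmin=-1.0, vmax=1.0)
    fig.colorbar(
        mpl.cm.ScalarMappable(norm=norm, cmap=cmap), cax=ax, label=index_name
    )
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
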