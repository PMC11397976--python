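"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: histogram
smoothing and the valley argmin are re-derived with explicit Python loops,
and connected components with a hand-written flood fill.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from canopyscope.config import PipelineConfig
from canopyscope.image_model import IntensityHistogram
from canopyscope.segmentation import SegmentationConfig
from canopyscope.synthetic_scenes import default_suite, generate, write_scene

SUITE_SEED = 42


@pytest.fixture(scope="session")
def suite_specs():
    return default_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def clean_scene(suite_specs):
    return generate(suite_specs["clean"], set_id="clean")


@pytest.fixture(scope="session")
def senescent_scene(suite_specs):
    return generate(suite_specs["senescent"], set_id="senescent")


@pytest.fixture
def manual_seg_config() -> SegmentationConfig:
    # bounds bracket the valley between the background (10) and plant (180)
    # fluorescence modes of the synthetic suite
    return SegmentationConfig(lo=40, hi=160)


@pytest.fixture
def pipeline_config(manual_seg_config) -> PipelineConfig:
    return PipelineConfig(segmentation=manual_seg_config)


@pytest.fixture
def sample_root(tmp_path, suite_specs) -> Path:
    """Three valid synthetic sample folders on disk."""
    root = tmp_path / "samples"
    for name in ("clean", "noisy", "speckled"):
        write_scene(suite_specs[name], root / name, set_id=name)
    return root


# --------------------------------------------------------------------------
# Brute-force oracles


def brute_smooth(counts, window: int) -> list[float]:
    """Moving average with replicate edge padding, by explicit loops."""
    counts = [float(c) for c in counts]
    half = window // 2
    padded = [counts[0]] * half + counts + [counts[-1]] * half
    return [
        sum(padded[i : i + window]) / window for i in range(len(counts))
    ]


def brute_valley(counts, lo: int, hi: int, window: int) -> int:
    """Exhaustive argmin of the smoothed histogram over [lo, hi], ties low."""
    smoothed = brute_smooth(counts, window)
    best, best_val = lo, smoothed[lo]
    for i in range(lo, hi + 1):
        if smoothed[i] < best_val:
            best, best_val = i, smoothed[i]
    return best


def brute_peaks(smoothed, min_prominence_frac: float) -> list[int]:
    """Prominence-filtered local maxima by direct scan.

    Prominence of a peak: height minus the highest minimum one must descend
    to on the lower of the two sides before reaching higher ground (or an
    edge).
    """
    smoothed = list(smoothed)
    n = len(smoothed)
    floor = min_prominence_frac * max(smoothed)
    peaks = []
    i = 0
    while i < n:
        # candidate local max (plateau-aware; edges count as lower ground)
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1
        left_lower = i == 0 or smoothed[i - 1] < smoothed[i]
        right_lower = j == n - 1 or smoothed[j + 1] < smoothed[i]
        if left_lower and right_lower:
            h = smoothed[i]
            # descend left until higher ground
            lmin = h
            for k in range(i - 1, -1, -1):
                lmin = min(lmin, smoothed[k])
                if smoothed[k] > h:
                    break
            rmin = h
            for k in range(j + 1, n):
                rmin = min(rmin, smoothed[k])
                if smoothed[k] > h:
                    break
            if h - max(lmin, rmin) >= floor:
                peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def brute_components(mask, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected components by flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def make_hist(counts) -> IntensityHistogram:
    full = np.zeros(256, dtype=np.int64)
    full[: len(counts)] = counts
    return IntensityHistogram(counts=full)


def triangular_bump(counts: np.ndarray, center: int, height: float, halfwidth: int) -> None:
    """Add a triangular mode in place (apex at ``center``)."""
    for d in range(-halfwidth + 1, halfwidth):
        i = center + d
        if 0 <= i < 256:
            counts[i] += int(round(height * (1 - abs(d) / halfwidth)))
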