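"""Batch orchestration over a directory of sample folders.

For every sample folder (lexicographic order) the pipeline loads the band
frames, segments the plant from the fluorescence image, converts the
foreground pixel count to projected canopy area in cm², evaluates each
configured normalized-difference index over the canopy, and writes per-sample
artifacts (mask PNG, false-color index PNGs, index-histogram CSVs) plus one
row per sample in ``results.csv``. A failing folder is logged and recorded
as an error row; it never aborts the batch.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .errors import CanopyScopeError
from .image_model import load_image_set, write_mask
from .indices import (
    CanopyStats,
    canopy_area,
    compute_index,
    index_stats,
    render_false_color,
    write_histogram_csv,
)
from .segmentation import segment

log = logging.getLogger(__name__)

RESULTS_FILENAME = "results.csv"


@dataclass(frozen=True)
class SampleResult:
    """One analyzed sample: segmentation bookkeeping plus per-index stats."""

    set_id: str
    timestamp: str
    threshold: int
    n_foreground_px: int
    canopy_area_cm2: float
    stats: dict[str, CanopyStats]  # index name -> stats
    error: str = ""


def _fmt(x: float) -> str:
    """Reals at 6 significant digits; NaN (undefined) as an empty field."""
    if x != x:  # NaN
        return ""
    return format(x, ".6g")


def csv_header(config: PipelineConfig) -> list[str]:
    cols = ["set_id", "timestamp", "threshold", "n_foreground_px", "canopy_area_cm2"]
    for defn in config.indices:
        cols += [f"{defn.name}_mean", f"{defn.name}_std", f"{defn.name}_n"]
    cols.append("error")
    return cols


def _result_row(result: SampleResult, config: PipelineConfig) -> list[str]:
    if result.error:
        row = [result.set_id, result.timestamp, "", "", ""]
        row += ["", "", ""] * len(config.indices)
        row.append(result.error)
        return row
    row = [
        result.set_id,
        result.timestamp,
        str(result.threshold),
        str(result.n_foreground_px),
        _fmt(result.canopy_area_cm2),
    ]
    for defn in config.indices:
        st = result.stats[defn.name]
        row += [_fmt(st.mean), _fmt(st.std), str(st.n_pixels)]
    row.append("")
    return row


def analyze_sample(
    folder: Path, config: PipelineConfig, out_dir: Path | None = None
) -> SampleResult:
    """Run the full per-sample analysis; optionally write artifacts."""
    image_set = load_image_set(folder, config)
    mask, threshold = segment(image_set, config.segmentation)
    area = canopy_area(mask, config.cm_per_pixel)
    stats: dict[str, CanopyStats] = {}
    index_images = {}
    for defn in config.indices:
        img = compute_index(image_set, mask, defn)
        stats[defn.name] = index_stats(img)
        index_images[defn.name] = img
    if out_dir is not None:
        sample_out = out_dir / image_set.set_id
        sample_out.mkdir(parents=True, exist_ok=True)
        write_mask(mask, sample_out / "mask.png")
        for name, img in index_images.items():
            render_false_color(img, config.colormap, sample_out / f"{name}.png")
            write_histogram_csv(stats[name], sample_out / f"{name}_hist.csv")
    log.debug(
        "%s: threshold=%d (bounds %s, method %s)",
        image_set.set_id,
        threshold.threshold,
        threshold.bounds,
        threshold.method,
    )
    return SampleResult(
        set_id=image_set.set_id,
        timestamp=image_set.timestamp or "",
        threshold=threshold.threshold,
        n_foreground_px=mask.n_foreground,
        canopy_area_cm2=area,
        stats=stats,
    )


def run_batch(
    root: str | Path, config: PipelineConfig, out_dir: str | Path | None = None
) -> list[SampleResult]:
    """Analyze every sample folder under ``root``; write ``results.csv``.

    Folders are processed in lexicographic order. Per-folder failures become
    error rows; an empty root is fatal.
    """
    root = Path(root)
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        raise CanopyScopeError(f"no sample folders under {root}")
    out = Path(out_dir) if out_dir is not None else root / "analysis"
    out.mkdir(parents=True, exist_ok=True)

    results: list[SampleResult] = []
    for folder in folders:
        start = time.perf_counter()
        try:
            result = analyze_sample(folder, config, out)
        except CanopyScopeError as exc:
            log.warning("skipping %s: %s", folder.name, exc)
            result = SampleResult(
                set_id=folder.name,
                timestamp="",
                threshold=0,
                n_foreground_px=0,
                canopy_area_cm2=float("nan"),
                stats={},
                error=str(exc),
            )
        else:
            log.info(
                "%s: %d px, %.6g cm² (%.0f ms)",
                folder.name,
                result.n_foreground_px,
                result.canopy_area_cm2,
                1e3 * (time.perf_counter() - start),
            )
        results.append(result)

    header = csv_header(config)
    lines = [",".join(header)]
    for result in results:
        lines.append(",".join(_result_row(result, config)))
    (out / RESULTS_FILENAME).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return results


def summarize(results_csv: str | Path) -> str:
    """Per-batch means and ranges of canopy area and every index."""
    try:
        frame = pd.read_csv(results_csv)
    except Exception as exc:
        raise CanopyScopeError(f"malformed results CSV: {exc}") from exc
    required = {"set_id", "canopy_area_cm2"}
    if not required.issubset(frame.columns):
        raise CanopyScopeError(
            f"malformed results CSV: missing columns {sorted(required - set(frame.columns))}"
        )
    if "error" in frame.columns:
        ok = frame[frame["error"].isna() | (frame["error"] == "")]
    else:
        ok = frame
    lines = [f"samples: {len(ok)} analyzed, {len(frame) - len(ok)} failed"]
    if ok.empty:
        lines.append("no samples")
        return "\n".join(lines)
    area = ok["canopy_area_cm2"].astype(float)
    lines.append(
        f"canopy_area_cm2: mean {area.mean():.6g}, "
        f"range [{area.min():.6g}, {area.max():.6g}]"
    )
    for col in ok.columns:
        if col.endswith("_mean"):
            vals = ok[col].astype(float).dropna()
            if vals.empty:
                continue
            name = col[: -len("_mean")]
            lines.append(
                f"{name}: mean {vals.mean():.6g}, "
                f"range [{vals.min():.6g}, {vals.max():.6g}]"
            )
    return "\n".join(lines)
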