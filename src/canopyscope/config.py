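"""TOML pipeline configuration.

Example::

    cm_per_pixel = 0.05

    [bands]
    cfi = "cfi.png"
    nir = "nir.png"
    red = "red.png"

    [segmentation]
    lo = 40
    hi = 160
    auto_bounds = false
    smooth_window = 5
    min_component_px = 50
    connectivity = 8
    median_prefilter = false

    [[index]]
    name = "ndvi"
    band_a = "nir"
    band_b = "red"

    [output]
    colormap = "viridis"
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .image_model import DEFAULT_BAND_FILES
from .indices import IndexDefinition
from .segmentation import DespeckleParams, SegmentationConfig

DEFAULT_COLORMAP = "viridis"


@dataclass
class PipelineConfig:
    band_files: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BAND_FILES)
    )
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    indices: tuple[IndexDefinition, ...] = (
        IndexDefinition(name="ndvi", band_a="nir", band_b="red"),
    )
    cm_per_pixel: float = 0.05
    colormap: str = DEFAULT_COLORMAP
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cm_per_pixel <= 0:
            raise ConfigurationError("cm_per_pixel must be positive")
        if not self.indices:
            raise ConfigurationError("at least one index must be defined")
        if "cfi" not in self.band_files:
            raise ConfigurationError("band map must include the cfi band")
        for defn in self.indices:
            for band in (defn.band_a, defn.band_b):
                if band not in self.band_files:
                    raise ConfigurationError(
                        f"index {defn.name!r} references band {band!r} "
                        "absent from the band map"
                    )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a TOML file into a :class:`PipelineConfig`."""
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    seg_raw = raw.get("segmentation", {})
    despeckle = DespeckleParams(
        min_component_px=int(seg_raw.get("min_component_px", 50)),
        connectivity=int(seg_raw.get("connectivity", 8)),
        median_prefilter=bool(seg_raw.get("median_prefilter", False)),
    )
    segmentation = SegmentationConfig(
        lo=seg_raw.get("lo"),
        hi=seg_raw.get("hi"),
        auto_bounds=bool(seg_raw.get("auto_bounds", True)),
        smooth_window=int(seg_raw.get("smooth_window", 5)),
        min_prominence_frac=float(seg_raw.get("min_prominence_frac", 0.05)),
        despeckle=despeckle,
    )
    indices = tuple(
        IndexDefinition(
            name=entry["name"], band_a=entry["band_a"], band_b=entry["band_b"]
        )
        for entry in raw.get("index", [])
    )
    if not indices:
        indices = (IndexDefinition(name="ndvi", band_a="nir", band_b="red"),)
    band_files = dict(DEFAULT_BAND_FILES)
    band_files.update(raw.get("bands", {}))
    output = raw.get("output", {})
    return PipelineConfig(
        band_files=band_files,
        segmentation=segmentation,
        indices=indices,
        cm_per_pixel=float(raw.get("cm_per_pixel", 0.05)),
        colormap=output.get("colormap", DEFAULT_COLORMAP),
        log_level=raw.get("log_level", "INFO"),
    )
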