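"""Synthetic multispectral scenes with exact ground truth.

Real canopy images are not required to verify the analysis chain: the
segmentation assumes only a statistical structure — a dark background and a
bright plant region in the fluorescence channel (a bimodal histogram),
per-band constant-reflectance regions, additive sensor noise, and occasional
small bright speckle artifacts. This module generates scenes with exactly
that structure and returns the exact expected mask, pixel count, area and
per-region index values, so every downstream result can be checked against a
closed form.

Generation order matters for exactness: the plant mask and ground truth are
fixed first, speckles are then placed strictly outside the plant (rejection
sampling), and per-band Gaussian noise is applied last (rounded, then
clipped to [0, 255]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import CanopyScopeError, ConfigurationError
from .image_model import (
    BinaryMask,
    MultispectralImageSet,
    WavebandImage,
    write_mask,
    write_waveband_image,
)
from .indices import BUILTIN_INDICES, IndexDefinition


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col) and semi-axes in pixels."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            ((rows - self.center_row) / self.semi_row) ** 2
            + ((cols - self.center_col) / self.semi_col) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class SpeckleSpec:
    """Small bright background artifacts: ``count`` blobs of ``size_px`` pixels."""

    count: int
    size_px: int
    intensity: int = 200


@dataclass(frozen=True)
class SenescencePatch:
    """A plant sub-region (e.g. a senescing older leaf) with its own reflectance."""

    ellipse: Ellipse
    band_intensity: Mapping[str, float]


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parametric description of one scene.

    ``band_intensity`` maps region ("plant" / "background") -> band -> mean
    intensity. ``noise_std`` is the additive Gaussian sensor noise (rounded
    then clipped). Plant and background fluorescence means must differ, or
    the scene is declared non-segmentable.
    """

    width: int = 96
    height: int = 96
    plant_ellipses: tuple[Ellipse, ...] = (Ellipse(48.0, 48.0, 28.0, 22.0),)
    explicit_mask: np.ndarray | None = None
    band_intensity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "plant": {"cfi": 180, "nir": 180, "red": 36, "green": 90, "blue": 40},
            "background": {"cfi": 10, "nir": 60, "red": 60, "green": 60, "blue": 60},
        }
    )
    noise_std: float = 0.0
    speckles: SpeckleSpec | None = None
    patch: SenescencePatch | None = None
    cm_per_pixel: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        plant = self.band_intensity["plant"]
        background = self.band_intensity["background"]
        if plant.keys() != background.keys():
            raise ConfigurationError("plant and background must define the same bands")
        for region, bands in self.band_intensity.items():
            for band, mean in bands.items():
                if not 0 <= mean <= 255:
                    raise ConfigurationError(
                        f"{region}/{band} mean {mean} outside [0, 255]"
                    )
        if "cfi" in plant and plant["cfi"] == background["cfi"]:
            raise ConfigurationError(
                "non-segmentable scene: plant and background fluorescence "
                "means are equal"
            )
        if self.noise_std < 0:
            raise ConfigurationError("noise_std must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact expectations for one generated scene (computed before noise)."""

    mask: BinaryMask
    n_plant_px: int
    area_cm2: float
    expected_index: dict[str, dict[str, float]]  # index -> region -> value
    region_px: dict[str, int]  # region -> pixel count


def _index_value(bands: Mapping[str, float], defn: IndexDefinition) -> float | None:
    if defn.band_a not in bands or defn.band_b not in bands:
        return None
    a, b = float(bands[defn.band_a]), float(bands[defn.band_b])
    if a + b == 0:
        return None
    return (a - b) / (a + b)


def _default_indices(bands: Sequence[str]) -> tuple[IndexDefinition, ...]:
    out = []
    for name, (a, b) in BUILTIN_INDICES.items():
        if a in bands and b in bands:
            out.append(IndexDefinition(name=name, band_a=a, band_b=b))
    return tuple(out)


def _plant_mask(spec: SyntheticSceneSpec) -> np.ndarray:
    if spec.explicit_mask is not None:
        mask = np.asarray(spec.explicit_mask, dtype=bool)
        if mask.shape != (spec.height, spec.width):
            raise CanopyScopeError("explicit mask does not match canvas size")
        return mask
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for ell in spec.plant_ellipses:
        if (
            ell.center_row - ell.semi_row < -0.5
            or ell.center_row + ell.semi_row > spec.height - 0.5
            or ell.center_col - ell.semi_col < -0.5
            or ell.center_col + ell.semi_col > spec.width - 0.5
        ):
            raise CanopyScopeError("plant shape exceeds the canvas")
        mask |= ell.contains(rows, cols)
    return mask


def _place_speckles(
    rng: np.random.Generator,
    plant: np.ndarray,
    speckles: SpeckleSpec,
    shape: tuple[int, int],
) -> np.ndarray:
    """Rejection-sample speckle footprints that never touch the plant."""
    h, w = shape
    n_px = speckles.size_px
    side = int(np.ceil(np.sqrt(n_px)))
    footprint = np.zeros((side, side), dtype=bool)
    footprint.ravel()[:n_px] = True
    out = np.zeros(shape, dtype=bool)
    for _ in range(speckles.count):
        for _attempt in range(1000):
            r = int(rng.integers(0, h - side + 1))
            c = int(rng.integers(0, w - side + 1))
            window = plant[r : r + side, c : c + side]
            if not (window & footprint).any():
                out[r : r + side, c : c + side] |= footprint
                break
        else:
            raise CanopyScopeError(
                "could not place speckles outside the plant region"
            )
    return out


def generate(
    spec: SyntheticSceneSpec,
    indices: Sequence[IndexDefinition] | None = None,
    set_id: str = "synthetic",
) -> tuple[MultispectralImageSet, GroundTruth]:
    """Render a scene and its exact ground truth.

    Deterministic given ``spec.seed``. In a noiseless spec every plant pixel
    carries exactly the configured band intensities, so pipeline outputs can
    be compared against closed-form values.
    """
    plant = _plant_mask(spec)
    bands = sorted(spec.band_intensity["plant"])
    if indices is None:
        indices = _default_indices(bands)

    patch_mask = np.zeros_like(plant)
    if spec.patch is not None:
        rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
        patch_mask = spec.patch.ellipse.contains(rows, cols)
        if (patch_mask & ~plant).any():
            raise CanopyScopeError("senescence patch extends outside the plant")

    # ground truth is fixed before speckles/noise touch the images
    main_mask = plant & ~patch_mask
    region_px = {"plant": int(main_mask.sum())}
    expected: dict[str, dict[str, float]] = {}
    for defn in indices:
        per_region: dict[str, float] = {}
        value = _index_value(spec.band_intensity["plant"], defn)
        if value is not None:
            per_region["plant"] = value
        if spec.patch is not None:
            pvalue = _index_value(spec.patch.band_intensity, defn)
            if pvalue is not None:
                per_region["patch"] = pvalue
        expected[defn.name] = per_region
    if spec.patch is not None:
        region_px["patch"] = int(patch_mask.sum())
    truth = GroundTruth(
        mask=BinaryMask(pixels=plant),
        n_plant_px=int(plant.sum()),
        area_cm2=int(plant.sum()) * spec.cm_per_pixel**2,
        expected_index=expected,
        region_px=region_px,
    )

    rng = np.random.default_rng(spec.seed)
    speckle_mask = None
    if spec.speckles is not None and spec.speckles.count > 0:
        speckle_mask = _place_speckles(
            rng, plant, spec.speckles, (spec.height, spec.width)
        )

    images: dict[str, WavebandImage] = {}
    for band in bands:
        frame = np.full(
            (spec.height, spec.width),
            float(spec.band_intensity["background"][band]),
        )
        frame[main_mask] = float(spec.band_intensity["plant"][band])
        if spec.patch is not None and band in spec.patch.band_intensity:
            frame[patch_mask] = float(spec.patch.band_intensity[band])
        elif spec.patch is not None:
            frame[patch_mask] = float(spec.band_intensity["plant"][band])
        if speckle_mask is not None:
            frame[speckle_mask] = float(spec.speckles.intensity)
        if spec.noise_std > 0:
            frame = frame + rng.normal(0.0, spec.noise_std, frame.shape)
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
        images[band] = WavebandImage(pixels=frame, waveband=band)

    image_set = MultispectralImageSet(
        images=images, set_id=set_id, cm_per_pixel=spec.cm_per_pixel
    )
    return image_set, truth


def generate_senescent(
    spec: SyntheticSceneSpec,
    patch: SenescencePatch,
    indices: Sequence[IndexDefinition] | None = None,
    set_id: str = "senescent",
) -> tuple[MultispectralImageSet, GroundTruth]:
    """Scene with a second plant sub-region of distinct reflectance.

    Emulates a senescing older leaf: the index histogram over the canopy
    becomes bimodal, with mode masses in the ratio of sub-region pixel
    counts.
    """
    return generate(replace(spec, patch=patch), indices=indices, set_id=set_id)


# --------------------------------------------------------------------------
# Named fixture suite


def default_suite(seed: int = 42) -> dict[str, SyntheticSceneSpec]:
    """Five canonical fixtures: clean, noisy, speckled, senescent, blank."""
    base = SyntheticSceneSpec(seed=seed)
    patch = SenescencePatch(
        ellipse=Ellipse(40.0, 48.0, 9.0, 9.0),
        band_intensity={"cfi": 180, "nir": 100, "red": 100, "green": 90, "blue": 40},
    )
    blank = replace(
        base,
        plant_ellipses=(),
        explicit_mask=np.zeros((base.height, base.width), dtype=bool),
        seed=seed + 4,
    )
    return {
        "clean": base,
        "noisy": replace(base, noise_std=5.0, seed=seed + 1),
        "speckled": replace(
            base, speckles=SpeckleSpec(count=3, size_px=2, intensity=200), seed=seed + 2
        ),
        "senescent": replace(base, patch=patch, seed=seed + 3),
        "blank": blank,
    }


def write_scene(
    spec: SyntheticSceneSpec,
    out_dir: str | Path,
    indices: Sequence[IndexDefinition] | None = None,
    set_id: str | None = None,
) -> GroundTruth:
    """Write band PNGs plus ``ground_truth.json`` for one scene."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_set, truth = generate(
        spec, indices=indices, set_id=set_id or out.name
    )
    for band, img in image_set.images.items():
        write_waveband_image(img, out / f"{band}.png")
    write_mask(truth.mask, out / "true_mask.png")
    payload = {
        "mask_path": "true_mask.png",
        "n_plant_px": truth.n_plant_px,
        "area_cm2": truth.area_cm2,
        "cm_per_pixel": spec.cm_per_pixel,
        "expected_index": truth.expected_index,
        "region_px": truth.region_px,
        "seed": spec.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return truth


def write_suite(out_dir: str | Path, seed: int = 42) -> dict[str, GroundTruth]:
    out = Path(out_dir)
    truths = {}
    for name, spec in default_suite(seed).items():
        truths[name] = write_scene(spec, out / name, set_id=name)
    return truths
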