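"""Gray-card exposure calibration.

Cross-band index arithmetic assumes intensities are comparable measures of
reflectance, which requires each waveband's exposure to be normalized. The
reference is a middle-gray card with ~50% reflectance at all wavebands: each
band's exposure time is adjusted until the card images at the 8-bit midpoint
intensity (target 127), under a linear-sensor model where mean intensity is
proportional to exposure time.

The procedure is a damped fixed-point iteration: measure the card mean,
rescale the exposure by target/measured, repeat until within tolerance. A
saturated card (mean 255) invalidates the linear model, so the exposure is
halved before resuming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ConfigurationError, NoSignalError
from .image_model import WavebandImage, load_waveband_image

log = logging.getLogger(__name__)

#: 8-bit midpoint: the target card intensity.
DEFAULT_TARGET = 127.0
DEFAULT_TOLERANCE = 1.0
DEFAULT_MAX_ITER = 10
DEFAULT_EXPOSURE_RANGE_MS = (0.01, 10_000.0)

#: Card region as (row_start, row_stop, col_start, col_stop), stop-exclusive.
Rect = tuple[int, int, int, int]

CaptureFn = Callable[[float], WavebandImage]


@dataclass(frozen=True)
class CalibrationRecord:
    """Outcome of calibrating one waveband's exposure."""

    waveband: str
    exposure_ms: float
    measured_mean: float
    target: float
    converged: bool
    iterations: int


def propose_exposure(
    current_ms: float,
    measured_mean: float,
    target: float = DEFAULT_TARGET,
    exposure_range_ms: tuple[float, float] = DEFAULT_EXPOSURE_RANGE_MS,
) -> float:
    """Next exposure under the linear-sensor model: current x target/measured.

    The result is clipped to the configured exposure range. A measured mean
    of 0 means the sensor saw nothing; no rescaling can recover signal from
    darkness.
    """
    if current_ms <= 0:
        raise ConfigurationError("current exposure must be positive")
    if measured_mean <= 0:
        raise NoSignalError(
            "no signal: gray-card mean intensity is 0; check lighting/region"
        )
    lo, hi = exposure_range_ms
    return float(np.clip(current_ms * target / measured_mean, lo, hi))


def _card_mean(image: WavebandImage, region: Rect) -> float:
    r0, r1, c0, c1 = region
    h, w = image.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ConfigurationError(
            f"card region {region} does not fit inside frame {image.shape}"
        )
    return float(image.pixels[r0:r1, c0:c1].mean())


def calibrate_band(
    capture: CaptureFn,
    card_region: Rect,
    waveband: str = "unknown",
    start_ms: float = 10.0,
    target: float = DEFAULT_TARGET,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    exposure_range_ms: tuple[float, float] = DEFAULT_EXPOSURE_RANGE_MS,
) -> CalibrationRecord:
    """Iterate exposure proposals until the card mean reaches the target.

    ``capture`` maps an exposure (ms) to a frame — a real camera backend or
    a simulator. Each capture counts as one iteration. A fully saturated
    card triggers an exposure halving (the linear model cannot extrapolate
    through clipping) before the iteration resumes.
    """
    exposure = float(start_ms)
    measured = float("nan")
    converged = False
    for iteration in range(1, max_iter + 1):
        frame = capture(exposure)
        measured = _card_mean(frame, card_region)
        if measured >= 255.0:
            log.warning(
                "%s: gray card saturated at %.4g ms; halving exposure",
                waveband,
                exposure,
            )
            exposure = max(exposure / 2.0, exposure_range_ms[0])
            continue
        if abs(measured - target) <= tolerance:
            converged = True
            break
        exposure = propose_exposure(exposure, measured, target, exposure_range_ms)
    return CalibrationRecord(
        waveband=waveband,
        exposure_ms=exposure,
        measured_mean=measured,
        target=target,
        converged=converged,
        iterations=iteration,
    )


def write_calibration_records(
    records: list[CalibrationRecord], path: str | Path
) -> None:
    """Persist per-band exposures as a TOML fragment for the analysis config."""
    lines = ["[calibration.exposure_ms]"]
    for rec in records:
        lines.append(f"{rec.waveband} = {rec.exposure_ms:.6g}")
    lines.append("")
    Path(path).write_text("\n".join(lines))


# --------------------------------------------------------------------------
# Capture backends


def _dithered_frame(level: float, shape: tuple[int, int]) -> np.ndarray:
    """8-bit frame whose spatial mean approximates ``level`` closely.

    A real sensor's photon/read noise spreads the card pixels around the
    true signal, so the region mean resolves far below one intensity count.
    Emulated here by deterministic dithering between floor and ceil: the
    frame mean matches ``level`` to within 1/(2·n_pixels).
    """
    level = min(max(level, 0.0), 255.0)
    lo = int(np.floor(level))
    frac = level - lo
    n = shape[0] * shape[1]
    n_high = int(round(frac * n))
    flat = np.full(n, lo, dtype=np.uint8)
    if lo < 255:
        flat[:n_high] = lo + 1
    return flat.reshape(shape)


class LinearCameraSim:
    """Synthetic camera: card mean intensity proportional to exposure.

    ``gain`` is intensity counts per millisecond on the gray card; the frame
    clips at 255 like any 8-bit sensor.
    """

    def __init__(self, gain: float, shape: tuple[int, int] = (32, 32)):
        self.gain = gain
        self.shape = shape

    def __call__(self, exposure_ms: float) -> WavebandImage:
        return WavebandImage(
            pixels=_dithered_frame(self.gain * exposure_ms, self.shape),
            waveband="card",
            exposure_ms=exposure_ms,
        )


class GammaCameraSim:
    """Synthetic mildly nonlinear camera: card mean ∝ exposure**gamma."""

    def __init__(self, gain: float, gamma: float = 0.9, shape: tuple[int, int] = (32, 32)):
        self.gain = gain
        self.gamma = gamma
        self.shape = shape

    def __call__(self, exposure_ms: float) -> WavebandImage:
        return WavebandImage(
            pixels=_dithered_frame(self.gain * exposure_ms**self.gamma, self.shape),
            waveband="card",
            exposure_ms=exposure_ms,
        )


class FolderCapture:
    """Capture backend over pre-taken card images named ``card_<ms>ms.png``.

    A folder of discrete exposures cannot honor an arbitrary proposal, so the
    file with the nearest encoded exposure is returned. Intended for
    after-the-fact calibration from a manually collected exposure sweep.
    """

    def __init__(self, folder: str | Path, waveband: str = "card"):
        self.folder = Path(folder)
        self.waveband = waveband
        self._exposures: dict[float, Path] = {}
        for path in sorted(self.folder.glob("card_*ms.*")):
            stem = path.stem  # card_<ms>ms
            try:
                ms = float(stem[len("card_") : -len("ms")])
            except ValueError:
                continue
            self._exposures[ms] = path
        if not self._exposures:
            raise ConfigurationError(
                f"no card_<ms>ms images found in {self.folder}"
            )

    def __call__(self, exposure_ms: float) -> WavebandImage:
        nearest = min(self._exposures, key=lambda ms: abs(ms - exposure_ms))
        img = load_waveband_image(self._exposures[nearest], self.waveband)
        return WavebandImage(
            pixels=img.pixels, waveband=self.waveband, exposure_ms=nearest
        )
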