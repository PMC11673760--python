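"""B-mode well intensity analysis and the decibel-change statistic.

Contrast agents are pipetted into wells bored in a tissue-mimicking agarose
phantom and imaged in B-mode before and after injection.  Each well is
covered by a saved region of interest; the mean 8-bit greyscale inside the
ROI quantifies echogenicity, and the change is reported in decibels:

    I_dB = 10 * log10(I_after / I_before)

Positive values mean the injected sample scatters more than the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .frames import ImageFrame

__all__ = [
    "WellROI",
    "WellMeasurement",
    "WellPanelSummary",
    "mean_roi_intensity",
    "subtract_mean_background",
    "decibel_change",
    "measure_well",
    "summarize_wells",
]


@dataclass
class WellROI:
    """Region of interest covering one phantom well.

    Wells are circular in plan but the echo appears as a band, so the
    default ROI is a rectangle of physical width ``diameter_mm`` (converted
    through ``pixel_pitch_mm``) and on-screen height ``height_px``; set
    ``shape='circle'`` for a disk of the same diameter.
    """

    center_px: Tuple[int, int]
    height_px: int
    pixel_pitch_mm: float
    diameter_mm: float = 8.0
    shape: str = "rect"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("diameter_mm and pixel_pitch_mm must be positive")
        if self.height_px < 1:
            raise ValueError("height_px must be >= 1")
        if self.shape not in ("rect", "circle"):
            raise ValueError(f"shape must be 'rect' or 'circle', got {self.shape!r}")

    @property
    def width_px(self) -> int:
        return max(1, int(round(self.diameter_mm / self.pixel_pitch_mm)))

    def mask(self, frame_shape: Tuple[int, int]) -> np.ndarray:
        rows, cols = frame_shape
        cr, cc = self.center_px
        if self.shape == "circle":
            r = self.width_px / 2.0
            if cr - r < 0 or cr + r > rows - 1 or cc - r < 0 or cc + r > cols - 1:
                raise ValueError(f"circular ROI at {self.center_px} extends outside the frame")
            yy, xx = np.mgrid[0:rows, 0:cols]
            return np.hypot(yy - cr, xx - cc) <= r
        r0 = cr - self.height_px // 2
        c0 = cc - self.width_px // 2
        r1, c1 = r0 + self.height_px, c0 + self.width_px
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            raise ValueError(f"rectangular ROI at {self.center_px} extends outside the frame")
        m = np.zeros((rows, cols), dtype=bool)
        m[r0:r1, c0:c1] = True
        return m


@dataclass
class WellMeasurement:
    """Per-well intensities and the derived decibel change."""

    well_id: int
    i_before: float
    i_after: float
    i_after_bg_subtracted: float
    delta_db: float


@dataclass
class WellPanelSummary:
    """Replicate-well summary: mean +/- SD of 'after' intensity and the
    panel decibel change computed from the panel means."""

    n_wells: int
    mean_i_before: float
    mean_i_after: float
    sd_i_after: float
    mean_delta_db: float


def mean_roi_intensity(frame8, roi: WellROI) -> float:
    """Arithmetic mean greyscale over the ROI pixels.

    Accepts an 8-bit :class:`ImageFrame` or a plain 2-D array already on
    the 8-bit scale.
    """
    if isinstance(frame8, ImageFrame):
        if frame8.bit_depth != 8:
            raise ValueError("mean_roi_intensity expects an 8-bit frame")
        arr = frame8.pixels
    else:
        arr = np.asarray(frame8, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("frame must be 2-D")
    return float(arr[roi.mask(arr.shape)].mean())


def subtract_mean_background(
    after_frames: Sequence[np.ndarray],
    background_frames: Sequence[np.ndarray],
    clip: bool = True,
) -> List[np.ndarray]:
    """Subtract the pixelwise mean of the background frames from each
    post-injection frame, removing stationary transducer artifacts.

    By default the result is clipped at 0 (greyscale images cannot go
    negative); pass ``clip=False`` for an unclipped diagnostic, since
    clipping biases pure-noise wells slightly positive.
    """
    if len(background_frames) < 1:
        raise ValueError("need at least one background frame")
    stacks = [np.asarray(f, dtype=np.float64) for f in background_frames]
    shape = stacks[0].shape
    for f in stacks:
        if f.shape != shape:
            raise ValueError("background frames have mismatched geometry")
    mean_bg = np.mean(stacks, axis=0)
    out = []
    for f in after_frames:
        a = np.asarray(f, dtype=np.float64)
        if a.shape != shape:
            raise ValueError("post-injection frame geometry does not match background")
        corrected = a - mean_bg
        out.append(np.clip(corrected, 0.0, None) if clip else corrected)
    return out


def decibel_change(i_after: float, i_before: float) -> float:
    """Decibel change 10*log10(i_after / i_before).

    Positive iff the post-injection intensity exceeds baseline.  A zero
    baseline is undefined (error); a zero post-injection intensity returns
    ``-inf`` with a warning.
    """
    if i_before <= 0:
        raise ValueError("decibel change undefined for non-positive baseline intensity")
    if i_after < 0:
        raise ValueError("post-injection intensity must be >= 0")
    if i_after == 0:
        warnings.warn("zero post-injection intensity: reporting -inf dB", stacklevel=2)
        return float("-inf")
    return 10.0 * np.log10(i_after / i_before)


def measure_well(
    well_id: int,
    roi: WellROI,
    before_frames: Sequence[np.ndarray],
    after_frames: Sequence[np.ndarray],
    corrected_frames: Optional[Sequence[np.ndarray]] = None,
) -> WellMeasurement:
    """Measure one well across replicate before/after frames.

    ``i_before``/``i_after`` are ROI means averaged over frames; the
    background-corrected mean is reported alongside, and the decibel change
    uses the raw after/before ratio.
    """
    i_before = float(np.mean([mean_roi_intensity(f, roi) for f in before_frames]))
    i_after = float(np.mean([mean_roi_intensity(f, roi) for f in after_frames]))
    if corrected_frames is None:
        corrected_frames = subtract_mean_background(after_frames, before_frames)
    i_corr = float(np.mean([mean_roi_intensity(f, roi) for f in corrected_frames]))
    return WellMeasurement(
        well_id=well_id,
        i_before=i_before,
        i_after=i_after,
        i_after_bg_subtracted=i_corr,
        delta_db=decibel_change(i_after, i_before),
    )


def summarize_wells(measurements: Sequence[WellMeasurement]) -> WellPanelSummary:
    """Panel summary across replicate wells.

    The panel decibel change divides the mean 'after' intensity by the
    mean 'before' intensity (panel means, not averaged per-well dBs).
    """
    if len(measurements) < 1:
        raise ValueError("need at least one well measurement")
    after = np.array([m.i_after for m in measurements], dtype=np.float64)
    before = np.array([m.i_before for m in measurements], dtype=np.float64)
    if len(measurements) == 1:
        warnings.warn("single well: SD is undefined, reporting 0", stacklevel=2)
        sd_after = 0.0
    else:
        sd_after = float(after.std(ddof=1))
    return WellPanelSummary(
        n_wells=len(measurements),
        mean_i_before=float(before.mean()),
        mean_i_after=float(after.mean()),
        sd_i_after=sd_after,
        mean_delta_db=decibel_change(float(after.mean()), float(before.mean())),
    )
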