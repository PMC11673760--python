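"""Synthetic micrograph and B-mode frame generation with exact ground truth.

No public image set exists for micron-scale bubble sizing with known truth,
so every downstream stage is validated on frames rendered here: brightfield
fields of dark-ringed bubbles or solid dark calibration beads on a noisy,
unevenly illuminated background (including touching aggregates and
out-of-focus objects), and speckled B-mode frames containing circular wells
whose mean intensity is lifted by a known amount over background.

The generator is a statistical stand-in, not an optics or acoustics model:
object edges are error-function profiles with ~1 px softness rather than a
diffraction PSF, and speckle is a smoothed multiplicative Rayleigh field
rather than beamformed echo data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import erfc

from .frames import ImageFrame

__all__ = [
    "BrightfieldSpec",
    "BModeSpec",
    "GroundTruth",
    "render_brightfield",
    "render_bead_field",
    "render_bmode_wells",
]

# in-focus edge softness: bubbles have a ~1 px soft lipid-shell rim; solid
# polystyrene beads are sharp to within pixel antialiasing
_EDGE_SOFTNESS_PX = {"bubble": 1.0, "bead": 0.5}
_DEFOCUS_SOFTNESS_PX = 2.5   # out-of-focus edge softness
_DEFOCUS_DEPTH = 0.8         # defocused objects fade but must stay countable
_RIM_DEPTH = 0.55            # fractional darkening of the bubble rim
_CORE_LIFT = 0.10            # fractional brightening of the bubble core
_BEAD_DEPTH = 0.60           # fractional darkening of a solid bead


@dataclass
class BrightfieldSpec:
    """Conditions of a simulated brightfield acquisition.

    Defaults mirror single-plane imaging of a dilute bubble suspension in a
    10 um-tall chamber at 40x magnification; pixel size and field of view
    have no canonical value and are freely configurable.
    """

    field_of_view_px: Tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.16
    chamber_height_um: float = 10.0
    radii_distribution: Tuple = ("fixed", 1.5)  # or ("lognormal", mu, sigma) of ln(r/um)
    target_count_per_image: float = 50.0
    aggregate_fraction: float = 0.0
    defocus_fraction: float = 0.0
    noise_sd: float = 300.0  # additive Gaussian, 16-bit intensity units
    illumination_gradient: float = 0.0  # max fractional shading across the frame
    background_level: float = 45000.0
    style: str = "bubble"  # "bubble" = dark rim + bright core; "bead" = solid dark disk
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("aggregate_fraction", "defocus_fraction", "illumination_gradient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.chamber_height_um <= 0:
            raise ValueError("chamber_height_um must be positive")
        if self.target_count_per_image < 0:
            raise ValueError("target_count_per_image must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.style not in ("bubble", "bead"):
            raise ValueError(f"style must be 'bubble' or 'bead', got {self.style!r}")
        kind = self.radii_distribution[0]
        if kind == "fixed":
            if self.radii_distribution[1] <= 0:
                raise ValueError("fixed radius must be positive")
        elif kind == "lognormal":
            if self.radii_distribution[2] <= 0:
                raise ValueError("lognormal sigma must be positive")
        else:
            raise ValueError(f"unknown radii distribution {kind!r}")


@dataclass
class BModeSpec:
    """Conditions of a simulated multi-well B-mode acquisition.

    Intensities (``background_mean``, ``well_intensity_lift``) are on the
    8-bit greyscale scale the analysis operates on; frames are stored as
    16-bit with a fixed x257 mapping, matching acquisition systems that
    save 16-bit files later converted to 8-bit.
    """

    frame_px: Tuple[int, int] = (512, 1024)
    pixel_pitch_mm: float = 0.05
    well_diameter_mm: float = 8.0
    well_centers: Sequence[Tuple[int, int]] = ((256, 512),)
    background_mean: float = 40.0
    speckle_scale: float = 0.2  # relative SD of the multiplicative speckle field
    well_intensity_lift: float = 30.0  # additive mean greyscale increase inside wells
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0 or self.well_diameter_mm <= 0:
            raise ValueError("pixel_pitch_mm and well_diameter_mm must be positive")
        if self.background_mean < 0:
            raise ValueError("background_mean must be >= 0")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        r = self.well_radius_px
        rows, cols = self.frame_px
        for cr, cc in self.well_centers:
            if cr - r < 0 or cr + r >= rows or cc - r < 0 or cc + r >= cols:
                raise ValueError(f"well at ({cr}, {cc}) does not fit inside the frame")
        centers = list(self.well_centers)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                if d < 2 * r:
                    raise ValueError(f"wells {i} and {j} overlap (separation {d:.1f} px)")

    @property
    def well_radius_px(self) -> float:
        return 0.5 * self.well_diameter_mm / self.pixel_pitch_mm


@dataclass
class GroundTruth:
    """Exact bookkeeping for a rendered frame.

    ``objects`` holds one row per rendered particle (center in px, radius
    in um, aggregate/defocus flags); ``label_mask`` is the noiseless
    footprint labeling (label i+1 = row i).  For B-mode frames ``wells``
    holds one row per well and ``well_masks`` the corresponding ROI masks.
    """

    objects: Optional[pd.DataFrame] = None
    label_mask: Optional[np.ndarray] = None
    wells: Optional[pd.DataFrame] = None
    well_masks: Optional[List[np.ndarray]] = None
    seed: Optional[int] = None

    @property
    def n_objects(self) -> int:
        return 0 if self.objects is None else len(self.objects)


# ---------------------------------------------------------------------------
# brightfield
# ---------------------------------------------------------------------------

def _soft_disk(rho: np.ndarray, radius_px: float, softness_px: float) -> np.ndarray:
    """Radial error-function step: ~1 inside ``radius_px``, ~0 outside."""
    return 0.5 * erfc((rho - radius_px) / (np.sqrt(2.0) * softness_px))


def _draw_radii(spec: BrightfieldSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.radii_distribution[0]
    if kind == "fixed":
        return np.full(n, float(spec.radii_distribution[1]))
    mu, sigma = spec.radii_distribution[1], spec.radii_distribution[2]
    return rng.lognormal(mu, sigma, size=n)


def _place_objects(spec: BrightfieldSpec, rng: np.random.Generator):
    """Sample object centers/radii with rejection so that only deliberate
    aggregate partners touch. Returns a list of dicts."""
    rows, cols = spec.field_of_view_px
    n_total = int(rng.poisson(spec.target_count_per_image))
    if n_total == 0:
        return []
    radii_um = _draw_radii(spec, n_total, rng)
    radii_px = radii_um / spec.pixel_size_um
    half_frame_px = min(rows, cols) / 2.0
    if np.any(radii_px > half_frame_px):
        raise ValueError(
            f"object radius {radii_um.max():.3g} um exceeds half the frame "
            f"({half_frame_px * spec.pixel_size_um:.3g} um); enlarge the field of view"
        )
    if np.any(radii_px < 2.0):
        warnings.warn(
            "objects of ~1 px radius are at the resolution limit; "
            "sizing will be dominated by pixelation",
            stacklevel=3,
        )

    n_agg = int(round(spec.aggregate_fraction * n_total))
    n_agg -= n_agg % 2  # aggregates come in pairs
    n_defocus = int(round(spec.defocus_fraction * n_total))

    placed: list = []

    def far_enough(r, c, rad, skip=None):
        for k, obj in enumerate(placed):
            if skip is not None and k == skip:
                continue
            if np.hypot(r - obj["row"], c - obj["col"]) < rad + obj["r_px"] + 6.0:
                return False
        return True

    def sample_center(rad):
        margin = rad + 8.0
        if rows - 2 * margin <= 1 or cols - 2 * margin <= 1:
            raise ValueError("object too large for the frame margins")
        for _ in range(2000):
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if far_enough(r, c, rad):
                return r, c
        raise ValueError("could not place objects without contact; lower the density")

    i = 0
    # aggregate pairs first: anchor placed freely, partner at a touching
    # distance 1.2-1.8 x the mean of the two radii
    while i < n_agg:
        r1, r2 = radii_px[i], radii_px[i + 1]
        ar, ac = sample_center(r1 + r2)  # reserve room for the partner
        placed.append({"row": ar, "col": ac, "r_px": r1, "r_um": radii_um[i], "agg": True})
        anchor_idx = len(placed) - 1
        for _ in range(2000):
            d = rng.uniform(1.2, 1.8) * (r1 + r2) / 2.0
            theta = rng.uniform(0, 2 * np.pi)
            pr, pc = ar + d * np.sin(theta), ac + d * np.cos(theta)
            m = r2 + 8.0
            if not (m <= pr <= rows - m and m <= pc <= cols - m):
                continue
            if far_enough(pr, pc, r2, skip=anchor_idx):
                break
        else:
            raise ValueError("could not place an aggregate partner; lower the density")
        placed.append({"row": pr, "col": pc, "r_px": r2, "r_um": radii_um[i + 1], "agg": True})
        i += 2
    while i < n_total:
        r, c = sample_center(radii_px[i])
        placed.append({"row": r, "col": c, "r_px": radii_px[i], "r_um": radii_um[i], "agg": False})
        i += 1

    defocus_idx = set(rng.choice(n_total, size=min(n_defocus, n_total), replace=False).tolist())
    for k, obj in enumerate(placed):
        obj["defocused"] = k in defocus_idx
    return placed


def _paint_object(mult: np.ndarray, label_mask: np.ndarray, obj: dict, label: int, style: str) -> None:
    rows, cols = mult.shape
    r_px = obj["r_px"]
    s = _DEFOCUS_SOFTNESS_PX if obj["defocused"] else _EDGE_SOFTNESS_PX[style]
    pad = int(np.ceil(r_px + 5 * s + 2))
    r0, r1 = max(0, int(obj["row"]) - pad), min(rows, int(obj["row"]) + pad + 1)
    c0, c1 = max(0, int(obj["col"]) - pad), min(cols, int(obj["col"]) + pad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    rho = np.hypot(yy - obj["row"], xx - obj["col"])
    depth_scale = _DEFOCUS_DEPTH if obj["defocused"] else 1.0
    if style == "bead":
        profile = -_BEAD_DEPTH * depth_scale * _soft_disk(rho, r_px, s)
    else:
        rim_w = max(2.5, 0.3 * r_px)
        outer = _soft_disk(rho, r_px, s)
        core = _soft_disk(rho, max(r_px - rim_w, 0.5), s)
        rim = np.clip(outer - core, 0.0, 1.0)
        profile = _CORE_LIFT * depth_scale * core - _RIM_DEPTH * depth_scale * rim
    mult[r0:r1, c0:c1] += profile
    footprint = rho <= r_px
    region = label_mask[r0:r1, c0:c1]
    region[footprint & (region == 0)] = label


def render_brightfield(spec: BrightfieldSpec) -> Tuple[ImageFrame, GroundTruth]:
    """Render one 16-bit brightfield frame plus its exact ground truth.

    Object count is Poisson-distributed around ``target_count_per_image``;
    bubbles are drawn as a dark annulus with a slightly brighter interior
    on the local background, beads (``style='bead'``) as solid dark disks.
    With ``noise_sd=0`` and the same seed the output is bit-identical
    across calls.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.field_of_view_px
    placed = _place_objects(spec, rng)

    # multiplicative shading: background level times (1 - gradient ramp)
    uu = (np.arange(cols, dtype=np.float64) / max(cols - 1, 1))[None, :]
    vv = (np.arange(rows, dtype=np.float64) / max(rows - 1, 1))[:, None]
    ramp = 0.5 * (uu + vv)  # diagonal ramp in [0, 1]
    background = spec.background_level * (1.0 - spec.illumination_gradient * ramp)

    mult = np.ones((rows, cols), dtype=np.float64)
    label_mask = np.zeros((rows, cols), dtype=np.int32)
    for k, obj in enumerate(placed):
        _paint_object(mult, label_mask, obj, k + 1, spec.style)
    img = background * np.clip(mult, 0.0, 2.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    objects = pd.DataFrame(
        {
            "center_row_px": [o["row"] for o in placed],
            "center_col_px": [o["col"] for o in placed],
            "radius_um": [o["r_um"] for o in placed],
            "is_aggregate": [o["agg"] for o in placed],
            "is_defocused": [o["defocused"] for o in placed],
        }
    )
    frame = ImageFrame(img, bit_depth=16, pixel_size_um=spec.pixel_size_um)
    return frame, GroundTruth(objects=objects, label_mask=label_mask, seed=spec.seed)


def render_bead_field(radius_um: float, **overrides) -> Tuple[ImageFrame, GroundTruth]:
    """Render a monodisperse field of solid dark disks (calibration beads).

    ``radius_um`` is the true bead radius; 0.5 and 1.5 um reproduce the
    1 um- and 3 um-diameter polystyrene size standards.  Keyword overrides
    are forwarded to :class:`BrightfieldSpec`.
    """
    if radius_um <= 0:
        raise ValueError("bead radius must be positive")
    overrides.pop("radii_distribution", None)
    overrides.pop("style", None)
    spec = BrightfieldSpec(
        radii_distribution=("fixed", float(radius_um)), style="bead", **overrides
    )
    return render_brightfield(spec)


# ---------------------------------------------------------------------------
# B-mode
# ---------------------------------------------------------------------------

def render_bmode_wells(spec: BModeSpec) -> Tuple[ImageFrame, GroundTruth]:
    """Render one 16-bit B-mode frame of circular wells on speckle.

    The background is a multiplicative speckle field (smoothed Rayleigh
    noise rescaled to mean 1 and relative SD ``speckle_scale``) around
    ``background_mean``; inside each well disk the mean is raised by
    ``well_intensity_lift``.  With ``speckle_scale=0`` the ROI mean equals
    ``background_mean + lift`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.frame_px
    r_px = spec.well_radius_px

    base = np.full((rows, cols), float(spec.background_mean))
    yy, xx = np.mgrid[0:rows, 0:cols]
    masks: List[np.ndarray] = []
    for cr, cc in spec.well_centers:
        m = np.hypot(yy - cr, xx - cc) <= r_px
        base[m] += spec.well_intensity_lift
        masks.append(m)

    if spec.speckle_scale > 0:
        raw = rng.rayleigh(scale=1.0, size=(rows, cols))
        smooth = ndi.gaussian_filter(raw, 1.0)
        field = 1.0 + spec.speckle_scale * (smooth - smooth.mean()) / smooth.std()
        img = base * np.clip(field, 0.0, None)
    else:
        img = base
    img16 = np.clip(np.rint(img * 257.0), 0, 65535).astype(np.uint16)

    wells = pd.DataFrame(
        {
            "center_row_px": [c[0] for c in spec.well_centers],
            "center_col_px": [c[1] for c in spec.well_centers],
            "radius_px": r_px,
            "true_lift": float(spec.well_intensity_lift),
        }
    )
    frame = ImageFrame(img16, bit_depth=16)
    return frame, GroundTruth(wells=wells, well_masks=masks, seed=spec.seed)
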