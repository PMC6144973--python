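"""Maculation segmentation and the per-egg trait report.

Spots are the dark pigmented blotches on the shell.  Segmentation is a
local-mean adaptive threshold restricted to the egg's region of interest:
a pixel is a spot candidate when its across-band VIS reflectance lies at
least ``offset_pp`` percentage points below the local RoI mean within a
``window_px`` square window.  Candidates are cleaned by a morphological
opening, connected with 8-connectivity, and components smaller than
``min_spot_px`` are discarded.

The report carries the seven per-egg trait variables used downstream:
spot number, mean spot size (mm^2), spottiness (% of RoI area), and mean
background/spot reflectance in the VIS (across-band mean of R, G, B) and
in the UV (the UV image's red band).  A spotless egg reports NaN for the
spot reflectances and size — the missing-value sentinel, written as a
blank CSV field, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from ovoscope.radiometry import ReflectanceImage, polygon_mask

__all__ = [
    "SpotMask",
    "SpotReport",
    "SegmentationParams",
    "DegenerateBackgroundError",
    "segment_spots",
    "summarize",
    "trait_vector",
    "TRAIT_ORDER",
]

#: trait order of the report vector and of the PCA variable listing
TRAIT_ORDER = (
    "spot_number",
    "spot_size",
    "spottiness",
    "b_vis",
    "s_vis",
    "b_uv",
    "s_uv",
)


class DegenerateBackgroundError(ValueError):
    """The RoI is entirely covered by spots; no background remains."""


@dataclass
class SegmentationParams:
    window_px: int = 31
    offset_pp: float = 5.0
    min_spot_px: int = 9

    def __post_init__(self) -> None:
        if self.window_px <= 0 or self.offset_pp <= 0 or self.min_spot_px <= 0:
            raise ValueError("segmentation parameters must be positive")


@dataclass
class SpotMask:
    """Labeled spot segmentation in a stated image frame."""

    mask: np.ndarray  # bool (H, W)
    labels: np.ndarray  # int (H, W), 0 = background, 1..n_spots
    areas_px: np.ndarray  # (n_spots,)
    frame: str = "VIS"

    @property
    def n_spots(self) -> int:
        return len(self.areas_px)


@dataclass
class SpotReport:
    egg_id: str
    spot_number: int
    spot_size: float  # mean spot size, mm^2 (NaN when spotless)
    spottiness: float  # % of RoI area covered by spots
    b_vis: float  # across-band mean background reflectance, %
    s_vis: float
    b_uv: float
    s_uv: float
    per_band_background: dict[str, float] = field(default_factory=dict)
    per_band_spot: dict[str, float] = field(default_factory=dict)
    roi_area_px: int = 0
    spot_area_px: int = 0
    mm_per_px: float = float("nan")
    frame: str = "VIS"


def _masked_local_mean(
    img: np.ndarray, mask: np.ndarray, window_px: int
) -> np.ndarray:
    """Mean of ``img`` over ``mask`` pixels within a square window."""
    size = int(window_px) | 1  # odd window
    vals = ndimage.uniform_filter(np.where(mask, img, 0.0), size=size)
    frac = ndimage.uniform_filter(mask.astype(float), size=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(frac > 0, vals / frac, np.nan)


def segment_spots(
    refl_vis: ReflectanceImage,
    roi: np.ndarray,
    params: SegmentationParams | None = None,
) -> SpotMask:
    """Adaptive-threshold spot segmentation inside the RoI."""
    params = params or SegmentationParams()
    h, w = refl_vis.shape
    poly = np.asarray(roi, dtype=float)
    if (
        poly[:, 0].min() < -0.5
        or poly[:, 1].min() < -0.5
        or poly[:, 0].max() > w - 0.5
        or poly[:, 1].max() > h - 0.5
    ):
        raise ValueError("RoI extends outside the image")
    roi_mask = polygon_mask(poly, (h, w))
    if roi_mask.sum() < 100:
        raise ValueError("RoI area must be at least 100 px")

    bands = [b for b in refl_vis.bands if b in ("R", "G", "B")]
    img = np.mean([refl_vis.band(b) for b in bands], axis=0)
    local = _masked_local_mean(img, roi_mask & ~refl_vis.flagged,
                               params.window_px)
    cand = roi_mask & (img < local - params.offset_pp)
    cand = morphology.opening(cand, morphology.disk(1))
    cand &= roi_mask
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    if n:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas >= params.min_spot_px) + 1
        relabel = np.zeros(n + 1, dtype=int)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
        areas = areas[keep - 1]
    else:
        areas = np.zeros(0, dtype=int)
    return SpotMask(
        mask=labels > 0, labels=labels, areas_px=areas, frame="VIS"
    )


def summarize(
    refl_vis: ReflectanceImage,
    refl_uv: ReflectanceImage | None,
    mask: SpotMask | np.ndarray,
    roi: np.ndarray,
    mm_per_px: float,
    egg_id: str = "",
) -> SpotReport:
    """Compute the seven trait variables from a segmentation.

    Background reflectance is measured over RoI minus spots, spot
    reflectance over the spots; VIS values are the unweighted mean of the
    R, G, B band means, UV uses the single band of ``refl_uv`` (already
    aligned to the VIS frame here; the misregistered case goes through
    :mod:`ovoscope.uvalign` instead and its values are merged by the
    caller).
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    spot_mask = mask.mask if isinstance(mask, SpotMask) else np.asarray(mask,
                                                                        bool)
    roi_mask = polygon_mask(np.asarray(roi, dtype=float), refl_vis.shape)
    spot_mask = spot_mask & roi_mask
    bg_mask = roi_mask & ~spot_mask
    if not bg_mask.any():
        raise DegenerateBackgroundError(
            "RoI fully covered by spots; no background left"
        )

    if isinstance(mask, SpotMask):
        n_spots = mask.n_spots
        areas = mask.areas_px
    else:
        lab, n_spots = ndimage.label(spot_mask,
                                     structure=np.ones((3, 3), dtype=int))
        areas = np.bincount(lab.ravel())[1:] if n_spots else np.zeros(0, int)

    vis_bands = [b for b in refl_vis.bands if b in ("R", "G", "B")]
    per_band_bg = {b: refl_vis.band_mean(b, bg_mask) for b in vis_bands}
    b_vis = float(np.mean(list(per_band_bg.values())))
    if n_spots:
        per_band_s = {b: refl_vis.band_mean(b, spot_mask) for b in vis_bands}
        s_vis = float(np.mean(list(per_band_s.values())))
        spot_size = float(areas.mean()) * mm_per_px**2
    else:
        per_band_s = {b: float("nan") for b in vis_bands}
        s_vis = float("nan")
        spot_size = float("nan")

    b_uv = s_uv = float("nan")
    if refl_uv is not None:
        uv_band = refl_uv.bands[0]
        b_uv = refl_uv.band_mean(uv_band, bg_mask)
        if n_spots:
            s_uv = refl_uv.band_mean(uv_band, spot_mask)

    roi_area = int(roi_mask.sum())
    spot_area = int(spot_mask.sum())
    return SpotReport(
        egg_id=egg_id,
        spot_number=int(n_spots),
        spot_size=spot_size,
        spottiness=100.0 * spot_area / roi_area,
        b_vis=b_vis,
        s_vis=s_vis,
        b_uv=b_uv,
        s_uv=s_uv,
        per_band_background=per_band_bg,
        per_band_spot=per_band_s,
        roi_area_px=roi_area,
        spot_area_px=spot_area,
        mm_per_px=float(mm_per_px),
        frame="VIS",
    )


def trait_vector(report: SpotReport) -> np.ndarray:
    """The ordered 7-trait vector (see :data:`TRAIT_ORDER`).

    NaN marks the spot reflectances and size of a spotless egg; a report
    claiming spots but missing their reflectance is inconsistent.
    """
    vals = np.array([getattr(report, k) for k in TRAIT_ORDER], dtype=float)
    if report.spot_number > 0 and np.isnan(
        [report.spot_size, report.s_vis]
    ).any():
        raise ValueError("spot fields missing although spot_number > 0")
    return vals
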