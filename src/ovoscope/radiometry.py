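"""Linearization and grey-standard normalization of raw egg photographs.

Raw camera counts are first linearized with respect to scene radiance
(gamma exponent or monotone lookup curve), then each band is scaled so that
the mean of a grey reflectance standard of known nominal reflectance
(a Spectralon panel, 40% here) equals that nominal value.  The result is a
per-band percent-reflectance image, the common currency of the image stage.

Coordinate convention for all polygons and points: pixel coordinates with
origin at the top-left corner, x rightward (columns), y downward (rows),
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "RawImage",
    "ReflectanceImage",
    "CalibrationError",
    "linearize",
    "to_reflectance",
    "polygon_mask",
]

#: raw counts within this fraction of full scale are treated as saturated
SATURATION_FRACTION = 0.99


class CalibrationError(ValueError):
    """Raised when the grey standard cannot be used for normalization."""


@dataclass
class RawImage:
    """Camera counts, either linear or through the camera response.

    pixels has shape (H, W) for a single band or (H, W, B); bands labels
    the last axis ("R", "G", "B" or "UV").
    """

    pixels: np.ndarray
    bands: tuple[str, ...]
    bit_depth: int = 16
    #: True where the *original* counts were within 1% of full scale
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.bands = tuple(self.bands)
        if len(set(self.bands)) != len(self.bands):
            raise ValueError("band labels must be unique")
        n_bands = 1 if self.pixels.ndim == 2 else self.pixels.shape[2]
        if n_bands != len(self.bands):
            raise ValueError(
                f"{len(self.bands)} band labels for {n_bands}-band image"
            )
        if np.nanmin(self.pixels) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    def band(self, label: str) -> np.ndarray:
        if self.pixels.ndim == 2:
            if label != self.bands[0]:
                raise KeyError(label)
            return self.pixels
        return self.pixels[..., self.bands.index(label)]


@dataclass
class ReflectanceImage:
    """Per-band percent reflectance with calibration provenance.

    ``standard_counts`` records the per-band mean linear count of the grey
    standard used for the normalization.  ``flagged`` marks pixels that are
    saturated in the raw data or exceed 100% reflectance (specular
    highlights); downstream means should exclude them.
    """

    pixels: np.ndarray
    bands: tuple[str, ...]
    standard_counts: dict[str, float]
    standard_value: float
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.bands = tuple(self.bands)
        if self.flagged is None:
            self.flagged = np.zeros(self.pixels.shape[:2], dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, label: str) -> np.ndarray:
        if self.pixels.ndim == 2:
            if label != self.bands[0]:
                raise KeyError(label)
            return self.pixels
        return self.pixels[..., self.bands.index(label)]

    def band_mean(self, label: str, mask: np.ndarray) -> float:
        """Mean reflectance of one band over ``mask``, excluding flagged
        pixels; NaN if nothing usable remains."""
        use = mask & ~self.flagged
        if not use.any():
            return float("nan")
        return float(self.band(label)[use].mean())


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed (x, y) polygon into a boolean (H, W) mask."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (N>=3, 2) array of (x, y)")
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, poly[:, ::-1])


def linearize(
    raw: RawImage, response: float | tuple[np.ndarray, np.ndarray]
) -> RawImage:
    """Undo the camera response so counts become proportional to radiance.

    Parameters
    ----------
    raw
        Image in camera counts.
    response
        Either a gamma exponent g (the camera is modelled as
        counts = radiance**(1/g), so linearization raises normalized counts
        to the power g), or a lookup curve ``(counts, radiance)`` of
        strictly increasing samples interpolated linearly.

    Returns
    -------
    RawImage
        Float image proportional to radiance, with the saturation mask
        (counts within 1% of full scale) recorded.
    """
    c = raw.pixels.astype(float)
    sat = c >= SATURATION_FRACTION * raw.full_scale
    if sat.ndim == 3:
        sat = sat.any(axis=2)
    if np.isscalar(response):
        gamma = float(response)  # type: ignore[arg-type]
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        linear = (c / raw.full_scale) ** gamma
    else:
        counts, radiance = (np.asarray(a, dtype=float) for a in response)
        if counts.shape != radiance.shape or counts.ndim != 1:
            raise ValueError("lookup curve must be two equal 1-D arrays")
        if np.any(np.diff(counts) <= 0) or np.any(np.diff(radiance) <= 0):
            raise ValueError("lookup curve must be strictly increasing")
        linear = np.interp(c, counts, radiance)
    out = RawImage(linear, raw.bands, raw.bit_depth, saturated=sat)
    return out


def to_reflectance(
    linear: RawImage,
    standard_roi: np.ndarray,
    standard_value: float = 40.0,
) -> ReflectanceImage:
    """Normalize a linear image to percent reflectance via the grey standard.

    Each band is scaled independently so that the mean of the standard
    patch equals ``standard_value`` (percent).  Saturated pixels are
    excluded from the patch mean; a fully saturated or zero patch raises
    :class:`CalibrationError`.  Reflectance above 100% is flagged, never
    clipped.
    """
    if not 0 < standard_value <= 100:
        raise ValueError("standard_value must be in (0, 100]")
    mask = polygon_mask(standard_roi, linear.pixels.shape[:2])
    if not mask.any():
        raise CalibrationError("standard patch is degenerate or outside image")
    sat = (
        linear.saturated
        if linear.saturated is not None
        else np.zeros(mask.shape, bool)
    )
    usable = mask & ~sat
    if not usable.any():
        raise CalibrationError("standard patch fully saturated")

    pix = linear.pixels.astype(float)
    if pix.ndim == 2:
        pix = pix[:, :, None]
    means = pix[usable].mean(axis=0)
    if np.any(means <= 0):
        bad = [b for b, m in zip(linear.bands, means) if m <= 0]
        raise CalibrationError(f"zero standard-patch signal in bands {bad}")

    refl = pix / means[None, None, :] * standard_value
    if linear.pixels.ndim == 2:
        refl = refl[..., 0]
    flagged = sat.copy()
    over = refl > 100.0
    if over.ndim == 3:
        over = over.any(axis=2)
    flagged |= over
    return ReflectanceImage(
        refl,
        linear.bands,
        standard_counts={b: float(m) for b, m in zip(linear.bands, means)},
        standard_value=float(standard_value),
        flagged=flagged,
    )
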