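"""VIS->UV registration by the Local Weighted Mean (LWM) method.

The VIS and UV photographs of an egg are taken a moment apart and are not
coincident; the misregistration varies across the frame.  Following
Goshtasby's local weighted mean construction, the mapping is a blend of
local second-order polynomials: one polynomial per control point, fitted by
least squares to that point's ``k_neighbors`` nearest control points under
the constraint that it passes exactly through its own point pair.  The
blend weight of polynomial i at an evaluation location p decreases
radially and vanishes at the point's influence radius (the distance to its
(k-1)-th nearest control neighbor), and diverges as p approaches control
point i, which makes the transform exactly interpolating.  Quadratic local
models contain every first-order map, so data generated by a global affine
transformation are reproduced exactly.

At least 13 control-point pairs are required, matching the minimum the
manual-marking protocol prescribes; fitting refuses below that.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ovoscope.radiometry import ReflectanceImage

__all__ = [
    "ControlPointSet",
    "LWMTransform",
    "RegistrationError",
    "fit_lwm",
    "warp_mask",
    "uv_measure",
    "MIN_CONTROL_POINTS",
]

MIN_CONTROL_POINTS = 13


class RegistrationError(ValueError):
    pass


@dataclass
class ControlPointSet:
    """Paired (x, y) coordinates in the VIS and UV frames, pixels."""

    vis: np.ndarray
    uv: np.ndarray

    def __post_init__(self) -> None:
        self.vis = np.atleast_2d(np.asarray(self.vis, dtype=float))
        self.uv = np.atleast_2d(np.asarray(self.uv, dtype=float))
        if self.vis.shape != self.uv.shape or self.vis.shape[1] != 2:
            raise ValueError("vis and uv must be matching (n, 2) arrays")
        d = np.linalg.norm(
            self.vis[:, None, :] - self.vis[None, :, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise ValueError("duplicated VIS control points")

    def __len__(self) -> int:
        return len(self.vis)

    def swapped(self) -> "ControlPointSet":
        return ControlPointSet(self.uv.copy(), self.vis.copy())


def _quad_basis(dp: np.ndarray) -> np.ndarray:
    """Second-order bivariate basis vanishing at dp = 0 (the constrained
    polynomial is anchored at its own control point)."""
    dx, dy = dp[:, 0], dp[:, 1]
    return np.column_stack([dx, dy, dx * dx, dx * dy, dy * dy])


@dataclass
class LWMTransform:
    """Interpolating space-variant map built from local quadratics."""

    source: np.ndarray  # (n, 2) control points in the source frame
    target: np.ndarray  # (n, 2) their partners
    coeffs: np.ndarray  # (n, 5, 2) constrained-quadratic coefficients
    radii: np.ndarray  # (n,) influence radii
    k_neighbors: int
    #: filled lazily with the reverse-direction fit for inverse mapping
    _inverse: "LWMTransform | None" = field(default=None, repr=False)

    def _local_values(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate every local polynomial and its blend weight at points p.

        Returns (values (m, n, 2), weights (m, n))."""
        dp = p[:, None, :] - self.source[None, :, :]  # (m, n, 2)
        m, n = dp.shape[:2]
        phi = np.stack(
            [
                dp[..., 0],
                dp[..., 1],
                dp[..., 0] ** 2,
                dp[..., 0] * dp[..., 1],
                dp[..., 1] ** 2,
            ],
            axis=-1,
        )  # (m, n, 5)
        values = self.target[None, :, :] + np.einsum(
            "mnk,nkd->mnd", phi, self.coeffs
        )
        dist = np.linalg.norm(dp, axis=2)  # (m, n)
        t = dist / self.radii[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(t < 1.0, (1.0 - t) ** 2 / np.maximum(t, 1e-300) ** 2,
                         0.0)
        return values, w

    def __call__(self, points: np.ndarray, chunk: int = 4096) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty_like(p)
        for lo in range(0, len(p), chunk):
            sl = slice(lo, min(lo + chunk, len(p)))
            out[sl] = self._evaluate(p[sl])
        return out

    def _evaluate(self, p: np.ndarray) -> np.ndarray:
        values, w = self._local_values(p)
        wsum = w.sum(axis=1)
        out = np.empty((len(p), 2))
        covered = wsum > 0
        if covered.any():
            # rows exactly on a control point have infinite weight and are
            # overwritten by the interpolation override below
            with np.errstate(invalid="ignore"):
                out[covered] = (
                    np.einsum("mn,mnd->md", w[covered], values[covered])
                    / wsum[covered, None]
                )
        if (~covered).any():
            # outside every kernel: fall back to the nearest point's local
            # polynomial (extrapolation; logged once per call)
            dist = np.linalg.norm(
                p[~covered][:, None, :] - self.source[None, :, :], axis=2
            )
            nearest = dist.argmin(axis=1)
            out[~covered] = values[~covered, nearest]
            warnings.warn(
                f"{(~covered).sum()} locations outside all LWM kernels; "
                "used nearest local polynomial",
                stacklevel=3,
            )
        # exact interpolation at (numerically coincident) control points
        dmin = np.linalg.norm(
            p[:, None, :] - self.source[None, :, :], axis=2
        )
        hit_j = dmin.argmin(axis=1)
        hit = dmin[np.arange(len(p)), hit_j] < 1e-9
        out[hit] = self.target[hit_j[hit]]
        return out

    def weights_at(self, points: np.ndarray) -> np.ndarray:
        """Normalized blend weights (rows sum to 1 where covered)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        _, w = self._local_values(p)
        s = w.sum(axis=1, keepdims=True)
        return np.divide(w, s, out=np.zeros_like(w), where=s > 0)

    def inverse(self) -> "LWMTransform":
        if self._inverse is None:
            self._inverse = fit_lwm(
                ControlPointSet(self.target, self.source), self.k_neighbors
            )
        return self._inverse

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": "local_weighted_mean",
                "k_neighbors": self.k_neighbors,
                "source": self.source.tolist(),
                "target": self.target.tolist(),
                "coeffs": self.coeffs.tolist(),
                "radii": self.radii.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LWMTransform":
        d = json.loads(text)
        return cls(
            source=np.asarray(d["source"], dtype=float),
            target=np.asarray(d["target"], dtype=float),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            radii=np.asarray(d["radii"], dtype=float),
            k_neighbors=int(d["k_neighbors"]),
        )


def fit_lwm(
    points: ControlPointSet | tuple[np.ndarray, np.ndarray],
    k_neighbors: int = 12,
) -> LWMTransform:
    """Fit the LWM transform from >= 13 control-point pairs.

    Each control point's quadratic is anchored through its own pair and
    least-squares fitted to its neighborhood; a neighborhood too close to
    collinear to determine the quadratic raises a singular-fit error
    naming the offending point.
    """
    if not isinstance(points, ControlPointSet):
        points = ControlPointSet(*points)
    n = len(points)
    if n < MIN_CONTROL_POINTS:
        raise RegistrationError(
            f"need at least {MIN_CONTROL_POINTS} control points, got {n}"
        )
    k = min(k_neighbors, n)
    tree = cKDTree(points.vis)
    coeffs = np.zeros((n, 5, 2))
    radii = np.zeros(n)
    for i in range(n):
        dist, idx = tree.query(points.vis[i], k=k)
        radii[i] = dist[-1]  # distance to the (k-1)-th nearest neighbor
        nb = idx[idx != i]
        dp = points.vis[nb] - points.vis[i]
        dq = points.uv[nb] - points.uv[i]
        A = _quad_basis(dp)
        sol, _, rank, _ = np.linalg.lstsq(A, dq, rcond=None)
        if rank < 5:
            raise RegistrationError(
                f"degenerate neighborhood around control point {i} at "
                f"{tuple(points.vis[i])}: local quadratic is singular"
            )
        coeffs[i] = sol
    return LWMTransform(
        source=points.vis.copy(),
        target=points.uv.copy(),
        coeffs=coeffs,
        radii=radii,
        k_neighbors=k,
    )


def warp_mask(
    mask: np.ndarray,
    transform: LWMTransform,
    uv_shape: tuple[int, int],
) -> np.ndarray:
    """Transfer a binary VIS-frame mask into the UV frame.

    Inverse mapping with nearest-neighbor assignment keeps the output
    strictly binary: each UV pixel looks up the VIS pixel its center maps
    back to.  ``transform`` is the fitted VIS->UV transform; its reverse
    fit (same control points, swapped roles) supplies the inverse mapping.
    If part of the mask maps outside the UV frame a warning reports the
    clipped coverage fraction.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = uv_shape
    inv = transform.inverse()
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = inv(np.column_stack([xs.ravel(), ys.ravel()]))
    sx = np.round(src[:, 0]).astype(int)
    sy = np.round(src[:, 1]).astype(int)
    ok = (sx >= 0) & (sx < mask.shape[1]) & (sy >= 0) & (sy < mask.shape[0])
    out = np.zeros((h, w), dtype=bool)
    out.ravel()[ok] = mask[sy[ok], sx[ok]]

    # coverage check: forward-map the mask pixels
    my, mx = np.nonzero(mask)
    if len(mx):
        fwd = transform(np.column_stack([mx, my]).astype(float))
        outside = (
            (fwd[:, 0] < -0.5)
            | (fwd[:, 0] > w - 0.5)
            | (fwd[:, 1] < -0.5)
            | (fwd[:, 1] > h - 0.5)
        )
        frac = outside.mean()
        if frac > 0:
            warnings.warn(
                f"{100 * frac:.1f}% of mask pixels map outside the UV frame",
                stacklevel=2,
            )
    return out


def uv_measure(
    refl_uv: ReflectanceImage,
    warped_mask: np.ndarray,
    warped_roi: np.ndarray,
) -> tuple[float, float]:
    """(S_UV, B_UV): mean UV-band reflectance of spots and background.

    Means are taken over the warped spot mask and over RoI minus spots on
    the UV image's red (UV) band; an empty spot mask yields NaN for S_UV.
    """
    warped_mask = np.asarray(warped_mask, dtype=bool)
    warped_roi = np.asarray(warped_roi, dtype=bool)
    band = refl_uv.bands[0]
    b_uv = refl_uv.band_mean(band, warped_roi & ~warped_mask)
    if not (warped_mask & warped_roi).any():
        return float("nan"), b_uv
    s_uv = refl_uv.band_mean(band, warped_mask & warped_roi)
    return s_uv, b_uv
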