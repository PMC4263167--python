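"""Similarity transforms (translation + rotation + isotropic scale) on wing rasters.

All transforms act about the raster centre, so that composition and inversion
are independent of image size as long as every raster in a run shares one
resolution (the model-space convention used throughout the package).

The forward map of a transform with parameters ``(tx, ty, theta, s)`` is

    p' = c + s * R(theta) @ (p - c) + t

with ``p = (x, y)`` in pixel coordinates (x = column, y = row), ``c`` the
raster centre and ``R`` the rotation matrix for ``theta`` degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class SimilarityTransform:
    """Translation (px) + rotation (degrees) + isotropic scale about the raster centre."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"scale must be positive, got {self.s}")

    # -- algebra ---------------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        a = np.deg2rad(self.theta)
        ca, sa = np.cos(a), np.sin(a)
        return np.array([[ca, -sa], [sa, ca]])

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        t1 = np.array([other.tx, other.ty])
        t = self.s * self.rotation @ t1 + np.array([self.tx, self.ty])
        return SimilarityTransform(
            tx=float(t[0]), ty=float(t[1]), theta=self.theta + other.theta, s=self.s * other.s
        )

    def inverse(self) -> "SimilarityTransform":
        inv_s = 1.0 / self.s
        a = np.deg2rad(-self.theta)
        ca, sa = np.cos(a), np.sin(a)
        r_inv = np.array([[ca, -sa], [sa, ca]])
        t = -inv_s * r_inv @ np.array([self.tx, self.ty])
        return SimilarityTransform(tx=float(t[0]), ty=float(t[1]), theta=-self.theta, s=inv_s)

    # -- application -----------------------------------------------------

    def apply_points(self, xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Map (n, 2) ``(x, y)`` points through the forward transform."""
        c = _centre(shape)
        xy = np.asarray(xy, dtype=float)
        return (self.s * (xy - c) @ self.rotation.T) + c + np.array([self.tx, self.ty])

    def warp_grid(
        self,
        grid: np.ndarray,
        fill: int = 0,
        shape_out: tuple[int, int] | None = None,
        method: str = "majority",
        sigma: float = 1.5,
    ) -> np.ndarray:
        """Warp a categorical class raster; labels never blend.

        method "majority" (default): each class's indicator field is lightly
        smoothed (``sigma`` px, averaging out rasterization jags along
        boundaries), sampled bilinearly at the inverse-mapped position, and the
        output takes the argmax class — a deterministic majority vote that
        localizes class boundaries to sub-pixel accuracy.  method "nearest"
        samples the label raster directly.  Ties go to the lower class code.
        Pixels mapping outside the source raster receive ``fill``; an exactly
        identity transform returns the input unchanged.
        """
        grid = np.asarray(grid)
        shape_out = shape_out or grid.shape
        if (
            shape_out == grid.shape
            and abs(self.tx) < 1e-12 and abs(self.ty) < 1e-12
            and abs(self.theta) < 1e-12 and abs(self.s - 1.0) < 1e-12
        ):
            return grid.copy()
        inv = self.inverse()
        rr, cc = np.meshgrid(
            np.arange(shape_out[0]), np.arange(shape_out[1]), indexing="ij"
        )
        xy = np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float)
        src = inv.apply_points(xy, shape_out)
        coords = np.stack([src[:, 1], src[:, 0]])  # (row, col) order
        if method == "nearest":
            out = ndimage.map_coordinates(
                grid.astype(np.int16), coords, order=0, mode="constant", cval=fill
            )
            return out.reshape(shape_out).astype(grid.dtype)
        if method != "majority":
            raise ValueError(f"unknown warp method {method!r}")
        inb = (
            (src[:, 0] > -0.5) & (src[:, 0] < grid.shape[1] - 0.5)
            & (src[:, 1] > -0.5) & (src[:, 1] < grid.shape[0] - 0.5)
        )
        codes = np.unique(grid)
        best = np.full(xy.shape[0], -np.inf)
        out = np.zeros(xy.shape[0], dtype=np.int16)
        for code in codes:
            ch = ndimage.gaussian_filter((grid == code).astype(np.float32), sigma)
            v = ndimage.map_coordinates(ch, coords, order=1, mode="nearest")
            sel = v > best
            best[sel] = v[sel]
            out[sel] = code
        out[~inb] = fill
        return out.reshape(shape_out).astype(grid.dtype)

    def warp_rgb(self, image: np.ndarray, fill_rgb: tuple[int, int, int]) -> np.ndarray:
        """Warp an RGB uint8 image channel-wise (nearest-neighbour)."""
        out = np.empty_like(image)
        for ch in range(image.shape[2]):
            out[..., ch] = self.warp_grid(image[..., ch], fill=fill_rgb[ch])
        return out

    def as_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta": self.theta, "s": self.s}

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(tx=d["tx"], ty=d["ty"], theta=d["theta"], s=d["s"])

    def is_close(self, other: "SimilarityTransform", tol_t=0.5, tol_theta=0.5, tol_s=0.01) -> bool:
        return (
            abs(self.tx - other.tx) <= tol_t
            and abs(self.ty - other.ty) <= tol_t
            and abs(self.theta - other.theta) <= tol_theta
            and abs(self.s / other.s - 1.0) <= tol_s
        )


def _centre(shape: tuple[int, int]) -> np.ndarray:
    return np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])


IDENTITY = SimilarityTransform()
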