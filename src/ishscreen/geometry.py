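"""Planar geometry helpers shared by the synthetic generator and the segmentation stage.

All coordinates are 0-based ``(row, col)`` pairs; boxes are half-open
``(r0, c0, r1, c1)``.  Curves are represented either parametrically (elliptic
:class:`Arc`) or as dense polylines, i.e. ``(n, 2)`` float arrays.

Sign convention for offsets perpendicular to a polyline: the normal at a point
with unit tangent ``t = (tr, tc)`` is ``n = (-tc, tr)``.  Positive offsets are
on that side of the curve; the package places the neuropil margin on the
positive side, which ties the convention to the control-point ordering of the
shape model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class Arc:
    """Elliptic arc: ``p(t) = center + (radii_r * sin t, radii_c * cos t)``.

    ``span`` may be decreasing, which reverses the travel direction (and hence
    flips the sign of perpendicular offsets).
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    span: tuple[float, float]

    def sample(self, n: int) -> np.ndarray:
        t = np.linspace(self.span[0], self.span[1], n)
        r = self.center[0] + self.radii[0] * np.sin(t)
        c = self.center[1] + self.radii[1] * np.cos(t)
        return np.column_stack([r, c])

    def polyline(self, n: int = 400) -> np.ndarray:
        """Dense polyline resampled to ~uniform arc length."""
        return resample_arclength(self.sample(4 * n), n)


def polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def cumulative_arclength(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_arclength(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` points equally spaced in arc length."""
    s = cumulative_arclength(poly)
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(target, s, poly[:, 0]), np.interp(target, s, poly[:, 1])]
    )


def polyline_tangents(poly: np.ndarray) -> np.ndarray:
    """Unit tangents at polyline vertices (central differences)."""
    t = np.gradient(poly, axis=0)
    norm = np.linalg.norm(t, axis=1)
    norm[norm == 0] = 1.0
    return t / norm[:, None]


def polyline_frame(
    poly: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arc length and signed perpendicular offset of ``points`` w.r.t. ``poly``.

    Returns ``(s, d)`` where ``s`` is the arc length of the nearest polyline
    vertex and ``d`` the signed distance (positive on the ``(-tc, tr)`` normal
    side).  ``poly`` should be densely sampled (vertex spacing ~1 px) for the
    nearest-vertex approximation to be accurate.
    """
    points = np.atleast_2d(points)
    tree = cKDTree(poly)
    dist, idx = tree.query(points)
    tang = polyline_tangents(poly)[idx]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    vec = points - poly[idx]
    side = np.sign(np.einsum("ij,ij->i", vec, normal))
    side[side == 0] = 1.0
    s = cumulative_arclength(poly)[idx]
    return s, side * dist


def pixel_grid(shape: tuple[int, int]) -> np.ndarray:
    """All pixel centers of an ``(H, W)`` raster as an ``(H*W, 2)`` array."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def clip_box(
    box: tuple[int, int, int, int], shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    r0, c0, r1, c1 = box
    return (max(r0, 0), max(c0, 0), min(r1, shape[0]), min(c1, shape[1]))


def centered_box(
    center: tuple[float, float], size: float
) -> tuple[int, int, int, int]:
    half = size / 2.0
    r0 = int(round(center[0] - half))
    c0 = int(round(center[1] - half))
    return (r0, c0, r0 + int(round(size)), c0 + int(round(size)))


def min_curve_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum vertex-to-vertex distance between two dense polylines."""
    d, _ = cKDTree(a).query(b)
    return float(d.min())
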