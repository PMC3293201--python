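"""Vectorised planar geometry for line-segment landscapes.

All coordinates are in kilometres. Segments are stored as an ``(n, 4)`` float
array of ``(x1, y1, x2, y2)`` endpoint rows; points as ``(m, 2)`` arrays.
"""
from __future__ import annotations

import numpy as np

__all__ = ["nearest_segment", "wrap_angle", "fold_into_interval"]


def nearest_segment(
    points: np.ndarray,
    segments: np.ndarray,
    chunk_cells: int = 4_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest segment for each query point.

    Returns ``(distance, index, foot)`` where ``foot`` is the closest point on
    the winning segment. Exact distance ties resolve to the lowest segment
    index (``argmin`` keeps the first minimum), which makes downstream
    orientation lookups deterministic.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    segments = np.asarray(segments, dtype=float)
    m = points.shape[0]
    n = segments.shape[0]
    if n == 0:
        raise ValueError("landscape has no segments")

    a = segments[:, 0:2]  # (n,2)
    d = segments[:, 2:4] - a  # (n,2)
    len2 = np.einsum("ij,ij->i", d, d)
    len2 = np.where(len2 == 0.0, 1.0, len2)  # degenerate segments act as points

    dist = np.empty(m)
    idx = np.empty(m, dtype=np.int64)
    foot = np.empty((m, 2))

    step = max(1, int(chunk_cells // max(n, 1)))
    for lo in range(0, m, step):
        p = points[lo : lo + step]  # (k,2)
        # projection parameter of every point on every segment, clipped to [0,1]
        ap = p[:, None, :] - a[None, :, :]  # (k,n,2)
        t = np.einsum("knj,nj->kn", ap, d) / len2[None, :]
        np.clip(t, 0.0, 1.0, out=t)
        f = a[None, :, :] + t[:, :, None] * d[None, :, :]  # (k,n,2)
        diff = p[:, None, :] - f
        d2 = np.einsum("knj,knj->kn", diff, diff)
        j = np.argmin(d2, axis=1)
        rows = np.arange(p.shape[0])
        dist[lo : lo + step] = np.sqrt(d2[rows, j])
        idx[lo : lo + step] = j
        foot[lo : lo + step] = f[rows, j]
    return dist, idx, foot


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (radians) into ``(-pi, pi]``."""
    out = -((-np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if np.isscalar(theta) else out


def fold_into_interval(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into ``[lo, hi]`` by specular reflection at the ends."""
    width = hi - lo
    if width <= 0:
        raise ValueError("interval must have positive width")
    y = np.mod(np.asarray(x, dtype=float) - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y
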