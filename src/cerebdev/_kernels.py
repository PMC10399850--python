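"""Numba-accelerated distance kernels for the collision engine.

All kernels operate on raw float64 arrays; they fall back to pure-numpy
implementations when numba is unavailable, so the engine stays importable
anywhere.  The segment–segment routine is the clamped closest-point
algorithm; degenerate segments (spheres) are zero-length segments.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install here
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

_EPS = 1e-12


@njit(cache=True)
def _seg_seg_one(p0x, p0y, p0z, p1x, p1y, p1z,
                 ax, ay, az, bx, by, bz):
    d1x, d1y, d1z = p1x - p0x, p1y - p0y, p1z - p0z
    d2x, d2y, d2z = bx - ax, by - ay, bz - az
    rx, ry, rz = p0x - ax, p0y - ay, p0z - az
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    s = 0.0
    t = 0.0
    if a <= _EPS and e <= _EPS:
        pass
    elif a <= _EPS:
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= _EPS:
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > _EPS:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    c1x = p0x + s * d1x
    c1y = p0y + s * d1y
    c1z = p0z + s * d1z
    c2x = ax + t * d2x
    c2y = ay + t * d2y
    c2z = az + t * d2z
    dx, dy, dz = c1x - c2x, c1y - c2y, c1z - c2z
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def seg_seg_dist_many(p0, p1, A, B):
    """Distances from one segment to M segments; returns (M,)."""
    m = A.shape[0]
    out = np.empty(m)
    for i in range(m):
        out[i] = _seg_seg_one(p0[0], p0[1], p0[2], p1[0], p1[1], p1[2],
                              A[i, 0], A[i, 1], A[i, 2],
                              B[i, 0], B[i, 1], B[i, 2])
    return out


@njit(cache=True)
def segments_free(S0, S1, radius, A, B, limits, tol):
    """For K proposed capsules vs M obstacles: True where no overlap.

    ``limits[m]`` is the obstacle radius; overlap when distance <
    radius + limits[m] − tol.  Early-exits per proposal.
    """
    k = S0.shape[0]
    m = A.shape[0]
    out = np.ones(k, dtype=np.bool_)
    for i in range(k):
        for j in range(m):
            d = _seg_seg_one(S0[i, 0], S0[i, 1], S0[i, 2],
                             S1[i, 0], S1[i, 1], S1[i, 2],
                             A[j, 0], A[j, 1], A[j, 2],
                             B[j, 0], B[j, 1], B[j, 2])
            if d < radius + limits[j] - tol:
                out[i] = False
                break
    return out


if not HAVE_NUMBA:  # pure-numpy fallbacks (same signatures)

    def seg_seg_dist_many(p0, p1, A, B):  # noqa: F811
        from .geometry import segment_segment_distance
        return segment_segment_distance(p0, p1, A, B)

    def segments_free(S0, S1, radius, A, B, limits, tol):  # noqa: F811
        from .geometry import segment_segment_distance
        out = np.ones(S0.shape[0], dtype=bool)
        for i in range(S0.shape[0]):
            d = segment_segment_distance(S0[i], S1[i], A, B)
            out[i] = not np.any(d < radius + limits - tol)
        return out
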