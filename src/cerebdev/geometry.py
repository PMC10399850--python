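"""Capsule geometry primitives.

Every structure in the simulation is a capsule: a sphere (soma, degenerate
segment with ``orig == end``) or a cylinder with hemispherical caps (neurite
segment).  Two capsules overlap when the distance between their axis segments
is smaller than the sum of their radii.  All routines here are vectorised
over the second operand so a proposed segment can be tested against every
candidate returned by the spatial index in one call.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_segment_distance",
    "point_segment_distance",
    "clip_segment_to_box",
    "unit",
]

_EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    """Normalise ``v``; returns +z for a (near) zero vector."""
    n = float(np.linalg.norm(v))
    if n < _EPS:
        return np.array([0.0, 0.0, 1.0])
    return np.asarray(v, dtype=float) / n


def point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from point ``p`` to segments ``a[i]→b[i]``.

    ``a`` and ``b`` are (M, 3); returns (M,).  Degenerate segments (a == b)
    are handled as points.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p[None, :] - a, ab)
    t = np.where(denom > _EPS, t / np.maximum(denom, _EPS), 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(closest - p[None, :], axis=1)


def segment_segment_distance(
    p0: np.ndarray,
    p1: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """Minimum distance between one segment ``p0→p1`` and M segments ``a→b``.

    Vectorised version of the clamped closest-point algorithm (Ericson,
    *Real-Time Collision Detection*, §5.1.9).  Handles all degeneracies
    (either or both segments reduced to points).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)

    d1 = (p1 - p0)[None, :]          # direction of segment 1, broadcast
    d2 = b - a                        # (M,3) directions of segment 2
    r = p0[None, :] - a               # (M,3)

    aa = float(np.dot(p1 - p0, p1 - p0))       # squared length of seg 1
    ee = np.einsum("ij,ij->i", d2, d2)         # squared lengths of seg 2
    f = np.einsum("ij,ij->i", d2, r)

    M = a.shape[0]
    s = np.zeros(M)
    t = np.zeros(M)

    seg1_pt = aa <= _EPS
    seg2_pt = ee <= _EPS

    # both points
    both = seg1_pt & seg2_pt
    # seg1 point, seg2 segment: project p0 on seg2
    only2 = seg1_pt & ~seg2_pt
    t = np.where(only2, np.clip(f / np.maximum(ee, _EPS), 0.0, 1.0), t)

    if not seg1_pt:
        c = float(np.dot(p1 - p0, p0)) - np.einsum("j,ij->i", p1 - p0, a)
        # seg2 point: project a on seg1
        s = np.where(seg2_pt, np.clip(-c / aa, 0.0, 1.0), s)

        gen = ~seg2_pt
        bb = np.einsum("j,ij->i", p1 - p0, d2)   # d1·d2
        denom = aa * ee - bb * bb
        s_gen = np.where(denom > _EPS,
                         np.clip((bb * f - c * ee) / np.maximum(denom, _EPS), 0.0, 1.0),
                         0.0)
        t_gen = (bb * s_gen + f) / np.maximum(ee, _EPS)
        # re-clamp t and recompute s where t was clamped
        t_cl = np.clip(t_gen, 0.0, 1.0)
        s_gen = np.where(t_gen != t_cl,
                         np.clip((t_cl * bb - c) / aa, 0.0, 1.0),
                         s_gen)
        s = np.where(gen, s_gen, s)
        t = np.where(gen, t_cl, t)
    del both  # s = t = 0 is already correct for point–point

    c1 = p0[None, :] + s[:, None] * d1
    c2 = a + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


def clip_segment_to_box(
    p0: np.ndarray,
    p1: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> float:
    """Fraction of segment ``p0→p1`` lying inside the axis-aligned box [lo, hi].

    Liang–Barsky parametric clipping; returns a value in [0, 1].
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for k in range(3):
        if abs(d[k]) < _EPS:
            if p0[k] < lo[k] or p0[k] > hi[k]:
                return 0.0
        else:
            ta = (lo[k] - p0[k]) / d[k]
            tb = (hi[k] - p0[k]) / d[k]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
            if t0 > t1:
                return 0.0
    return t1 - t0
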