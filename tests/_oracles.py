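"""Brute-force geometric oracles used by the acceptance-level tests.

Deliberately independent of the package's shapely-based implementation:
dense polyline resampling, direct point-to-segment arithmetic, and
ray-casting point-in-polygon.
"""

import numpy as np


def resampled_polyline_distance(cells_xy, coords, spacing=0.01):
    samples = []
    coords = np.asarray(coords, float)
    for a, b in zip(coords[:-1], coords[1:]):
        seg_len = np.hypot(*(b - a))
        n = max(int(np.ceil(seg_len / spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        samples.append(a + t * (b - a))
    samples = np.vstack(samples)
    out = np.empty(len(cells_xy))
    for i in range(0, len(cells_xy), 64):
        chunk = np.asarray(cells_xy)[i : i + 64]
        d2 = ((chunk[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
        out[i : i + 64] = np.sqrt(d2.min(axis=1))
    return out


def point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return np.hypot(*(a + t * ab - p))


def polygon_boundary_distance(p, coords):
    coords = np.asarray(coords, float)
    return min(
        point_segment_distance(np.asarray(p, float), a, b)
        for a, b in zip(coords[:-1], coords[1:])
    )


def ray_cast_inside(p, poly_coords):
    x, y = p
    inside = False
    pts = list(poly_coords)
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside
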