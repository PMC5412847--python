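"""Naive brute-force reference implementations used as oracles.

These deliberately mirror the documented numerical conventions (corner
order, base-corner-relative trilinear accumulation, tie rules) with plain
per-voxel Python loops, so that integer outputs of the production code can
be compared bit-exactly and angles to tight tolerances.
"""

from __future__ import annotations

import math

import numpy as np

CORNERS = [(c0, c1, c2) for c0 in (0, 1) for c1 in (0, 1) for c2 in (0, 1)]


def trilinear(data: np.ndarray, centre, offset) -> float:
    """Base-corner-relative trilinear interpolation at ``centre + offset``.

    Fractional weights derive from the offset alone (the sampling stencil is
    translation invariant), matching the documented convention.
    """
    base = [math.floor(o) for o in offset]
    frac = [o - b for o, b in zip(offset, base)]
    i0 = [int(c) + b for c, b in zip(centre, base)]
    v000 = float(data[i0[0], i0[1], i0[2]])
    acc = v000
    for c in CORNERS:
        if c == (0, 0, 0):
            continue
        w = 1.0
        for ax in range(3):
            w = w * (frac[ax] if c[ax] else 1.0 - frac[ax])
        if w == 0.0:
            continue
        v = float(data[i0[0] + c[0], i0[1] + c[1], i0[2] + c[2]])
        acc = acc + w * (v - v000)
    return acc


def neighbor_samples(data, centre, directions, radius):
    return np.array([trilinear(data, centre, radius * d) for d in directions])


def code_at(data, centre, directions, radius) -> int:
    samples = neighbor_samples(data, centre, directions, radius)
    c = float(data[centre])
    code = 0
    for i, s in enumerate(samples):
        if s >= c:
            code |= 1 << i
    return code


def full_code_field(data, directions, radius):
    """(codes, max_neighbor, interior) by per-voxel loops."""
    data = np.asarray(data, dtype=np.float64)
    m = math.ceil(radius)
    codes = np.full(data.shape, -1, dtype=np.int64)
    maxnb = np.full(data.shape, -np.inf)
    interior = np.zeros(data.shape, dtype=bool)
    for i in range(m, data.shape[0] - m):
        for j in range(m, data.shape[1] - m):
            for k in range(m, data.shape[2] - m):
                samples = neighbor_samples(data, (i, j, k), directions, radius)
                c = float(data[i, j, k])
                code = 0
                for b, s in enumerate(samples):
                    if s >= c:
                        code |= 1 << b
                codes[i, j, k] = code
                maxnb[i, j, k] = samples.max()
                interior[i, j, k] = True
    return codes, maxnb, interior


def histogram(data, mask, directions, radius) -> dict[int, int]:
    codes, _, interior = full_code_field(data, directions, radius)
    out: dict[int, int] = {}
    sel = np.asarray(mask, bool) & interior
    for code in codes[sel]:
        out[int(code)] = out.get(int(code), 0) + 1
    return out


def pattern_markers(code: int) -> list[int]:
    return [i for i in range(26) if (code >> i) & 1]


def pattern_valid(code, positions, min_markers=3, max_markers=24, centroid_rule=True):
    markers = pattern_markers(code)
    n = len(markers)
    if n < min_markers or n > max_markers:
        return False
    if centroid_rule:
        pts = positions[markers]
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(positions - centroid, axis=1)
        non = [i for i in range(26) if i not in markers]
        if d[markers].mean() > d[non].mean():
            return False
    return True


def pattern_elevation(code, positions) -> float:
    """Elevation (deg) of the top principal axis of the marker positions."""
    pts = positions[pattern_markers(code)]
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    return math.degrees(math.asin(min(1.0, abs(axis[2]))))


def alcm_counts(angles, bin_width, n_bins, adjacency=26):
    """Raw symmetric co-occurrence counts by triple-loop pair enumeration."""
    if adjacency == 26:
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = angles.shape
    counts = np.zeros((n_bins, n_bins))

    def bin_of(a):
        return min(int(a // bin_width), n_bins - 1)

    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                a = angles[i, j, k]
                if not np.isfinite(a):
                    continue
                for dx, dy, dz in offsets:
                    x, y, z = i + dx, j + dy, k + dz
                    if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
                        continue
                    b = angles[x, y, z]
                    if not np.isfinite(b):
                        continue
                    counts[bin_of(a), bin_of(b)] += 1
    return counts


def windowed_minmax_binarize(data, pre_threshold, radius, shape="ball"):
    """Per-voxel clipped-window midrange thresholding, brute force."""
    data = np.asarray(data, dtype=np.float64)
    out = np.zeros(data.shape, dtype=bool)
    offsets = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if shape == "ball" and dx * dx + dy * dy + dz * dz > radius * radius:
                    continue
                offsets.append((dx, dy, dz))
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                if data[i, j, k] < pre_threshold:
                    continue
                vals = [
                    data[i + dx, j + dy, k + dz]
                    for dx, dy, dz in offsets
                    if 0 <= i + dx < data.shape[0]
                    and 0 <= j + dy < data.shape[1]
                    and 0 <= k + dz < data.shape[2]
                ]
                mid = (min(vals) + max(vals)) / 2.0
                out[i, j, k] = data[i, j, k] >= mid
    return out


def weighted_pearson(x, y, w):
    w = np.asarray(w, float)
    w = w / w.sum()
    mx = (w * x).sum()
    my = (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    return cov / math.sqrt((w * (x - mx) ** 2).sum() * (w * (y - my) ** 2).sum())
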