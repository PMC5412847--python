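"""Volumetric local binary patterns on a 26-neighbor sphere.

Each voxel is compared against 26 points fitted on a sphere centred on it
(the normalized directions of the 3x3x3 neighborhood, centre excluded).
Neighbor gray values are obtained by trilinear interpolation of the
surrounding voxels.  A neighbor whose value is greater than or equal to the
centre value is a *marker*; the 26 marker bits form the pattern code.

Codes are collected into a sparse histogram over the voxels of an analysis
mask.  Only voxels with at least one interpolated neighbor above a fixed
threshold are eligible, which restricts the analysis to bone and its
immediate surroundings and excludes empty space.

Summary statistics are the Shannon entropy of the pattern distribution
(randomness of local structure), the number of distinct patterns, and the
mean number of markers per pattern.

Numerical conventions
---------------------
Trilinear samples are computed relative to the base corner of the sampling
cell, ``v000 + sum_c w_c * (v_c - v000)``, accumulating corners in
lexicographic order with weights multiplied axis 0, then 1, then 2 and
skipping corners with exactly zero weight.  The relative form makes the
sample *exactly* equal to the voxel value whenever all contributing corners
share one value, so the tie rule of the marker comparison
(``sample >= centre``) behaves deterministically on flat and ramp-like
fields instead of depending on rounding of the weight sum.
Voxels within ``ceil(radius)`` of a volume face are never eligible (no
extrapolation).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .volume_io import BinaryVolume, GrayVolume

#: 26 integer offsets of the 3x3x3 neighborhood (centre excluded), ordered
#: lexicographically by (offset along axis 2, axis 1, axis 0).  Columns are
#: array-axis components (axis 0, axis 1, axis 2).
NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.float64,
)

_CORNERS = [(c0, c1, c2) for c0 in (0, 1) for c1 in (0, 1) for c2 in (0, 1)]


@dataclasses.dataclass
class SphericalNeighborhood:
    """26 sampling directions on a sphere of ``radius_vox`` voxels."""

    radius_vox: float
    directions: np.ndarray  # (26, 3) unit vectors, fixed order

    @property
    def n_neighbors(self) -> int:
        return len(self.directions)

    @property
    def positions(self) -> np.ndarray:
        """Sampling offsets (26, 3) = radius * directions, in voxel units."""
        return self.radius_vox * self.directions

    @property
    def margin(self) -> int:
        """Number of boundary voxels on each face excluded from analysis."""
        return int(math.ceil(self.radius_vox))


def build_neighborhood(radius_vox: float = 1.0) -> SphericalNeighborhood:
    """The canonical 26-direction spherical neighborhood.

    Directions are the normalized offsets of the 3x3x3 neighborhood in a
    fixed documented order, so the 6 axial sampling points sit at exact
    lattice offsets when ``radius_vox`` is an integer.
    """
    if not radius_vox > 0:
        raise ValueError("radius_vox must be positive")
    norms = np.linalg.norm(NEIGHBOR_OFFSETS, axis=1, keepdims=True)
    return SphericalNeighborhood(float(radius_vox), NEIGHBOR_OFFSETS / norms)


@dataclasses.dataclass
class PatternHistogram:
    """Sparse histogram of 26-bit pattern codes."""

    counts: dict[int, int]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("histogram total must be positive")
        if sum(self.counts.values()) != self.total:
            raise ValueError("sum of counts must equal total")
        for code in self.counts:
            if not 0 <= code < 2 ** 26:
                raise ValueError(f"invalid 26-bit code {code}")

    def proportions(self) -> dict[int, float]:
        return {c: n / self.total for c, n in self.counts.items()}

    def codes_and_counts(self) -> tuple[np.ndarray, np.ndarray]:
        codes = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        counts = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
        return codes, counts


@dataclasses.dataclass
class LBPSummary:
    entropy_bits: float
    n_distinct_patterns: int
    mean_marker_count: float


def _weighted_shift(data: np.ndarray, offset: np.ndarray, margin: int) -> np.ndarray:
    """Trilinear sample of ``data`` at every interior voxel + ``offset``.

    Interior means ``margin`` voxels away from every face.  Accumulates the
    8 corner terms in lexicographic corner order; zero-weight corners are
    skipped, keeping all integer shifts within ``margin``.
    """
    base = np.floor(offset).astype(int)
    frac = offset - base
    n = data.shape

    def corner_view(c):
        s = base + np.array(c)
        return data[
            margin + s[0] : n[0] - margin + s[0],
            margin + s[1] : n[1] - margin + s[1],
            margin + s[2] : n[2] - margin + s[2],
        ]

    base_view = corner_view((0, 0, 0))
    out = base_view.copy()
    for c in _CORNERS:
        if c == (0, 0, 0):
            continue
        w = 1.0
        for ax in range(3):
            w = w * (frac[ax] if c[ax] else 1.0 - frac[ax])
        if w == 0.0:
            continue
        out += w * (corner_view(c) - base_view)
    return out


def _interior_slices(shape: tuple[int, ...], margin: int) -> tuple[slice, ...]:
    return tuple(slice(margin, n - margin) for n in shape)


def _require_interior(vol: GrayVolume, nbhd: SphericalNeighborhood) -> int:
    m = nbhd.margin
    if min(vol.shape) <= 2 * m:
        raise ValueError(
            f"volume shape {vol.shape} too small for neighborhood radius "
            f"{nbhd.radius_vox} (needs > {2 * m} voxels per axis)"
        )
    return m


def code_field(
    vol: GrayVolume, nbhd: SphericalNeighborhood
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pattern code at every interior voxel.

    Returns ``(codes, max_neighbor, interior)`` where ``codes`` is an int64
    array (-1 outside the interior), ``max_neighbor`` holds the maximum
    interpolated neighbor value (-inf outside the interior) and ``interior``
    is the boolean interior mask.
    """
    m = _require_interior(vol, nbhd)
    data = vol.data.astype(np.float64, copy=False)
    centre = data[_interior_slices(data.shape, m)]
    codes_in = np.zeros(centre.shape, dtype=np.int64)
    max_in = np.full(centre.shape, -np.inf)
    for i, direction in enumerate(nbhd.directions):
        sample = _weighted_shift(data, nbhd.radius_vox * direction, m)
        codes_in |= (sample >= centre).astype(np.int64) << i
        np.maximum(max_in, sample, out=max_in)
    codes = np.full(vol.shape, -1, dtype=np.int64)
    max_neighbor = np.full(vol.shape, -np.inf)
    interior = np.zeros(vol.shape, dtype=bool)
    sl = _interior_slices(vol.shape, m)
    codes[sl] = codes_in
    max_neighbor[sl] = max_in
    interior[sl] = True
    return codes, max_neighbor, interior


def sample_neighbors(
    vol: GrayVolume, centre: tuple[int, int, int], nbhd: SphericalNeighborhood
) -> np.ndarray:
    """The 26 interpolated neighbor values of one voxel, in direction order."""
    m = nbhd.margin
    for ax in range(3):
        if not m <= centre[ax] < vol.shape[ax] - m:
            raise ValueError(
                f"centre {centre} is within {m} voxels of a face of {vol.shape}"
            )
    data = vol.data.astype(np.float64, copy=False)
    out = np.empty(nbhd.n_neighbors)
    for i, direction in enumerate(nbhd.directions):
        offset = nbhd.radius_vox * direction
        base = np.floor(offset).astype(int)
        frac = offset - base

        def corner_value(c):
            return data[
                centre[0] + base[0] + c[0],
                centre[1] + base[1] + c[1],
                centre[2] + base[2] + c[2],
            ]

        v000 = corner_value((0, 0, 0))
        acc = v000
        for c in _CORNERS:
            if c == (0, 0, 0):
                continue
            w = 1.0
            for ax in range(3):
                w = w * (frac[ax] if c[ax] else 1.0 - frac[ax])
            if w == 0.0:
                continue
            acc = acc + w * (corner_value(c) - v000)
        out[i] = acc
    return out


def compute_code(centre_value: float, neighbor_values: np.ndarray) -> int:
    """Pattern code: bit i set iff neighbor i >= centre (markers)."""
    neighbor_values = np.asarray(neighbor_values)
    bits = (neighbor_values >= centre_value).astype(np.int64)
    return int((bits << np.arange(len(bits), dtype=np.int64)).sum())


def eligibility_mask(
    vol: GrayVolume, nbhd: SphericalNeighborhood, fixed_threshold: float
) -> BinaryVolume:
    """Interior voxels with at least one interpolated neighbor strictly above
    the fixed threshold (captures bone, skips empty space)."""
    _, max_neighbor, interior = code_field(vol, nbhd)
    return BinaryVolume(interior & (max_neighbor > fixed_threshold), vol.voxel_size_um)


def analysis_mask(
    vol: GrayVolume,
    nbhd: SphericalNeighborhood,
    fixed_threshold: float,
    roi: BinaryVolume | None = None,
) -> BinaryVolume:
    """Eligibility mask intersected with an optional region of interest."""
    mask = eligibility_mask(vol, nbhd, fixed_threshold)
    if roi is not None:
        if roi.shape != vol.shape:
            raise ValueError("ROI shape does not match volume shape")
        mask = BinaryVolume(mask.data & roi.data, vol.voxel_size_um)
    return mask


def lbp_histogram(
    vol: GrayVolume, mask: BinaryVolume, nbhd: SphericalNeighborhood
) -> PatternHistogram:
    """Sparse pattern histogram over the masked voxels.

    The mask is intersected with the interior region; it should already be
    restricted to eligible voxels (see :func:`analysis_mask`).
    """
    codes, _, interior = code_field(vol, nbhd)
    if mask.shape != vol.shape:
        raise ValueError("mask shape does not match volume shape")
    selected = mask.data & interior
    if not selected.any():
        raise ValueError("empty analysis mask: no voxels to analyze")
    values, counts = np.unique(codes[selected], return_counts=True)
    return PatternHistogram(
        {int(v): int(c) for v, c in zip(values, counts)}, int(counts.sum())
    )


def pattern_entropy(hist: PatternHistogram) -> float:
    """Shannon entropy (bits) of the pattern proportions; one pattern -> 0."""
    _, counts = hist.codes_and_counts()
    p = counts / hist.total
    return float(-(p * np.log2(p)).sum() + 0.0)  # + 0.0 avoids -0.0


def lbp_summary(hist: PatternHistogram) -> LBPSummary:
    """Entropy, number of distinct patterns, and mean marker count."""
    codes, counts = hist.codes_and_counts()
    popcounts = np.bitwise_count(codes)
    mean_markers = float((popcounts * counts).sum() / hist.total)
    return LBPSummary(
        entropy_bits=pattern_entropy(hist),
        n_distinct_patterns=int((counts > 0).sum()),
        mean_marker_count=mean_markers,
    )
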