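"""Pattern orientation: elevation angles, their entropy, and co-occurrence homogeneity.

The markers of a valid pattern are treated as a point set on the sampling
sphere and reduced to a principal axis by principal component analysis; the
*elevation* of the pattern is the angle of that axis against the transverse
plane, measured along the distal-proximal axis (array axis 2):

* 0 degrees  = transverse (axis in the imaging plane),
* 90 degrees = longitudinal (axis along distal-proximal).

Because the sign of the principal axis and the azimuth carry no information
here, the elevation uses ``arcsin(|axis . z|)`` and lies in [0, 90].

Patterns without a consistent orientation are discarded: fewer than 3 or
more than 24 markers, marker sets whose mean distance to their own centroid
exceeds that of the non-markers (dispersed/ring-like sets), and patterns
whose top two principal components are numerically tied (no unique axis).

Spatial continuity of orientation is summarized by an angle-level
co-occurrence matrix (ALCM): for every ordered pair of adjacent valid
voxels (26-adjacency, i.e. within one voxel-size radius including
diagonals) the cell (bin(a), bin(b)) is incremented; counting both orders
makes the matrix symmetric.  The homogeneity of elevation is

    H = sum_ij ALCM(i, j) / (1 + |i - j|)

over the normalized matrix, which is 1 exactly when all co-occurring pairs
share a bin and decreases as mass moves off the diagonal.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .lbp3d import BinaryVolume, GrayVolume, SphericalNeighborhood, code_field
from .volume_io import VolumeFormatError  # noqa: F401  (re-export convenience)

#: Relative eigenvalue-gap tolerance below which a pattern has no unique
#: principal axis and is treated as orientation-inconsistent.
EIGEN_TIE_RTOL = 1e-9

_CHUNK = 1 << 16


@dataclasses.dataclass
class PatternValidity:
    """Rules deciding which patterns have a consistent orientation."""

    min_markers: int = 3
    max_markers: int = 24
    centroid_rule: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_markers <= self.max_markers < 26:
            raise ValueError("require 0 < min_markers <= max_markers < 26")


@dataclasses.dataclass
class ElevationField:
    """Per-voxel elevation in degrees; NaN marks invalid or unevaluated voxels."""

    angles: np.ndarray
    bin_width_deg: float = 5.0
    evaluated: np.ndarray | None = None  # voxels that were in the analysis mask

    def __post_init__(self) -> None:
        valid = self.angles[np.isfinite(self.angles)]
        if valid.size and (valid.min() < 0 or valid.max() > 90):
            raise ValueError("elevation angles must lie in [0, 90] degrees")
        if not self.bin_width_deg > 0:
            raise ValueError("bin_width_deg must be positive")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(90.0 / self.bin_width_deg))

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.angles)

    def bin_indices(self) -> np.ndarray:
        """Bin index per voxel (int), -1 where invalid; 90 deg falls in the last bin."""
        idx = np.full(self.angles.shape, -1, dtype=np.int64)
        valid = self.valid_mask
        bins = np.minimum(
            (self.angles[valid] / self.bin_width_deg).astype(np.int64), self.n_bins - 1
        )
        idx[valid] = bins
        return idx


@dataclasses.dataclass
class ALCMatrix:
    """Normalized, symmetric angle-level co-occurrence matrix."""

    cells: np.ndarray
    n_bins: int
    bin_width_deg: float = 5.0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.float64)
        if self.cells.shape != (self.n_bins, self.n_bins):
            raise ValueError("cells must be a square n_bins x n_bins matrix")
        if (self.cells < 0).any():
            raise ValueError("ALCM entries must be nonnegative")


@dataclasses.dataclass
class OrientationSummary:
    mean_elevation_deg: float
    elevation_entropy_bits: float
    valid_fraction: float
    homogeneity: float | None = None


def _decode_markers(codes: np.ndarray) -> np.ndarray:
    """Boolean marker matrix (K, 26) from an array of pattern codes."""
    codes = np.asarray(codes, dtype=np.int64).reshape(-1)
    return ((codes[:, None] >> np.arange(26)) & 1).astype(bool)


def _batch_validity_and_elevation(
    codes: np.ndarray, nbhd: SphericalNeighborhood, rules: PatternValidity
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized validity + elevation for an array of distinct codes.

    Returns ``(valid, elevation_deg)``; elevation is NaN where invalid.
    Processes in chunks to bound the memory of the (K, 26) intermediates.
    """
    codes = np.asarray(codes, dtype=np.int64).reshape(-1)
    positions = nbhd.positions  # (26, 3)
    valid_out = np.zeros(codes.shape, dtype=bool)
    elev_out = np.full(codes.shape, np.nan)
    for start in range(0, len(codes), _CHUNK):
        sl = slice(start, start + _CHUNK)
        markers = _decode_markers(codes[sl])  # (K, 26)
        n = markers.sum(axis=1)
        ok = (n >= rules.min_markers) & (n <= rules.max_markers)
        mf = markers.astype(np.float64)
        n_safe = np.maximum(n, 1).astype(np.float64)
        centroid = (mf @ positions) / n_safe[:, None]  # (K, 3)
        if rules.centroid_rule:
            dist = np.linalg.norm(
                positions[None, :, :] - centroid[:, None, :], axis=2
            )  # (K, 26)
            marker_d = (mf * dist).sum(axis=1) / n_safe
            n_non = np.maximum(26 - n, 1).astype(np.float64)
            non_d = ((1.0 - mf) * dist).sum(axis=1) / n_non
            ok &= ~(marker_d > non_d)
        # covariance of marker positions about their centroid
        second = np.einsum("ki,ia,ib->kab", mf, positions, positions) / n_safe[:, None, None]
        cov = second - centroid[:, :, None] * centroid[:, None, :]
        eigvals, eigvecs = np.linalg.eigh(cov)
        gap = eigvals[:, 2] - eigvals[:, 1]
        ok &= gap > EIGEN_TIE_RTOL * np.maximum(eigvals[:, 2], np.finfo(float).tiny)
        axis_z = np.abs(eigvecs[:, 2, 2])  # z-component of the top eigenvector
        elev = np.degrees(np.arcsin(np.clip(axis_z, 0.0, 1.0)))
        valid_out[sl] = ok
        elev_out[sl][ok] = elev[ok]
    return valid_out, elev_out


def is_valid_pattern(
    code: int, nbhd: SphericalNeighborhood, rules: PatternValidity | None = None
) -> bool:
    """Marker-count and centroid-dispersion validity of a single pattern.

    The additional principal-axis tie check applied by
    :func:`elevation_field` is not part of this rule set.
    """
    rules = rules or PatternValidity()
    markers = _decode_markers([code])[0]
    n = int(markers.sum())
    if n < rules.min_markers or n > rules.max_markers:
        return False
    if rules.centroid_rule:
        positions = nbhd.positions
        centroid = positions[markers].mean(axis=0)
        dist = np.linalg.norm(positions - centroid, axis=1)
        if dist[markers].mean() > dist[~markers].mean():
            return False
    return True


def pattern_elevation(
    code: int, nbhd: SphericalNeighborhood, rules: PatternValidity | None = None
) -> float:
    """Elevation (degrees in [0, 90]) of one valid pattern's principal axis."""
    rules = rules or PatternValidity()
    valid, elev = _batch_validity_and_elevation(np.array([code]), nbhd, rules)
    if not valid[0]:
        raise ValueError(f"pattern {code} has no consistent orientation")
    return float(elev[0])


def elevation_field(
    vol: GrayVolume,
    mask: BinaryVolume,
    nbhd: SphericalNeighborhood,
    rules: PatternValidity | None = None,
    bin_width_deg: float = 5.0,
) -> ElevationField:
    """Per-voxel elevation over an analysis mask; NaN where invalid.

    Elevation is a pure function of the pattern code, so it is computed once
    per distinct code and broadcast back to the field.
    """
    rules = rules or PatternValidity()
    codes, _, interior = code_field(vol, nbhd)
    if mask.shape != vol.shape:
        raise ValueError("mask shape does not match volume shape")
    selected = mask.data & interior
    if not selected.any():
        raise ValueError("empty analysis mask: no voxels to analyze")
    uniq, inverse = np.unique(codes[selected], return_inverse=True)
    _, elev_u = _batch_validity_and_elevation(uniq, nbhd, rules)
    angles = np.full(vol.shape, np.nan)
    angles[selected] = elev_u[inverse]
    return ElevationField(angles, bin_width_deg, evaluated=selected)


def elevation_summary(field: ElevationField) -> OrientationSummary:
    """Mean elevation, entropy of the binned elevation distribution, and the
    fraction of evaluated voxels that carried a valid orientation."""
    valid = field.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid elevation values in the field")
    angles = field.angles[valid]
    bins = field.bin_indices()[valid]
    counts = np.bincount(bins, minlength=field.n_bins)
    p = counts[counts > 0] / n_valid
    entropy = float(-(p * np.log2(p)).sum() + 0.0)
    n_evaluated = (
        int(field.evaluated.sum()) if field.evaluated is not None else int(valid.size)
    )
    return OrientationSummary(
        mean_elevation_deg=float(angles.mean()),
        elevation_entropy_bits=entropy,
        valid_fraction=n_valid / n_evaluated,
    )


_ALL_OFFSETS = [
    (dx, dy, dz)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
# one representative per +/- pair; the transpose restores both orders
_POSITIVE_OFFSETS_26 = [o for o in _ALL_OFFSETS if o > (0, 0, 0)]
_POSITIVE_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


def _offset_slices(shape, offset):
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def compute_alcm(field: ElevationField, adjacency: int = 26) -> ALCMatrix:
    """Angle-level co-occurrence matrix over adjacent valid voxels.

    Every ordered pair of adjacent valid voxels contributes one count, so
    the matrix is symmetric; it is normalized to sum to 1.
    """
    if adjacency == 26:
        offsets = _POSITIVE_OFFSETS_26
    elif adjacency == 6:
        offsets = _POSITIVE_OFFSETS_6
    else:
        raise ValueError("adjacency must be 6 or 26")
    nb = field.n_bins
    bins = field.bin_indices()
    counts = np.zeros((nb, nb), dtype=np.float64)
    for offset in offsets:
        sl_a, sl_b = _offset_slices(bins.shape, offset)
        a = bins[sl_a].ravel()
        b = bins[sl_b].ravel()
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        flat = a[ok] * nb + b[ok]
        counts += np.bincount(flat, minlength=nb * nb).reshape(nb, nb)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no adjacent pairs of valid voxels: ALCM undefined")
    return ALCMatrix(counts / total, nb, field.bin_width_deg)


def homogeneity_of_elevation(alcm: ALCMatrix) -> float:
    """H = sum_ij ALCM(i,j) / (1 + |i - j|) over bin indices; in (0, 1]."""
    idx = np.arange(alcm.n_bins)
    weights = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    return float((alcm.cells * weights).sum())


def orientation_summary(field: ElevationField, adjacency: int = 26) -> OrientationSummary:
    """Full orientation summary: mean, entropy, valid fraction and homogeneity."""
    summary = elevation_summary(field)
    try:
        summary.homogeneity = homogeneity_of_elevation(compute_alcm(field, adjacency))
    except ValueError:
        summary.homogeneity = None  # no adjacent valid pairs
    return summary
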