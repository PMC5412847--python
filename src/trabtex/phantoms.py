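"""Synthetic gray-level phantoms with analytic ground truth.

The generator emulates reconstructed micro-CT volumes of idealized
rod/plate structures: a binary geometry defined in continuous space is
voxelized at voxel centres, given two-level intensities, and then degraded
by a Gaussian blur (the scanner point-spread function) and additive
Gaussian noise.  Defaults mimic an 8-bit trabecular-bone reconstruction:
bone ~200, marrow ~40 on a 0-255 scale, blur sigma 0.8 voxel, noise SD 5.

Kinds
-----
rod_lattice
    Parallel circular rods on a square lattice, tilted in the x-z plane so
    their elevation against the transverse plane is ``elevation_deg``
    (90 = along the distal-proximal axis).  BV/TV = pi r^2 / spacing^2.
plate_stack
    Parallel plates perpendicular to the distal-proximal axis
    (transverse structures).  BV/TV = thickness / spacing.
sphere_pack
    Spheres on a simple cubic lattice.  BV/TV = (4/3) pi r^3 / spacing^3.
ramp
    Strictly increasing intensity along the distal-proximal axis; every
    interior voxel carries the same local pattern.
two_phase_noise
    Smoothed Gaussian random field thresholded at a quantile, producing an
    irregular two-phase structure at a controlled volume fraction.

All randomness derives from the integer ``seed`` in the spec; no global
random state is touched.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import GrayVolume

_KINDS = ("rod_lattice", "plate_stack", "sphere_pack", "ramp", "two_phase_noise")


@dataclasses.dataclass
class PhantomSpec:
    kind: str
    size_vox: tuple[int, int, int] = (64, 64, 64)
    elevation_deg: float = 90.0
    element_radius_vox: float = 3.0
    thickness_vox: float = 4.0
    spacing_vox: float = 12.0
    fg_intensity: float = 200.0
    bg_intensity: float = 40.0
    blur_sigma_vox: float = 0.8
    noise_sd: float = 5.0
    volume_fraction: float = 0.3  # two_phase_noise only
    seed: int = 0
    voxel_size_um: float = 27.8

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not self.fg_intensity > self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if not 0 <= self.elevation_deg <= 90:
            raise ValueError("elevation_deg must lie in [0, 90]")
        if self.blur_sigma_vox < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_vox and noise_sd must be nonnegative")
        if self.kind in ("rod_lattice", "sphere_pack"):
            if not self.spacing_vox > 2 * self.element_radius_vox:
                raise ValueError("spacing_vox must exceed 2*element_radius_vox")
        if self.kind == "plate_stack" and not self.spacing_vox > self.thickness_vox:
            raise ValueError("spacing_vox must exceed thickness_vox")


@dataclasses.dataclass
class GroundTruth:
    """Analytic quantities of the generated structure (None = not applicable)."""

    bv_tv: float | None = None
    elevation_deg: float | None = None
    thickness_vox: float | None = None
    spacing_vox: float | None = None
    n_distinct_patterns: int | None = None


def _grid(size):
    return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in size), indexing="ij")


def _rod_lattice_fg(spec: PhantomSpec) -> np.ndarray:
    e = np.radians(spec.elevation_deg)
    # rod direction in the x-z plane; u, v span the perpendicular section
    u = np.array([-np.sin(e), 0.0, np.cos(e)])
    v = np.array([0.0, 1.0, 0.0])
    x, y, z = _grid(spec.size_vox)
    centre = [(n - 1) / 2.0 for n in spec.size_vox]
    px, py, pz = x - centre[0], y - centre[1], z - centre[2]
    pu = px * u[0] + py * u[1] + pz * u[2]
    pv = px * v[0] + py * v[1] + pz * v[2]
    s = spec.spacing_vox
    du = np.mod(pu + s / 2.0, s) - s / 2.0
    dv = np.mod(pv + s / 2.0, s) - s / 2.0
    return du ** 2 + dv ** 2 <= spec.element_radius_vox ** 2


def _plate_stack_fg(spec: PhantomSpec) -> np.ndarray:
    _, _, z = _grid(spec.size_vox)
    return np.mod(z, spec.spacing_vox) < spec.thickness_vox


def _sphere_pack_fg(spec: PhantomSpec) -> np.ndarray:
    coords = _grid(spec.size_vox)
    s = spec.spacing_vox
    centre = [(n - 1) / 2.0 for n in spec.size_vox]
    d2 = np.zeros(spec.size_vox)
    for c, c0 in zip(coords, centre):
        d = np.mod(c - c0 + s / 2.0, s) - s / 2.0
        d2 += d ** 2
    return d2 <= spec.element_radius_vox ** 2


def generate(spec: PhantomSpec) -> tuple[GrayVolume, GroundTruth]:
    """Deterministic phantom volume plus its analytic ground truth."""
    r, s = spec.element_radius_vox, spec.spacing_vox
    if spec.kind == "rod_lattice":
        fg = _rod_lattice_fg(spec)
        truth = GroundTruth(
            bv_tv=float(np.pi * r ** 2 / s ** 2),
            elevation_deg=spec.elevation_deg,
            thickness_vox=2 * r,
            spacing_vox=s,
        )
    elif spec.kind == "plate_stack":
        fg = _plate_stack_fg(spec)
        truth = GroundTruth(
            bv_tv=float(spec.thickness_vox / s),
            elevation_deg=0.0,
            thickness_vox=spec.thickness_vox,
            spacing_vox=s,
        )
    elif spec.kind == "sphere_pack":
        fg = _sphere_pack_fg(spec)
        truth = GroundTruth(bv_tv=float(4.0 / 3.0 * np.pi * r ** 3 / s ** 3), spacing_vox=s)
    elif spec.kind == "ramp":
        _, _, z = _grid(spec.size_vox)
        nz = spec.size_vox[2]
        slope = (spec.fg_intensity - spec.bg_intensity) / max(nz - 1, 1)
        data = spec.bg_intensity + slope * z
        vol = GrayVolume(data, spec.voxel_size_um)
        vol = degrade(vol, spec.blur_sigma_vox, spec.noise_sd, spec.seed)
        return vol, GroundTruth(n_distinct_patterns=1)
    else:  # two_phase_noise
        rng = np.random.default_rng(spec.seed)
        field = ndimage.gaussian_filter(rng.standard_normal(spec.size_vox), 3.0)
        cut = np.quantile(field, 1.0 - spec.volume_fraction)
        fg = field >= cut
        truth = GroundTruth(bv_tv=float(fg.mean()))
    data = np.where(fg, spec.fg_intensity, spec.bg_intensity)
    vol = GrayVolume(data, spec.voxel_size_um)
    # derive the degradation seed from the spec seed; distinct from the
    # geometry stream used by two_phase_noise
    vol = degrade(vol, spec.blur_sigma_vox, spec.noise_sd, spec.seed + 1)
    return vol, truth


def binary_ground_truth(spec: PhantomSpec) -> np.ndarray:
    """The clean voxelized foreground of a structural phantom spec."""
    if spec.kind == "rod_lattice":
        return _rod_lattice_fg(spec)
    if spec.kind == "plate_stack":
        return _plate_stack_fg(spec)
    if spec.kind == "sphere_pack":
        return _sphere_pack_fg(spec)
    if spec.kind == "two_phase_noise":
        rng = np.random.default_rng(spec.seed)
        field = ndimage.gaussian_filter(rng.standard_normal(spec.size_vox), 3.0)
        return field >= np.quantile(field, 1.0 - spec.volume_fraction)
    raise ValueError(f"phantom kind {spec.kind!r} has no binary ground truth")


def degrade(
    vol: GrayVolume, blur_sigma_vox: float, noise_sd: float, seed: int
) -> GrayVolume:
    """Gaussian blur then additive Gaussian noise, clipped to the input range."""
    if blur_sigma_vox < 0 or noise_sd < 0:
        raise ValueError("blur_sigma_vox and noise_sd must be nonnegative")
    data = vol.data.astype(np.float64, copy=True)
    lo, hi = float(data.min()), float(data.max())
    if blur_sigma_vox > 0:
        data = ndimage.gaussian_filter(data, blur_sigma_vox)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * rng.standard_normal(data.shape)
    data = np.clip(data, lo, hi)
    return GrayVolume(data, vol.voxel_size_um)


def mixed_rod_phantom(
    orientations_deg: list[float],
    size_vox: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    **spec_kwargs,
) -> GrayVolume:
    """Blocks of rod lattices at different elevations, stacked along axis 1.

    More orientation blocks means more orientation interfaces, hence lower
    elevation homogeneity; a single orientation reproduces a plain lattice.
    """
    if not orientations_deg:
        raise ValueError("need at least one orientation")
    n_blocks = len(orientations_deg)
    edges = np.linspace(0, size_vox[1], n_blocks + 1).round().astype(int)
    parts = []
    for i, elev in enumerate(orientations_deg):
        width = int(edges[i + 1] - edges[i])
        block_size = (size_vox[0], max(width, 3), size_vox[2])
        spec = PhantomSpec(
            kind="rod_lattice",
            size_vox=block_size,
            elevation_deg=elev,
            seed=seed + i,
            **spec_kwargs,
        )
        vol, _ = generate(spec)
        parts.append(vol.data[:, :width, :])
    data = np.concatenate(parts, axis=1)
    voxel = spec_kwargs.get("voxel_size_um", 27.8)
    return GrayVolume(data, voxel)
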