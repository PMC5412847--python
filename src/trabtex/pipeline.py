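"""End-to-end pipeline: binarize, split compartments, LBP, orientation, morphometry.

The pipeline mirrors a standard micro-CT workflow on an osteochondral
sample: the gray volume is segmented, optional plate/trabecular ROI masks
split the compartments (plate segmentation itself is manual and supplied as
masks), and each compartment is summarized by conventional morphometry and
by the pattern-based texture measures.  The report is a versioned JSON
document; all numeric fields carry units in their key names, and the run is
deterministic for a fixed configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from .binarization import BinarizationParams, adaptive_binarize, resolve_pre_threshold
from .lbp3d import analysis_mask, build_neighborhood, lbp_histogram, lbp_summary
from .morphometry import morphometry_summary
from .orientation import PatternValidity, elevation_field, orientation_summary
from .volume_io import BinaryVolume, read_mask, read_volume

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    volume_path: str
    voxel_size_um: float | None = None
    trab_mask_path: str | None = None
    plate_mask_path: str | None = None
    pre_threshold: float | None = None
    window_radius_px: int = 5
    window_shape: str = "ball"
    lbp_radius_vox: float = 1.0
    lbp_threshold: float | None = None  # defaults to the binarization pre-threshold
    min_markers: int = 3
    max_markers: int = 24
    bin_width_deg: float = 5.0
    out_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (
            ("volume", self.volume_path),
            ("trabecular mask", self.trab_mask_path),
            ("plate mask", self.plate_mask_path),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        BinarizationParams(self.pre_threshold, self.window_radius_px, self.window_shape)
        PatternValidity(self.min_markers, self.max_markers)
        if not self.lbp_radius_vox > 0:
            raise ValueError("lbp_radius_vox must be positive")
        if not self.bin_width_deg > 0:
            raise ValueError("bin_width_deg must be positive")


def _sha256(path) -> str:
    h = hashlib.sha256()
    p = Path(path)
    if p.is_dir():
        for f in sorted(p.iterdir()):
            h.update(f.read_bytes())
    else:
        h.update(p.read_bytes())
    return h.hexdigest()


def _compartment_report(vol, bin_vol, roi, nbhd, threshold, rules, bin_width, is_plate):
    morpho = morphometry_summary(bin_vol, roi, plate_roi=roi if is_plate else None)
    mask = analysis_mask(vol, nbhd, threshold, roi)
    lbp = texture = orient = None
    if mask.data.any():
        hist = lbp_histogram(vol, mask, nbhd)
        texture = lbp_summary(hist)
        field = elevation_field(vol, mask, nbhd, rules, bin_width)
        if field.valid_mask.any():
            orient = orientation_summary(field)
    report = {
        "bv_tv_fraction": morpho.bv_tv,
        "bs_bv_per_mm": morpho.bs_bv_per_mm,
        "tb_th_mm": morpho.tb_th_mm,
        "tb_sp_mm": morpho.tb_sp_mm,
        "tb_n_per_mm": morpho.tb_n_per_mm,
        "fractal_dim": morpho.fractal_dim,
        "plate_th_mm": morpho.plate_th_mm,
        "lbp_entropy_bits": texture.entropy_bits if texture else None,
        "lbp_n_distinct_patterns": texture.n_distinct_patterns if texture else None,
        "lbp_mean_marker_count": texture.mean_marker_count if texture else None,
        "mean_elevation_deg": orient.mean_elevation_deg if orient else None,
        "elevation_entropy_bits": orient.elevation_entropy_bits if orient else None,
        "elevation_homogeneity": orient.homogeneity if orient else None,
        "orientation_valid_fraction": orient.valid_fraction if orient else None,
        # reserved for values from external tools (not computed here)
        "external": {
            "smi": None,
            "connectivity": None,
            "connectivity_density_per_mm3": None,
            "trabecular_pattern_factor_per_mm": None,
            "degree_of_anisotropy": None,
        },
    }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config`` and return the report.

    If ``config.out_path`` is set the report is also written there as JSON
    (sorted keys, so reruns are byte-identical).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    vol = _stage("read volume", read_volume, config.volume_path, config.voxel_size_um)
    bin_params = BinarizationParams(
        config.pre_threshold, config.window_radius_px, config.window_shape
    )
    bin_vol = _stage("binarization", adaptive_binarize, vol, bin_params)
    nbhd = build_neighborhood(config.lbp_radius_vox)
    threshold = (
        config.lbp_threshold
        if config.lbp_threshold is not None
        else resolve_pre_threshold(vol, bin_params)
    )
    rules = PatternValidity(config.min_markers, config.max_markers)

    compartments = {}
    rois = {}
    if config.trab_mask_path:
        rois["trabecular"] = (read_mask(config.trab_mask_path, vol.voxel_size_um), False)
    if config.plate_mask_path:
        rois["plate"] = (read_mask(config.plate_mask_path, vol.voxel_size_um), True)
    if not rois:  # whole volume analyzed as a single trabecular compartment
        full = BinaryVolume(bin_vol.data | True, vol.voxel_size_um)
        rois["trabecular"] = (full, False)
    for name, (roi, is_plate) in rois.items():
        compartments[name] = _stage(
            f"analyze {name}",
            _compartment_report,
            vol, bin_vol, roi, nbhd, threshold, rules, config.bin_width_deg, is_plate,
        )

    from . import __version__

    hashes = {"volume": _sha256(config.volume_path)}
    for key, attr in (("trabecular_mask", "trab_mask_path"), ("plate_mask", "plate_mask_path")):
        p = getattr(config, attr)
        if p:
            hashes[key] = _sha256(p)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "parameters": dataclasses.asdict(config),
            "input_sha256": hashes,
            "units": {
                "lengths": "mm",
                "angles": "degrees",
                "entropy": "bits",
                "voxel_size": "um",
            },
        },
        "compartments": compartments,
    }
    if config.out_path:
        Path(config.out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
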