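"""Two-stage bone segmentation: fixed pre-threshold, then local adaptive threshold.

The segmentation first discards voxels below a fixed intensity (default 60
on an 8-bit scale), then keeps a remaining voxel only if its intensity
reaches the midrange ``(local_min + local_max) / 2`` of a window centred on
it (default: ball of radius 5 voxels).  Windows are clipped at the volume
boundary, i.e. min/max are taken over the intersection of the window with
the volume.  A voxel exactly at the midrange is foreground, which keeps
constant volumes stable under the rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import BinaryVolume, GrayVolume


@dataclasses.dataclass
class BinarizationParams:
    """Parameters of the two-stage segmentation.

    ``pre_threshold=None`` selects the default of 60 on the data's intensity
    scale: 60 for 8-bit and float data, and 60/255 of full scale for 16-bit
    data (the canonical value presumes an 8-bit reconstruction).
    """

    pre_threshold: float | None = None
    window_radius_px: int = 5
    window_shape: str = "ball"  # "ball" or "cube"

    def __post_init__(self) -> None:
        if self.window_radius_px < 1:
            raise ValueError("window_radius_px must be >= 1")
        if self.window_shape not in ("ball", "cube"):
            raise ValueError(f"unknown window_shape {self.window_shape!r}")


def resolve_pre_threshold(vol: GrayVolume, params: BinarizationParams) -> float:
    """Pre-threshold on the volume's own intensity scale."""
    if params.pre_threshold is not None:
        thr = float(params.pre_threshold)
        if np.issubdtype(vol.data.dtype, np.integer):
            info = np.iinfo(vol.data.dtype)
            if not (info.min <= thr <= info.max):
                raise ValueError(
                    f"pre_threshold {thr} outside representable range of {vol.data.dtype}"
                )
        return thr
    if vol.data.dtype == np.uint16:
        return 60.0 / 255.0 * 65535.0
    return 60.0


def ball_footprint(radius: int, ndim: int = 3) -> np.ndarray:
    """Boolean ball (disc in 2D) of given voxel radius, centre included."""
    grid = np.indices((2 * radius + 1,) * ndim) - radius
    return (grid ** 2).sum(axis=0) <= radius ** 2


def _footprint(params: BinarizationParams, ndim: int) -> np.ndarray:
    r = params.window_radius_px
    if params.window_shape == "cube":
        return np.ones((2 * r + 1,) * ndim, dtype=bool)
    return ball_footprint(r, ndim)


def pre_threshold_mask(vol: GrayVolume, params: BinarizationParams | None = None) -> BinaryVolume:
    """Voxels with intensity >= the fixed pre-threshold (inclusive)."""
    params = params or BinarizationParams()
    thr = resolve_pre_threshold(vol, params)
    return BinaryVolume(vol.data >= thr, vol.voxel_size_um)


def adaptive_binarize(
    vol: GrayVolume,
    params: BinarizationParams | None = None,
    slicewise: bool = False,
) -> BinaryVolume:
    """Local midrange thresholding of the voxels that pass the pre-threshold.

    With ``slicewise=True`` the window is a disc/square applied within each
    transverse slice (plane perpendicular to axis 2) instead of a 3D window.
    """
    params = params or BinarizationParams()
    data = vol.data.astype(np.float64, copy=False)
    fp = _footprint(params, 2 if slicewise else 3)
    if slicewise:
        fp = fp[:, :, None]  # in-plane window, one slice thick
    # mode="nearest" replicates edge voxels whose values already lie inside
    # the clipped window, so min/max equal the clipped-window min/max.
    local_min = ndimage.minimum_filter(data, footprint=fp, mode="nearest")
    local_max = ndimage.maximum_filter(data, footprint=fp, mode="nearest")
    midrange = (local_min + local_max) / 2.0
    pre = pre_threshold_mask(vol, params).data
    return BinaryVolume(pre & (data >= midrange), vol.voxel_size_um)
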