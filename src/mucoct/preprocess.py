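"""Denoising and tissue segmentation of grayscale micro-CT volumes.

Mirrors the two-step preparation used for contrast-enhanced biopsy scans:
edge-preserving denoising (non-local means; a median filter is kept as the
tested alternative) followed by thresholding of the bright, iodine-stained
tissue against the background.  Thresholds are explicit numbers for
reproducibility; Otsu's criterion is available as the unattended default.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means

from .errors import ConfigurationError, DegenerateHistogramError
from .volume_io import BinaryVolume, VoxelVolume

__all__ = ["denoise_nl", "denoise_median", "segment"]


def denoise_nl(
    vol: VoxelVolume,
    patch_radius: int = 2,
    search_radius: int = 5,
    strength: float = 12.0,
) -> VoxelVolume:
    """Non-local means denoising (3-D patches).

    ``strength`` is the filtering parameter *h* in intensity units — of the
    order of the noise standard deviation.  Defaults were chosen so that the
    render → denoise → segment chain recovers phantom occupancy with
    Dice ≥ 0.99 at tissue/background levels 200/50 and noise σ up to 20.
    """
    if patch_radius < 1 or search_radius < 1:
        raise ConfigurationError("patch_radius and search_radius must be >= 1 voxel")
    if strength <= 0:
        raise ConfigurationError("strength must be > 0")
    values = np.asarray(vol.values, dtype=np.float32)
    out = denoise_nl_means(
        values,
        patch_size=2 * patch_radius + 1,
        patch_distance=search_radius,
        h=strength,
        fast_mode=True,
        preserve_range=True,
    ).astype(np.float32)
    return VoxelVolume(out, vol.spacing, vol.origin)


def denoise_median(vol: VoxelVolume, radius: int = 1) -> VoxelVolume:
    """Cubic rank filter: each voxel becomes the median of its
    (2·radius+1)³ neighbourhood (edges handled by reflection)."""
    if radius < 1:
        raise ConfigurationError("radius must be >= 1 voxel")
    out = ndimage.median_filter(vol.values, size=2 * radius + 1, mode="reflect")
    return VoxelVolume(out, vol.spacing, vol.origin)


def segment(
    vol: VoxelVolume,
    threshold: float | str = "auto",
    keep_largest: bool = False,
    polarity: str = "bright",
) -> BinaryVolume:
    """Threshold tissue from background.

    ``threshold="auto"`` uses Otsu's criterion; a number reproduces the
    manual-threshold workflow exactly.  ``polarity="bright"`` (default,
    matching iodine-stained tissue) takes values ≥ threshold as tissue;
    ``"dark"`` inverts that.  ``keep_largest`` retains only the largest
    26-connected tissue component.
    """
    values = np.asarray(vol.values)
    if threshold == "auto":
        if values.max() == values.min():
            raise DegenerateHistogramError(
                "automatic thresholding impossible: volume has a single intensity level"
            )
        thr = float(threshold_otsu(values))
    else:
        thr = float(threshold)
    if polarity == "bright":
        occ = values >= thr
    elif polarity == "dark":
        occ = values <= thr
    else:
        raise ConfigurationError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    if keep_largest and occ.any():
        labels, n = ndimage.label(occ, structure=np.ones((3, 3, 3), dtype=bool))
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            occ = labels == counts.argmax()
    return BinaryVolume(occ, vol.spacing, vol.origin)
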