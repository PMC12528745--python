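"""MRI preprocessing: skull strip, [0,1] scaling, in-plane resample, equalization.

The chain is fixed as mask -> normalize -> resample -> equalize.  The
skull mask is computed once on the first channel (T1) and shared across
modalities, which assumes co-registration (true for BraTS-style inputs
and for the synthetic generator by construction).  Normalization min-max
scales brain voxels only, leaving background at exactly 0; equalization
is a global 256-bin histogram equalization restricted to brain voxels, so
rank order among brain intensities is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

__all__ = ["PreprocessConfig", "skull_strip_mask", "preprocess_volume"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    target_inplane: int = 128
    equalize: bool = True
    equalize_bins: int = 256

    def __post_init__(self) -> None:
        if self.target_inplane < 16 or self.target_inplane % 16 != 0:
            raise ValueError(
                f"target_inplane must be >= 16 and divisible by 16, "
                f"got {self.target_inplane}"
            )


def skull_strip_mask(volume: np.ndarray) -> np.ndarray:
    """Binary brain mask from a single-channel volume.

    Otsu threshold, largest 26-connected foreground component, binary
    closing (radius 2), hole filling.  The result is one connected
    component.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    if np.ptp(volume) == 0:
        raise ValueError("cannot skull-strip a constant volume")

    foreground = volume > threshold_otsu(volume)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(foreground, structure=structure)
    if n == 0:
        raise ValueError("no foreground voxels above the Otsu threshold")
    sizes = ndimage.sum_labels(foreground, labeled, index=np.arange(1, n + 1))
    mask = labeled == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(mask, structure=ball(2))
    mask = ndimage.binary_fill_holes(mask)
    return mask


def _equalize_brain(channel: np.ndarray, mask: np.ndarray, bins: int) -> np.ndarray:
    values = channel[mask]
    if np.ptp(values) == 0:  # degenerate channel: nothing to equalize
        return channel
    hist, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist).astype(float)
    if cdf[-1] == 0:
        return channel
    cdf /= cdf[-1]
    out = channel.copy()
    bin_idx = np.clip((values * bins).astype(int), 0, bins - 1)
    out[mask] = cdf[bin_idx]
    return out


def preprocess_volume(
    volume: np.ndarray, cfg: PreprocessConfig | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Preprocess a 4-channel volume; returns (volume, brain_mask).

    Output in-plane shape is (target, target); the depth axis is never
    resampled.  All channels end up in [0, 1] with background at 0.
    Degenerate (constant-brain) channels map to all-zeros with a warning
    rather than failing.
    """
    cfg = cfg or PreprocessConfig()
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[0] != 4:
        raise ValueError(f"expected shape (4, X, Y, Z), got {volume.shape}")

    mask = skull_strip_mask(volume[0])

    normalized = np.zeros_like(volume)
    for ch in range(4):
        brain_vals = volume[ch][mask]
        lo, hi = brain_vals.min(), brain_vals.max()
        if hi - lo <= 0:
            logger.warning(
                "channel %d is constant over the brain mask; mapped to zeros", ch
            )
            continue
        normalized[ch][mask] = (volume[ch][mask] - lo) / (hi - lo)

    # trilinear in-plane resample; depth (N) kept as-is
    in_x, in_y, depth = volume.shape[1:]
    zoom = (cfg.target_inplane / in_x, cfg.target_inplane / in_y, 1.0)
    if zoom[:2] != (1.0, 1.0):
        resampled = np.stack(
            [ndimage.zoom(normalized[ch], zoom, order=1) for ch in range(4)]
        )
        mask = ndimage.zoom(mask.astype(float), zoom, order=1) > 0.5
    else:
        resampled = normalized
    resampled = np.clip(resampled, 0.0, 1.0)
    resampled *= mask

    if cfg.equalize:
        resampled = np.stack(
            [
                _equalize_brain(resampled[ch], mask, cfg.equalize_bins)
                for ch in range(4)
            ]
        )
    assert resampled.shape[1:3] == (cfg.target_inplane, cfg.target_inplane)
    assert resampled.shape[3] == depth
    return resampled, mask
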