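"""Patch intensity normalization and gray-level quantization.

A cropped two-channel lesion patch (T2W-like and ADC-like intensities) is
min-max normalized to [0, 255] per patch and discretized into ``n_levels``
gray-level bins (default 64, levels 1..64) before co-occurrence extraction.
Per-patch normalization makes the pipeline invariant to affine rescaling of
the raw scanner intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumetricPatch", "QuantizedVolume", "normalize_0_255", "quantize",
           "quantize_patch"]

CHANNEL_NAMES = ("t2w", "adc")


@dataclass
class VolumetricPatch:
    """Two-channel 3D intensity patch for one lesion, indexed (i, j, k)."""

    lesion_id: str
    t2w: np.ndarray
    adc: np.ndarray

    def __post_init__(self):
        self.t2w = np.asarray(self.t2w, dtype=np.float64)
        self.adc = np.asarray(self.adc, dtype=np.float64)
        if self.t2w.ndim != 3 or self.adc.ndim != 3:
            raise ValueError("patch channels must be 3-D arrays")
        if self.t2w.shape != self.adc.shape:
            raise ValueError("patch channels must share a shape")
        if min(self.t2w.shape) < 2:
            raise ValueError("all patch dimensions must be >= 2")
        if not (np.isfinite(self.t2w).all() and np.isfinite(self.adc).all()):
            raise ValueError("patch intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2w.shape

    @property
    def channels(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.t2w, self.adc)


@dataclass
class QuantizedVolume:
    """3D integer gray-level volume with values in 1..n_levels."""

    levels: np.ndarray
    n_levels: int = 64

    def __post_init__(self):
        self.levels = np.asarray(self.levels)
        if self.levels.size and (self.levels.min() < 1 or self.levels.max() > self.n_levels):
            raise ValueError(f"levels must lie in [1, {self.n_levels}]")


def normalize_0_255(channel: np.ndarray) -> np.ndarray:
    """Affine min-max map of a finite array onto [0, 255].

    A constant input maps to all zeros (degenerate convention, avoids
    division by zero).
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty array")
    if not np.isfinite(arr).all():
        raise ValueError("input must be finite")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    # clip guards float roundoff at the top of the range
    return np.clip((arr - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def quantize(channel_0_255: np.ndarray, n_levels: int = 64) -> QuantizedVolume:
    """Discretize values in [0, 255] into gray levels 1..n_levels.

    level = floor(v * n_levels / 256) + 1, clamped to [1, n_levels]; the map
    is monotone non-decreasing in v with uniform bin edges on [0, 256).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = np.asarray(channel_0_255, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot quantize an empty array")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("values must lie in [0, 255]")
    levels = np.floor(arr * n_levels / 256.0).astype(np.int64) + 1
    return QuantizedVolume(np.clip(levels, 1, n_levels), n_levels)


def quantize_patch(patch: VolumetricPatch, n_levels: int = 64) -> tuple[QuantizedVolume, QuantizedVolume]:
    """Normalize then quantize both channels of a patch."""
    return tuple(quantize(normalize_0_255(ch), n_levels) for ch in patch.channels)
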