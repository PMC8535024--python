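"""Haralick descriptors of normalized co-occurrence matrices.

Four statistics per directional matrix P (levels x, y = 1..L):

* contrast     = sum P(x,y) (x-y)^2
* correlation  = sum P(x,y) (x-mu_x)(y-mu_y) / (sigma_x sigma_y)
* homogeneity  = sum P(x,y) / (1 + (x-y)^2)   (inverse difference moment)
* energy       = sum P(x,y)^2                  (angular second moment)

Correlation is defined as 1 when sigma_x sigma_y = 0 (a point-mass matrix
is perfectly correlated). Over 13 directions and 2 modalities this yields
the 104-dimensional vector consumed by the random-forest baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .glcm import GLCMStack, _offset_label, canonical_directions
from .preprocess import CHANNEL_NAMES

__all__ = ["haralick4", "feature_vector", "FeatureVector", "HaralickTransformer",
           "DESCRIPTOR_NAMES", "feature_names"]

DESCRIPTOR_NAMES = ("contrast", "correlation", "homogeneity", "energy")


def haralick4(P: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, correlation, homogeneity, energy) of a normalized GLCM."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    if (P < 0).any():
        raise ValueError("P must be non-negative")
    total = P.sum()
    if total == 0:
        raise ValueError("all-zero matrix has no pairs")
    if abs(total - 1.0) > 1e-9:
        P = P / total
    L = P.shape[0]
    lv = np.arange(1, L + 1, dtype=np.float64)
    diff2 = (lv[:, None] - lv[None, :]) ** 2
    contrast = float((P * diff2).sum())
    homogeneity = float((P / (1.0 + diff2)).sum())
    energy = float((P * P).sum())
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ lv)
    mu_y = float(py @ lv)
    var_x = float(px @ lv**2) - mu_x**2
    var_y = float(py @ lv**2) - mu_y**2
    sxsy = np.sqrt(max(var_x, 0.0) * max(var_y, 0.0))
    if sxsy == 0:
        correlation = 1.0
    else:
        exy = float(lv @ P @ lv)
        correlation = (exy - mu_x * mu_y) / sxsy
    return contrast, correlation, homogeneity, energy


@dataclass
class FeatureVector:
    """Named Haralick descriptor vector for one lesion (104 at defaults)."""

    values: np.ndarray
    names: list[str]
    lesion_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")
        if not np.isfinite(self.values).all():
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.lesion_id)


def feature_names(directions=None, channel_names: tuple[str, ...] = CHANNEL_NAMES) -> list[str]:
    """Fixed (modality, direction, descriptor)-ordered feature names."""
    directions = canonical_directions() if directions is None else tuple(directions)
    return [f"{mod}_{_offset_label(d)}_{desc}"
            for mod in channel_names
            for d in directions
            for desc in DESCRIPTOR_NAMES]


def feature_vector(stack: GLCMStack) -> FeatureVector:
    """Concatenate the four descriptors of every stack channel.

    Channels with a zero pair count are an error (the descriptors are
    undefined without pairs); the offending channel is named.
    """
    names = []
    values = []
    channel_names = stack.channel_names()
    for ch in range(stack.n_channels):
        if stack.pair_counts[ch] == 0:
            raise ValueError(f"channel {channel_names[ch]} has no voxel pairs")
        stats = haralick4(stack.matrices[ch])
        for desc, v in zip(DESCRIPTOR_NAMES, stats):
            names.append(f"{channel_names[ch]}_{desc}")
            values.append(v)
    return FeatureVector(np.array(values), names, lesion_id=stack.lesion_id)


class HaralickTransformer(TransformerMixin, BaseEstimator):
    """Map GLCM stacks to the handcrafted Haralick feature table.

    ``transform`` accepts a sequence of :class:`GLCMStack` and returns a
    DataFrame with one named column per (modality, direction, descriptor),
    indexed by lesion_id when available.
    """

    def fit(self, X, y=None):
        self.feature_names_ = feature_names()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = [feature_vector(stack).to_series() for stack in X]
        return pd.DataFrame(rows)
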