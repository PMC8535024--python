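"""3D gray-level co-occurrence matrices along 13 neighbor directions.

For a quantized volume f, the co-occurrence matrix at displacement
d = (di, dj, dk) counts ordered voxel pairs::

    GLCM(x, y) = #{ (i, j, k) : f(i, j, k) = x and f(i+di, j+dj, k+dk) = y }

with pairs whose destination falls outside the volume skipped. The 26
nonzero offsets in {-1, 0, 1}^3 fall into 13 equivalence classes under
d ~ -d; one representative per class (canonical half-space: first nonzero
component +1) gives the 13 directions. One matrix per direction per
modality yields the 26-channel stack consumed by the classifier.

Accumulation is asymmetric (ordered pairs along +d only) by default; the
``symmetric`` flag adds the transpose, the common Haralick convention.
Matrices are normalized to probabilities by default so the stack is
invariant to patch size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import CHANNEL_NAMES, QuantizedVolume, VolumetricPatch, quantize_patch

__all__ = ["canonical_directions", "glcm_single", "glcm_stack", "GLCMStack",
           "GLCMTransformer", "N_DIRECTIONS"]

N_DIRECTIONS = 13


def canonical_directions() -> tuple[tuple[int, int, int], ...]:
    """The 13 canonical displacement triples, in lexicographic order.

    Every nonzero offset in {-1, 0, 1}^3 is equivalent to its negation
    (pair reversal transposes the matrix); the representative kept is the
    one whose first nonzero component is +1.
    """
    dirs = []
    for d in product((-1, 0, 1), repeat=3):
        nz = [c for c in d if c != 0]
        if nz and nz[0] == 1:
            dirs.append(d)
    return tuple(sorted(dirs))


def _as_levels(volume) -> tuple[np.ndarray, int]:
    if isinstance(volume, QuantizedVolume):
        return volume.levels, volume.n_levels
    raise TypeError("volume must be a QuantizedVolume")


def glcm_single(volume: QuantizedVolume, offset: tuple[int, int, int]) -> tuple[np.ndarray, int]:
    """Raw co-occurrence counts for one displacement.

    Returns ``(matrix, pair_count)`` where matrix[x-1, y-1] counts pairs
    with source level x and destination level y. The pair count equals
    (I-|di|)(J-|dj|)(K-|dk|); a volume too small along a displaced axis
    yields an all-zero matrix with pair count 0.
    """
    levels, n_levels = _as_levels(volume)
    offset = tuple(int(d) for d in offset)
    if len(offset) != 3 or all(d == 0 for d in offset):
        raise ValueError("offset must be a nonzero displacement triple")
    src_sl, dst_sl = [], []
    for d, size in zip(offset, levels.shape):
        if size - abs(d) <= 0:
            return np.zeros((n_levels, n_levels), dtype=np.int64), 0
        if d >= 0:
            src_sl.append(slice(0, size - d))
            dst_sl.append(slice(d, size))
        else:
            src_sl.append(slice(-d, size))
            dst_sl.append(slice(0, size + d))
    src = levels[tuple(src_sl)].ravel()
    dst = levels[tuple(dst_sl)].ravel()
    flat = (src - 1) * n_levels + (dst - 1)
    mat = np.bincount(flat, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return mat.astype(np.int64), int(src.size)


@dataclass
class GLCMStack:
    """26-channel stack of co-occurrence matrices (13 directions x 2 modalities).

    Channel order is [t2w dir 1..13, adc dir 1..13] with directions in
    canonical lexicographic order.
    """

    matrices: np.ndarray            # (n_channels, n_levels, n_levels)
    pair_counts: np.ndarray         # (n_channels,)
    normalized: bool
    n_levels: int
    directions: tuple[tuple[int, int, int], ...]
    lesion_id: str | None = None

    def __post_init__(self):
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (n_channels, L, L)")
        if (self.matrices < 0).any():
            raise ValueError("co-occurrence entries must be non-negative")
        if self.normalized:
            sums = self.matrices.sum(axis=(1, 2))
            ok = (self.pair_counts == 0) | (np.abs(sums - 1.0) <= 1e-9)
            if not ok.all():
                raise ValueError("normalized channels must each sum to 1")

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[0]

    def channel_names(self) -> list[str]:
        names = []
        for mod in CHANNEL_NAMES:
            for d in self.directions:
                names.append(f"{mod}_{_offset_label(d)}")
        return names


_OFFSET_CHAR = {-1: "m", 0: "0", 1: "p"}


def _offset_label(d: tuple[int, int, int]) -> str:
    return "d" + "".join(_OFFSET_CHAR[c] for c in d)


def glcm_stack(patch: VolumetricPatch,
               directions: tuple[tuple[int, int, int], ...] | None = None,
               n_levels: int = 64,
               normalize: bool = True,
               symmetric: bool = False) -> GLCMStack:
    """Normalize, quantize, and extract the full directional GLCM stack.

    With ``symmetric`` each matrix is replaced by M + M^T (counting each
    pair in both orders) before probability normalization.
    """
    directions = canonical_directions() if directions is None else tuple(directions)
    quantized = quantize_patch(patch, n_levels)
    mats = np.empty((2 * len(directions), n_levels, n_levels), dtype=np.float64)
    counts = np.empty(2 * len(directions), dtype=np.int64)
    ch = 0
    for vol in quantized:
        for d in directions:
            m, c = glcm_single(vol, d)
            m = m.astype(np.float64)
            if symmetric:
                m = m + m.T
                c = 2 * c
            if normalize and c > 0:
                m /= c
            mats[ch] = m
            counts[ch] = c
            ch += 1
    return GLCMStack(mats, counts, normalized=normalize, n_levels=n_levels,
                     directions=directions, lesion_id=patch.lesion_id)


class GLCMTransformer(TransformerMixin, BaseEstimator):
    """Map lesion patches to stacked directional GLCM arrays.

    Parameters
    ----------
    n_levels : int
        Gray-level bin count (levels 1..n_levels).
    normalize : bool
        Divide each matrix by its pair count (probability normalization).
    symmetric : bool
        Add the transposed counts before normalization.

    ``transform`` accepts a sequence of :class:`VolumetricPatch` and returns
    a float32 array of shape ``(n_lesions, 26, n_levels, n_levels)``.
    """

    def __init__(self, n_levels: int = 64, normalize: bool = True, symmetric: bool = False):
        self.n_levels = n_levels
        self.normalize = normalize
        self.symmetric = symmetric

    def fit(self, X, y=None):
        self.directions_ = canonical_directions()
        self.n_channels_ = 2 * len(self.directions_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "directions_"):
            self.fit(X)
        out = np.empty((len(X), self.n_channels_, self.n_levels, self.n_levels),
                       dtype=np.float32)
        for i, patch in enumerate(X):
            out[i] = glcm_stack(patch, self.directions_, self.n_levels,
                                self.normalize, self.symmetric).matrices
        return out

    def transform_stacks(self, X) -> list[GLCMStack]:
        """Like ``transform`` but keeping full per-lesion stack metadata."""
        if not hasattr(self, "directions_"):
            self.fit(X)
        return [glcm_stack(p, self.directions_, self.n_levels,
                           self.normalize, self.symmetric) for p in X]
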