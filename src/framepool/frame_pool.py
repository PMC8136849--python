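"""Frame pooling: masked global max/average pooling within reading frames.

The feature map produced by the convolutional stack is first reversed along
the position axis so that index 0 is the 3'-most position.  Because the 3'
end of a 5'UTR abuts the canonical start codon, positions at equal distance
mod 3 from the 3' end always share a reading-frame class, for any sequence
length — this 3'-anchored reversal is what makes the pooled representation
length-agnostic.  After reversal the map is sliced into three interleaved
frame slices (reversed indices j, j+3, j+6, ... for slice j), and each slice
is pooled with masked global max and masked global average pooling.

Layout of the pooled vector (F filters): ``[max f0 | max f1 | max f2 |
avg f0 | avg f1 | avg f2]``, each block of length F, total 6F.  Positions
invalidated by the batch mask are excluded from both statistics (not merely
down-weighted); a frame slice with no valid position pools to 0 for both
statistics, matching the padding value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvFeatureMap",
    "FramePooledVector",
    "frame_slices",
    "frame_pool",
    "frame_pool_oracle",
    "masked_frame_pool_batch",
]


@dataclass(frozen=True)
class ConvFeatureMap:
    """An ``L x F`` feature map (positions 5'->3') with a validity mask."""

    values: np.ndarray  # (L, F)
    mask: np.ndarray | None = None  # (L,) bool; None = all valid

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got {self.values.shape}")
        if self.mask is not None and self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask length must equal position count")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_filters(self) -> int:
        return self.values.shape[1]

    def mask_or_full(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.n_positions, dtype=bool)
        return self.mask.astype(bool)


@dataclass(frozen=True)
class FramePooledVector:
    """Length-6F pooled vector: [max f0|f1|f2 | avg f0|f1|f2]."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 1 or self.values.shape[0] % 6 != 0:
            raise ValueError(f"expected a 6F vector, got shape {self.values.shape}")

    @property
    def n_filters(self) -> int:
        return self.values.shape[0] // 6


def frame_slices(fmap: ConvFeatureMap) -> tuple[ConvFeatureMap, ConvFeatureMap, ConvFeatureMap]:
    """Reverse the map along the position axis and slice by frame.

    Slice ``j`` receives reversed indices ``j, j+3, j+6, ...``; the position
    at original index ``i`` lands in slice ``(L - 1 - i) % 3``.  Masks are
    sliced identically.
    """
    rev = fmap.values[::-1]
    rev_mask = fmap.mask_or_full()[::-1]
    return tuple(
        ConvFeatureMap(values=rev[j::3].copy(), mask=rev_mask[j::3].copy())
        for j in range(3)
    )


def frame_pool(fmap: ConvFeatureMap) -> FramePooledVector:
    """Masked max/average pooling per frame slice, concatenated to 6F."""
    pooled = masked_frame_pool_batch(
        fmap.values[None], fmap.mask_or_full()[None]
    )[0]
    return FramePooledVector(values=pooled)


def frame_pool_oracle(fmap: ConvFeatureMap) -> FramePooledVector:
    """Brute-force reference for :func:`frame_pool`.

    Walks every position with explicit Python loops; no slicing or
    vectorization.  Kept as an independent cross-check of the batched kernel.
    """
    L, F = fmap.values.shape
    mask = fmap.mask_or_full()
    members: list[list[int]] = [[], [], []]
    for i in range(L):
        if mask[i]:
            members[(L - 1 - i) % 3].append(i)
    maxes = np.zeros((3, F))
    avgs = np.zeros((3, F))
    for j in range(3):
        for f in range(F):
            vals = [float(fmap.values[i, f]) for i in members[j]]
            if vals:
                maxes[j, f] = max(vals)
                avgs[j, f] = sum(vals) / len(vals)
    return FramePooledVector(values=np.concatenate([maxes.ravel(), avgs.ravel()]))


def masked_frame_pool_batch(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Batched frame pooling kernel: ``(B, L, F), (B, L) -> (B, 6F)``.

    Requires the batch to be 3'-aligned (as produced by
    :func:`framepool.seq_core.pad_batch`), so one reversal serves all rows.
    """
    B, L, F = values.shape
    rev = values[:, ::-1, :]
    rev_mask = mask[:, ::-1].astype(bool)
    out = np.empty((B, 6 * F), dtype=values.dtype)
    for j in range(3):
        sl = rev[:, j::3, :]  # (B, Lj, F)
        m = rev_mask[:, j::3]  # (B, Lj)
        n_valid = m.sum(axis=1)  # (B,)
        neg_inf = np.array(-np.inf, dtype=values.dtype)
        mx = np.where(m[:, :, None], sl, neg_inf).max(axis=1, initial=-np.inf)
        mx = np.where(n_valid[:, None] > 0, mx, 0.0)
        sm = np.where(m[:, :, None], sl, 0.0).sum(axis=1)
        denom = np.maximum(n_valid, 1)[:, None]
        av = np.where(n_valid[:, None] > 0, sm / denom, 0.0)
        out[:, j * F : (j + 1) * F] = mx
        out[:, (3 + j) * F : (4 + j) * F] = av
    return out
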