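"""Pixel-level fusion of registered slice sequences.

Two pairwise rules plus a one-pass reference variant:

* ``direct``: in the overlap of two frames the fused value is the plain
  average (f₁ + f₂)/2; outside the overlap each frame fills its own region.
* ``weighted``: gradual-in/gradual-out blending — across the overlap the
  weights ramp linearly along x, ω₁ = (x₂ − xᵢ)/(x₂ − x₁), ω₂ = 1 − ω₁,
  where x₁/x₂ are the overlap's low/high x-bounds and the first image owns
  the low-x side.  ω₁ + ω₂ = 1 with both in [0, 1] everywhere.
* ``mean``: mask-weighted per-pixel mean over all frames in one pass — the
  statistically symmetric variant, recommended for near-fully-overlapping
  registered fMRI slices.

Sequences with more than two frames are folded in temporal order:
F ← rule(F, warped[i]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sequence_registration import RegisteredSequence

FUSION_METHODS = ("weighted", "direct", "mean")


@dataclass
class FusedSlice:
    """A fused 2D slice with its per-pixel support.

    ``support`` counts contributing frames per pixel; the fused value is a
    convex combination of the contributors, so it lies within their
    min/max envelope.
    """

    data: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.support = np.asarray(self.support, dtype=float)
        if self.data.shape != self.support.shape:
            raise ValueError("data and support must share a shape")


def _check_shapes(f1, f2, mask1, mask2):
    shapes = {np.shape(a) for a in (f1, f2, mask1, mask2)}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among fusion inputs: {shapes}")


def direct_average(
    f1: np.ndarray, f2: np.ndarray,
    mask1: Optional[np.ndarray] = None, mask2: Optional[np.ndarray] = None,
) -> FusedSlice:
    """Direct-average fusion of two frames.

    f₁-only regions keep f₁, f₂-only keep f₂, the overlap averages, and
    pixels covered by neither are 0 with support 0.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    mask1 = np.ones_like(f1) if mask1 is None else np.asarray(mask1, float)
    mask2 = np.ones_like(f2) if mask2 is None else np.asarray(mask2, float)
    _check_shapes(f1, f2, mask1, mask2)
    m1 = mask1 > 0
    m2 = mask2 > 0
    out = np.zeros_like(f1)
    out[m1 & ~m2] = f1[m1 & ~m2]
    out[m2 & ~m1] = f2[m2 & ~m1]
    both = m1 & m2
    out[both] = 0.5 * (f1[both] + f2[both])
    return FusedSlice(data=out, support=m1.astype(float) + m2.astype(float))


def weighted_average(
    f1: np.ndarray, f2: np.ndarray,
    mask1: Optional[np.ndarray] = None, mask2: Optional[np.ndarray] = None,
) -> FusedSlice:
    """Gradual-in/gradual-out weighted fusion of two frames.

    In the overlap the weights ramp linearly with the x-coordinate (first
    array axis): ω₁ = (x₂ − xᵢ)/(x₂ − x₁) so image 1 dominates the low-x
    boundary and fades out toward x₂.  A single-column overlap (x₁ = x₂)
    degenerates to equal weights 0.5/0.5.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    mask1 = np.ones_like(f1) if mask1 is None else np.asarray(mask1, float)
    mask2 = np.ones_like(f2) if mask2 is None else np.asarray(mask2, float)
    _check_shapes(f1, f2, mask1, mask2)
    m1 = mask1 > 0
    m2 = mask2 > 0
    out = np.zeros_like(f1)
    out[m1 & ~m2] = f1[m1 & ~m2]
    out[m2 & ~m1] = f2[m2 & ~m1]
    both = m1 & m2
    if both.any():
        rows = np.nonzero(both.any(axis=1))[0]
        x1, x2 = rows.min(), rows.max()
        if x2 > x1:
            xi = np.arange(f1.shape[0], dtype=float)
            w1 = (x2 - xi) / (x2 - x1)
            w1 = np.clip(w1, 0.0, 1.0)[:, None]
        else:
            w1 = np.full((f1.shape[0], 1), 0.5)
        blend = w1 * f1 + (1.0 - w1) * f2
        out[both] = blend[both]
    return FusedSlice(data=out, support=m1.astype(float) + m2.astype(float))


def fuse_sequence(reg: RegisteredSequence, method: str = "weighted") -> FusedSlice:
    """Fuse all usable frames of a registered sequence into one slice.

    ``weighted`` and ``direct`` fold pairwise in temporal order starting
    from the first usable frame; ``mean`` computes the mask-weighted
    per-pixel mean in one pass.  Excluded frames never contribute.  Pixels
    no frame covered are 0 with support 0.
    """
    if method not in FUSION_METHODS:
        raise ValueError(f"unknown fusion method {method!r}")
    usable = reg.usable
    if not usable:
        raise ValueError("no usable frames to fuse")
    frames = [reg.warped[i] for i in usable]
    masks = [reg.masks[i] for i in usable]

    support = np.sum(masks, axis=0)
    if method == "mean":
        weighted_sum = np.sum([f * m for f, m in zip(frames, masks)], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            data = np.where(support > 0, weighted_sum / np.maximum(support, 1e-12), 0.0)
        return FusedSlice(data=data, support=support)

    rule = weighted_average if method == "weighted" else direct_average
    acc = frames[0]
    acc_mask = masks[0] > 0
    for f, m in zip(frames[1:], masks[1:]):
        fused = rule(acc, f, acc_mask.astype(float), m)
        acc = fused.data
        acc_mask = acc_mask | (m > 0)
    return FusedSlice(data=acc, support=support)
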