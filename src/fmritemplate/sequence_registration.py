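"""Sequential registration of a slice sequence to its first frame.

Adjacent time points of an fMRI slice sequence are far more similar than
distant ones, so each consecutive pair (i, i+1) is registered directly
(features → descriptors → ratio matching → RANSAC) and the pairwise
transforms are chained:

    cumulative[i] = T₁ × T₂ × … × Tᵢ

maps frame i into the coordinate system of frame 0 (the reference).  Frames
whose pairwise estimation fails are recorded with an identity transform and
excluded from fusion; the chain continues through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io_nifti import SliceSequence
from .scale_space_features import FeatureParams, detect_features_with_pyramid
from .gloh_descriptor import describe_all
from .matching import match_features, DEFAULT_RATIO_THRESHOLD
from .transform_estimation import (
    DEFAULT_CRITICAL_FRACTION,
    DEFAULT_MAX_ITERATIONS,
    DEFAULT_M,
    DEFAULT_P,
    DEFAULT_TR,
    PlanarTransform,
    RansacFailure,
    ransac,
)


class RegistrationError(RuntimeError):
    """Raised when a whole layer cannot be registered."""


@dataclass
class RegistrationParams:
    """Parameter bundle for per-layer sequence registration."""

    features: FeatureParams = field(default_factory=FeatureParams)
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    tr: float = DEFAULT_TR
    p: float = DEFAULT_P
    m: int = DEFAULT_M
    max_iterations: int = DEFAULT_MAX_ITERATIONS
    critical_fraction: float = DEFAULT_CRITICAL_FRACTION
    model: str = "homography"
    seed: int = 0


@dataclass
class RegisteredSequence:
    """A slice sequence warped into its first frame's pixel grid."""

    layer_index: int
    warped: List[np.ndarray]
    masks: List[np.ndarray]
    cumulative: List[PlanarTransform]
    pairwise: List[PlanarTransform]
    excluded: List[int]               # frame_ids whose estimation failed
    frame_ids: np.ndarray
    inlier_counts: List[int] = field(default_factory=list)
    match_counts: List[int] = field(default_factory=list)

    @property
    def usable(self) -> List[int]:
        """Positional indices of frames that enter fusion."""
        excluded = set(self.excluded)
        return [i for i, fid in enumerate(self.frame_ids)
                if fid not in excluded]


def register_adjacent_pairs(
    seq: SliceSequence,
    params: Optional[RegistrationParams] = None,
) -> Tuple[List[PlanarTransform], List[int], List[int], List[int]]:
    """Estimate the transform of every consecutive frame pair.

    Element i maps frame i+1 pixel coordinates into frame i.  Features are
    detected once per frame and reused for both pairs that touch it.  On
    estimation failure (too few matches, no RANSAC consensus) the identity
    is recorded and frame i+1 is flagged excluded.

    Returns (pairwise transforms, excluded frame_ids, inlier counts,
    match counts).
    """
    if params is None:
        params = RegistrationParams()
    if seq.frame_count < 2:
        raise ValueError("need at least 2 frames to register")

    cache = {}

    def features_of(i: int):
        if i not in cache:
            kps, gp = detect_features_with_pyramid(seq.frames[i],
                                                   params.features)
            cache[i] = (kps, describe_all(gp, kps))
        return cache[i]

    pairwise: List[PlanarTransform] = []
    excluded: List[int] = []
    inlier_counts: List[int] = []
    match_counts: List[int] = []
    for i in range(seq.frame_count - 1):
        kps_ref, desc_ref = features_of(i)
        kps_mov, desc_mov = features_of(i + 1)
        matches = match_features(desc_ref, desc_mov,
                                 threshold=params.ratio_threshold)
        match_counts.append(len(matches))
        try:
            if len(matches) < params.m:
                raise RansacFailure("too few matches")
            result = ransac(
                matches, kps_ref, kps_mov,
                tr=params.tr, p=params.p, m=params.m,
                max_iterations=params.max_iterations,
                critical_fraction=params.critical_fraction,
                model=params.model,
                seed=(params.seed + i) % (2 ** 31),
            )
            pairwise.append(result.model)
            inlier_counts.append(len(result.inliers))
        except RansacFailure:
            pairwise.append(PlanarTransform.identity())
            excluded.append(int(seq.frame_ids[i + 1]))
            inlier_counts.append(0)
        # free features of the frame that is no longer needed
        cache.pop(i, None)
    return pairwise, excluded, inlier_counts, match_counts


def compose_to_reference(
    pairwise: List[PlanarTransform],
) -> List[PlanarTransform]:
    """Chain pairwise transforms back to the first frame.

    cumulative[0] is the identity; cumulative[i] = P₀·P₁·…·Pᵢ₋₁ where Pⱼ
    maps frame j+1 into frame j — so cumulative[i] maps frame i into
    frame 0.
    """
    cumulative = [PlanarTransform.identity()]
    for p in pairwise:
        cumulative.append(cumulative[-1] @ p)
    return cumulative


def warp_slice(
    frame: np.ndarray,
    transform: PlanarTransform,
    out_shape: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Warp a frame into the reference grid by inverse bilinear sampling.

    Every output pixel (x, y) samples the source at transform⁻¹·(x, y, 1)ᵀ.
    Samples falling outside the source get value 0 and mask 0; in-bounds
    samples get mask 1.
    """
    frame = np.asarray(frame, dtype=float)
    if out_shape is None:
        out_shape = frame.shape
    h, w = out_shape
    xs, ys = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = transform.inverse().apply(pts)
    sx = src[:, 0].reshape(out_shape)
    sy = src[:, 1].reshape(out_shape)
    inside = (
        (sx >= 0) & (sx <= frame.shape[0] - 1)
        & (sy >= 0) & (sy <= frame.shape[1] - 1)
    )
    warped = ndimage.map_coordinates(
        frame, [sx, sy], order=1, mode="constant", cval=0.0, prefilter=False
    )
    warped = np.where(inside, warped, 0.0)
    return warped, inside.astype(float)


def register_sequence(
    seq: SliceSequence,
    params: Optional[RegistrationParams] = None,
) -> RegisteredSequence:
    """Register a whole slice sequence into its first frame's space.

    Pairwise estimation, recursive composition, then inverse warping of
    every frame.  Deterministic for a fixed seed.  Raises
    :class:`RegistrationError` when every pair fails.
    """
    if params is None:
        params = RegistrationParams()
    pairwise, excluded, inlier_counts, match_counts = register_adjacent_pairs(
        seq, params)
    if len(excluded) == seq.frame_count - 1:
        raise RegistrationError(
            f"registration failed for every frame pair of layer "
            f"{seq.layer_index}"
        )
    cumulative = compose_to_reference(pairwise)
    ref_shape = seq.frames[0].shape
    warped, masks = [], []
    for i, frame in enumerate(seq.frames):
        wf, mask = warp_slice(frame, cumulative[i], out_shape=ref_shape)
        warped.append(wf)
        masks.append(mask)
    return RegisteredSequence(
        layer_index=seq.layer_index,
        warped=warped,
        masks=masks,
        cumulative=cumulative,
        pairwise=pairwise,
        excluded=excluded,
        frame_ids=seq.frame_ids.copy(),
        inlier_counts=inlier_counts,
        match_counts=match_counts,
    )


def dump_transforms_tsv(reg: RegisteredSequence, path: str) -> None:
    """Per-frame transform log: frame_id then the 9 matrix entries."""
    with open(path, "w") as fh:
        fh.write("frame_id\t" + "\t".join(
            f"m{i}{j}" for i in range(3) for j in range(3)) + "\n")
        for fid, t in zip(reg.frame_ids, reg.cumulative):
            vals = "\t".join(f"{v:.8f}" for v in t.matrix.ravel())
            fh.write(f"{fid}\t{vals}\n")
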