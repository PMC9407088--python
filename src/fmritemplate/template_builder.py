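"""Pipeline orchestration: preprocessing, per-layer registration + fusion,
and stacking into the final subject-specific template.

Preprocessing follows common fMRI practice: the first few frames (before
signal equilibrium) are discarded, and frames whose head motion exceeds a
limit are excluded.  Motion can come from an external 6-parameter table
(3 translations mm, 3 rotations deg, e.g. realignment output); without a
table a data-driven proxy drops frames whose mean absolute difference to
the previous retained frame is an outlier on the robust (median/MAD) scale
of all consecutive frame differences.

Each z-layer's slice sequence is then registered to its first retained
frame and fused; the fused slices are stacked in z-order into a 3D
template carrying the source affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .io_nifti import FmriSequence, TemplateVolume, extract_slice_sequences
from .fusion import FUSION_METHODS, fuse_sequence
from .sequence_registration import (
    RegistrationError,
    RegistrationParams,
    register_sequence,
)

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """All tunables of a template build.

    ``n_discard`` leading frames are dropped (4 by default, the usual
    equilibration allowance); motion limits are 2 mm / 2° per axis;
    ``k_mad`` scales the table-free motion proxy.
    """

    n_discard: int = 4
    motion_limit_mm: float = 2.0
    motion_limit_deg: float = 2.0
    k_mad: float = 5.0
    fusion_method: str = "weighted"
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.motion_limit_mm <= 0 or self.motion_limit_deg <= 0:
            raise ValueError("motion limits must be positive")
        if self.k_mad <= 0:
            raise ValueError("k_mad must be positive")
        if self.fusion_method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.fusion_method!r}")
        self.registration.seed = self.seed


def drop_unstable_frames(seq: FmriSequence, n: int) -> FmriSequence:
    """Drop the first ``n`` frames, keeping frame-id bookkeeping."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= seq.frame_count - 1:
        raise ValueError(
            f"cannot drop {n} of {seq.frame_count} frames: "
            "at least 2 must remain"
        )
    if n == 0:
        return seq
    return FmriSequence(
        data=seq.data[:, :, :, n:],
        affine=seq.affine,
        frame_ids=seq.frame_ids[n:],
    )


def exclude_high_motion_frames(
    seq: FmriSequence,
    motion_table: Optional[np.ndarray] = None,
    limit_mm: float = 2.0,
    limit_deg: float = 2.0,
    k_mad: float = 5.0,
) -> FmriSequence:
    """Exclude frames with excessive head motion.

    With a motion table (one row per current frame: 3 translations mm,
    3 rotations deg) a frame is dropped when any |translation| > limit_mm
    or any |rotation| > limit_deg.  Without a table, the proxy rule drops
    frames whose mean absolute difference to the previous retained frame
    exceeds median + k_mad · MAD of all consecutive-frame differences.
    """
    t = seq.frame_count
    if motion_table is not None:
        motion_table = np.atleast_2d(np.asarray(motion_table, dtype=float))
        if motion_table.shape != (t, 6):
            raise ValueError(
                f"motion table shape {motion_table.shape} does not match "
                f"{t} frames x 6 parameters"
            )
        bad = (
            (np.abs(motion_table[:, :3]) > limit_mm).any(axis=1)
            | (np.abs(motion_table[:, 3:]) > limit_deg).any(axis=1)
        )
        keep = ~bad
    else:
        diffs = np.array([
            np.mean(np.abs(seq.data[..., i] - seq.data[..., i - 1]))
            for i in range(1, t)
        ])
        med = np.median(diffs)
        mad = np.median(np.abs(diffs - med))
        cut = med + k_mad * max(mad, 1e-12)
        keep = np.ones(t, dtype=bool)
        prev = 0
        for i in range(1, t):
            d = np.mean(np.abs(seq.data[..., i] - seq.data[..., prev]))
            if d > cut:
                keep[i] = False
            else:
                prev = i
    if keep.sum() < 2:
        raise ValueError("fewer than 2 frames remain after motion exclusion")
    if keep.all():
        return seq
    dropped = seq.frame_ids[~keep]
    logger.info("excluding %d high-motion frames: %s",
                len(dropped), dropped.tolist())
    return FmriSequence(
        data=seq.data[:, :, :, keep],
        affine=seq.affine,
        frame_ids=seq.frame_ids[keep],
    )


def build_template(
    seq: FmriSequence,
    cfg: Optional[BuildConfig] = None,
    motion_table: Optional[np.ndarray] = None,
) -> TemplateVolume:
    """Build the subject-specific 3D template from a 4D series.

    Applies frame discarding and motion exclusion, registers and fuses each
    z-layer independently, and stacks the fused slices.  The template's
    spatial shape always equals the input's; the affine is copied through.
    Deterministic for a fixed seed.  A full-row motion table (one row per
    original frame) is subset by the retained frame ids.

    Raises :class:`RegistrationError` naming the first layer on which every
    frame pair fails.
    """
    if cfg is None:
        cfg = BuildConfig()
    retained = drop_unstable_frames(seq, cfg.n_discard)
    if motion_table is not None:
        motion_table = np.atleast_2d(np.asarray(motion_table, dtype=float))
        if motion_table.shape[0] == seq.frame_count:
            motion_table = motion_table[retained.frame_ids - seq.frame_ids[0]]
    retained = exclude_high_motion_frames(
        retained, motion_table,
        limit_mm=cfg.motion_limit_mm,
        limit_deg=cfg.motion_limit_deg,
        k_mad=cfg.k_mad,
    )

    slices = extract_slice_sequences(retained)
    fused_layers = []
    layer_log: List[dict] = []
    for sl in slices:
        try:
            reg = register_sequence(sl, cfg.registration)
        except RegistrationError as exc:
            raise RegistrationError(
                f"layer {sl.layer_index}: {exc}"
            ) from exc
        fused = fuse_sequence(reg, method=cfg.fusion_method)
        fused_layers.append(fused.data)
        entry = {
            "layer": sl.layer_index,
            "pairs": len(reg.pairwise),
            "mean_inliers": float(np.mean(reg.inlier_counts))
            if reg.inlier_counts else 0.0,
            "mean_matches": float(np.mean(reg.match_counts))
            if reg.match_counts else 0.0,
            "excluded_frames": list(map(int, reg.excluded)),
        }
        layer_log.append(entry)
        logger.info("layer %(layer)d: %(pairs)d pairs, "
                    "mean inliers %(mean_inliers).1f, "
                    "excluded %(excluded_frames)s", entry)

    data = np.stack(fused_layers, axis=2)
    provenance = {
        "frame_ids": retained.frame_ids.tolist(),
        "n_discard": cfg.n_discard,
        "fusion_method": cfg.fusion_method,
        "seed": cfg.seed,
        "ratio_threshold": cfg.registration.ratio_threshold,
        "ransac": {
            "tr": cfg.registration.tr,
            "p": cfg.registration.p,
            "m": cfg.registration.m,
            "model": cfg.registration.model,
            "max_iterations": cfg.registration.max_iterations,
        },
        "layers": layer_log,
    }
    return TemplateVolume(data=data, affine=seq.affine, provenance=provenance)
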