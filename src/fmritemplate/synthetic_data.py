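"""Synthetic phantoms with known ground truth.

Real fMRI cannot ship with a test suite, so every stage of the pipeline is
exercised on generated data instead: a brain-like textured phantom volume,
an animated 4D version of it with known per-frame planar motion, additive
noise, optional unstable leading frames and injected outlier frames, and
labelled point-correspondence sets for the RANSAC estimator.  Everything is
seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .io_nifti import FmriSequence
from .sequence_registration import warp_slice
from .transform_estimation import PlanarTransform


@dataclass
class PhantomSpec:
    """Study conditions for an animated phantom.

    Motion is an in-plane random walk per frame (the pipeline's planar
    model; through-plane motion is out of scope): each step draws uniform
    increments within ±max_step of translation (px), rotation (deg) and
    log-scale.  ``noise_sigma`` is additive Gaussian noise on the [0, 1]
    intensity scale; ``n_unstable`` leading frames receive an extra
    low-frequency intensity drift; ``outlier_frames`` get a large
    intensity jump, to be caught by motion scrubbing.
    """

    shape: Tuple[int, int, int, int] = (64, 64, 4, 10)
    max_step_translation: float = 1.0
    max_step_rotation: float = 1.0
    max_step_log_scale: float = 0.0
    noise_sigma: float = 0.02
    n_unstable: int = 0
    outlier_frames: Tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.shape[:2]) or self.shape[3] < 2:
            raise ValueError("invalid phantom shape")
        for v in (self.max_step_translation, self.max_step_rotation,
                  self.max_step_log_scale, self.noise_sigma):
            if not np.isfinite(v) or v < 0:
                raise ValueError("motion/noise ranges must be finite and >= 0")


@dataclass
class GroundTruth:
    """Everything the tests need to score the pipeline."""

    clean_volume: np.ndarray
    per_frame_transforms: List[List[PlanarTransform]]  # [layer][frame]
    dropped_frames: List[int]


def make_textured_phantom(w: int = 64, h: int = 64, z: int = 4,
                          seed: int = 0) -> np.ndarray:
    """A brain-like textured 3D volume in [0, 1].

    An elliptical "head" filled with Gaussian blobs of mixed polarity on a
    jittered grid, over a smooth ringed background — blob-like local
    extrema are exactly what a scale-space detector responds to, so every
    layer carries a rich keypoint set (dozens at 64×64, >50 at the native
    96×96 slice size with the detector's small-image upsample octave).
    Texture varies with z.
    """
    if min(w, h) < 32 or z < 1:
        raise ValueError("phantom needs w, h >= 32 and z >= 1")
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rr = ((xs - cx) / (0.42 * w)) ** 2 + ((ys - cy) / (0.38 * h)) ** 2
    head = rr <= 1.0
    rim = np.clip(1.0 - rr, 0.0, 1.0) ** 0.5

    spacing = 5.0  # grid pitch: separated blobs keep their own extrema
    vol = np.zeros((w, h, z))
    for k in range(z):
        blobs = np.zeros((w, h))
        for gx in np.arange(6.0, w - 6.0, spacing):
            for gy in np.arange(6.0, h - 6.0, spacing):
                bx = gx + rng.uniform(-1.2, 1.2)
                by = gy + rng.uniform(-1.2, 1.2)
                if (((bx - cx) / (0.40 * w)) ** 2
                        + ((by - cy) / (0.36 * h)) ** 2) > 1:
                    continue
                bs = rng.uniform(1.6, 2.4)
                amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 0.95)
                blobs += amp * np.exp(-((xs - bx) ** 2 + (ys - by) ** 2)
                                      / (2.0 * bs * bs))
        rings = 0.5 + 0.5 * np.cos(
            2 * np.pi * np.sqrt(rr + 1e-9) * (3 + k % 3))
        layer = (0.15 * rings + 0.5) * rim + 0.45 * blobs
        vol[:, :, k] = np.where(head, np.clip(layer, 0.0, None), 0.0)
    vmax = vol.max()
    if vmax > 0:
        vol /= vmax
    return vol


def _walk_transforms(spec: PhantomSpec, rng: np.random.Generator,
                     centre: Tuple[float, float]) -> List[PlanarTransform]:
    """Random-walk rigid/similarity motion, one transform per frame.

    Frame 0 is the identity; frame i maps frame-i pixels into frame-0
    (clean) coordinates.
    """
    t = spec.shape[3]
    tx = ty = rot = log_s = 0.0
    transforms = [PlanarTransform.identity()]
    for _ in range(1, t):
        tx += rng.uniform(-spec.max_step_translation, spec.max_step_translation)
        ty += rng.uniform(-spec.max_step_translation, spec.max_step_translation)
        rot += rng.uniform(-spec.max_step_rotation, spec.max_step_rotation)
        log_s += rng.uniform(-spec.max_step_log_scale, spec.max_step_log_scale)
        transforms.append(
            PlanarTransform.rigid(rot, tx, ty, scale=float(np.exp(log_s)),
                                  centre=centre)
        )
    return transforms


def animate_phantom(clean: np.ndarray, spec: PhantomSpec
                    ) -> Tuple[FmriSequence, GroundTruth]:
    """Animate a clean volume into a 4D series with known ground truth.

    Each frame warps every layer by that frame's planar transform (shared
    across layers — the head moves as one) and adds Gaussian noise.  The
    first ``n_unstable`` frames get a decaying low-frequency intensity
    drift; ``outlier_frames`` get a one-sided intensity jump.  The
    recorded transform of frame i maps frame-i pixels into clean (frame-0)
    coordinates, i.e. exactly what sequential registration estimates.
    """
    clean = np.asarray(clean, dtype=float)
    w, h, z = clean.shape
    if (w, h, z) != spec.shape[:3]:
        raise ValueError("clean volume shape does not match spec")
    t = spec.shape[3]
    rng = np.random.default_rng(spec.seed)
    centre = ((w - 1) / 2.0, (h - 1) / 2.0)
    frame_transforms = _walk_transforms(spec, rng, centre)

    xs, ys = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    drift_field = np.exp(-(((xs - 0.3 * w) / (0.4 * w)) ** 2
                           + ((ys - 0.3 * h) / (0.4 * h)) ** 2))
    jump_field = (xs >= w // 2).astype(float)

    data = np.zeros((w, h, z, t))
    per_layer = [[frame_transforms[i] for i in range(t)] for _ in range(z)]
    for i in range(t):
        tf = frame_transforms[i]
        for k in range(z):
            if i == 0:
                frame = clean[:, :, k].copy()
            else:
                frame, _ = warp_slice(clean[:, :, k], tf.inverse(),
                                      out_shape=(w, h))
            if i < spec.n_unstable:
                frame = frame + 0.3 * (1.0 - i / max(spec.n_unstable, 1)) \
                    * drift_field
            if i in spec.outlier_frames:
                frame = frame + 0.8 * jump_field
            if spec.noise_sigma > 0:
                frame = frame + rng.normal(0.0, spec.noise_sigma, size=(w, h))
            data[:, :, k, i] = frame

    seq = FmriSequence(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]))
    gt = GroundTruth(
        clean_volume=clean,
        per_frame_transforms=per_layer,
        dropped_frames=sorted(spec.outlier_frames),
    )
    return seq, gt


def make_correspondence_set(
    n_inliers: int,
    n_outliers: int,
    transform: PlanarTransform,
    noise_px: float = 0.0,
    seed: int = 0,
    domain: Tuple[float, float] = (0.0, 96.0),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled point pairs for scoring robust estimation.

    Inliers are uniform source points mapped by ``transform`` plus
    Gaussian jitter of ``noise_px``; outliers are independent uniform
    pairs.  Returns (src, dst, labels) with labels True for inliers.
    """
    if n_inliers < 0 or n_outliers < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = domain
    src_in = rng.uniform(lo, hi, size=(n_inliers, 2))
    dst_in = transform.apply(src_in)
    if noise_px > 0 and n_inliers:
        dst_in = dst_in + rng.normal(0.0, noise_px, size=dst_in.shape)
    src_out = rng.uniform(lo, hi, size=(n_outliers, 2))
    dst_out = rng.uniform(lo, hi, size=(n_outliers, 2))
    src = np.vstack([src_in, src_out])
    dst = np.vstack([dst_in, dst_out])
    labels = np.array([True] * n_inliers + [False] * n_outliers)
    return src, dst, labels
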