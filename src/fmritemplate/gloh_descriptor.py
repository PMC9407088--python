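"""GLOH descriptors: 136-dimensional log-polar gradient histograms.

Each oriented keypoint is described by a gradient location-orientation
histogram over a log-polar spatial grid: an undivided central disc plus two
annuli each split into 8 angular sectors (ring radii 6, 11, 15 pixels at the
detection scale), giving 17 spatial bins; each spatial bin holds an 8-bin
histogram of gradient orientation measured relative to the keypoint's
dominant direction, magnitude-weighted.  The grid is rotated so the dominant
direction maps to angle zero, which makes the descriptor approximately
rotation-invariant.  17 × 8 = 136 dimensions, L2-normalized with the usual
clip-at-0.2 / renormalize step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .scale_space_features import (
    GaussianPyramid,
    OrientedKeypoint,
    gradient_polar,
)

DESCRIPTOR_SIZE = 136
N_SPATIAL_BINS = 17       # 1 central disc + 8 + 8 sectors
N_ANGULAR_SECTORS = 8
N_ORIENT_BINS = 8
RING_RADII = (6.0, 11.0, 15.0)   # pixels at the keypoint's octave, unit scale
CLIP_VALUE = 0.2
#: Ring "centres" used for soft radial assignment: the central disc behaves
#: as radius 0, annuli by their mid-radius.
_RING_CENTRES = np.array([0.0, 8.5, 13.0])


@dataclass
class Descriptor:
    """A 136-d feature vector tied back to its keypoint.

    ``flagged`` marks featureless (zero-gradient) patches whose vector is
    all zero instead of unit-norm.
    """

    vector: np.ndarray
    keypoint: OrientedKeypoint
    flagged: bool = False

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (DESCRIPTOR_SIZE,):
            raise ValueError(
                f"descriptor must have {DESCRIPTOR_SIZE} dimensions"
            )


def _soft_radial(r: np.ndarray, unit: float):
    """Continuous ring coordinate in [0, 2] with linear interpolation
    between ring centres; returns (lower ring, upper ring, upper weight)."""
    centres = _RING_CENTRES * unit
    coord = np.interp(r, centres, [0.0, 1.0, 2.0])
    lo = np.floor(coord).astype(int)
    lo = np.clip(lo, 0, 2)
    hi = np.clip(lo + 1, 0, 2)
    w_hi = np.clip(coord - lo, 0.0, 1.0)
    return lo, hi, w_hi


def compute_descriptor(gp: GaussianPyramid, kp: OrientedKeypoint) -> Descriptor:
    """Compute the GLOH vector for one oriented keypoint.

    Samples gradients from the keypoint's Gaussian-pyramid level inside a
    disc of radius 15u, u = σ/σ0, so the support scales with detected size.
    Every sample is soft-assigned bilinearly to adjacent radial rings,
    angular sectors and orientation bins.  Samples falling outside the image
    contribute nothing (window clipped at borders).
    """
    level = int(np.clip(kp.level, 0, len(gp.octaves[kp.octave]) - 1))
    img = gp.octaves[kp.octave][level]
    h, w = img.shape
    unit = kp.sigma_oct / gp.base_sigma
    r_max = RING_RADII[2] * unit
    xc, yc = kp.x_oct, kp.y_oct

    x0 = max(1, int(np.floor(xc - r_max)))
    x1 = min(h - 2, int(np.ceil(xc + r_max)))
    y0 = max(1, int(np.floor(yc - r_max)))
    y1 = min(w - 2, int(np.ceil(yc + r_max)))
    hist = np.zeros((N_SPATIAL_BINS, N_ORIENT_BINS))
    if x0 > x1 or y0 > y1:
        return Descriptor(hist.ravel(), kp, flagged=True)

    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1),
                         indexing="ij")
    dx = xs - xc
    dy = ys - yc
    r = np.hypot(dx, dy)
    keep = r <= r_max
    xs, ys, dx, dy, r = xs[keep], ys[keep], dx[keep], dy[keep], r[keep]
    if xs.size == 0:
        return Descriptor(hist.ravel(), kp, flagged=True)

    m, theta = gradient_polar(img, xs, ys)
    # rotate sample positions and gradient directions into the keypoint frame
    phi = (np.degrees(np.arctan2(dy, dx)) - kp.orientation) % 360.0
    theta_rel = (theta - kp.orientation) % 360.0

    ring_lo, ring_hi, w_ring_hi = _soft_radial(r, unit)

    sector_coord = phi / (360.0 / N_ANGULAR_SECTORS) - 0.5
    sector_lo = np.floor(sector_coord).astype(int) % N_ANGULAR_SECTORS
    sector_hi = (sector_lo + 1) % N_ANGULAR_SECTORS
    w_sector_hi = (sector_coord - np.floor(sector_coord))

    orient_coord = theta_rel / (360.0 / N_ORIENT_BINS) - 0.5
    orient_lo = np.floor(orient_coord).astype(int) % N_ORIENT_BINS
    orient_hi = (orient_lo + 1) % N_ORIENT_BINS
    w_orient_hi = (orient_coord - np.floor(orient_coord))

    def spatial_index(ring, sector):
        # bin 0 = centre; rings 1 and 2 hold 8 sectors each, counter-
        # clockwise from angle 0
        centre = ring == 0
        return np.where(centre, 0, 1 + (ring - 1) * N_ANGULAR_SECTORS + sector)

    flat = hist.ravel()
    for ring, w_r in ((ring_lo, 1.0 - w_ring_hi), (ring_hi, w_ring_hi)):
        for sector, w_s in ((sector_lo, 1.0 - w_sector_hi),
                            (sector_hi, w_sector_hi)):
            s_idx = spatial_index(ring, sector)
            # the centre disc has no angular division: collapse the two
            # sector contributions onto the single bin without double weight
            w_spatial = np.where(ring == 0, w_r * 0.5, w_r * w_s)
            for orient, w_o in ((orient_lo, 1.0 - w_orient_hi),
                                (orient_hi, w_orient_hi)):
                np.add.at(flat, s_idx * N_ORIENT_BINS + orient,
                          m * w_spatial * w_o)

    vec = flat
    norm = np.linalg.norm(vec)
    if norm <= 0:
        return Descriptor(vec, kp, flagged=True)
    vec = np.minimum(vec / norm, CLIP_VALUE)
    norm = np.linalg.norm(vec)
    if norm <= 0:  # pragma: no cover - clip keeps positive mass
        return Descriptor(vec, kp, flagged=True)
    return Descriptor(vec / norm, kp)


def describe_all(gp: GaussianPyramid, keypoints: List[OrientedKeypoint]
                 ) -> List[Descriptor]:
    """Order-preserving, deterministic map of :func:`compute_descriptor`."""
    return [compute_descriptor(gp, kp) for kp in keypoints]


def dump_descriptors_tsv(descriptors: List[Descriptor], path: str) -> None:
    """TSV dump: keypoint columns followed by the 136 vector entries."""
    with open(path, "w") as fh:
        head = "x\ty\tsigma\torientation_deg\t" + "\t".join(
            f"d{i}" for i in range(DESCRIPTOR_SIZE))
        fh.write(head + "\n")
        for d in descriptors:
            kp = d.keypoint
            vals = "\t".join(f"{v:.6f}" for v in d.vector)
            fh.write(f"{kp.x:.4f}\t{kp.y:.4f}\t{kp.sigma:.4f}\t"
                     f"{kp.orientation:.2f}\t{vals}\n")
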