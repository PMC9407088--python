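"""Scale-space keypoint detection on 2D slices.

A SIFT-style detector: a Gaussian pyramid L(x, y, σ) = G(σ) * I is built over
several octaves, adjacent levels are subtracted into a difference-of-Gaussians
(DoG) pyramid D(x, y, σ) = L(kσ) − L(σ), and keypoints are strict 26-neighbour
extrema of D, refined to sub-pixel position and scale by a second-order Taylor
fit, filtered for low contrast and for edge-like responses via the principal
curvature ratio of the 2×2 spatial Hessian, and finally given a single
dominant orientation from a 36-bin gradient-direction histogram.

Detection is fully deterministic: identical input and parameters produce an
identical keypoint list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io_nifti import normalize_slice

#: Orientation histogram resolution: 36 columns of 10 degrees.
N_ORIENTATION_BINS = 36


@dataclass
class FeatureParams:
    """Tunable parameters of the detector.

    base_sigma / intervals follow common scale-space practice (σ0 = 1.6,
    s = 3 intervals per octave, k = 2^(1/s)); contrast_threshold applies to
    [0, 1]-normalized intensities; edge_r is the maximum allowed principal
    curvature ratio r in Tr²/Det < (r+1)²/r.
    """

    base_sigma: float = 1.6
    intervals: int = 3
    num_octaves: Optional[int] = None  # None = floor(log2(min(w,h))) - 2
    contrast_threshold: float = 0.03
    edge_r: float = 10.0
    border: int = 5
    upsample: bool = False


@dataclass
class GaussianPyramid:
    octaves: List[List[np.ndarray]]
    sigmas: List[float]  # absolute blur per level, octave-0 units, octave o scales by 2^o
    k_factor: float
    base_sigma: float
    intervals: int
    upsampled: bool = False  # octave 0 is a 2x bilinear upsampling of the input

    def level_sigma(self, octave: int, level: int) -> float:
        """Absolute σ of a level in full-resolution units."""
        return self.sigmas[level] * (2.0 ** octave)

    def octave_sigma(self, level: int) -> float:
        """σ of a level expressed in its own octave's pixel grid."""
        return self.sigmas[level]


@dataclass
class DoGPyramid:
    octaves: List[List[np.ndarray]]
    sigmas: List[float]
    k_factor: float
    base_sigma: float
    intervals: int


@dataclass
class Keypoint:
    """A refined scale-space extremum.

    x, y are sub-pixel full-resolution coordinates (x = first array axis);
    x_oct, y_oct are the same point in the pixel grid of its octave, where
    orientation and descriptor sampling happen.
    """

    x: float
    y: float
    octave: int
    level: int
    sigma: float        # absolute scale, full-resolution units
    sigma_oct: float    # scale in octave units
    response: float
    x_oct: float = 0.0
    y_oct: float = 0.0


@dataclass
class OrientedKeypoint(Keypoint):
    orientation: float = 0.0  # degrees in [0, 360)
    low_confidence: bool = False


def auto_num_octaves(shape: Tuple[int, int]) -> int:
    """Octave-count rule: floor(log2(min(w, h))) − 2, at least 1."""
    return max(1, int(math.floor(math.log2(min(shape)))) - 2)


def build_gaussian_pyramid(
    image: np.ndarray,
    intervals_s: int = 3,
    base_sigma: float = 1.6,
    num_octaves: Optional[int] = None,
    upsample: bool = False,
) -> GaussianPyramid:
    """Build a multi-octave Gaussian scale space.

    Octave o, level j holds the image at absolute blur
    σ = base_sigma · 2^o · k^j with k = 2^(1/s); each octave has s + 3
    levels so that the s + 2 DoG levels bracket a full doubling of scale.
    Blur is applied incrementally (σ_inc = sqrt(σ_next² − σ_prev²)) so the
    composed blur equals the absolute σ; the input is treated as blur-free.
    Octave o+1 starts from octave o's level-s image subsampled by 2.

    With ``upsample=True`` the input is first bilinearly doubled, adding a
    −1 octave for small slices; coordinates reported by the detector remain
    in the original pixel grid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D slice")
    if min(image.shape) < 16:
        raise ValueError("image too small for a scale-space pyramid (< 16 px)")
    if intervals_s < 1:
        raise ValueError("intervals_s must be >= 1")
    if base_sigma <= 0:
        raise ValueError("base_sigma must be positive")
    if upsample:
        image = ndimage.zoom(image, 2.0, order=1, mode="reflect", grid_mode=True)
    if num_octaves is None:
        num_octaves = auto_num_octaves(image.shape)
    if min(image.shape) // (2 ** (num_octaves - 1)) < 4:
        raise ValueError(
            f"image {image.shape} too small for {num_octaves} octaves"
        )

    s = intervals_s
    k = 2.0 ** (1.0 / s)
    n_levels = s + 3
    sigmas = [base_sigma * (k ** j) for j in range(n_levels)]

    octaves: List[List[np.ndarray]] = []
    base = ndimage.gaussian_filter(image, base_sigma, mode="reflect")
    for o in range(num_octaves):
        levels = [base]
        for j in range(1, n_levels):
            sigma_inc = math.sqrt(sigmas[j] ** 2 - sigmas[j - 1] ** 2)
            levels.append(
                ndimage.gaussian_filter(levels[-1], sigma_inc, mode="reflect")
            )
        octaves.append(levels)
        # level s has twice the octave's base blur; halving the grid halves σ
        base = levels[s][::2, ::2]
    return GaussianPyramid(
        octaves=octaves, sigmas=sigmas, k_factor=k,
        base_sigma=base_sigma, intervals=s, upsampled=upsample,
    )


def build_dog_pyramid(gp: GaussianPyramid) -> DoGPyramid:
    """Difference-of-Gaussians: D_j = L_{j+1} − L_j per octave, exactly."""
    octaves = [
        [levels[j + 1] - levels[j] for j in range(len(levels) - 1)]
        for levels in gp.octaves
    ]
    return DoGPyramid(
        octaves=octaves, sigmas=gp.sigmas, k_factor=gp.k_factor,
        base_sigma=gp.base_sigma, intervals=gp.intervals,
    )


def detect_extrema(dog: DoGPyramid, border: int = 5) -> List[Tuple[int, int, int, int]]:
    """Strict 26-neighbour extrema of the DoG stacks.

    Returns (octave, level, x, y) integer candidates where the sample is
    strictly greater than (or strictly smaller than) all 8 same-scale and
    2 × 9 adjacent-scale neighbours.  Plateaus are discarded by strictness.
    Only interior levels (1 .. s) and positions at least ``border`` pixels
    from the image edge qualify.
    """
    candidates = []
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    for o, levels in enumerate(dog.octaves):
        if len(levels) < 3:
            continue
        stack = np.stack(levels, axis=0)
        neigh_max = ndimage.maximum_filter(stack, footprint=footprint,
                                           mode="constant", cval=-np.inf)
        neigh_min = ndimage.minimum_filter(stack, footprint=footprint,
                                           mode="constant", cval=np.inf)
        is_ext = (stack > neigh_max) | (stack < neigh_min)
        is_ext[0] = False
        is_ext[-1] = False
        h, w = stack.shape[1:]
        lo = border
        mask = np.zeros_like(is_ext)
        if h > 2 * lo and w > 2 * lo:
            mask[:, lo:h - lo, lo:w - lo] = True
        is_ext &= mask
        for lvl, x, y in zip(*np.nonzero(is_ext)):
            candidates.append((o, int(lvl), int(x), int(y)))
    return candidates


def _taylor_fit(stack: np.ndarray, lvl: int, x: int, y: int):
    """Gradient and Hessian of D at (lvl, x, y) by central differences."""
    d = stack
    g = np.array([
        (d[lvl + 1, x, y] - d[lvl - 1, x, y]) / 2.0,
        (d[lvl, x + 1, y] - d[lvl, x - 1, y]) / 2.0,
        (d[lvl, x, y + 1] - d[lvl, x, y - 1]) / 2.0,
    ])
    dss = d[lvl + 1, x, y] - 2 * d[lvl, x, y] + d[lvl - 1, x, y]
    dxx = d[lvl, x + 1, y] - 2 * d[lvl, x, y] + d[lvl, x - 1, y]
    dyy = d[lvl, x, y + 1] - 2 * d[lvl, x, y] + d[lvl, x, y - 1]
    dsx = (d[lvl + 1, x + 1, y] - d[lvl + 1, x - 1, y]
           - d[lvl - 1, x + 1, y] + d[lvl - 1, x - 1, y]) / 4.0
    dsy = (d[lvl + 1, x, y + 1] - d[lvl + 1, x, y - 1]
           - d[lvl - 1, x, y + 1] + d[lvl - 1, x, y - 1]) / 4.0
    dxy = (d[lvl, x + 1, y + 1] - d[lvl, x + 1, y - 1]
           - d[lvl, x - 1, y + 1] + d[lvl, x - 1, y - 1]) / 4.0
    hess = np.array([
        [dss, dsx, dsy],
        [dsx, dxx, dxy],
        [dsy, dxy, dyy],
    ])
    return g, hess


def refine_keypoint(
    dog: DoGPyramid,
    candidate: Tuple[int, int, int, int],
    contrast_threshold: float = 0.03,
    border: int = 5,
    max_attempts: int = 5,
) -> Optional[Keypoint]:
    """Sub-pixel/sub-scale refinement of an integer extremum.

    Solves the second-order Taylor offset X̂ = −H⁻¹ ∇D around the sample.
    If any component of X̂ exceeds 0.5 the interpolation centre has shifted:
    the integer position is moved accordingly and the fit repeated, at most
    ``max_attempts`` times.  Rejects on a singular Hessian, on failure to
    converge, on leaving the interior, and on interpolated contrast
    |D(X̂)| below ``contrast_threshold``.
    """
    o, lvl, x, y = candidate
    stack = np.stack(dog.octaves[o], axis=0)
    n_lvl, h, w = stack.shape
    offset = None
    for _ in range(max_attempts):
        if not (1 <= lvl <= n_lvl - 2 and border <= x < h - border
                and border <= y < w - border):
            return None
        g, hess = _taylor_fit(stack, lvl, x, y)
        try:
            offset = np.linalg.solve(hess, -g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(offset) <= 0.5):
            break
        step = np.clip(np.round(offset), -1, 1).astype(int)
        lvl += step[0]
        x += step[1]
        y += step[2]
    else:
        return None

    value = stack[lvl, x, y] + 0.5 * float(g @ offset)
    if abs(value) < contrast_threshold:
        return None
    k = dog.k_factor
    lvl_f = lvl + offset[0]
    x_oct = x + offset[1]
    y_oct = y + offset[2]
    scale = 2.0 ** o
    return Keypoint(
        x=x_oct * scale,
        y=y_oct * scale,
        octave=o,
        level=lvl,
        sigma=dog.base_sigma * scale * (k ** lvl_f),
        sigma_oct=dog.base_sigma * (k ** lvl_f),
        response=abs(value),
        x_oct=float(x_oct),
        y_oct=float(y_oct),
    )


def edge_response_filter(dog: DoGPyramid, kp: Keypoint, r: float = 10.0) -> bool:
    """Reject edge-like keypoints via the principal-curvature ratio.

    With H the 2×2 spatial Hessian of D at the keypoint's sample and
    eigenvalues α = rβ ≥ β, the ratio Tr(H)²/Det(H) = (r+1)²/r grows with
    the anisotropy r.  Keep iff Det(H) > 0 and Tr(H)²/Det(H) < (r+1)²/r
    (isotropic blobs give the minimum ratio 4; a straight edge fails).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    d = dog.octaves[kp.octave][kp.level]
    x, y = int(round(kp.x_oct)), int(round(kp.y_oct))
    h, w = d.shape
    if not (1 <= x < h - 1 and 1 <= y < w - 1):
        return False
    dxx = d[x + 1, y] - 2 * d[x, y] + d[x - 1, y]
    dyy = d[x, y + 1] - 2 * d[x, y] + d[x, y - 1]
    dxy = (d[x + 1, y + 1] - d[x + 1, y - 1]
           - d[x - 1, y + 1] + d[x - 1, y - 1]) / 4.0
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    return tr * tr / det < (r + 1.0) ** 2 / r


def gradient_polar(img: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Central-difference gradient modulus and direction (degrees, [0, 360)).

    m = sqrt((L(x+1,y) − L(x−1,y))² + (L(x,y+1) − L(x,y−1))²) and the
    direction is the four-quadrant arctangent of the same differences.
    Callers must pass interior coordinates (1 .. n−2).
    """
    gx = img[x + 1, y] - img[x - 1, y]
    gy = img[x, y + 1] - img[x, y - 1]
    m = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 360.0
    return m, theta


def assign_orientation(gp: GaussianPyramid, kp: Keypoint) -> OrientedKeypoint:
    """Assign the single dominant gradient orientation to a keypoint.

    Gradient modulus and direction are accumulated over a disc of radius 3σ
    around the keypoint (σ in octave units) into a 36-bin histogram (10° per
    bin), weighted by modulus and a Gaussian falloff of width 1.5σ.  The
    orientation is the centre of the maximal bin after parabolic
    interpolation over its two circular neighbours.  All-zero gradients give
    orientation 0 with ``low_confidence=True``.
    """
    level = int(np.clip(kp.level, 0, len(gp.octaves[kp.octave]) - 1))
    img = gp.octaves[kp.octave][level]
    h, w = img.shape
    sigma = kp.sigma_oct
    radius = max(1, int(round(3.0 * sigma)))
    xc, yc = kp.x_oct, kp.y_oct
    x0 = max(1, int(math.floor(xc - radius)))
    x1 = min(h - 2, int(math.ceil(xc + radius)))
    y0 = max(1, int(math.floor(yc - radius)))
    y1 = min(w - 2, int(math.ceil(yc + radius)))
    if x0 > x1 or y0 > y1:
        return OrientedKeypoint(**kp.__dict__, orientation=0.0, low_confidence=True)

    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1),
                         indexing="ij")
    dist2 = (xs - xc) ** 2 + (ys - yc) ** 2
    disc = dist2 <= radius * radius
    xs, ys, dist2 = xs[disc], ys[disc], dist2[disc]
    m, theta = gradient_polar(img, xs, ys)
    weight = m * np.exp(-dist2 / (2.0 * (1.5 * sigma) ** 2))

    hist = np.zeros(N_ORIENTATION_BINS)
    bins = (theta / 10.0).astype(int) % N_ORIENTATION_BINS
    np.add.at(hist, bins, weight)
    if hist.max() <= 0:
        return OrientedKeypoint(**kp.__dict__, orientation=0.0, low_confidence=True)

    b = int(np.argmax(hist))
    left = hist[(b - 1) % N_ORIENTATION_BINS]
    right = hist[(b + 1) % N_ORIENTATION_BINS]
    denom = left - 2.0 * hist[b] + right
    shift = 0.0 if denom == 0 else 0.5 * (left - right) / denom
    orientation = ((b + 0.5 + shift) * 10.0) % 360.0
    return OrientedKeypoint(**kp.__dict__, orientation=float(orientation))


def detect_features(
    slice2d: np.ndarray, params: Optional[FeatureParams] = None
) -> List[OrientedKeypoint]:
    """Full detection pipeline for one 2D slice.

    Min-max normalizes to [0, 1], builds the Gaussian and DoG pyramids,
    finds strict extrema, refines, applies the edge-response filter, and
    assigns one orientation per keypoint.  Output is sorted by
    (y, x, sigma) for reproducibility.
    """
    keypoints, _ = detect_features_with_pyramid(slice2d, params)
    return keypoints


def detect_features_with_pyramid(
    slice2d: np.ndarray, params: Optional[FeatureParams] = None
):
    """As :func:`detect_features`, also returning the Gaussian pyramid.

    The descriptor stage samples gradients from the same pyramid; returning
    it avoids rebuilding the scale space per slice.
    """
    if params is None:
        params = FeatureParams()
    slice2d = np.asarray(slice2d, dtype=float)
    if not np.all(np.isfinite(slice2d)):
        raise ValueError("non-finite values in slice")
    norm = normalize_slice(slice2d)
    gp = build_gaussian_pyramid(
        norm, intervals_s=params.intervals, base_sigma=params.base_sigma,
        num_octaves=params.num_octaves, upsample=params.upsample,
    )
    dog = build_dog_pyramid(gp)
    keypoints: List[OrientedKeypoint] = []
    for cand in detect_extrema(dog, border=params.border):
        kp = refine_keypoint(
            dog, cand, contrast_threshold=params.contrast_threshold,
            border=params.border,
        )
        if kp is None:
            continue
        if not edge_response_filter(dog, kp, r=params.edge_r):
            continue
        okp = assign_orientation(gp, kp)
        if gp.upsampled:
            # octave 0 is the doubled grid: report input-grid coordinates
            okp.x /= 2.0
            okp.y /= 2.0
            okp.sigma /= 2.0
        keypoints.append(okp)
    keypoints.sort(key=lambda p: (p.y, p.x, p.sigma))
    return keypoints, gp


def dump_keypoints_tsv(keypoints: List[OrientedKeypoint], path: str) -> None:
    """Write keypoints as TSV: x, y, sigma, orientation_deg, response."""
    with open(path, "w") as fh:
        fh.write("x\ty\tsigma\torientation_deg\tresponse\n")
        for kp in keypoints:
            fh.write(f"{kp.x:.4f}\t{kp.y:.4f}\t{kp.sigma:.4f}\t"
                     f"{kp.orientation:.2f}\t{kp.response:.6f}\n")
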