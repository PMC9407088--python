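"""Robust planar-transform estimation from matched keypoints by RANSAC.

A hypothesis is fitted from a minimal random sample (4 non-collinear point
pairs for a projective homography; 3 for affine, 2 for rigid), all
correspondences are scored by one-sided transfer error, and the consensus
set is tracked.  The iteration bound is adaptive: with confidence p and
current inlier fraction w = f/n the number of rounds needed is

    k = log(1 − p) / log(1 − w^m),

re-evaluated whenever the best consensus improves.  The final model is
refitted by least squares on the best inlier set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .matching import MatchSet

DEFAULT_TR = 2.0           # inlier threshold, pixels
DEFAULT_P = 0.995          # confidence that one sample is all-inlier
DEFAULT_M = 4              # minimal sample size (homography)
DEFAULT_MAX_ITERATIONS = 2000
DEFAULT_CRITICAL_FRACTION = 0.8

_MIN_SAMPLE = {"homography": 4, "affine": 3, "rigid": 2}


class DegenerateSampleError(ValueError):
    """Raised when a point sample cannot determine the transform
    (collinear points, coincident points)."""


class RansacFailure(RuntimeError):
    """Raised when no model with sufficient support is found."""


@dataclass
class PlanarTransform:
    """3×3 homogeneous matrix mapping moving-slice pixels (x, y, 1)ᵀ into
    reference-slice pixel coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if abs(self.matrix[2, 2]) > 1e-12:
            self.matrix = self.matrix / self.matrix[2, 2]
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "PlanarTransform":
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return cls(m)

    @classmethod
    def rigid(cls, angle_deg: float, dx: float = 0.0, dy: float = 0.0,
              scale: float = 1.0, centre: Tuple[float, float] = (0.0, 0.0)
              ) -> "PlanarTransform":
        """Similarity transform rotating by ``angle_deg`` about ``centre``."""
        a = math.radians(angle_deg)
        c, s = scale * math.cos(a), scale * math.sin(a)
        cx, cy = centre
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        to_origin = np.eye(3)
        to_origin[:2, 2] = (-cx, -cy)
        back = np.eye(3)
        back[:2, 2] = (cx + dx, cy + dy)
        return cls(back @ rot @ to_origin)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        w = out[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            mapped = out[:, :2] / w[:, None]
        mapped[np.abs(w) < 1e-12] = np.inf
        return mapped

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return PlanarTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "PlanarTransform") -> "PlanarTransform":
        return self.compose(other)


@dataclass
class RansacResult:
    model: PlanarTransform
    inliers: np.ndarray          # indices into the MatchSet
    iterations_used: int
    final_k: float


def _has_collinear_triple(pts: np.ndarray, tol_scale: float = 1e-6) -> bool:
    """True if any 3 of the points are (near-)collinear.

    The area tolerance scales with the squared bounding-box diagonal so the
    test is invariant to the coordinate units.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    bbox = pts.max(axis=0) - pts.min(axis=0)
    tol = tol_scale * float(bbox @ bbox + 1.0)
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                area2 = abs((b[0] - a[0]) * (c[1] - a[1])
                            - (b[1] - a[1]) * (c[0] - a[0]))
                if area2 <= tol:
                    return True
    return False


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity normalizing points to zero mean and √2 RMS radius."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if rms <= 0:
        raise DegenerateSampleError("coincident points")
    s = math.sqrt(2.0) / rms
    t = np.array([
        [s, 0.0, -s * centroid[0]],
        [0.0, s, -s * centroid[1]],
        [0.0, 0.0, 1.0],
    ])
    return t


def fit_homography(
    src: np.ndarray,
    dst: np.ndarray,
    model: str = "homography",
) -> PlanarTransform:
    """Fit a planar transform mapping ``src`` points onto ``dst`` points.

    Direct linear transform with Hartley normalization for the projective
    case: exact interpolation for a minimal non-degenerate sample, total
    least squares (smallest singular vector) for more points.  ``model``
    may be ``homography`` (4+ pairs), ``affine`` (3+) or ``rigid``
    (2+, rotation + translation + isotropic scale by Procrustes).
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    m = _MIN_SAMPLE[model]
    if len(src) < m:
        raise ValueError(f"{model} needs at least {m} correspondences")

    if model == "rigid":
        return _fit_similarity(src, dst)

    if model == "homography" and len(src) >= 3 and _has_collinear_triple(src):
        raise DegenerateSampleError("3 or more collinear source points")
    if model == "affine" and _has_collinear_triple(src):
        raise DegenerateSampleError("collinear source points")

    t_src = _normalization(src)
    t_dst = _normalization(dst)
    s = (np.column_stack([src, np.ones(len(src))]) @ t_src.T)[:, :2]
    d = (np.column_stack([dst, np.ones(len(dst))]) @ t_dst.T)[:, :2]

    if model == "affine":
        a = np.zeros((2 * len(s), 6))
        b = np.zeros(2 * len(s))
        a[0::2, 0:2] = s
        a[0::2, 2] = 1.0
        a[1::2, 3:5] = s
        a[1::2, 5] = 1.0
        b[0::2] = d[:, 0]
        b[1::2] = d[:, 1]
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        hn = np.array([
            [sol[0], sol[1], sol[2]],
            [sol[3], sol[4], sol[5]],
            [0.0, 0.0, 1.0],
        ])
    else:
        a = np.zeros((2 * len(s), 9))
        x, y = s[:, 0], s[:, 1]
        u, v = d[:, 0], d[:, 1]
        a[0::2, 0] = x
        a[0::2, 1] = y
        a[0::2, 2] = 1.0
        a[0::2, 6] = -u * x
        a[0::2, 7] = -u * y
        a[0::2, 8] = -u
        a[1::2, 3] = x
        a[1::2, 4] = y
        a[1::2, 5] = 1.0
        a[1::2, 6] = -v * x
        a[1::2, 7] = -v * y
        a[1::2, 8] = -v
        _, sv, vt = np.linalg.svd(a)
        hn = vt[-1].reshape(3, 3)
        if abs(hn[2, 2]) < 1e-12 or sv[-2] < 1e-10 * sv[0]:
            raise DegenerateSampleError("degenerate point configuration")

    h = np.linalg.inv(t_dst) @ hn @ t_src
    try:
        return PlanarTransform(h)
    except ValueError as exc:
        raise DegenerateSampleError(str(exc)) from exc


def _fit_similarity(src: np.ndarray, dst: np.ndarray) -> PlanarTransform:
    """Least-squares rotation + isotropic scale + translation (Procrustes)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    var_s = np.sum(sc ** 2)
    if var_s <= 0:
        raise DegenerateSampleError("coincident source points")
    cov = dc.T @ sc
    u, sv, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, sign])
    rot = u @ d @ vt
    scale = np.trace(np.diag(sv) @ d) / var_s
    if abs(scale) < 1e-12:
        raise DegenerateSampleError("degenerate similarity fit")
    t = mu_d - scale * rot @ mu_s
    m = np.eye(3)
    m[:2, :2] = scale * rot
    m[:2, 2] = t
    return PlanarTransform(m)


def projection_error(
    model: PlanarTransform, src: np.ndarray, dst: np.ndarray
) -> np.ndarray:
    """One-sided transfer error: |T·src − dst| in pixels, per pair.

    Points mapped to infinity (homogeneous w ≈ 0) get error +∞ and can
    never be inliers.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    proj = model.apply(src)
    err = np.sqrt(np.sum((proj - dst) ** 2, axis=1))
    return np.where(np.isfinite(err), err, np.inf)


def required_iterations(p: float, w: float, m: int) -> float:
    """Adaptive RANSAC iteration bound k = log(1 − p) / log(1 − wᵐ).

    Conventions: w = 1 → 0 (every sample is all-inlier); w = 0 → +∞
    (callers cap by max_iterations).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if w >= 1.0:
        return 0.0
    if w == 0.0:
        return math.inf
    wm = w ** m
    denom = math.log1p(-wm)
    if denom == 0.0:
        return math.inf
    return math.log1p(-p) / denom


def _match_points(
    matches: MatchSet, keypoints_ref: Sequence, keypoints_mov: Sequence
) -> Tuple[np.ndarray, np.ndarray]:
    """Pull (x, y) arrays for the matched pairs; accepts keypoint objects
    or raw (n, 2) coordinate arrays."""

    def coords(kps, idx):
        if isinstance(kps, np.ndarray):
            return kps[idx]
        return np.array([(kps[i].x, kps[i].y) for i in idx], dtype=float)

    ref_idx = matches.ref_indices
    mov_idx = matches.mov_indices
    return coords(keypoints_mov, mov_idx), coords(keypoints_ref, ref_idx)


def ransac(
    matches: MatchSet,
    keypoints_ref: Sequence,
    keypoints_mov: Sequence,
    tr: float = DEFAULT_TR,
    p: float = DEFAULT_P,
    m: int = DEFAULT_M,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    seed: int = 0,
    critical_fraction: float = DEFAULT_CRITICAL_FRACTION,
    model: str = "homography",
    min_inliers: Optional[int] = None,
) -> RansacResult:
    """RANSAC planar-transform estimation from a match set.

    Repeats: draw m non-degenerate pairs, fit, count correspondences with
    projection error < ``tr``.  After every consensus improvement the
    inlier fraction w = f/n updates the adaptive bound k; iteration stops
    at min(k, max_iterations) or as soon as the consensus reaches
    ``critical_fraction`` of all matches.  The best model is refitted by
    least squares on its inlier set (kept only if it does not lose
    support).  Success requires at least ``min_inliers`` supporters
    (default m + 2: a minimal sample fits itself exactly, so bare-m support
    carries no evidence).  Fully reproducible for a fixed seed.
    """
    n = len(matches)
    m_model = _MIN_SAMPLE[model]
    m = max(m, m_model)
    if min_inliers is None:
        min_inliers = m + 2
    if n < m:
        raise RansacFailure(f"need at least {m} matches, got {n}")

    src, dst = _match_points(matches, keypoints_ref, keypoints_mov)
    rng = np.random.default_rng(seed)

    best_count = 0
    best_inliers = np.array([], dtype=int)
    best_model: Optional[PlanarTransform] = None
    k = math.inf
    iterations = 0
    while iterations < min(k, max_iterations):
        iterations += 1
        idx = rng.choice(n, size=m, replace=False)
        try:
            hyp = fit_homography(src[idx], dst[idx], model=model)
        except DegenerateSampleError:
            continue
        err = projection_error(hyp, src, dst)
        inliers = np.nonzero(err < tr)[0]
        if len(inliers) > best_count:
            best_count = len(inliers)
            best_inliers = inliers
            best_model = hyp
            w = best_count / n
            k = required_iterations(p, w, m)
            if best_count >= critical_fraction * n:
                break

    if best_model is None or best_count < min_inliers:
        raise RansacFailure(
            f"no consensus with >= {min_inliers} inliers "
            f"(best {best_count} of {n})"
        )

    # refit on the full consensus; keep only if support does not shrink
    if best_count > m_model:
        try:
            refit = fit_homography(src[best_inliers], dst[best_inliers],
                                   model=model)
            err = projection_error(refit, src, dst)
            refit_inliers = np.nonzero(err < tr)[0]
            if len(refit_inliers) >= best_count:
                best_model = refit
                best_inliers = refit_inliers
        except DegenerateSampleError:
            pass

    return RansacResult(
        model=best_model,
        inliers=best_inliers,
        iterations_used=iterations,
        final_k=float(k),
    )
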