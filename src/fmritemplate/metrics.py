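"""Registration-quality metrics: MSE, NCC, MI, NMI.

Standard single-modality definitions over an evaluation mask: mean squared
error; zero-mean normalized cross-correlation (Pearson correlation of the
masked intensities); mutual information of the joint intensity histogram
(32 bins per image, min-max binned over the mask, natural logarithm); and
normalized mutual information NMI = (H(a) + H(b)) / H(a, b), which is 2 for
identical images and tends to 1 for independent ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np

DEFAULT_BINS = 32


@dataclass
class MetricReport:
    mse: float
    ncc: float
    mi: float
    nmi: float
    n_pixels: int
    histogram_bins: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _masked(a: np.ndarray, b: np.ndarray,
            mask: Optional[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        return a.ravel(), b.ravel()
    mask = np.asarray(mask) > 0
    if mask.shape != a.shape:
        raise ValueError("mask shape must match the images")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return a[mask], b[mask]


def mse(a: np.ndarray, b: np.ndarray,
        mask: Optional[np.ndarray] = None) -> float:
    """Mean squared intensity difference over the mask (lower is better)."""
    av, bv = _masked(a, b, mask)
    return float(np.mean((av - bv) ** 2))


def ncc(a: np.ndarray, b: np.ndarray,
        mask: Optional[np.ndarray] = None) -> float:
    """Zero-mean normalized cross-correlation (Pearson) over the mask.

    Raises on zero variance: correlation with a constant image is
    undefined.
    """
    av, bv = _masked(a, b, mask)
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt(np.sum(av ** 2) * np.sum(bv ** 2))
    if denom == 0:
        raise ValueError("zero variance: NCC undefined for constant input")
    return float(np.clip(np.sum(av * bv) / denom, -1.0, 1.0))


def _joint_histogram(av: np.ndarray, bv: np.ndarray, bins: int) -> np.ndarray:
    """bins × bins joint probability table, each axis min-max binned."""

    def edges(v):
        lo, hi = v.min(), v.max()
        if hi <= lo:
            hi = lo + 1.0  # constant image: everything in one bin
        return np.linspace(lo, hi, bins + 1)

    h, _, _ = np.histogram2d(av, bv, bins=[edges(av), edges(bv)])
    return h / h.sum()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(a: np.ndarray, b: np.ndarray,
                       mask: Optional[np.ndarray] = None,
                       bins: int = DEFAULT_BINS) -> float:
    """Mutual information (nats) of the joint intensity histogram.

    MI(a, a) equals the entropy of a's own histogram; MI of independent
    images tends to 0 with sample size.  Invariant to monotone affine
    rescaling of either image (binning is min-max per image).
    """
    av, bv = _masked(a, b, mask)
    if av.size < bins:
        raise ValueError("mask smaller than the number of bins")
    pab = _joint_histogram(av, bv, bins)
    return _entropy(pab.sum(axis=1)) + _entropy(pab.sum(axis=0)) - _entropy(pab)


def nmi(a: np.ndarray, b: np.ndarray,
        mask: Optional[np.ndarray] = None,
        bins: int = DEFAULT_BINS) -> float:
    """Normalized mutual information (H(a) + H(b)) / H(a, b) ∈ [1, 2]."""
    av, bv = _masked(a, b, mask)
    if av.size < bins:
        raise ValueError("mask smaller than the number of bins")
    pab = _joint_histogram(av, bv, bins)
    h_joint = _entropy(pab)
    if h_joint == 0:
        # both images constant: identical by construction of the binning
        return 2.0
    return (_entropy(pab.sum(axis=1)) + _entropy(pab.sum(axis=0))) / h_joint


def evaluate_pair(a: np.ndarray, b: np.ndarray,
                  mask: Optional[np.ndarray] = None,
                  bins: int = DEFAULT_BINS) -> MetricReport:
    """All four metrics of one image pair in a single report."""
    av, _ = _masked(a, b, mask)
    return MetricReport(
        mse=mse(a, b, mask),
        ncc=ncc(a, b, mask),
        mi=mutual_information(a, b, mask, bins),
        nmi=nmi(a, b, mask, bins),
        n_pixels=int(av.size),
        histogram_bins=bins,
    )


def evaluate_series(series4d: np.ndarray, reference3d: np.ndarray,
                    mask: Optional[np.ndarray] = None,
                    bins: int = DEFAULT_BINS) -> MetricReport:
    """Mean of each metric over all frames of a 4D series vs a 3D reference.

    The per-frame metric values are averaged — the usual protocol for
    scoring a whole time series against one template.
    """
    series4d = np.asarray(series4d, dtype=float)
    reference3d = np.asarray(reference3d, dtype=float)
    if series4d.ndim != 4 or reference3d.ndim != 3:
        raise ValueError("expected a 4D series and a 3D reference")
    if series4d.shape[:3] != reference3d.shape:
        raise ValueError("spatial shapes differ")
    reports = [
        evaluate_pair(series4d[..., i], reference3d, mask, bins)
        for i in range(series4d.shape[3])
    ]
    return MetricReport(
        mse=float(np.mean([r.mse for r in reports])),
        ncc=float(np.mean([r.ncc for r in reports])),
        mi=float(np.mean([r.mi for r in reports])),
        nmi=float(np.mean([r.nmi for r in reports])),
        n_pixels=reports[0].n_pixels,
        histogram_bins=bins,
    )
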