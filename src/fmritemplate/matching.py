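"""Feature matching by Euclidean distance with the nearest/second-nearest
ratio test, plus the matching-similarity statistic.

For every descriptor of the image to be registered, the nearest and
second-nearest reference descriptors are found by exhaustive Euclidean
search; the match is accepted when nearest / second-nearest < threshold
(0.9 by default).  Matches are made one-to-one: if several moving
descriptors claim the same reference keypoint, only the closest claim
survives (ties broken by lower moving index).

The matching similarity between two keypoint sets is
100 · n_matches / min(n_ref, n_mov) percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .gloh_descriptor import Descriptor

DEFAULT_RATIO_THRESHOLD = 0.9


@dataclass
class MatchSet:
    """One-to-one index pairs between two descriptor lists.

    ``pairs`` rows are (index_ref, index_mov, distance, ratio); each side's
    index appears at most once.
    """

    pairs: List[Tuple[int, int, float, float]]
    n_ref: int
    n_mov: int
    threshold: float = DEFAULT_RATIO_THRESHOLD

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ref_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def mov_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _as_matrix(descs: Sequence) -> np.ndarray:
    if len(descs) == 0:
        return np.zeros((0, 1))
    rows = [d.vector if isinstance(d, Descriptor) else np.asarray(d, float)
            for d in descs]
    return np.vstack(rows)


def match_features(
    ref_desc: Sequence,
    mov_desc: Sequence,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> MatchSet:
    """Ratio-test matching with one-to-one pruning.

    Accepts :class:`Descriptor` lists or raw vector sequences.  A moving
    descriptor whose nearest and second-nearest reference distances are d1
    and d2 is kept iff d1/d2 < threshold (d1 = d2 = 0, i.e. exact
    duplicates of an exact match, count as ratio 0).  Fewer than two
    reference descriptors leave the ratio undefined: the result is empty
    and a warning is issued.
    """
    n_ref, n_mov = len(ref_desc), len(mov_desc)
    if n_ref < 2 or n_mov == 0:
        if n_ref < 2:
            warnings.warn(
                "need at least 2 reference descriptors for the ratio test",
                stacklevel=2,
            )
        return MatchSet(pairs=[], n_ref=n_ref, n_mov=n_mov, threshold=threshold)

    dists = cdist(_as_matrix(mov_desc), _as_matrix(ref_desc))
    order = np.argsort(dists, axis=1, kind="stable")
    nearest = order[:, 0]
    d1 = dists[np.arange(n_mov), nearest]
    d2 = dists[np.arange(n_mov), order[:, 1]]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d1 == 0.0, 0.0, d1 / d2)
    ratio = np.where((d2 == 0.0) & (d1 > 0.0), np.inf, ratio)

    # one-to-one: per reference index keep the smallest distance, then the
    # lower moving index
    best: dict = {}
    for j in range(n_mov):
        if not ratio[j] < threshold:
            continue
        i = int(nearest[j])
        cand = (float(d1[j]), j)
        if i not in best or cand < best[i]:
            best[i] = cand
    pairs = sorted(
        (i, j, d, float(ratio[j])) for i, (d, j) in best.items()
    )
    return MatchSet(pairs=pairs, n_ref=n_ref, n_mov=n_mov, threshold=threshold)


def matching_similarity(n_ref: int, n_mov: int, n_matches: int) -> float:
    """Matching similarity percentage: 100 · n_matches / min(n_ref, n_mov).

    Reported to two decimals, as in per-pair similarity tables.
    """
    if n_ref <= 0 or n_mov <= 0:
        raise ValueError("keypoint counts must be positive")
    if n_matches > min(n_ref, n_mov):
        raise ValueError("matches cannot exceed the smaller keypoint count")
    return round(100.0 * n_matches / min(n_ref, n_mov), 2)


def threshold_sweep(
    ref_desc: Sequence,
    mov_desc: Sequence,
    thresholds: Sequence[float],
) -> List[Tuple[float, int]]:
    """Match count as a function of the ratio threshold.

    The same acceptance rule (ratio test then one-to-one pruning) is applied
    at every threshold, so counts are monotone non-decreasing in the
    threshold.
    """
    return [
        (float(t), len(match_features(ref_desc, mov_desc, threshold=t)))
        for t in thresholds
    ]


def dump_matches_tsv(matches: MatchSet, path: str) -> None:
    """TSV dump: ref_idx, mov_idx, distance, ratio."""
    with open(path, "w") as fh:
        fh.write("ref_idx\tmov_idx\tdistance\tratio\n")
        for i, j, d, r in matches.pairs:
            fh.write(f"{i}\t{j}\t{d:.6f}\t{r:.6f}\n")
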