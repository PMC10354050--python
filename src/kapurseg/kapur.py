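"""Kapur's maximum-entropy criterion for multilevel thresholding.

A gray image with levels ``0..255`` is partitioned by ``M`` strictly
increasing thresholds ``th_1 < ... < th_M`` into ``M + 1`` classes::

    Class(0) = {0, ..., th_1 - 1}
    Class(j) = {th_j, ..., th_{j+1} - 1}
    Class(M) = {th_M, ..., 255}

i.e. a threshold value always *starts* the next class.  The objective is
the sum of the Shannon entropies of the normalized within-class
histograms,

    F(th_1..th_M) = sum_j E_j,
    E_j = -sum_{i in Class(j)} (P_i / w_j) ln(P_i / w_j),
    w_j = sum_{i in Class(j)} P_i,

with the conventions ``0 ln 0 := 0`` and an empty class (``w_j = 0``)
contributing 0.  Natural logarithms throughout.  ``F`` is maximized to
select thresholds that produce homogeneous intensity classes.

The module also provides an exhaustive combinatorial search over all
threshold tuples for ``M <= 3``; it serves as a ground-truth oracle for
the stochastic optimizers.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

N_LEVELS = 256


class InvalidThresholdError(ValueError):
    """Threshold set is unsorted, duplicated or out of the 1..255 range."""


def compute_histogram(image: np.ndarray) -> np.ndarray:
    """Count pixel frequencies per intensity level.

    Parameters
    ----------
    image : ndarray
        2-D integer array with values in ``[0, 255]``.

    Returns
    -------
    ndarray
        Length-256 vector of non-negative counts summing to the number
        of pixels.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot build a histogram of an empty image")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return np.bincount(image.astype(np.int64).ravel(), minlength=N_LEVELS)


def to_probabilities(hist: np.ndarray) -> np.ndarray:
    """Normalize a 256-bin histogram to a probability vector P_i = f_i / N."""
    hist = np.asarray(hist, dtype=np.float64)
    n = hist.sum()
    if n <= 0:
        raise ZeroDivisionError("histogram has zero total mass")
    return hist / n


def _validate_thresholds(thresholds: np.ndarray) -> np.ndarray:
    th = np.asarray(thresholds, dtype=np.int64).ravel()
    if th.size < 1 or th.size > N_LEVELS - 1:
        raise InvalidThresholdError(f"need 1..255 thresholds, got {th.size}")
    if np.any(th < 1) or np.any(th > N_LEVELS - 1):
        raise InvalidThresholdError("thresholds must lie in [1, 255]")
    if np.any(np.diff(th) <= 0):
        raise InvalidThresholdError("thresholds must be strictly increasing")
    return th


class KapurObjective:
    """Kapur entropy evaluator with O(1) per-class cost.

    Precomputes cumulative sums of ``P_i`` and ``P_i ln P_i`` so that the
    entropy of a class reduces to ``ln w_j - S_j / w_j`` where ``S_j`` is
    the partial sum of ``P_i ln P_i`` over the class.  This makes a
    single evaluation O(M) instead of O(256), which matters inside the
    population optimizers and the exhaustive oracle.
    """

    def __init__(self, p: np.ndarray):
        p = np.asarray(p, dtype=np.float64)
        if p.shape != (N_LEVELS,):
            raise ValueError("probability vector must have 256 entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.p = p
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        # index k holds the sum over levels [0, k)
        self._cum_p = np.concatenate(([0.0], np.cumsum(p)))
        self._cum_plogp = np.concatenate(([0.0], np.cumsum(plogp)))

    def class_entropy(self, lo: int, hi: int) -> float:
        """Entropy of the class covering levels ``[lo, hi)``; 0 if empty.

        Class mass below ~1e-13 is treated as empty: the cumulative-sum
        difference is dominated by cancellation error at that scale, and
        such a class is unrealizable in an integer-count histogram.
        """
        w = self._cum_p[hi] - self._cum_p[lo]
        if w <= 1e-13:
            return 0.0
        s = self._cum_plogp[hi] - self._cum_plogp[lo]
        return float(np.log(w) - s / w)

    def __call__(self, thresholds: np.ndarray) -> float:
        th = _validate_thresholds(thresholds)
        edges = np.concatenate(([0], th, [N_LEVELS]))
        return float(sum(self.class_entropy(int(a), int(b))
                         for a, b in zip(edges[:-1], edges[1:])))


def kapur_entropy(p: np.ndarray, thresholds: np.ndarray) -> float:
    """Total Kapur entropy F of a threshold set over probability vector `p`."""
    return KapurObjective(p)(thresholds)


def exhaustive_optimal_thresholds(p: np.ndarray, m: int) -> tuple[np.ndarray, float]:
    """Globally optimal thresholds by full enumeration (oracle, ``m <= 3``).

    Enumerates every strictly increasing tuple of ``m`` thresholds in
    ``[1, 255]`` and returns the maximizer of the Kapur entropy, breaking
    ties by the lexicographically smallest tuple.
    """
    if m not in (1, 2, 3):
        raise ValueError("exhaustive oracle supports m in {1, 2, 3} only")
    obj = KapurObjective(p)
    best_th: tuple[int, ...] | None = None
    best_f = -np.inf
    for th in combinations(range(1, N_LEVELS), m):
        edges = (0,) + th + (N_LEVELS,)
        f = sum(obj.class_entropy(edges[j], edges[j + 1]) for j in range(m + 1))
        if f > best_f + 1e-15:
            best_f = f
            best_th = th
    assert best_th is not None
    return np.array(best_th, dtype=np.int64), float(best_f)
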