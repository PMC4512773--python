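"""Discrete mutual information and greedy mRMR selection (MID criterion).

Minimal-Redundancy-Maximal-Relevance (mRMR) ranks features by balancing
relevance to the class label against redundancy with features already
chosen.  The MID (Mutual Information Difference) form used here scores an
unselected feature x_j at step t as

    I(x_j; c) - (1/|S|) * sum_{x_i in S} I(x_j; x_i)

where S is the selected set and I is plug-in mutual information over the
empirical joint histogram of the categorical codes, in bits.  Step one
simply maximizes relevance.  Ties are broken by higher relevance, then
lower input index, making the ordering deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, ParameterError
from .preprocess import DiscreteMatrix

__all__ = ["RankedFeatureList", "mutual_information", "mrmr_mid_select"]


@dataclass
class RankedFeatureList:
    """Features in selection order with their MID score at the step each
    was chosen and their relevance I(x; c)."""

    feature_ids: list[str]
    scores: np.ndarray
    relevance: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.relevance = np.asarray(self.relevance, dtype=float)
        if len({*self.feature_ids}) != len(self.feature_ids):
            raise ParameterError("duplicate feature ids in ranking")

    def __len__(self) -> int:
        return len(self.feature_ids)


def _encode(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary categorical values to dense integers 0..k-1."""
    _, codes = np.unique(np.asarray(v), return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1 if codes.size else 0


def _mi_profile(X: np.ndarray, y: np.ndarray, x_levels: int, y_levels: int) -> np.ndarray:
    """Mutual information, in bits, between every row of ``X`` and ``y``.

    ``X`` is ``(F, n)`` with entries in ``[0, x_levels)``; ``y`` is ``(n,)``
    with entries in ``[0, y_levels)``.  Plug-in (maximum-likelihood)
    estimate on the joint counts; the 0*log0 terms are dropped.
    """
    n = y.size
    mi = np.zeros(X.shape[0])
    # marginal counts per row of X
    nx = np.stack([(X == a).sum(axis=1) for a in range(x_levels)], axis=1)
    for b in range(y_levels):
        mask = y == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        Xb = X[:, mask]
        for a in range(x_levels):
            nab = (Xb == a).sum(axis=1)
            pos = nab > 0
            if not pos.any():
                continue
            mi[pos] += (nab[pos] / n) * np.log2(
                nab[pos] * n / (nx[pos, a] * nb)
            )
    # clip tiny negative round-off
    return np.maximum(mi, 0.0)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two categorical vectors, in bits.

    Symmetric, non-negative, and equal to the empirical entropy H(x) when
    ``y`` is a relabeling of ``x``.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if x.size == 0:
        raise ParameterError("vectors must be non-empty")
    xc, kx = _encode(x)
    yc, ky = _encode(y)
    return float(_mi_profile(xc[None, :], yc, kx, ky)[0])


def _greedy_mid(
    X: np.ndarray, y: np.ndarray, k: int, x_levels: int = 3
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Greedy MID forward selection on an encoded code matrix.

    ``X`` is ``(F, n)`` with entries in ``[0, x_levels)``; ``y`` encoded
    ``0..K-1``.  Returns (selected row indices in order, score at each
    step, relevance of all F features).
    """
    F = X.shape[0]
    y_levels = int(y.max()) + 1
    relevance = _mi_profile(X, y, x_levels, y_levels)
    available = np.ones(F, dtype=bool)
    redundancy_sum = np.zeros(F)
    selected: list[int] = []
    scores = np.empty(k)
    for t in range(k):
        objective = relevance if t == 0 else relevance - redundancy_sum / t
        masked = np.where(available, objective, -np.inf)
        best = masked.max()
        # objectives within an ulp-scale band are mathematical ties (the
        # same MI sums accumulated in different orders); break them by
        # higher relevance, then lower input index
        ties = np.flatnonzero(masked >= best - 1e-10)
        if ties.size > 1:
            r = relevance[ties]
            ties = ties[r >= r.max() - 1e-10]
        j = int(ties[0])
        selected.append(j)
        scores[t] = objective[j]
        available[j] = False
        if t < k - 1:
            redundancy_sum += _mi_profile(X, X[j], x_levels, x_levels)
    return selected, scores, relevance


def mrmr_mid_select(
    codes: DiscreteMatrix, labels: np.ndarray, k: int
) -> RankedFeatureList:
    """Select ``k`` features by greedy mRMR under the MID criterion.

    ``labels`` is the per-sample class vector aligned to the matrix
    columns (use the class, never the subclass).  The first feature is the
    most class-relevant one; subsequent picks maximize relevance minus
    mean pairwise mutual information with the already-selected set.
    """
    if not 1 <= k <= codes.n_features:
        raise ParameterError(
            f"k={k} out of range for {codes.n_features} features"
        )
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size != codes.n_samples:
        raise ParameterError("labels must align with sample columns")
    y, y_levels = _encode(labels)
    if y_levels < 2:
        raise DegenerateDataError("selection needs at least two class labels")
    X = (codes.codes + 1).astype(np.int64)  # {-1,0,1} -> {0,1,2}
    order, scores, relevance = _greedy_mid(X, y, k)
    return RankedFeatureList(
        feature_ids=[codes.feature_ids[i] for i in order],
        scores=scores,
        relevance=relevance[order],
    )
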