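"""Preprocessing: per-sample normalization, sparsity filtering, discretization.

Raw read counts are converted to relative abundances (each sample column
divided by its total), features that are zero in at least 80% of samples
are dropped, and the surviving matrix is discretized per feature into three
levels around its mean: values above mu + sigma/2 become +1, values below
mu - sigma/2 become -1, everything else 0.  The three-level coding tames
heavy-tailed abundance noise and is what the discrete mutual-information
machinery in :mod:`metaboot.mrmr` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateDataError, ParameterError
from .table import AbundanceTable

__all__ = [
    "DiscreteMatrix",
    "DiscretizationModel",
    "normalize_relative",
    "filter_sparse",
    "discretize",
    "discretize_values",
]


@dataclass
class DiscretizationModel:
    """Per-feature mean and standard deviation used for three-level coding.

    ``ddof`` records the denominator convention (1 = sample sd, the
    default; 0 = population sd)."""

    means: np.ndarray
    stds: np.ndarray
    ddof: int = 1

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if self.means.shape != self.stds.shape or self.means.ndim != 1:
            raise ParameterError("means and stds must be 1-D arrays of equal length")
        if np.any(self.stds < 0):
            raise ParameterError("standard deviations must be non-negative")


@dataclass
class DiscreteMatrix:
    """Three-level codes {-1, 0, +1} with the same ids as the source table."""

    feature_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ParameterError("codes shape does not match ids")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ParameterError("codes must lie in {-1, 0, +1}")
        self.codes = self.codes.astype(np.int8)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total so columns sum to one.

    Idempotent: a table of relative abundances passes through (numerically)
    unchanged.  A sample whose column sums to zero has no reads at all and
    raises :class:`DegenerateDataError`.
    """
    if np.any(table.values < 0):
        raise DegenerateDataError("negative values cannot be normalized as counts")
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise DegenerateDataError(
            f"sample(s) with zero total abundance: {[table.sample_ids[i] for i in zero[:5]]}"
        )
    out = replace(table, values=table.values / sums, is_normalized=True)
    assert np.allclose(out.values.sum(axis=0), 1.0, atol=1e-9)
    return out


def filter_sparse(
    table: AbundanceTable, zero_fraction: float = 0.8
) -> tuple[AbundanceTable, list[str]]:
    """Drop features that are zero in at least ``zero_fraction`` of samples.

    The boundary is inclusive: with the default 0.8, a feature with exactly
    80% zeros is removed.  Returns the filtered table (survivor order
    preserved) and the list of removed feature ids.
    """
    if not 0 < zero_fraction <= 1:
        raise ParameterError("zero_fraction must be in (0, 1]")
    frac = (table.values == 0).mean(axis=1)
    keep = frac < zero_fraction
    if not keep.any():
        raise DegenerateDataError("all features removed by the sparsity filter")
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    filtered = replace(
        table,
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        values=table.values[keep],
    )
    return filtered, removed


def discretize_values(
    values: np.ndarray, *, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three-level coding of a ``(features, samples)`` matrix.

    Returns ``(codes, means, stds)``.  The inequalities are strict, so a
    value exactly on a threshold codes to 0, and a constant feature
    (sigma = 0) codes to all zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise DegenerateDataError("discretization needs at least two samples")
    means = values.mean(axis=1)
    stds = values.std(axis=1, ddof=ddof)
    half = stds[:, None] / 2.0
    mu = means[:, None]
    codes = np.zeros(values.shape, dtype=np.int8)
    codes[values > mu + half] = 1
    codes[values < mu - half] = -1
    return codes, means, stds


def discretize(
    table: AbundanceTable, *, ddof: int = 1
) -> tuple[DiscreteMatrix, DiscretizationModel]:
    """Discretize every feature of ``table`` by its own mean and sd."""
    codes, means, stds = discretize_values(table.values, ddof=ddof)
    return (
        DiscreteMatrix(list(table.feature_ids), list(table.sample_ids), codes),
        DiscretizationModel(means, stds, ddof=ddof),
    )
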