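"""Scoring selections against ground truth, comparator methods, and the
classification / significance utilities.

Metrics (all on the selected feature list of size m):

* redundancy rate   = 100 * (# redundant features) / m, where a selected
  positive feature is redundant when its marker group already has an
  earlier selected representative;
* non-redundancy rate = 100 - redundancy rate;
* error rate        = 100 * (# selected negative features) / m;
* classification accuracy = 100 * (# correctly classified test samples) /
  (# test samples), averaged over cross-validation folds.

The rank-sum comparator mirrors the bottom-up baseline: every feature is
tested between the two classes with the two-sided Wilcoxon rank-sum test
(exact null for tiny tie-free groups, otherwise the normal approximation
with tie and continuity corrections) and the k smallest-p features are
returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .exceptions import ConsistencyError, DegenerateDataError, ParameterError
from .simulate import GroundTruth
from .table import AbundanceTable, SampleMetadata

__all__ = [
    "EvaluationReport",
    "score_selection",
    "count_positive",
    "wilcoxon_select",
    "svm_cv_accuracy",
    "permutation_exact_test",
    "aggregate_reports",
]

# easy.py-style RBF grid: log2 C in -5..15 step 2, log2 gamma in -15..3 step 2
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class EvaluationReport:
    """Redundancy/error metrics for one selected feature list."""

    n_selected: int
    redundancy_rate: float
    non_redundancy_rate: float
    error_rate: float
    positive_count: int
    classification_accuracy: float | None = None


def score_selection(selected: list[str], truth: GroundTruth) -> EvaluationReport:
    """Score a ranked selection against the ground truth.

    Redundant features are selected positives beyond the first
    representative of their group (negatives count toward the error rate
    only, never as redundant).
    """
    if not selected:
        raise ParameterError("empty selection")
    seen_groups: set[str] = set()
    redundant = negatives = positives = 0
    for fid in selected:
        if truth.is_positive_feature(fid):
            positives += 1
            group = truth.group_of(fid)
            if group in seen_groups:
                redundant += 1
            seen_groups.add(group)
        else:
            negatives += 1
    m = len(selected)
    redundancy = 100.0 * redundant / m
    return EvaluationReport(
        n_selected=m,
        redundancy_rate=redundancy,
        non_redundancy_rate=100.0 - redundancy,
        error_rate=100.0 * negatives / m,
        positive_count=positives,
    )


def count_positive(selected: list[str], truth: GroundTruth) -> int:
    """Number of selected features that are true positive markers."""
    if not selected:
        raise ParameterError("empty selection")
    return sum(truth.is_positive_feature(f) for f in selected)


def wilcoxon_select(
    table: AbundanceTable, metadata: SampleMetadata, k: int
) -> list[tuple[str, float]]:
    """Rank features by the two-sided rank-sum p-value between classes.

    Returns the ``k`` smallest-p ``(feature_id, p)`` pairs, p-values
    non-decreasing; ties keep input feature order.  Exactly two classes
    are required, each with at least two samples.
    """
    metadata = metadata.aligned_to(table)
    classes = metadata.classes
    if len(classes) != 2:
        raise DegenerateDataError(f"rank-sum comparator needs exactly 2 classes, got {len(classes)}")
    if not 1 <= k <= table.n_features:
        raise ParameterError(f"k={k} out of range")
    y = metadata.class_vector()
    a, b = table.values[:, y == 0], table.values[:, y == 1]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DegenerateDataError("each class needs at least two samples")
    # scipy picks the exact null distribution for tiny tie-free groups and
    # the tie/continuity-corrected normal approximation otherwise
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="auto")
    pvals = np.asarray(res.pvalue, dtype=float)
    # constant features produce no rank separation: p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    order = np.argsort(pvals, kind="stable")[:k]
    return [(table.feature_ids[i], float(pvals[i])) for i in order]


def svm_cv_accuracy(
    table: AbundanceTable,
    selected: list[str],
    metadata: SampleMetadata,
    folds: int = 6,
    seed: int = 0,
    *,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 5,
) -> float:
    """Cross-validated RBF-SVM accuracy (percent) on the selected features.

    Per outer fold, features are min-max scaled to [-1, 1] on the
    training split only and (C, gamma) are grid-searched by inner
    stratified cross-validation before scoring the held-out fold; the
    returned value is the mean held-out accuracy times 100.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    metadata = metadata.aligned_to(table)
    sub = table.subset_features(selected)
    X = sub.values.T  # samples x features
    y = metadata.class_vector()
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ParameterError(
            f"folds={folds} exceeds the smallest class size {counts.min()}"
        )
    pipe = Pipeline(
        [("scale", MinMaxScaler(feature_range=(-1, 1))), ("svm", SVC(kernel="rbf"))]
    )
    grid = GridSearchCV(
        pipe,
        {"svm__C": list(c_grid), "svm__gamma": list(gamma_grid)},
        cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
        n_jobs=None,
    )
    outer = StratifiedKFold(folds, shuffle=True, random_state=seed)
    accuracies = []
    for train, test in outer.split(X, y):
        grid.fit(X[train], y[train])
        correct = int((grid.predict(X[test]) == y[test]).sum())
        accuracies.append(100.0 * correct / test.size)
    return float(np.mean(accuracies))


def permutation_exact_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    max_exact: int = 20,
    n_draws: int = 20000,
    seed: int | None = None,
) -> float:
    """One-way exact permutation test on the difference of group means.

    All C(n_a+n_b, n_a) reassignments of the pooled values are enumerated
    (combined size up to ``max_exact``) and the two-sided p-value is the
    fraction with |mean difference| at least the observed one.  Larger
    problems fall back to ``n_draws`` Monte-Carlo permutations (the
    observed assignment is always counted).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    total = pooled.sum()
    tol = 1e-12 * max(1.0, observed)

    if n <= max_exact:
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (total - sa) / (n - na))
            if stat >= observed - tol:
                count += 1
        return count / comb(n, na)

    rng = np.random.default_rng(seed)
    count = 1  # the observed assignment
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        if stat >= observed - tol:
            count += 1
    return count / (n_draws + 1)


def aggregate_reports(reports: list[EvaluationReport]) -> dict[str, tuple[float, float]]:
    """Mean and sample sd (ddof=1) of each metric over replicate reports."""
    if not reports:
        raise ParameterError("no reports to aggregate")

    def ms(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    out = {
        "non_redundancy_rate": ms([r.non_redundancy_rate for r in reports]),
        "redundancy_rate": ms([r.redundancy_rate for r in reports]),
        "error_rate": ms([r.error_rate for r in reports]),
        "positive_count": ms([float(r.positive_count) for r in reports]),
    }
    accs = [r.classification_accuracy for r in reports if r.classification_accuracy is not None]
    if accs:
        out["classification_accuracy"] = ms(accs)
    return out
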