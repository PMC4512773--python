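"""The MetaBoot selection pipeline.

Biomarker discovery proceeds in three stages: (1) a first mRMR screen of
the full discretized table keeps the M most informative, least redundant
candidate features; (2) B stratified bootstrap replicates of the samples
are drawn — resampling with replacement within each subclass (or class)
so every replicate keeps the original stratum sizes — and mRMR re-selects
the top M' candidates on each replicate; (3) candidates are ranked by how
many of the B bootstrap lists they appear in, and the M' most frequent
become the final biomarkers.  The bootstrap stage is what suppresses both
negative markers (whose selection is unstable) and redundant positives
(group members substitute for one another across replicates, splitting
their occurrence counts).

Randomness flows from one root seed through per-bootstrap child streams
(numpy ``SeedSequence.spawn``), so replicate b is the same no matter how
many replicates are drawn — growing B only appends new bootstraps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ParameterError
from .mrmr import _encode, _greedy_mid
from .preprocess import discretize, discretize_values
from .table import AbundanceTable, SampleMetadata

__all__ = [
    "MetaBootParams",
    "BootstrapSelection",
    "BiomarkerResult",
    "stratified_bootstrap",
    "rank_by_occurrence",
    "run_metaboot",
    "sweep_parameters",
    "write_result",
]


@dataclass(frozen=True)
class MetaBootParams:
    """The three MetaBoot parameters plus the root seed.

    M
        Number of first-stage candidates (default 50).
    B
        Number of stratified bootstrap replicates (default 40).
    m_prime
        Number of features selected per bootstrap and returned as final
        biomarkers (default 10).  M must exceed m_prime.
    """

    M: int = 50
    B: int = 40
    m_prime: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M <= 0 or self.B <= 0 or self.m_prime <= 0:
            raise ParameterError("M, B and M' must be positive")
        if self.M <= self.m_prime:
            raise ParameterError(
                f"M ({self.M}) must be greater than M' ({self.m_prime})"
            )


@dataclass
class BootstrapSelection:
    """One bootstrap replicate: its index, the resampled sample indices
    (with repetition) and the ordered M' features mRMR picked on it."""

    index: int
    sample_indices: np.ndarray
    feature_ids: list[str]


@dataclass
class BiomarkerResult:
    """Final biomarkers with their bootstrap support.

    ``occurrence`` maps every first-stage candidate to the number of
    bootstrap lists containing it (these sum to B * M');
    ``mean_bootstrap_rank`` is the average 1-based position of a feature
    within the bootstrap lists that contain it (NaN if never selected).
    """

    feature_ids: list[str]
    occurrence_counts: list[int]
    candidates: list[str]
    occurrence: dict[str, int]
    mean_bootstrap_rank: dict[str, float]
    params: MetaBootParams
    selections: list[BootstrapSelection] = field(repr=False, default_factory=list)


def stratified_bootstrap(
    strata: list[str] | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Resample sample indices with replacement, stratum by stratum.

    For each stratum of size n_s, n_s indices are drawn uniformly with
    replacement from that stratum, so the replicate has exactly the same
    per-stratum composition as the original design.
    """
    strata = np.asarray(strata)
    if strata.size == 0:
        raise DegenerateDataError("no samples to bootstrap")
    out = np.empty(strata.size, dtype=np.int64)
    pos = 0
    for label in dict.fromkeys(strata.tolist()):  # original stratum order
        members = np.flatnonzero(strata == label)
        out[pos : pos + members.size] = rng.choice(members, size=members.size)
        pos += members.size
    return out


def rank_by_occurrence(
    selections: list[BootstrapSelection],
    m_prime: int,
    first_stage_rank: dict[str, int] | None = None,
) -> list[tuple[str, int]]:
    """Rank candidate features by bootstrap occurrence count.

    Ties are broken by lower mean within-bootstrap rank, then by lower
    first-stage rank (when provided).  Returns the top ``m_prime``
    ``(feature_id, count)`` pairs.
    """
    if not selections:
        raise ParameterError("no bootstrap selections to rank")
    counts: dict[str, int] = {}
    rank_sums: dict[str, int] = {}
    for sel in selections:
        for r, fid in enumerate(sel.feature_ids, start=1):
            counts[fid] = counts.get(fid, 0) + 1
            rank_sums[fid] = rank_sums.get(fid, 0) + r
    fs_rank = first_stage_rank or {}
    ordered = sorted(
        counts,
        key=lambda f: (
            -counts[f],
            rank_sums[f] / counts[f],
            fs_rank.get(f, np.inf),
            f,
        ),
    )
    return [(f, counts[f]) for f in ordered[:m_prime]]


def run_metaboot(
    table: AbundanceTable,
    metadata: SampleMetadata,
    params: MetaBootParams = MetaBootParams(),
    *,
    rediscretize_per_bootstrap: bool = True,
    ddof: int = 1,
) -> BiomarkerResult:
    """Run the full three-stage MetaBoot selection.

    ``table`` must already be normalized and sparsity-filtered (synthetic
    benchmark matrices are used as generated).  Each bootstrap replicate
    is treated as a fresh dataset: the per-feature mean and sd are
    re-estimated on the resampled columns before three-level coding, just
    as the first stage codes the original table (pass
    ``rediscretize_per_bootstrap=False`` to reuse the full-table codes
    inside every replicate instead — cheaper, slightly less robust).  The
    result is a pure function of (data, params): identical seeds give
    identical output.
    """
    metadata = metadata.aligned_to(table)
    if len(metadata.classes) < 2:
        raise DegenerateDataError("need at least two classes")
    if params.M > table.n_features:
        raise ParameterError(
            f"M={params.M} exceeds the {table.n_features} available features"
        )
    codes, _ = discretize(table, ddof=ddof)
    y, _ = _encode(metadata.class_vector())
    X = (codes.codes + 1).astype(np.int64)

    # stage 1: screen to M candidates on the full table
    order, _, _ = _greedy_mid(X, y, params.M)
    candidates = [table.feature_ids[i] for i in order]
    cand_rows = np.asarray(order)
    first_stage_rank = {f: r for r, f in enumerate(candidates, start=1)}

    # stage 2: B stratified bootstraps, mRMR top-M' on candidates only
    strata = np.asarray(metadata.strata())
    children = np.random.SeedSequence(params.seed).spawn(params.B)
    cand_values = table.values[cand_rows]
    selections: list[BootstrapSelection] = []
    for b in range(params.B):
        rng = np.random.default_rng(children[b])
        idx = stratified_bootstrap(strata, rng)
        if rediscretize_per_bootstrap:
            Xb = (discretize_values(cand_values[:, idx], ddof=ddof)[0] + 1).astype(
                np.int64
            )
        else:
            Xb = X[cand_rows][:, idx]
        sel, _, _ = _greedy_mid(Xb, y[idx], params.m_prime)
        selections.append(
            BootstrapSelection(
                index=b + 1,
                sample_indices=idx,
                feature_ids=[candidates[i] for i in sel],
            )
        )

    # stage 3: occurrence ranking
    top = rank_by_occurrence(selections, params.m_prime, first_stage_rank)
    occurrence = {f: 0 for f in candidates}
    rank_sums: dict[str, int] = {}
    for sel in selections:
        for r, fid in enumerate(sel.feature_ids, start=1):
            occurrence[fid] += 1
            rank_sums[fid] = rank_sums.get(fid, 0) + r
    mean_rank = {
        f: (rank_sums[f] / occurrence[f] if occurrence[f] else float("nan"))
        for f in candidates
    }
    return BiomarkerResult(
        feature_ids=[f for f, _ in top],
        occurrence_counts=[c for _, c in top],
        candidates=candidates,
        occurrence=occurrence,
        mean_bootstrap_rank=mean_rank,
        params=params,
        selections=selections,
    )


def mrmr_only_select(
    table: AbundanceTable,
    metadata: SampleMetadata,
    k: int,
    *,
    ddof: int = 1,
) -> list[str]:
    """One-shot mRMR baseline: a single MID selection of ``k`` features on
    the full discretized table, no bootstrap stage."""
    metadata = metadata.aligned_to(table)
    codes, _ = discretize(table, ddof=ddof)
    y, y_levels = _encode(metadata.class_vector())
    if y_levels < 2:
        raise DegenerateDataError("need at least two classes")
    if not 1 <= k <= table.n_features:
        raise ParameterError(f"k={k} out of range")
    X = (codes.codes + 1).astype(np.int64)
    order, _, _ = _greedy_mid(X, y, k)
    return [table.feature_ids[i] for i in order]


def sweep_parameters(
    table: AbundanceTable,
    metadata: SampleMetadata,
    M_grid: list[int],
    B_grid: list[int],
    params: MetaBootParams = MetaBootParams(),
    truth=None,
) -> dict[str, dict[int, int]]:
    """Unique-feature counts over grids of M and B, for elbow selection.

    For each M in ``M_grid``: the number of distinct positive marker
    groups represented in the first-stage top-M (or distinct features when
    no ground truth is given).  For each B in ``B_grid``: the number of
    distinct features appearing in any bootstrap top-M' list among the
    first B replicates.  Bootstrap streams are nested, so the B-curve is
    non-decreasing by construction.
    """
    if not M_grid or not B_grid:
        raise ParameterError("grids must be non-empty")
    metadata = metadata.aligned_to(table)
    codes, _ = discretize(table)
    y, _ = _encode(metadata.class_vector())
    X = (codes.codes + 1).astype(np.int64)

    m_max = max(M_grid)
    if m_max > table.n_features:
        raise ParameterError("M grid exceeds feature count")
    order, _, _ = _greedy_mid(X, y, m_max)
    ranked = [table.feature_ids[i] for i in order]
    m_curve: dict[int, int] = {}
    for M in sorted(M_grid):
        top = ranked[:M]
        if truth is not None:
            groups = {
                truth.group_of(f) for f in top if truth.is_positive_feature(f)
            }
            m_curve[M] = len(groups)
        else:
            m_curve[M] = len(set(top))

    b_max = max(B_grid)
    result = run_metaboot(
        table,
        metadata,
        MetaBootParams(params.M, b_max, params.m_prime, params.seed),
    )
    b_curve: dict[int, int] = {}
    seen: set[str] = set()
    wanted = sorted(B_grid)
    for sel in result.selections:
        seen.update(sel.feature_ids)
        if sel.index in wanted:
            b_curve[sel.index] = len(seen)
    return {"M": m_curve, "B": b_curve}


def write_result(result: BiomarkerResult, path: str | Path) -> None:
    """Write the final biomarkers as TSV plus a JSON provenance sidecar."""
    path = Path(path)
    fs_rank = {f: r for r, f in enumerate(result.candidates, start=1)}
    pd.DataFrame(
        {
            "feature_id": result.feature_ids,
            "occurrence_count": result.occurrence_counts,
            "mean_bootstrap_rank": [
                result.mean_bootstrap_rank[f] for f in result.feature_ids
            ],
            "first_stage_rank": [fs_rank[f] for f in result.feature_ids],
        }
    ).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "M": result.params.M,
                "B": result.params.B,
                "M_prime": result.params.m_prime,
                "seed": result.params.seed,
            },
            indent=2,
        )
    )
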