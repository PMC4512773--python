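"""End-to-end benchmark orchestration: simulate -> select -> evaluate.

A :class:`RunConfig` names either a synthetic design (s1/s2/s3) or a pair
of input files, the selection arms to run (metaboot, one-shot mrmr,
wilcoxon), the selection size, and the replicate seeds.  For every
replicate seed the data is generated (or loaded), each enabled arm
selects its features, the selection is scored against the ground truth,
and the per-arm metrics are aggregated as mean +/- sample sd — the
layout of the published redundancy and robustness comparisons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .evaluate import EvaluationReport, aggregate_reports, score_selection, wilcoxon_select
from .exceptions import ParameterError
from .selector import MetaBootParams, mrmr_only_select, run_metaboot
from .simulate import generate_s1, generate_s2, generate_s3
from .table import read_abundance_table

__all__ = ["RunConfig", "run_benchmark"]

_GENERATORS = {"s1": generate_s1, "s2": generate_s2, "s3": generate_s3}
_METHODS = ("metaboot", "mrmr", "wilcoxon")


@dataclass
class RunConfig:
    """One benchmark run: data source, arms, sizes, replicate seeds."""

    design: str | None = None  # s1 | s2 | s3
    sd: float = 1.0  # S1 only
    table_path: str | None = None
    metadata_path: str | None = None
    truth_path: str | None = None  # required with file inputs for scoring
    methods: tuple[str, ...] = ("metaboot",)
    selection_size: int = 10
    M: int = 50
    B: int = 40
    seeds: tuple[int, ...] = (0,)
    folds: int = 6
    out_dir: str | None = None

    def __post_init__(self) -> None:
        from_files = self.table_path is not None
        if from_files != (self.metadata_path is not None):
            raise ParameterError("table_path and metadata_path go together")
        if (self.design is None) == (not from_files):
            raise ParameterError("give exactly one input source: design XOR files")
        if self.design is not None and self.design not in _GENERATORS:
            raise ParameterError(f"unknown design {self.design!r}; pick one of {sorted(_GENERATORS)}")
        unknown = [m for m in self.methods if m not in _METHODS]
        if unknown:
            raise ParameterError(f"unknown method(s) {unknown}; pick from {_METHODS}")
        if len(set(self.seeds)) != len(self.seeds):
            raise ParameterError("replicate seeds must be distinct")
        if self.selection_size < 1:
            raise ParameterError("selection_size must be positive")
        if self.M <= self.selection_size:
            raise ParameterError("M must exceed the selection size")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("methods", "seeds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_truth(path: str | Path):
    from .simulate import GroundTruth

    frame = pd.read_csv(path, sep="\t", dtype=str)
    return GroundTruth(
        feature_ids=list(frame["feature_id"]),
        group_ids=list(frame["group_id"]),
        is_positive=frame["is_positive"].astype(int).to_numpy().astype(bool),
    )


def _replicate_inputs(config: RunConfig, seed: int):
    """(table, metadata, truth) for one replicate seed."""
    if config.design is not None:
        if config.design == "s1":
            ds = generate_s1(sd=config.sd, seed=seed)
        else:
            ds = _GENERATORS[config.design](seed=seed)
        return ds.table, ds.metadata, ds.truth
    table, meta = read_abundance_table(config.table_path, config.metadata_path)
    return table, meta, _load_truth(config.truth_path)


def run_benchmark(config: RunConfig) -> dict[str, Any]:
    """Run every configured arm over the replicate seeds and aggregate.

    Returns ``{"config_digest": ..., "arms": {method: {metric: (mean,
    sd)}}, "replicates": per-seed reports}``; when ``out_dir`` is set a
    TSV summary and a JSON provenance record are written there.
    """
    if config.design is None and config.truth_path is None:
        raise ParameterError(
            "benchmarking file inputs needs a ground-truth TSV (truth_path) "
            "to score selections against"
        )
    per_arm: dict[str, list[EvaluationReport]] = {m: [] for m in config.methods}
    for seed in config.seeds:
        table, meta, truth = _replicate_inputs(config, seed)
        for method in config.methods:
            if method == "metaboot":
                result = run_metaboot(
                    table,
                    meta,
                    MetaBootParams(config.M, config.B, config.selection_size, seed),
                )
                selected = result.feature_ids
            elif method == "mrmr":
                selected = mrmr_only_select(table, meta, config.selection_size)
            else:
                selected = [f for f, _ in wilcoxon_select(table, meta, config.selection_size)]
            per_arm[method].append(score_selection(selected, truth))

    arms = {m: aggregate_reports(reports) for m, reports in per_arm.items()}
    summary: dict[str, Any] = {
        "config_digest": config.digest(),
        "seeds": list(config.seeds),
        "arms": arms,
        "replicates": {
            m: [r.__dict__ for r in reports] for m, reports in per_arm.items()
        },
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for m, metrics in arms.items():
            for metric, (mean, sd) in metrics.items():
                rows.append({"method": m, "metric": metric, "mean": mean, "sd": sd})
        pd.DataFrame(rows).to_csv(out / "benchmark_summary.tsv", sep="\t", index=False)
        (out / "benchmark_provenance.json").write_text(
            json.dumps(
                {"config": config.__dict__, "digest": config.digest()},
                indent=2,
                default=str,
            )
        )
    return summary
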