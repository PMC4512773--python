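"""Synthetic benchmark generators with embedded ground truth.

Three designs, each 1,000 features with 10 redundant positive marker
groups of 10 features (100 positives) and 900 negative background
features, over two classes split into subclasses:

S1 (normal)
    120 samples = 2 classes x 3 subclasses x 20.  Every feature is
    Gaussian with a shared sd.  For positive groups 1-5 the per-feature,
    per-subclass mean is drawn from {11, 12, 13, 14} in class 1 and
    {17, 18, 19, 20} in class 2; groups 6-10 use the two vectors the
    other way round.  Negatives all have mean 15, so classes differ only
    through the positive groups.

S2 (mixture)
    100 samples = 2 classes x 2 subclasses x 25.  Positive groups 1-5
    are gamma in both classes with class-separated shape parameters;
    groups 6-10 are gamma in class 1 but normal in class 2 with means
    matched to the class-1 gamma means — the class difference is a
    difference of distributional shape, not location.  Negatives are
    normal(0.14, 0.06) everywhere.

S3 (gamma)
    120 samples = 2 classes x 3 subclasses x 20.  Everything is gamma;
    positive groups differ between classes in shape (and partly rate),
    negatives form three blocks of 300 features with subclass-invariant
    parameters.

Gamma blocks are parameterized by (shape, rate) with mean = shape/rate —
the R ``rgamma`` convention; numpy's scale is 1/rate.  Normal blocks are
left untruncated (small negative draws are kept).  Matrices are emitted
with the normalized flag set: the benchmark distributions are defined on
the generated scale and must not be renormalized before selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ParameterError
from .table import AbundanceTable, SampleMetadata, write_abundance_table, write_metadata

__all__ = ["GroundTruth", "SyntheticDataset", "generate_s1", "generate_s2", "generate_s3", "write_dataset"]

N_GROUPS = 10
GROUP_SIZE = 10

# --- S2 (mixture) parameter grid: 2 classes x 2 subclasses x 25 samples ----
# Positive groups 1-5: gamma in both classes (shape varies by subclass,
# rate by class).  Groups 6-10: gamma in class 1 (same parameters as
# groups 1-5), normal in class 2 with mean/sd tuned near the class-1
# gamma means.  Negatives: 900 features, normal(0.14, 0.06) everywhere.
S2_GAMMA_SHAPES = {  # subclass -> shapes for the five gamma archetypes
    1: (7.18, 0.61, 1.70, 0.81, 2.36),
    2: (6.98, 0.51, 1.80, 0.91, 2.46),
    3: (5.70, 0.85, 1.32, 0.33, 2.88),
    4: (6.60, 0.75, 1.22, 0.43, 2.98),
}
S2_GAMMA_RATES = {
    1: (44.38, 71.12, 517.0, 79.70, 316.0),
    2: (44.38, 71.12, 517.0, 79.70, 316.0),
    3: (44.38, 27.40, 210.0, 91.20, 507.0),
    4: (44.38, 27.40, 210.0, 91.20, 507.0),
}
S2_NORMAL_MEANS = {  # class-2 subclasses, groups 6-10
    3: (0.14, 0.009, 0.005, 0.004, 0.009),
    4: (0.13, 0.010, 0.004, 0.003, 0.010),
}
# Group 10's class-2 sd follows the stated construction rule (normal
# moments matched to the corresponding gamma archetype, whose sd is
# 0.0049); see docs/methods.md for why the value is 0.005.
S2_NORMAL_SDS = {
    3: (0.06, 0.007, 0.002, 0.006, 0.005),
    4: (0.06, 0.007, 0.002, 0.006, 0.005),
}
S2_NEGATIVE_MEAN, S2_NEGATIVE_SD = 0.14, 0.06

# --- S3 (gamma) parameter grid: 2 classes x 3 subclasses x 20 samples ------
S3_POS_SHAPES = {  # subclass -> shapes for positive groups 1-10
    1: (7.18, 0.61, 2.22, 1.70, 1.29, 0.87, 0.81, 2.56, 1.50, 1.66),
    2: (7.38, 0.71, 2.12, 1.80, 1.19, 0.67, 0.91, 2.46, 1.50, 1.56),
    3: (6.98, 0.51, 2.02, 1.90, 1.09, 0.77, 1.01, 2.36, 1.50, 1.46),
    4: (5.70, 0.85, 1.72, 0.92, 0.50, 1.37, 0.53, 3.28, 0.91, 2.49),
    5: (5.60, 0.75, 1.62, 0.82, 0.40, 1.47, 0.43, 3.28, 0.81, 2.39),
    6: (5.80, 0.95, 1.52, 0.72, 0.60, 1.57, 0.33, 3.28, 0.71, 2.59),
}
S3_POS_RATES_CLASS1 = (44.38, 71.12, 33.40, 517.0, 94.70, 203.0, 79.70, 316.0, 44.4, 66.16)
S3_POS_RATES_CLASS2 = (44.38, 27.40, 37.68, 210.0, 66.20, 734.0, 91.20, 507.0, 42.32, 171.0)
# Three negative blocks of 300 features, identical in every subclass.
S3_NEG_SHAPES = (6.20, 3.10, 0.61)
S3_NEG_RATES = (24.30, 66.40, 71.10)

# --- S1 (normal) mean vectors ----------------------------------------------
S1_LOW_MEANS = (11.0, 12.0, 13.0, 14.0)
S1_HIGH_MEANS = (17.0, 18.0, 19.0, 20.0)
S1_NEGATIVE_MEAN = 15.0


@dataclass
class GroundTruth:
    """Feature-level truth: marker group membership and positive status.

    Features sharing a positive group id are redundant by construction —
    they carry the same class signal up to sampling noise.
    """

    feature_ids: list[str]
    group_ids: list[str]
    is_positive: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.is_positive = np.asarray(self.is_positive, dtype=bool)
        if not (len(self.feature_ids) == len(self.group_ids) == self.is_positive.size):
            raise ParameterError("ground-truth fields must align")
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    def _row(self, feature_id: str) -> int:
        try:
            return self._index[feature_id]
        except KeyError:
            raise ConsistencyError(f"unknown feature id: {feature_id!r}") from None

    def group_of(self, feature_id: str) -> str:
        return self.group_ids[self._row(feature_id)]

    def is_positive_feature(self, feature_id: str) -> bool:
        return bool(self.is_positive[self._row(feature_id)])

    @property
    def n_positive(self) -> int:
        return int(self.is_positive.sum())


@dataclass
class SyntheticDataset:
    """A generated benchmark: matrix, sample labels, truth, provenance."""

    table: AbundanceTable
    metadata: SampleMetadata
    truth: GroundTruth
    provenance: dict[str, Any]


def _positive_ids() -> tuple[list[str], list[str]]:
    fids, gids = [], []
    for g in range(1, N_GROUPS + 1):
        for f in range(1, GROUP_SIZE + 1):
            fids.append(f"pos_g{g:02d}_f{f:02d}")
            gids.append(f"pos_g{g:02d}")
    return fids, gids


def _metadata(n_subclasses: int, per_subclass: int) -> SampleMetadata:
    """Two classes, equal subclass split, ``per_subclass`` samples each."""
    half = n_subclasses // 2
    sample_ids, classes, subclasses = [], [], []
    for sc in range(1, n_subclasses + 1):
        cls = "class1" if sc <= half else "class2"
        for i in range(1, per_subclass + 1):
            sample_ids.append(f"sub{sc}_s{i:02d}")
            classes.append(cls)
            subclasses.append(f"subclass{sc}")
    return SampleMetadata(sample_ids, classes, subclasses)


def generate_s1(sd: float = 1.0, seed: int | None = None, *, per_feature_means: bool = False) -> SyntheticDataset:
    """The normal-distribution benchmark: 1,000 features x 120 samples.

    ``sd`` is the common standard deviation of every feature (larger sd
    blurs the class separation).  With the default
    ``per_feature_means=False`` each (feature, subclass) cell draws its
    own mean from the group's 4-value vector; with ``True`` one mean per
    (feature, class) is drawn and shared by that class's three
    subclasses.  Drawn means are recorded in the provenance.
    """
    if sd <= 0:
        raise ParameterError("sd must be positive")
    rng = np.random.default_rng(seed)
    meta = _metadata(n_subclasses=6, per_subclass=20)
    pos_ids, pos_groups = _positive_ids()
    neg_ids = [f"neg_f{i:03d}" for i in range(1, 901)]
    n_samples = meta.n_samples
    values = np.empty((1000, n_samples))
    drawn_means: dict[str, dict[str, float]] = {}

    col = {f"subclass{sc}": slice((sc - 1) * 20, sc * 20) for sc in range(1, 7)}
    for row, (fid, gid) in enumerate(zip(pos_ids, pos_groups)):
        g = int(gid[len("pos_g"):])
        low_first = g <= 5  # groups 6-10 use the vectors reversely
        drawn_means[fid] = {}
        for sc in range(1, 7):
            vec = S1_LOW_MEANS if (sc <= 3) == low_first else S1_HIGH_MEANS
            if per_feature_means and sc in (2, 3, 5, 6):
                mean = drawn_means[fid][f"subclass{1 if sc <= 3 else 4}"]
            else:
                mean = float(rng.choice(vec))
            drawn_means[fid][f"subclass{sc}"] = mean
            values[row, col[f"subclass{sc}"]] = rng.normal(mean, sd, size=20)
    values[100:] = rng.normal(S1_NEGATIVE_MEAN, sd, size=(900, n_samples))

    table = AbundanceTable(pos_ids + neg_ids, meta.sample_ids, values, is_normalized=True)
    truth = GroundTruth(
        pos_ids + neg_ids,
        pos_groups + ["neg"] * 900,
        np.r_[np.ones(100, bool), np.zeros(900, bool)],
    )
    return SyntheticDataset(
        table,
        meta,
        truth,
        provenance={
            "generator": "s1",
            "sd": sd,
            "seed": seed,
            "per_feature_means": per_feature_means,
            "drawn_means": drawn_means,
        },
    )


def generate_s2(seed: int | None = None) -> SyntheticDataset:
    """The mixture benchmark: 1,000 features x 100 samples.

    Groups 1-5 are gamma in both classes; groups 6-10 are gamma in
    class 1 and normal in class 2 with matched means, so their signal is
    a shape difference.  All block parameters are fixed by the design
    (module constants) and echoed in the provenance.
    """
    rng = np.random.default_rng(seed)
    meta = _metadata(n_subclasses=4, per_subclass=25)
    pos_ids, pos_groups = _positive_ids()
    neg_ids = [f"neg_f{i:03d}" for i in range(1, 901)]
    values = np.empty((1000, 100))

    for g in range(1, N_GROUPS + 1):
        rows = slice((g - 1) * GROUP_SIZE, g * GROUP_SIZE)
        arch = (g - 1) % 5  # groups 6-10 reuse the five gamma archetypes
        for sc in range(1, 5):
            cols = slice((sc - 1) * 25, sc * 25)
            if g >= 6 and sc >= 3:  # class 2, groups 6-10: normal blocks
                mean = S2_NORMAL_MEANS[sc][arch]
                sd_ = S2_NORMAL_SDS[sc][arch]
                block = rng.normal(mean, sd_, size=(GROUP_SIZE, 25))
            else:
                shape = S2_GAMMA_SHAPES[sc][arch]
                rate = S2_GAMMA_RATES[sc][arch]
                block = rng.gamma(shape, 1.0 / rate, size=(GROUP_SIZE, 25))
            values[rows, cols] = block
    values[100:] = rng.normal(S2_NEGATIVE_MEAN, S2_NEGATIVE_SD, size=(900, 100))

    table = AbundanceTable(pos_ids + neg_ids, meta.sample_ids, values, is_normalized=True)
    truth = GroundTruth(
        pos_ids + neg_ids,
        pos_groups + ["neg"] * 900,
        np.r_[np.ones(100, bool), np.zeros(900, bool)],
    )
    return SyntheticDataset(
        table,
        meta,
        truth,
        provenance={
            "generator": "s2",
            "seed": seed,
            "gamma_shapes": S2_GAMMA_SHAPES,
            "gamma_rates": S2_GAMMA_RATES,
            "normal_means": S2_NORMAL_MEANS,
            "normal_sds": S2_NORMAL_SDS,
            "negative": {"mean": S2_NEGATIVE_MEAN, "sd": S2_NEGATIVE_SD},
        },
    )


def generate_s3(seed: int | None = None) -> SyntheticDataset:
    """The all-gamma benchmark: 1,000 features x 120 samples, 60 per class.

    Positive groups differ between classes in shape (rates differ for
    most groups too); the three negative blocks of 300 features use the
    same parameters in every subclass, so they carry no class signal.
    """
    rng = np.random.default_rng(seed)
    meta = _metadata(n_subclasses=6, per_subclass=20)
    pos_ids, pos_groups = _positive_ids()
    neg_ids = [f"neg_f{i:03d}" for i in range(1, 901)]
    values = np.empty((1000, 120))

    for g in range(N_GROUPS):
        rows = slice(g * GROUP_SIZE, (g + 1) * GROUP_SIZE)
        for sc in range(1, 7):
            cols = slice((sc - 1) * 20, sc * 20)
            shape = S3_POS_SHAPES[sc][g]
            rate = (S3_POS_RATES_CLASS1 if sc <= 3 else S3_POS_RATES_CLASS2)[g]
            values[rows, cols] = rng.gamma(shape, 1.0 / rate, size=(GROUP_SIZE, 20))
    neg_groups: list[str] = []
    for block in range(3):
        rows = slice(100 + block * 300, 100 + (block + 1) * 300)
        values[rows] = rng.gamma(
            S3_NEG_SHAPES[block], 1.0 / S3_NEG_RATES[block], size=(300, 120)
        )
        neg_groups += [f"neg_b{block + 1}"] * 300

    table = AbundanceTable(pos_ids + neg_ids, meta.sample_ids, values, is_normalized=True)
    truth = GroundTruth(
        pos_ids + neg_ids,
        pos_groups + neg_groups,
        np.r_[np.ones(100, bool), np.zeros(900, bool)],
    )
    return SyntheticDataset(
        table,
        meta,
        truth,
        provenance={
            "generator": "s3",
            "seed": seed,
            "pos_shapes": S3_POS_SHAPES,
            "pos_rates_class1": S3_POS_RATES_CLASS1,
            "pos_rates_class2": S3_POS_RATES_CLASS2,
            "neg_shapes": S3_NEG_SHAPES,
            "neg_rates": S3_NEG_RATES,
        },
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write abundance, metadata and ground-truth TSVs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_abundance_table(dataset.table, out / "abundance.tsv")
    write_metadata(dataset.metadata, out / "metadata.tsv")
    pd.DataFrame(
        {
            "feature_id": dataset.truth.feature_ids,
            "group_id": dataset.truth.group_ids,
            "is_positive": dataset.truth.is_positive.astype(int),
        }
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
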