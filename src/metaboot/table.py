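"""Abundance tables and sample metadata.

The canonical layout follows mothur/QIIME summary exports: features (taxa)
in rows, samples in columns, tab-separated, with the first header cell
``feature_id``.  Metadata is a second TSV mapping ``sample_id`` to a class
label and an optional subclass label; subclasses define the strata used by
the bootstrap stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, TableFormatError

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "read_abundance_table",
    "write_abundance_table",
    "write_metadata",
]


def _check_unique(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise TableFormatError(f"duplicate {kind} id: {dup!r}")


@dataclass
class AbundanceTable:
    """A feature x sample numeric matrix with string ids.

    Parameters
    ----------
    feature_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        ``(n_features, n_samples)`` float array.  Raw counts and relative
        abundances are non-negative; synthetic benchmark matrices may carry
        small negative values from untruncated normal draws.
    is_normalized
        When true the table is ready for selection as-is: either each
        sample column sums to one (real data after
        :func:`~metaboot.preprocess.normalize_relative`) or the matrix was
        generated directly on the benchmark scale and must not be
        renormalized.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableFormatError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, is_normalized: bool = False) -> "AbundanceTable":
        return cls(
            feature_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            is_normalized=is_normalized,
        )

    def subset_features(self, feature_ids: list[str]) -> "AbundanceTable":
        """Return a table restricted to ``feature_ids``, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            rows = [index[f] for f in feature_ids]
        except KeyError as exc:
            raise ConsistencyError(f"unknown feature id: {exc.args[0]!r}") from None
        return replace(self, feature_ids=list(feature_ids), values=self.values[rows])


@dataclass
class SampleMetadata:
    """Per-sample class (and optional subclass) labels, aligned to a table.

    The subclass labels, when present, define the bootstrap strata; the
    class labels are the two phenotypes the biomarkers must discriminate.
    """

    sample_ids: list[str]
    class_labels: list[str]
    subclass_labels: list[str] | None = None
    _class_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c) for c in self.class_labels]
        _check_unique(self.sample_ids, "sample")
        if len(self.class_labels) != len(self.sample_ids):
            raise TableFormatError("class labels not aligned to sample ids")
        if self.subclass_labels is not None:
            self.subclass_labels = [str(s) for s in self.subclass_labels]
            if len(self.subclass_labels) != len(self.sample_ids):
                raise TableFormatError("subclass labels not aligned to sample ids")
        self._class_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        """Distinct class labels in order of first appearance."""
        return list(dict.fromkeys(self.class_labels))

    def strata(self) -> list[str]:
        """Stratum label per sample: the subclass when present, else the class."""
        return list(self.subclass_labels or self.class_labels)

    def class_vector(self) -> np.ndarray:
        """Class labels encoded as integers 0..K-1 (order of first appearance)."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[c] for c in self.class_labels], dtype=np.int64)

    def aligned_to(self, table: AbundanceTable) -> "SampleMetadata":
        """Reorder records to the column order of ``table``.

        Raises :class:`ConsistencyError` if the sample sets differ.
        """
        missing = [s for s in self.sample_ids if s not in set(table.sample_ids)]
        if missing:
            raise ConsistencyError(
                f"metadata sample(s) not present in table: {missing[:5]}"
            )
        absent = [s for s in table.sample_ids if s not in self._class_index]
        if absent:
            raise ConsistencyError(
                f"table sample(s) missing from metadata: {absent[:5]}"
            )
        order = [self._class_index[s] for s in table.sample_ids]
        return SampleMetadata(
            sample_ids=[self.sample_ids[i] for i in order],
            class_labels=[self.class_labels[i] for i in order],
            subclass_labels=(
                [self.subclass_labels[i] for i in order]
                if self.subclass_labels is not None
                else None
            ),
        )


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path,
    *,
    transpose: bool = False,
) -> tuple[AbundanceTable, SampleMetadata]:
    """Read an abundance TSV plus its sample metadata TSV.

    The table's first column holds feature ids and the header holds sample
    ids (pass ``transpose=True`` for the samples-in-rows dialect).  The
    metadata file needs columns ``sample_id`` and ``class``; a ``subclass``
    column is optional.  Metadata records are aligned to the table's column
    order on return.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    if transpose:
        frame = frame.T
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"non-numeric value {frame.iat[r, c]!r} at feature "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        raise TableFormatError(f"missing values in {path}")
    table = AbundanceTable.from_frame(numeric)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "class"}
    if not required.issubset(meta.columns):
        raise TableFormatError(
            f"metadata {metadata_path} must have columns sample_id and class"
        )
    metadata = SampleMetadata(
        sample_ids=list(meta["sample_id"]),
        class_labels=list(meta["class"]),
        subclass_labels=list(meta["subclass"]) if "subclass" in meta.columns else None,
    )
    return table, metadata.aligned_to(table)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as TSV with ``feature_id`` as the first header cell."""
    frame = table.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(Path(path), sep="\t", float_format="%.12g")


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    data = {"sample_id": metadata.sample_ids, "class": metadata.class_labels}
    if metadata.subclass_labels is not None:
        data["subclass"] = metadata.subclass_labels
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False)
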