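"""Reading, validating and writing expression matrices and label vectors.

The canonical in-memory layout is *features x samples* (``d x N``), the
usual orientation of microarray series matrices, regardless of how the
file on disk is oriented.  Orientation is always an explicit argument —
with ``d >> N`` a silently transposed matrix is the classic failure mode,
so nothing here ever guesses.

Supported on-disk formats:

* delimited text (TSV/CSV) with a header row and an id column — primary;
* ARFF with numeric attributes and a trailing nominal class attribute —
  optional, via :func:`read_arff`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    FormatError,
    ParseError,
    ValidationError,
)

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "read_expression",
    "read_labels",
    "write_matrix",
    "write_labels",
    "read_arff",
]

_ORIENTATIONS = ("features_in_rows", "samples_in_rows")

# 17 significant digits round-trips any IEEE double exactly through text.
_FLOAT_FMT = "%.17g"


@dataclass
class ExpressionMatrix:
    """A ``d x N`` real-valued expression matrix with row/column ids.

    Parameters
    ----------
    values
        Array of shape ``(d, N)``: *d* features (genes/probes/constructed
        features) by *N* samples. Units are arbitrary expression units.
    feature_ids, sample_ids
        Unique identifiers for rows and columns respectively.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError(
                f"expression values must be 2-D, got shape {self.values.shape}"
            )
        d, n = self.values.shape
        if d < 1:
            raise ValidationError("need at least one feature")
        if n < 2:
            raise ValidationError(f"need at least two samples, got {n}")
        if len(self.feature_ids) != d:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {d} rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        if len(set(self.feature_ids)) != d:
            raise ValidationError("feature_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                "expression matrix contains non-finite values after load"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        """Column subset (e.g. a CV fold), preserving feature order."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, indices],
            list(self.feature_ids),
            [self.sample_ids[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class LabelVector:
    """Binary class labels aligned with an :class:`ExpressionMatrix`.

    ``labels`` holds 1 for the positive class and 0 otherwise;
    ``positive_class_name`` records what "positive" meant in the source
    file (e.g. ``"SCC"``).
    """

    labels: np.ndarray
    positive_class_name: str
    sample_ids: list[str]
    negative_class_name: str = field(default="other")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        if len(self.sample_ids) != self.labels.size:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.labels.size} labels"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def subset(self, indices: np.ndarray) -> "LabelVector":
        indices = np.asarray(indices, dtype=int)
        return LabelVector(
            self.labels[indices],
            self.positive_class_name,
            [self.sample_ids[i] for i in indices],
            self.negative_class_name,
        )

    def check_aligned(self, matrix: ExpressionMatrix) -> None:
        """Raise :class:`AlignmentError` unless ids match the matrix in order."""
        if self.n_samples != matrix.n_samples:
            raise AlignmentError(
                f"{self.n_samples} labels paired with "
                f"{matrix.n_samples} samples"
            )
        if self.sample_ids != matrix.sample_ids:
            raise AlignmentError(
                "label sample_ids do not match matrix sample_ids in order"
            )


def read_expression(
    path,
    orientation: str,
    delimiter: str = "\t",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression matrix.

    Parameters
    ----------
    path
        File with a header row and an id column (first column).
    orientation
        ``"features_in_rows"`` or ``"samples_in_rows"`` — how the file is
        laid out on disk. The returned matrix is always features x samples.
    delimiter
        Cell separator, ``"\\t"`` by default.
    impute_missing
        If True, missing cells (empty / NA / NaN) are replaced by the mean
        of their feature over the non-missing samples. Default is a hard
        :class:`ParseError`.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
        )
    try:
        # round_trip parsing keeps read(write(m)) exact at 17 significant digits
        df = pd.read_csv(
            path, sep=delimiter, index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed delimited file: {exc}") from exc

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate column ids: {dups[:5]}")

    # Locate non-numeric tokens before missing values, to name the cell.
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )

    if orientation == "samples_in_rows":
        numeric = numeric.T  # now features x samples

    if numeric.isna().to_numpy().any():
        if not impute_missing:
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ParseError(
                f"{path}: missing value at feature {numeric.index[r]!r}, "
                f"sample {numeric.columns[c]!r} "
                "(pass impute_missing=True to mean-impute per feature)"
            )
        means = numeric.mean(axis=1)
        if means.isna().any():
            feat = means.index[means.isna()][0]
            raise ParseError(
                f"{path}: feature {feat!r} has no observed values to impute from"
            )
        numeric = numeric.apply(lambda row: row.fillna(means[row.name]), axis=1)

    return ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        list(numeric.index),
        list(numeric.columns),
    )


def read_labels(path, positive_class: str, delimiter: str = "\t") -> LabelVector:
    """Load a two-column (sample_id, label) file; map labels onto {0, 1}.

    Exactly two distinct label strings must be present; ``positive_class``
    names the one mapped to 1.
    """
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=None, dtype=str, comment=None
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed label file: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(
            f"{path}: expected two columns (sample_id, label), got {df.shape[1]}"
        )
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    classes = sorted(raw.unique())
    if len(classes) != 2:
        raise ValidationError(
            f"{path}: expected exactly two classes, found {classes}"
        )
    if positive_class not in classes:
        raise ValidationError(
            f"{path}: positive class {positive_class!r} not among {classes}"
        )
    negative = [c for c in classes if c != positive_class][0]
    labels = (raw == positive_class).astype(int).to_numpy()
    return LabelVector(labels, positive_class, sample_ids, negative)


def write_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write features-in-rows delimited text that round-trips exactly.

    Values are printed with 17 significant digits, so
    ``read_expression(write_matrix(m))`` reproduces ``m`` bit for bit.
    """
    try:
        m.to_frame().to_csv(
            path, sep=delimiter, float_format=_FLOAT_FMT, index_label="feature_id"
        )
    except OSError as exc:
        raise OSError(f"could not write expression matrix to {path}: {exc}") from exc


def write_labels(y: LabelVector, path, delimiter: str = "\t") -> None:
    """Write the two-column (sample_id, class name) label file."""
    names = np.where(
        y.labels == 1, y.positive_class_name, y.negative_class_name
    )
    pd.DataFrame({0: y.sample_ids, 1: names}).to_csv(
        path, sep=delimiter, header=False, index=False
    )


def read_arff(path, positive_class: str | None = None):
    """Read an ARFF file (numeric attributes + trailing nominal class).

    Rows are samples, as is conventional for ARFF. Returns an
    ``(ExpressionMatrix, LabelVector)`` pair; sample ids are generated
    ``sample_1..sample_N`` since ARFF carries none. If ``positive_class``
    is None the lexicographically larger class name is taken as positive.
    """
    from scipy.io import arff as _arff

    try:
        data, meta = _arff.loadarff(path)
    except Exception as exc:  # scipy raises assorted parse errors
        raise FormatError(f"{path}: could not parse ARFF: {exc}") from exc

    names = list(meta.names())
    class_attr = names[-1]
    if meta[class_attr][0] != "nominal":
        raise FormatError(
            f"{path}: last attribute {class_attr!r} must be the nominal class"
        )
    feature_names = names[:-1]
    X = np.column_stack([np.asarray(data[f], dtype=float) for f in feature_names])
    raw = [
        v.decode() if isinstance(v, bytes) else str(v) for v in data[class_attr]
    ]
    classes = sorted(set(raw))
    if len(classes) != 2:
        raise ValidationError(
            f"{path}: expected exactly two classes, found {classes}"
        )
    if positive_class is None:
        positive_class = classes[-1]
    if positive_class not in classes:
        raise ValidationError(
            f"{path}: positive class {positive_class!r} not among {classes}"
        )
    negative = [c for c in classes if c != positive_class][0]
    sample_ids = [f"sample_{i + 1}" for i in range(X.shape[0])]
    matrix = ExpressionMatrix(X.T, feature_names, sample_ids)
    labels = LabelVector(
        np.asarray([1 if v == positive_class else 0 for v in raw]),
        positive_class,
        sample_ids,
        negative,
    )
    return matrix, labels
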