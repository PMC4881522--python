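"""Expression-matrix I/O and per-sample normalization.

Matrices follow the GEO series-matrix layout: tab-delimited, features on
rows, samples on columns, the first row holding sample identifiers and the
first column holding feature (probe / gene / miRNA) identifiers.  Each
sample carries a two-class label (case vs. control).

Normalization standardizes every sample column over the features so that
the per-column feature mean is 0 and the per-column mean square is 1
(population variance, denominator ``n_features``).  Expression profiles
distributed on a log2 scale can be de-logged first with :func:`unlog2`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: accepted spellings for the two classes, canonicalized on ingestion
_LABEL_SYNONYMS = {
    "case": CASE,
    "tumor": CASE,
    "tumour": CASE,
    "cancer": CASE,
    "patient": CASE,
    "disease": CASE,
    "control": CONTROL,
    "normal": CONTROL,
    "healthy": CONTROL,
    "hc": CONTROL,
}

#: tolerance on the normalization identities (column mean 0, mean square 1)
NORM_TOL = 1e-10


class ParseError(ValueError):
    """Malformed expression table or annotation file."""


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with two-class sample labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_features, n_samples)``; no missing entries.
    feature_ids
        Unique probe / gene / miRNA identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    labels
        Per-sample class, each ``"case"`` or ``"control"``; may be ``None``
        until labels are attached.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ParseError(f"duplicate {name} identifiers")
        if self.labels is not None:
            self.labels = np.asarray(
                [canonical_label(lab) for lab in self.labels], dtype=object
            )
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels must align with sample_ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        self.require_labels()
        return self.labels == CASE

    def require_labels(self, min_per_class: int = 2) -> None:
        """Raise unless both classes are present with ``min_per_class`` samples."""
        if self.labels is None:
            raise ValueError("matrix has no sample labels attached")
        n_case = int(np.sum(self.labels == CASE))
        n_control = int(np.sum(self.labels == CONTROL))
        if n_case < min_per_class or n_control < min_per_class:
            raise ValueError(
                f"need >= {min_per_class} samples per class, "
                f"got {n_case} case / {n_control} control"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        """Row-restriction to ``keep`` (order preserved as given)."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [index[f] for f in keep]
        return replace(self, values=self.values[rows, :], feature_ids=list(keep))


def canonical_label(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _LABEL_SYNONYMS:
        raise ValueError(
            f"unrecognized class label {label!r}; expected case/control "
            "(tumor/normal synonyms accepted)"
        )
    return _LABEL_SYNONYMS[key]


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression_table(
    path,
    labels: dict[str, str] | None = None,
    label_path=None,
) -> ExpressionMatrix:
    """Read a tab-delimited features x samples table.

    The first row holds sample identifiers, the first column feature
    identifiers; quoting around identifiers is stripped.  Rows containing
    missing values are dropped (with a logged count).  Class labels can be
    attached from a mapping or a two-column TSV via ``label_path``.

    Raises
    ------
    ParseError
        On a non-numeric cell (reported with row/column coordinates),
        duplicate identifiers, or ragged rows.
    """
    with _open_text(path) as fh:
        try:
            frame = pd.read_csv(
                fh, sep="\t", index_col=0, header=0, dtype=str,
                quotechar='"', skip_blank_lines=True,
            )
        except pd.errors.ParserError as exc:  # ragged rows
            raise ParseError(f"{path}: malformed table: {exc}") from exc

    frame.index = frame.index.astype(str).str.strip().str.strip('"')
    frame.columns = frame.columns.astype(str).str.strip().str.strip('"')
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature identifiers: {dupes[:5]}")
    if frame.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample identifiers")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    # distinguish unparseable text (error) from genuinely missing cells (drop row)
    bad = numeric.isna() & frame.notna() & (frame.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {frame.iat[i, j]!r} at feature "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    complete = ~numeric.isna().any(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("%s: dropped %d rows with missing values", path, n_missing)
    # re-parse from the raw strings with strtod so values round-trip bitwise
    numeric = frame.loc[complete].astype(float)

    matrix = ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        feature_ids=list(numeric.index),
        sample_ids=list(numeric.columns),
    )
    if label_path is not None:
        labels = read_labels(label_path)
    if labels is not None:
        matrix = attach_labels(matrix, labels)
    return matrix


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, label) into a mapping.

    A header row is tolerated if its second field is not a recognizable
    class label.
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, label = parts
            try:
                label = canonical_label(label)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ParseError(f"{path}:{lineno}: unrecognized label {label!r}")
            if sample in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate sample {sample!r}")
            mapping[sample] = label
    return mapping


def attach_labels(m: ExpressionMatrix, labels: dict[str, str]) -> ExpressionMatrix:
    missing = [s for s in m.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"no label for samples: {missing[:5]}")
    return replace(m, labels=np.array([labels[s] for s in m.sample_ids], dtype=object))


def write_expression_table(m: ExpressionMatrix, path) -> None:
    """Write the matrix back in the same TSV layout (round-trip safe)."""
    with _open_text(path, "wt") as fh:
        # shortest-repr float formatting guarantees a bitwise round-trip
        m.to_frame().to_csv(fh, sep="\t", index_label="ID_REF")


def write_labels(m: ExpressionMatrix, path) -> None:
    m.require_labels(min_per_class=0)
    with _open_text(path, "wt") as fh:
        for s, lab in zip(m.sample_ids, m.labels):
            fh.write(f"{s}\t{lab}\n")


def unlog2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Invert a log2 transform: every value x becomes 2**x.

    Raises
    ------
    OverflowError
        If any de-logged value is not finite (instead of silently
        propagating infinities).
    """
    with np.errstate(over="ignore"):
        raw = np.exp2(m.values)
    if not np.all(np.isfinite(raw)):
        i, j = np.argwhere(~np.isfinite(raw))[0]
        raise OverflowError(
            f"2**{m.values[i, j]} overflows at feature {m.feature_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}"
        )
    return replace(m, values=raw)


def normalize_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each sample column over the features.

    After normalization every column satisfies mean(x) = 0 and
    mean(x**2) = 1, with the population (1/N) variance so that the second
    identity holds exactly.

    Raises
    ------
    ValueError
        If a column is constant across features ("zero variance"),
        naming the offending sample.
    """
    mean = m.values.mean(axis=0, keepdims=True)
    centered = m.values - mean
    sd = np.sqrt(np.mean(centered**2, axis=0, keepdims=True))
    zero = np.flatnonzero(sd[0] == 0.0)
    if zero.size:
        raise ValueError(
            f"zero variance in sample column {m.sample_ids[zero[0]]!r}; "
            "cannot normalize a constant column"
        )
    return replace(m, values=centered / sd)


def is_normalized(m: ExpressionMatrix, tol: float = NORM_TOL) -> bool:
    mean = m.values.mean(axis=0)
    msq = np.mean(m.values**2, axis=0)
    return bool(np.all(np.abs(mean) < tol) and np.all(np.abs(msq - 1.0) < tol))
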