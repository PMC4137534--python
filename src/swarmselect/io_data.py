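"""Reading, validating and writing binary-class expression matrices.

The on-disk dialect is delimited text with genes as rows: the first header
row carries sample identifiers (first cell is an arbitrary corner label),
an optional second ``#labels`` row carries one class token per sample, and
every subsequent row is ``gene_id`` followed by one expression value per
sample.  Labels may alternatively live in a two-column headerless companion
file mapping ``sample_id`` to class token.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_DELIMITERS = {"tab": "\t", "csv": ","}

LABELS_SENTINEL = "#labels"


class MatrixParseError(ValueError):
    """Malformed matrix file (inconsistent row lengths, bad numbers...)."""


class LabelError(ValueError):
    """Class labels missing, unresolvable, or not exactly two classes."""


class DatasetValidationError(ValueError):
    """A dataset violating the ExpressionDataset invariants."""


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with one binary label per sample.

    ``class_names`` fixes which token is class 1 and which is class 2;
    the statistics downstream are sign-sensitive in that order.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    class_names: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DatasetValidationError("matrix must be 2-dimensional")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if self.class_names is None:
            self.class_names = _classes_in_order(self.labels)
        else:
            self.class_names = (str(self.class_names[0]), str(self.class_names[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def class_indices(self, class_name: str) -> np.ndarray:
        """Column indices of the samples labelled ``class_name``."""
        return np.asarray([i for i, l in enumerate(self.labels) if l == class_name],
                          dtype=int)

    @property
    def n1(self) -> int:
        return sum(1 for l in self.labels if l == self.class_names[0])

    @property
    def n2(self) -> int:
        return sum(1 for l in self.labels if l == self.class_names[1])

    # -- validation -----------------------------------------------------
    def check_valid(self) -> None:
        """Raise :class:`DatasetValidationError` on the first violation."""
        violations = validate_dataset(self)
        if violations:
            raise DatasetValidationError("; ".join(violations))

    def subset_genes(self, gene_indices: Sequence[int]) -> "ExpressionDataset":
        """New dataset restricted to the given gene rows, order preserved."""
        idx = np.asarray(gene_indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[idx, :].copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            labels=list(self.labels),
            class_names=self.class_names,
        )


def _classes_in_order(labels: Sequence[str]) -> tuple[str, str]:
    seen: list[str] = []
    for l in labels:
        if l not in seen:
            seen.append(l)
    if len(seen) != 2:
        raise LabelError(
            f"expected exactly 2 classes, found {len(seen)}: {seen}"
        )
    return (seen[0], seen[1])


def validate_dataset(ds: ExpressionDataset) -> list[str]:
    """Report every ExpressionDataset invariant violation; never raises."""
    out: list[str] = []
    n_genes, n_samples = ds.matrix.shape
    if n_genes == 0:
        out.append("matrix has 0 genes")
    if n_samples == 0:
        out.append("matrix has 0 samples")
    if len(ds.gene_ids) != n_genes:
        out.append(f"gene_ids length {len(ds.gene_ids)} != {n_genes} matrix rows")
    if len(ds.sample_ids) != n_samples:
        out.append(
            f"sample_ids length {len(ds.sample_ids)} != {n_samples} matrix columns"
        )
    if len(ds.labels) != n_samples:
        out.append(f"labels length {len(ds.labels)} != {n_samples} matrix columns")
    if len(set(ds.gene_ids)) != len(ds.gene_ids):
        dupes = sorted({g for g in ds.gene_ids if ds.gene_ids.count(g) > 1})
        out.append(f"duplicate gene ids: {dupes}")
    if len(set(ds.sample_ids)) != len(ds.sample_ids):
        dupes = sorted({s for s in ds.sample_ids if ds.sample_ids.count(s) > 1})
        out.append(f"duplicate sample ids: {dupes}")

    distinct = sorted(set(ds.labels))
    if len(distinct) != 2:
        out.append(f"expected exactly 2 classes, found {len(distinct)}: {distinct}")
    else:
        if set(distinct) != set(ds.class_names):
            out.append(
                f"class_names {ds.class_names} do not match label tokens {distinct}"
            )
        for cls in distinct:
            n_cls = ds.labels.count(cls)
            if n_cls < 2:
                out.append(f"class size < 2 for class {cls!r} ({n_cls} sample)")

    if ds.matrix.size:
        bad = np.argwhere(~np.isfinite(ds.matrix))
        for gi, si in bad[:20]:
            gene = ds.gene_ids[gi] if gi < len(ds.gene_ids) else f"row {gi}"
            sample = ds.sample_ids[si] if si < len(ds.sample_ids) else f"col {si}"
            out.append(f"non-finite value at gene {gene!r}, sample {sample!r}")
        if len(bad) > 20:
            out.append(f"... and {len(bad) - 20} further non-finite values")
    return out


def _read_labels_file(path: str | Path, delimiter: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise LabelError(
                    f"{path}: labels file line {lineno} has {len(row)} columns, "
                    "expected 2 (sample_id, label)"
                )
            sample, label = row[0].strip(), row[1].strip()
            if sample in mapping:
                raise LabelError(f"{path}: duplicate sample id {sample!r} in labels")
            mapping[sample] = label
    return mapping


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tab",
    labels_path: str | Path | None = None,
    labels_in_header: bool = False,
    class_order: tuple[str, str] | None = None,
    missing: str = "error",
) -> ExpressionDataset:
    """Parse a delimited expression matrix into an :class:`ExpressionDataset`.

    Parameters
    ----------
    dialect:
        ``"tab"`` or ``"csv"``.
    labels_path:
        Two-column companion file (sample_id, label).  Mutually exclusive
        with ``labels_in_header``.
    labels_in_header:
        Expect a ``#labels`` row immediately after the sample-id header.
    class_order:
        Explicit (class-1, class-2) token pair; default is order of first
        appearance among the labels.
    missing:
        ``"error"`` rejects empty/NaN cells; ``"mean"`` imputes the
        per-gene mean of the finite values.
    """
    if dialect not in _DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DELIMITERS)}")
    if missing not in ("error", "mean"):
        raise ValueError(f"missing policy must be 'error' or 'mean', got {missing!r}")
    if labels_in_header and labels_path is not None:
        raise ValueError("labels_in_header and labels_path are mutually exclusive")
    if not labels_in_header and labels_path is None:
        raise LabelError("no label source: pass labels_path or labels_in_header=True")
    delim = _DELIMITERS[dialect]

    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [row for row in reader]
    rows = [r for r in rows if r and not (len(r) == 1 and not r[0].strip())]
    if not rows:
        raise MatrixParseError(f"{path}: empty file")

    header = rows[0]
    if len(header) < 2:
        raise MatrixParseError(f"{path}: header row has no sample columns")
    sample_ids = [c.strip() for c in header[1:]]
    n_samples = len(sample_ids)

    body_start = 1
    labels: list[str] | None = None
    if labels_in_header:
        if len(rows) < 2 or rows[1][0].strip() != LABELS_SENTINEL:
            raise LabelError(f"{path}: expected '{LABELS_SENTINEL}' row after the header")
        label_row = rows[1]
        if len(label_row) != n_samples + 1:
            raise LabelError(
                f"{path}: labels row has {len(label_row) - 1} entries, "
                f"expected {n_samples}"
            )
        labels = [c.strip() for c in label_row[1:]]
        body_start = 2

    gene_ids: list[str] = []
    values: list[list[float]] = []
    missing_cells: list[tuple[int, int]] = []
    for data_row, row in enumerate(rows[body_start:], start=1):
        if len(row) != n_samples + 1:
            raise MatrixParseError(
                f"{path}: row {data_row} has {len(row) - 1} values, "
                f"expected {n_samples}"
            )
        gene_ids.append(row[0].strip())
        parsed: list[float] = []
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                parsed.append(math.nan)
                missing_cells.append((data_row - 1, j))
            else:
                try:
                    parsed.append(float(cell))
                except ValueError as exc:
                    raise MatrixParseError(
                        f"{path}: row {data_row}, column {j + 2}: "
                        f"cannot parse {cell!r} as a number"
                    ) from exc
        values.append(parsed)

    matrix = np.asarray(values, dtype=float) if values else np.empty((0, n_samples))

    if missing_cells:
        if missing == "error":
            gi, si = missing_cells[0]
            raise MatrixParseError(
                f"{path}: missing value at gene {gene_ids[gi]!r}, "
                f"sample {sample_ids[si]!r} ({len(missing_cells)} missing total); "
                "pass missing='mean' to impute"
            )
        logger.warning("imputing %d missing cells with per-gene means", len(missing_cells))
        for gi in {g for g, _ in missing_cells}:
            row_vals = matrix[gi]
            finite = row_vals[np.isfinite(row_vals)]
            if finite.size == 0:
                raise MatrixParseError(
                    f"{path}: gene {gene_ids[gi]!r} has no finite values to impute from"
                )
            row_vals[~np.isfinite(row_vals)] = finite.mean()

    if labels is None:
        mapping = _read_labels_file(labels_path, delim)  # type: ignore[arg-type]
        unresolved = [s for s in sample_ids if s not in mapping]
        if unresolved:
            raise LabelError(
                f"{labels_path}: no label for sample(s) {unresolved[:5]}"
            )
        labels = [mapping[s] for s in sample_ids]

    distinct = _classes_in_order(labels)
    if class_order is not None:
        if set(class_order) != set(distinct):
            raise LabelError(
                f"class_order {class_order} does not match label tokens {distinct}"
            )
        distinct = (str(class_order[0]), str(class_order[1]))

    ds = ExpressionDataset(
        matrix=matrix,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        class_names=distinct,
    )
    ds.check_valid()
    return ds


def write_expression_matrix(
    ds: ExpressionDataset,
    path: str | Path,
    dialect: str = "tab",
    include_labels: bool = True,
) -> None:
    """Write a dataset so that :func:`read_expression_matrix` reproduces it.

    Values are written with 17 significant digits (exact float round trip).
    """
    if dialect not in _DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DELIMITERS)}")
    ds.check_valid()
    delim = _DELIMITERS[dialect]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["gene_id", *ds.sample_ids])
        if include_labels:
            writer.writerow([LABELS_SENTINEL, *ds.labels])
        for gid, row in zip(ds.gene_ids, ds.matrix):
            writer.writerow([gid, *(format(v, ".17g") for v in row)])


def write_labels_file(
    ds: ExpressionDataset, path: str | Path, dialect: str = "tab"
) -> None:
    """Write the two-column (sample_id, label) companion file."""
    delim = _DELIMITERS[dialect]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        for sid, lab in zip(ds.sample_ids, ds.labels):
            writer.writerow([sid, lab])
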