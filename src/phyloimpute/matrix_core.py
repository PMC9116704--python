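"""Distance-matrix data model, file I/O, missingness and matrix errors.

The central object is a labeled square matrix of pairwise evolutionary
distances (substitutions/site) over a set of OTUs, together with a boolean
mask marking the entries that are unknown.  Missingness is injected in
symmetric (i, j)/(j, i) pairs, mirroring how missing pairwise distances
arise in practice from non-overlapping sequence regions.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DiagonalMissingError,
    DistanceMatrixError,
    DuplicateLabelError,
    MatrixParseError,
    NegativeDistanceError,
    NonSquareMatrixError,
)

DEFAULT_MISSING_TOKENS = ("NA", "?", "-1")
#: token emitted for masked cells on write
CANONICAL_MISSING_TOKEN = "NA"

_FLOAT_FMT = "%.17g"  # lossless for float64 round-trips


@dataclass
class DistanceMatrix:
    """Square matrix of pairwise distances over labeled OTUs.

    Parameters
    ----------
    labels
        Ordered, unique OTU identifiers.
    values
        N x N float array; diagonal is structurally zero.  Cells flagged
        missing by an accompanying mask may hold NaN placeholders until
        :func:`initial_guess` runs.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise NonSquareMatrixError(
                f"values must be square, got shape {values.shape}"
            )
        if len(labels) != values.shape[0]:
            raise DistanceMatrixError(
                f"{len(labels)} labels for a {values.shape[0]}-row matrix"
            )
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise DuplicateLabelError(f"duplicate OTU labels: {dup}")
        self.labels = labels
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.labels, self.values.copy())

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        v = self.values
        finite = np.isfinite(v) & np.isfinite(v.T)
        return bool(np.all(np.abs(v - v.T)[finite] <= tol))


@dataclass
class ColumnOrder:
    """Imputation order: columns sorted by ascending missing count.

    ``order`` excludes fully observed columns; ties in the per-column
    missing counts are broken by lowest column index.
    """

    order: np.ndarray
    missing_counts: np.ndarray


def validate_mask(matrix: DistanceMatrix, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != matrix.values.shape:
        raise DistanceMatrixError(
            f"mask shape {mask.shape} != matrix shape {matrix.values.shape}"
        )
    if np.any(np.diag(mask)):
        raise DiagonalMissingError("diagonal cells cannot be missing")
    return mask


def _infer_format(path: str) -> str:
    return "csv" if os.path.splitext(path)[1].lower() == ".csv" else "phylip_square"


def read_distance_matrix(
    path: str,
    format: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Read a labeled square distance matrix with missing-data sentinels.

    Supports the PHYLIP square dialect (first line: N; one row per OTU:
    label followed by N whitespace-separated values) and CSV with a label
    header row and label first column.  Cells equal to one of
    ``missing_tokens`` are flagged missing and set to NaN placeholders.

    Returns
    -------
    (DistanceMatrix, mask)
        ``mask[i, j]`` is True where the file carried a missing sentinel.
    """
    fmt = format or _infer_format(path)
    tokens = set(missing_tokens)
    if fmt == "phylip_square":
        labels, cells = _read_phylip_cells(path)
    elif fmt == "csv":
        labels, cells = _read_csv_cells(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise DuplicateLabelError(f"{path}: duplicate OTU labels {dup}")

    n = len(labels)
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            tok = cells[i][j].strip()
            if tok in tokens:
                if i == j:
                    raise DiagonalMissingError(
                        f"{path}: missing token on diagonal at row {labels[i]!r}"
                    )
                mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                x = float(tok)
            except ValueError as exc:
                raise MatrixParseError(
                    f"{path}: cannot parse {tok!r} at row {labels[i]!r}, "
                    f"column {labels[j]!r}"
                ) from exc
            if i == j:
                x = 0.0  # diagonal forced observed and zero
            elif x < 0:
                raise NegativeDistanceError(
                    f"{path}: negative distance {x} at row {labels[i]!r}, "
                    f"column {labels[j]!r}"
                )
            values[i, j] = x
    return DistanceMatrix(labels, values), mask


def _read_phylip_cells(path: str) -> tuple[list[str], list[list[str]]]:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise MatrixParseError(f"{path}: first line must hold N") from exc
    rows = lines[1:]
    if len(rows) != n:
        raise NonSquareMatrixError(
            f"{path}: header says {n} rows, file has {len(rows)}"
        )
    labels, cells = [], []
    for k, ln in enumerate(rows):
        parts = ln.split()
        if len(parts) != n + 1:
            raise NonSquareMatrixError(
                f"{path}: row {k + 1} has {len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        cells.append(parts[1:])
    return labels, cells


def _read_csv_cells(path: str) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    header = [c.strip() for c in rows[0][1:]]
    n = len(header)
    body = rows[1:]
    if len(body) != n:
        raise NonSquareMatrixError(
            f"{path}: {n} header labels but {len(body)} data rows"
        )
    labels, cells = [], []
    for k, row in enumerate(body):
        if len(row) != n + 1:
            raise NonSquareMatrixError(
                f"{path}: row {k + 1} has {len(row) - 1} values, expected {n}"
            )
        labels.append(row[0].strip())
        cells.append(row[1:])
    if labels != header:
        raise MatrixParseError(
            f"{path}: row labels do not match header labels"
        )
    return labels, cells


def write_distance_matrix(
    matrix: DistanceMatrix,
    mask: np.ndarray | None,
    path: str,
    format: str | None = None,
) -> None:
    """Write the matrix, emitting the canonical missing token at masked cells.

    Inverse of :func:`read_distance_matrix` on (observed values, mask,
    labels).
    """
    fmt = format or _infer_format(path)
    if mask is None:
        mask = np.zeros_like(matrix.values, dtype=bool)
    mask = validate_mask(matrix, mask)

    def cell(i: int, j: int) -> str:
        if mask[i, j]:
            return CANONICAL_MISSING_TOKEN
        return _FLOAT_FMT % matrix.values[i, j]

    n = matrix.n
    if fmt == "phylip_square":
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for i, lab in enumerate(matrix.labels):
                fh.write(lab + "  " + "  ".join(cell(i, j) for j in range(n)) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + list(matrix.labels))
            for i, lab in enumerate(matrix.labels):
                w.writerow([lab] + [cell(i, j) for j in range(n)])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def max_missing_pairs(n: int) -> int:
    """Largest pair count compatible with >=1 observed off-diagonal per column."""
    return n * (n - 2) // 2


def inject_missing(
    matrix: DistanceMatrix,
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Mask ``floor(fraction * N(N-1)/2)`` off-diagonal pairs uniformly.

    Pairs are drawn without replacement; both (i, j) and (j, i) are masked.
    A draw that would leave some column without any observed off-diagonal
    entry is rejected and redrawn.
    """
    if not matrix.is_symmetric() or np.isnan(matrix.values).any():
        raise DistanceMatrixError("inject_missing needs a complete symmetric matrix")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = matrix.n
    n_pairs = n * (n - 1) // 2
    m = math.floor(fraction * n_pairs)
    mask = np.zeros((n, n), dtype=bool)
    if m == 0:
        return mask
    if m > max_missing_pairs(n):
        raise DistanceMatrixError(
            f"cannot mask {m} pairs on {n} OTUs: some column would lose all "
            f"observed off-diagonal entries (max {max_missing_pairs(n)})"
        )
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(10000):
        pick = rng.choice(n_pairs, size=m, replace=False)
        cand = np.zeros((n, n), dtype=bool)
        cand[iu[pick], ju[pick]] = True
        cand |= cand.T
        if cand.sum(axis=0).max() <= n - 2:
            return cand
    raise DistanceMatrixError(
        f"could not draw a feasible mask for fraction={fraction}, n={n}"
    )


def initial_guess(matrix: DistanceMatrix, mask: np.ndarray) -> DistanceMatrix:
    """Column-mean fill followed by pairwise symmetrization.

    Step 1 replaces each missing cell in column c with the mean of c's
    observed off-diagonal entries (the structural diagonal zero is
    excluded).  Step 2 replaces every (i, j)/(j, i) pair by its mean, so
    the output is symmetric and ready to seed the imputation loop.
    """
    mask = validate_mask(matrix, mask)
    v = matrix.values.copy()
    n = matrix.n
    off_diag = ~np.eye(n, dtype=bool)
    for c in range(n):
        obs = off_diag[:, c] & ~mask[:, c]
        if not obs.any():
            raise DistanceMatrixError(
                f"column {matrix.labels[c]!r} has no observed off-diagonal "
                f"entry; remove this OTU before imputing"
            )
        miss = mask[:, c]
        if miss.any():
            v[miss, c] = v[obs, c].mean()
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(matrix.labels, v)


def column_order(mask: np.ndarray) -> ColumnOrder:
    """Ascending missing-count order over columns with missing entries."""
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=0)
    order = np.argsort(counts, kind="stable")
    order = order[counts[order] > 0]
    return ColumnOrder(order=order.astype(int), missing_counts=counts.astype(int))


def set_difference_error(
    x_new: DistanceMatrix | np.ndarray, x_old: DistanceMatrix | np.ndarray
) -> float:
    """Normalized squared matrix difference between two iterations.

    ``sum((new - old)^2) / sum(new^2)`` over all cells; zero iff the
    matrices are identical, and invariant to a common rescaling.
    """
    a = x_new.values if isinstance(x_new, DistanceMatrix) else np.asarray(x_new, float)
    b = x_old.values if isinstance(x_old, DistanceMatrix) else np.asarray(x_old, float)
    if a.shape != b.shape:
        raise DistanceMatrixError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ZeroDivisionError("set_difference_error undefined for all-zero matrix")
    return float(np.sum((a - b) ** 2)) / denom
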