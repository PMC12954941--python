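"""Core representation of two-level designs.

A design is an N x n matrix of runs by factors with entries coded -1/+1.
This module owns validation, level recoding, model-matrix construction for
main-effects / two-factor-interaction models, and plain-text file I/O
(labelled CSV and the ``oa_text`` 0/1 dialect used by public orthogonal-array
catalogues).
"""

from __future__ import annotations

import csv
import itertools
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CodingError",
    "LabelError",
    "SubsetError",
    "ParseError",
    "Design",
    "ModelSpec",
    "default_labels",
    "make_design",
    "model_matrix",
    "read_design",
    "write_design",
]


class CodingError(ValueError):
    """Matrix entries are not a valid two-level coding."""


class LabelError(ValueError):
    """Factor labels are duplicated or otherwise invalid."""


class SubsetError(KeyError):
    """A requested factor label is not present in the design."""


class ParseError(ValueError):
    """A design file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def default_labels(n: int) -> tuple[str, ...]:
    """Default factor labels: A..Z, then A1..Z1, A2..Z2, ..."""
    labels = []
    for i in range(n):
        letter = string.ascii_uppercase[i % 26]
        cycle = i // 26
        labels.append(letter if cycle == 0 else f"{letter}{cycle}")
    return tuple(labels)


@dataclass(frozen=True)
class Design:
    """An N-run, n-factor two-level design coded -1/+1.

    Parameters
    ----------
    matrix
        Integer array of shape ``(runs, n_factors)`` with entries in {-1, +1}.
    factors
        Ordered, unique factor labels, one per column.
    """

    matrix: np.ndarray
    factors: tuple[str, ...]

    def __post_init__(self):
        mat = np.asarray(self.matrix)
        if mat.ndim != 2:
            raise CodingError(f"design matrix must be 2-D, got shape {mat.shape}")
        if mat.shape[0] < 1 or mat.shape[1] < 1:
            raise CodingError("design must have at least one run and one factor")
        if not np.isin(mat, (-1, 1)).all():
            bad = sorted(set(np.unique(mat)) - {-1, 1})
            raise CodingError(f"entries must be -1 or +1; found {bad}")
        mat = mat.astype(np.int64, copy=True)
        mat.flags.writeable = False
        object.__setattr__(self, "matrix", mat)
        labels = tuple(str(f) for f in self.factors)
        if len(labels) != mat.shape[1]:
            raise LabelError(
                f"{len(labels)} labels for {mat.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise LabelError(f"duplicate factor labels in {labels}")
        object.__setattr__(self, "factors", labels)

    @property
    def runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        """The -1/+1 column for a single factor."""
        try:
            j = self.factors.index(label)
        except ValueError:
            raise SubsetError(f"unknown factor {label!r}; have {self.factors}")
        return self.matrix[:, j]

    def select(self, labels: Sequence[str]) -> "Design":
        """Sub-design restricted to the given factors, in the given order."""
        cols = np.column_stack([self.column(f) for f in labels])
        return Design(cols, tuple(labels))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Design):
            return NotImplemented
        return self.factors == other.factors and np.array_equal(
            self.matrix, other.matrix
        )

    def __hash__(self):
        return hash((self.factors, self.matrix.tobytes()))

    def __repr__(self):
        return f"Design(runs={self.runs}, factors={list(self.factors)})"


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of effect words over a factor subset.

    Each term is a frozenset of factor labels; the empty set is the
    intercept.  The canonical main-effects-plus-two-factor-interactions
    ("ME+2FI") spec over m factors has 1 + m + m(m-1)/2 terms: intercept
    first, then main effects, then interactions, each block in subset order.
    """

    terms: tuple[frozenset, ...]

    def __post_init__(self):
        terms = tuple(frozenset(t) for t in self.terms)
        if len(set(terms)) != len(terms):
            raise LabelError("duplicate terms in model spec")
        object.__setattr__(self, "terms", terms)

    @classmethod
    def me_only(cls, subset: Sequence[str]) -> "ModelSpec":
        return cls((frozenset(),) + tuple(frozenset({f}) for f in subset))

    @classmethod
    def me2fi(cls, subset: Sequence[str]) -> "ModelSpec":
        terms = [frozenset()]
        terms += [frozenset({f}) for f in subset]
        terms += [frozenset(p) for p in itertools.combinations(subset, 2)]
        return cls(tuple(terms))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def validate_over(self, subset: Sequence[str]) -> None:
        allowed = set(subset)
        for t in self.terms:
            if not t <= allowed:
                raise SubsetError(
                    f"term {sorted(t)} uses factors outside subset {sorted(allowed)}"
                )


def make_design(matrix, labels: Sequence[str] | None = None) -> Design:
    """Validate a two-level matrix and return a :class:`Design`.

    Entries must all be in {-1, +1} or all in {0, 1}; a 0/1 matrix is recoded
    by the fixed convention 0 -> -1, 1 -> +1.
    """
    mat = np.asarray(matrix)
    if mat.ndim != 2:
        raise CodingError(f"design matrix must be 2-D, got shape {mat.shape}")
    values = set(np.unique(mat).tolist())
    if values <= {-1, 1}:
        coded = mat
    elif values <= {0, 1}:
        coded = 2 * mat - 1
    else:
        raise CodingError(
            f"entries must be two-level ({{-1,+1}} or {{0,1}}); found {sorted(values)}"
        )
    if labels is None:
        labels = default_labels(mat.shape[1])
    return Design(np.asarray(coded, dtype=np.int64), tuple(labels))


def model_matrix(
    design: Design, subset: Sequence[str], spec: ModelSpec | None = None
) -> np.ndarray:
    """Model matrix for a factor subset under an effect-word spec.

    Column j is the elementwise product of the design columns named by term
    j; the intercept term yields the all-ones column.  Defaults to the
    canonical ME+2FI spec over ``subset``.
    """
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise LabelError(f"duplicate labels in subset {subset}")
    for f in subset:
        if f not in design.factors:
            raise SubsetError(f"unknown factor {f!r}; have {design.factors}")
    if spec is None:
        spec = ModelSpec.me2fi(subset)
    spec.validate_over(subset)
    cols = []
    for term in spec.terms:
        if not term:
            cols.append(np.ones(design.runs, dtype=np.int64))
        else:
            prod = np.ones(design.runs, dtype=np.int64)
            for f in sorted(term):
                prod = prod * design.column(f)
            cols.append(prod)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# File I/O.  CSV: header of labels, body of -1/+1.  oa_text: one run per
# line of contiguous 0/1 digits (0 -> -1, 1 -> +1), an optional leading
# "N n t" header line is tolerated and ignored on read.
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "oa_text")


def _check_format(fmt: str) -> None:
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_design(design: Design, path, fmt: str = "csv") -> None:
    _check_format(fmt)
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(design.factors)
            writer.writerows(design.matrix.tolist())
    else:
        zero_one = (design.matrix + 1) // 2
        lines = ["".join(str(v) for v in row) for row in zero_one.tolist()]
        path.write_text("\n".join(lines) + "\n")


def read_design(path, fmt: str = "csv") -> Design:
    _check_format(fmt)
    path = Path(path)
    if fmt == "csv":
        return _read_csv(path)
    return _read_oa_text(path)


def _read_csv(path: Path) -> Design:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError("empty file")
    labels = [c.strip() for c in rows[0]]
    width = len(labels)
    body = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # blank line
        if len(row) != width:
            raise ParseError(f"expected {width} fields, got {len(row)}", lineno)
        parsed = []
        for cell in row:
            cell = cell.strip()
            if cell not in ("-1", "+1", "1"):
                raise ParseError(f"invalid level {cell!r} (expected -1 or +1)", lineno)
            parsed.append(int(cell))
        body.append(parsed)
    if not body:
        raise ParseError("no data rows")
    return make_design(np.array(body, dtype=np.int64), labels)


def _read_oa_text(path: Path) -> Design:
    raw = path.read_text().splitlines()
    rows: list[list[int]] = []
    width = None
    for lineno, line in enumerate(raw, start=1):
        line = line.strip()
        if not line:
            continue
        if any(ch.isspace() for ch in line):
            # "N n t" style catalogue header: only valid as the very first
            # non-empty line, and only if every token is an integer.
            tokens = line.split()
            if not rows and width is None and all(t.lstrip("-").isdigit() for t in tokens):
                continue
            raise ParseError(f"unexpected whitespace in run line {line!r}", lineno)
        if set(line) - {"0", "1"}:
            bad = sorted(set(line) - {"0", "1"})
            raise ParseError(f"non-level symbols {bad} in run line", lineno)
        if width is None:
            width = len(line)
        elif len(line) != width:
            raise ParseError(f"expected {width} digits, got {len(line)}", lineno)
        rows.append([int(ch) for ch in line])
    if not rows:
        raise ParseError("no run lines found")
    return make_design(np.array(rows, dtype=np.int64))
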