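"""Orthogonal-array strength verification and hidden-projection analysis.

Strength t is checked by exhaustive counting of level combinations over
every t-column submatrix.  Hidden-projection estimability is measured as
full-rank coverage: the fraction of k-factor subsets whose intercept +
main-effects + two-factor-interaction model matrix has full column rank.
Rank is computed exactly over the integers (authoritative) with a
floating-point SVD cross-check at tolerance 1e-8 x largest singular value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import sympy

from .design import Design, ModelSpec, model_matrix

__all__ = [
    "StrengthReport",
    "ProjectionReport",
    "DesignSummary",
    "Comparison",
    "verify_strength",
    "max_strength",
    "exact_rank",
    "float_rank",
    "is_full_rank_projection",
    "projection_coverage",
    "cheng_guarantee",
    "run_reduction_pct",
    "compare_designs",
]


# ---------------------------------------------------------------------------
# Strength
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrengthReport:
    """Outcome of an orthogonal-array strength check.

    ``witness`` is None when the claim holds; otherwise it names the first
    column tuple and level combination whose count differs from N / 2^t.
    """

    claimed_t: int
    holds: bool
    max_t: int
    witness: tuple | None = None


def _strength_failure(design: Design, t: int):
    """First (columns, levels, count, expected) violating strength t, or None."""
    N, n = design.runs, design.n_factors
    if N % (2 ** t) != 0:
        # Equal counts are impossible; report the first combination found.
        cols = design.factors[:t]
        return (cols, None, None, Fraction(N, 2 ** t))
    expected = N // (2 ** t)
    bits = (design.matrix + 1) // 2
    weights = 1 << np.arange(t)
    for combo in itertools.combinations(range(n), t):
        codes = bits[:, combo] @ weights
        counts = np.bincount(codes, minlength=2 ** t)
        if not (counts == expected).all():
            bad = int(np.argmax(counts != expected))
            levels = tuple(2 * ((bad >> i) & 1) - 1 for i in range(t))
            cols = tuple(design.factors[j] for j in combo)
            return (cols, levels, int(counts[bad]), expected)
    return None


def max_strength(design: Design) -> int:
    """Largest t for which the design is an OA(N, 2^n, t); 0 if none."""
    t = 0
    while t < design.n_factors and _strength_failure(design, t + 1) is None:
        t += 1
    return t


def verify_strength(design: Design, t: int) -> StrengthReport:
    """Check the strength-t property by exhaustive counting.

    Counts all 2^t level combinations in every t-column submatrix; the claim
    holds iff every count equals N / 2^t.
    """
    if not 1 <= t <= design.n_factors:
        raise ValueError(f"need 1 <= t <= {design.n_factors}, got t={t}")
    witness = _strength_failure(design, t)
    return StrengthReport(
        claimed_t=t,
        holds=witness is None,
        max_t=max_strength(design),
        witness=witness,
    )


# ---------------------------------------------------------------------------
# Rank / hidden projection
# ---------------------------------------------------------------------------

def exact_rank(M: np.ndarray) -> int:
    """Exact rank of an integer matrix.

    Uses rank(M) == rank(M.T @ M) (true over the reals) to reduce the N x p
    model matrix to its p x p integer Gram matrix, whose rank is computed by
    exact rational elimination.
    """
    M = np.asarray(M, dtype=np.int64)
    gram = (M.T @ M).tolist()
    return int(sympy.Matrix(gram).rank())


def float_rank(M: np.ndarray) -> int:
    """Floating rank via SVD with tolerance 1e-8 x largest singular value."""
    s = np.linalg.svd(np.asarray(M, dtype=float), compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > 1e-8 * s[0]))


def is_full_rank_projection(design: Design, subset: Sequence[str]) -> tuple[bool, int]:
    """Whether the ME+2FI model matrix over ``subset`` has full column rank.

    Returns ``(full_rank, rank)``.  Rank is exact (integer elimination),
    cross-checked against the floating SVD rank; a model with more columns
    than runs simply reports full_rank=False.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    M = model_matrix(design, subset, ModelSpec.me2fi(subset))
    p = M.shape[1]
    r_exact = exact_rank(M)
    r_float = float_rank(M)
    if r_exact != r_float:  # pragma: no cover - would indicate a rank bug
        raise ArithmeticError(
            f"rank oracle disagreement on subset {subset}: exact {r_exact}, float {r_float}"
        )
    return (r_exact == p, r_exact)


@dataclass(frozen=True)
class ProjectionReport:
    """Full-rank coverage of the ME+2FI model over k-factor subsets."""

    subset_size: int
    total_subsets: int
    full_rank_count: int
    deficient_subsets: tuple[tuple[str, ...], ...]
    exhaustive: bool = True

    @property
    def coverage(self) -> Fraction:
        return Fraction(self.full_rank_count, self.total_subsets)

    @property
    def coverage_pct(self) -> float:
        return float(100 * self.coverage)

    def __str__(self):
        scope = "all" if self.exhaustive else "sampled"
        return (
            f"k={self.subset_size}: {self.full_rank_count}/{self.total_subsets} "
            f"({scope}) full rank = {round(self.coverage_pct, 1)}%"
        )


def projection_coverage(
    design: Design,
    k: int,
    subsets: Iterable[Sequence[str]] | None = None,
) -> ProjectionReport:
    """Full-rank coverage over k-factor projections.

    By default enumerates all C(n, k) subsets; an explicit ``subsets``
    iterable restricts the check (e.g. a fixed random sample for very wide
    designs) and marks the report as non-exhaustive.
    """
    if not 1 <= k <= design.n_factors:
        raise ValueError(f"need 1 <= k <= {design.n_factors}, got k={k}")
    exhaustive = subsets is None
    if subsets is None:
        subsets = itertools.combinations(design.factors, k)
    deficient = []
    total = 0
    for subset in subsets:
        subset = tuple(subset)
        if len(subset) != k:
            raise ValueError(f"subset {subset} does not have size {k}")
        total += 1
        ok, _ = is_full_rank_projection(design, subset)
        if not ok:
            deficient.append(subset)
    return ProjectionReport(
        subset_size=k,
        total_subsets=total,
        full_rank_count=total - len(deficient),
        deficient_subsets=tuple(deficient),
        exhaustive=exhaustive,
    )


def cheng_guarantee(N: int, n: int, t: int) -> int | None:
    """Guaranteed hidden-projection subset size from run-count divisibility.

    For a strength-2 OA with N not a multiple of 8 and n >= 4, every
    4-factor projection supports the full ME+2FI model; for strength 3 with
    N not a multiple of 16 and n >= 5, every 5-factor projection does.
    Returns the guaranteed projection size, or None when the sufficient
    conditions do not apply.
    """
    if t not in (2, 3):
        raise ValueError(f"guarantees are stated for strengths 2 and 3 only, got t={t}")
    if t == 2 and N % 8 != 0 and n >= 4:
        return 4
    if t == 3 and N % 16 != 0 and n >= 5:
        return 5
    return None


# ---------------------------------------------------------------------------
# Design comparison
# ---------------------------------------------------------------------------

def run_reduction_pct(baseline_runs: int, runs: int) -> int:
    """Percent run reduction vs a baseline, rounded to the nearest integer."""
    return round(100 * (baseline_runs - runs) / baseline_runs)


@dataclass(frozen=True)
class DesignSummary:
    name: str
    runs: int
    n_factors: int
    strength: int
    coverage: dict  # k -> ProjectionReport
    reduction_vs_baseline_pct: int | None = None


@dataclass(frozen=True)
class Comparison:
    k_values: tuple[int, ...]
    designs: tuple[DesignSummary, ...]
    baseline: str | None = None


def compare_designs(
    designs: Sequence[tuple[str, Design]],
    k_values: Sequence[int],
    baseline: str | None = None,
) -> Comparison:
    """Side-by-side projection coverage, strength, and run accounting.

    ``baseline`` names one of the designs; the others report their percent
    run reduction relative to it.
    """
    names = [name for name, _ in designs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate design names {names}")
    if baseline is not None and baseline not in names:
        raise ValueError(f"baseline {baseline!r} not among {names}")
    base_runs = dict(designs)[baseline].runs if baseline is not None else None
    summaries = []
    for name, d in designs:
        coverage = {k: projection_coverage(d, k) for k in k_values}
        summaries.append(
            DesignSummary(
                name=name,
                runs=d.runs,
                n_factors=d.n_factors,
                strength=max_strength(d),
                coverage=coverage,
                reduction_vs_baseline_pct=(
                    None if base_runs is None else run_reduction_pct(base_runs, d.runs)
                ),
            )
        )
    return Comparison(tuple(k_values), tuple(summaries), baseline)
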