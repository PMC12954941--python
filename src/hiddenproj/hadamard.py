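"""Hadamard matrix constructions and derived two-level orthogonal arrays.

Implements the Sylvester tensor-doubling construction and the two Paley
quadratic-residue constructions over a prime field (type I for primes
q = 3 mod 4, order q+1; type II for primes q = 1 mod 4, order 2(q+1)).
Dropping the all-ones column of a normalized order-N Hadamard matrix gives
an OA(N, 2^(N-1), 2); taking its first n columns gives an N-run, n-factor
non-regular design of strength two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import sympy

from .design import Design, make_design

__all__ = [
    "DomainError",
    "HadamardMatrix",
    "quadratic_residues",
    "paley_type1",
    "paley_type2",
    "sylvester",
    "hadamard_to_oa",
]


class DomainError(ValueError):
    """Arguments outside the domain of a construction."""


@dataclass(frozen=True)
class HadamardMatrix:
    """An N x N +/-1 matrix with H @ H.T == N * I (verified exactly)."""

    matrix: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=np.int64)
        N = H.shape[0]
        if H.ndim != 2 or H.shape[1] != N:
            raise DomainError(f"Hadamard matrix must be square, got shape {H.shape}")
        if not np.isin(H, (-1, 1)).all():
            raise DomainError("Hadamard entries must be -1 or +1")
        if not np.array_equal(H @ H.T, N * np.eye(N, dtype=np.int64)):
            raise DomainError("matrix is not Hadamard: H @ H.T != N * I")
        H = H.copy()
        H.flags.writeable = False
        object.__setattr__(self, "matrix", H)

    @property
    def order(self) -> int:
        return self.matrix.shape[0]

    @property
    def is_normalized(self) -> bool:
        return bool((self.matrix[0] == 1).all() and (self.matrix[:, 0] == 1).all())

    def normalized(self) -> "HadamardMatrix":
        """Negate rows then columns so the first row and column are all +1."""
        H = self.matrix.copy()
        H[H[:, 0] == -1] *= -1
        H[:, H[0] == -1] *= -1
        return HadamardMatrix(H)

    def __eq__(self, other):
        if not isinstance(other, HadamardMatrix):
            return NotImplemented
        return np.array_equal(self.matrix, other.matrix)

    def __hash__(self):
        return hash(self.matrix.tobytes())


def _require_odd_prime(q: int) -> None:
    if q < 3 or q % 2 == 0 or not sympy.isprime(q):
        raise DomainError(f"q={q} is not an odd prime")


def quadratic_residues(q: int) -> frozenset:
    """The (q-1)/2 non-zero squares modulo an odd prime q."""
    _require_odd_prime(q)
    return frozenset(pow(x, 2, q) for x in range(1, q))


def _legendre_table(q: int) -> np.ndarray:
    """chi[x] = +1 if x is a non-zero square mod q, -1 if a non-square, 0 at x=0."""
    chi = -np.ones(q, dtype=np.int64)
    chi[0] = 0
    chi[list(quadratic_residues(q))] = 1
    return chi


def _jacobsthal(q: int) -> np.ndarray:
    """Q[i, j] = chi(j - i) for i, j in GF(q)."""
    chi = _legendre_table(q)
    idx = (np.arange(q)[None, :] - np.arange(q)[:, None]) % q
    return chi[idx]


def paley_type1(q: int) -> HadamardMatrix:
    """Paley type-I Hadamard matrix of order q+1, for prime q = 3 (mod 4).

    Returns the normalized form (first row and column all +1); every other
    row of the result sums to zero.
    """
    _require_odd_prime(q)
    if q % 4 != 3:
        raise DomainError(f"Paley type I needs q = 3 (mod 4); q={q} = {q % 4} (mod 4)")
    N = q + 1
    H = np.ones((N, N), dtype=np.int64)
    H[1:, 0] = -1
    H[1:, 1:] = _jacobsthal(q) + np.eye(q, dtype=np.int64)
    return HadamardMatrix(H).normalized()


def paley_type2(q: int) -> HadamardMatrix:
    """Paley type-II Hadamard matrix of order 2(q+1), for prime q = 1 (mod 4).

    Built by doubling the symmetric conference matrix of order q+1; returned
    in normalized form.
    """
    _require_odd_prime(q)
    if q % 4 != 1:
        raise DomainError(f"Paley type II needs q = 1 (mod 4); q={q} = {q % 4} (mod 4)")
    n = q + 1
    C = np.zeros((n, n), dtype=np.int64)
    C[0, 1:] = 1
    C[1:, 0] = 1
    C[1:, 1:] = _jacobsthal(q)  # symmetric since -1 is a square for q = 1 mod 4
    on_entry = np.array([[1, 1], [1, -1]], dtype=np.int64)
    diag_entry = np.array([[1, -1], [-1, -1]], dtype=np.int64)
    H = np.kron(C, on_entry) + np.kron(np.eye(n, dtype=np.int64), diag_entry)
    return HadamardMatrix(H).normalized()


def sylvester(m: int) -> HadamardMatrix:
    """Sylvester (tensor-doubling) Hadamard matrix of order 2^m, m >= 0."""
    if m < 0:
        raise DomainError(f"m must be >= 0, got {m}")
    return HadamardMatrix(scipy.linalg.hadamard(2 ** m, dtype=np.int64))


def hadamard_to_oa(H: HadamardMatrix, n: int) -> Design:
    """Strength-2 orthogonal array from a Hadamard matrix.

    Normalizes H, drops the all-ones first column, and returns the first n
    of the remaining order-1 columns as an (order x n) design — an
    OA(order, 2^n, 2).
    """
    if not 1 <= n <= H.order - 1:
        raise DomainError(f"need 1 <= n <= {H.order - 1}, got n={n}")
    Hn = H if H.is_normalized else H.normalized()
    return make_design(Hn.matrix[:, 1 : n + 1])
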