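"""Regular two-level fractional factorial designs.

Builds 2^(k) full factorials and 2^(n-g) regular fractions from generator
words (e.g. ``E=ABC``), and computes the defining contrast subgroup,
word-length pattern, resolution, and alias sets.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .design import Design, default_labels

__all__ = [
    "SpecError",
    "Word",
    "IDENTITY",
    "GeneratorSet",
    "parse_word",
    "parse_generators",
    "build_regular",
    "defining_contrast_subgroup",
    "wordlength_pattern",
    "resolution",
    "alias_words",
]

FULL_FACTORIAL = math.inf  # resolution flag for an empty defining subgroup


class SpecError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class Word:
    """A signed effect word: a set of factor labels with a +/-1 sign.

    The empty word is the identity I.  Multiplication is symmetric
    difference of the factor sets with multiplied signs, matching the group
    of +/-1 column products.
    """

    factors: frozenset
    sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "factors", frozenset(self.factors))
        if self.sign not in (-1, 1):
            raise SpecError(f"word sign must be +/-1, got {self.sign}")

    @property
    def length(self) -> int:
        return len(self.factors)

    def __mul__(self, other: "Word") -> "Word":
        return Word(self.factors ^ other.factors, self.sign * other.sign)

    def __str__(self):
        body = "".join(sorted(self.factors)) if self.factors else "I"
        return body if self.sign > 0 else f"-{body}"

    def __repr__(self):
        return f"Word({self})"


IDENTITY = Word(frozenset())

_GEN_RE = re.compile(r"^\s*([A-Za-z]\d*)\s*=\s*([+-]?)\s*([A-Za-z\d]+)\s*$")


def parse_word(text: str) -> Word:
    """Parse a word like ``ABC``, ``-ABC`` or ``+ABC`` into single-letter factors."""
    text = text.strip()
    sign = 1
    if text[:1] in "+-":
        sign = -1 if text[0] == "-" else 1
        text = text[1:]
    letters = re.findall(r"[A-Za-z]\d*", text)
    if not letters or "".join(letters) != text:
        raise SpecError(f"cannot parse word {text!r}")
    if len(set(letters)) != len(letters):
        raise SpecError(f"repeated factor in word {text!r}")
    return Word(frozenset(letters), sign)


def parse_generators(text: str) -> tuple[tuple[str, Word], ...]:
    """Parse the generator mini-language, e.g. ``"E=ABC,F=ACD"``."""
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = _GEN_RE.match(part)
        if not m:
            raise SpecError(f"cannot parse generator {part!r} (expected LABEL=WORD)")
        label, sign, word = m.groups()
        out.append((label, parse_word(sign + word)))
    return tuple(out)


@dataclass(frozen=True)
class GeneratorSet:
    """k base factors plus generator words defining the extra columns.

    ``generators`` maps each new-factor label to a word over the base
    factors; the fraction has n = k + g factors in N = 2^k runs.
    """

    k: int
    generators: tuple[tuple[str, Word], ...] = ()
    base_labels: tuple[str, ...] = None

    def __post_init__(self):
        if self.k < 1:
            raise SpecError(f"need at least one base factor, got k={self.k}")
        base = self.base_labels
        if base is None:
            base = default_labels(self.k)
        base = tuple(base)
        if len(base) != self.k or len(set(base)) != self.k:
            raise SpecError(f"base labels must be {self.k} unique labels, got {base}")
        gens = tuple((str(lab), w if isinstance(w, Word) else parse_word(w))
                     for lab, w in self.generators)
        new_labels = [lab for lab, _ in gens]
        if len(set(new_labels)) != len(new_labels):
            raise SpecError(f"duplicate generated-factor labels {new_labels}")
        if set(new_labels) & set(base):
            raise SpecError("generated-factor labels must be disjoint from base labels")
        for lab, w in gens:
            if not w.factors:
                raise SpecError(f"generator for {lab} is empty")
            unknown = w.factors - set(base)
            if unknown:
                raise SpecError(
                    f"generator {lab}={w} references unknown base factors {sorted(unknown)}"
                )
        object.__setattr__(self, "base_labels", base)
        object.__setattr__(self, "generators", gens)

    @classmethod
    def from_strings(cls, k: int, generators: str = "",
                     base_labels: Sequence[str] | None = None) -> "GeneratorSet":
        return cls(k, parse_generators(generators),
                   None if base_labels is None else tuple(base_labels))

    @property
    def n_factors(self) -> int:
        return self.k + len(self.generators)

    @property
    def runs(self) -> int:
        return 2 ** self.k


def build_regular(gen: GeneratorSet) -> Design:
    """Construct the 2^(n-g) regular fraction defined by a generator set.

    Base columns enumerate the full 2^k factorial in standard (Yates) order:
    base factor j alternates sign in blocks of 2^(j-1), starting low.  Each
    generated column is the (signed) elementwise product of its generator's
    base columns.
    """
    N = gen.runs
    cols: dict[str, np.ndarray] = {}
    for j, lab in enumerate(gen.base_labels):
        block = 2 ** j
        cols[lab] = np.tile(
            np.repeat(np.array([-1, 1], dtype=np.int64), block), N // (2 * block)
        )
    for lab, word in gen.generators:
        prod = np.full(N, word.sign, dtype=np.int64)
        for b in sorted(word.factors):
            prod = prod * cols[b]
        cols[lab] = prod
    labels = gen.base_labels + tuple(lab for lab, _ in gen.generators)
    return Design(np.column_stack([cols[lab] for lab in labels]), labels)


def defining_contrast_subgroup(gen: GeneratorSet) -> frozenset:
    """The 2^g - 1 non-identity words generated by the defining words.

    Each generator ``E = w`` contributes the defining word ``{E} | w`` (with
    the generator's sign); the subgroup is the closure under
    symmetric-difference multiplication, excluding the identity.
    """
    defining = [
        Word(frozenset({lab}) | w.factors, w.sign) for lab, w in gen.generators
    ]
    words = set()
    for r in range(1, len(defining) + 1):
        for combo in itertools.combinations(defining, r):
            prod = IDENTITY
            for w in combo:
                prod = prod * w
            words.add(prod)
    return frozenset(words)


def wordlength_pattern(subgroup: Iterable[Word], n: int | None = None) -> tuple[int, ...]:
    """Counts of defining words by length 1..n."""
    words = list(subgroup)
    if n is None:
        n = max((w.length for w in words), default=0)
    counts = [0] * n
    for w in words:
        if w.length < 1:
            raise SpecError("identity word has no place in a defining subgroup")
        counts[w.length - 1] += 1
    return tuple(counts)


def resolution(subgroup: Iterable[Word]):
    """Minimum defining-word length; ``math.inf`` for a full factorial."""
    lengths = [w.length for w in subgroup]
    return min(lengths) if lengths else FULL_FACTORIAL


def alias_words(term: Word, subgroup: Iterable[Word]) -> frozenset:
    """The alias coset of a term: {term * w} over the subgroup plus identity.

    On the coded design, the model-matrix columns of all words in one coset
    are identical up to the subgroup's sign structure (exactly identical for
    unsigned generators).
    """
    return frozenset({term * w for w in subgroup} | {term})
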