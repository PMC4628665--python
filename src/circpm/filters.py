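"""The six rotation-invariant filter functions and the pattern signature.

Each filter is a cheap integer function ``F`` with a one-sided guarantee:
if ``F(window) != F(pattern)`` the window cannot be any rotation of the
pattern (no false negatives); equal values do not imply a match (false
positives are removed later by exact verification).

Filters 1 and 4 act on the plain string; Filters 2, 3, 5 and 6 act on
consecutive character pairs of the *extended* string ``ext(S) = S + S[0]``,
whose pairs are exactly the cyclic pairs of ``S`` and therefore invariant
under rotation.

Filter 3 (the signed distance sum) telescopes to
``codes[0] - codes[-1] == 0`` on every extended string, so it can never
reject a window; it is kept for fidelity to the filter family and can be
dropped by passing a filter subset that excludes 3.
"""

from __future__ import annotations

from dataclasses import dataclass

from .numeric_core import ALPHABET, ExtendedSequence, NumericSequence, extend

__all__ = [
    "ALL_FILTERS",
    "PatternSignature",
    "total_sum",
    "abs_total_distance",
    "total_distance",
    "per_char_sums",
    "sum_modulo",
    "sum_xor",
    "compute_signature",
]

#: Filter identifiers, in the order the family is defined.
ALL_FILTERS = frozenset({1, 2, 3, 4, 5, 6})


@dataclass(frozen=True)
class PatternSignature:
    """The six filter values of a circular pattern.

    Identical for every rotation of the pattern; equality is exact integer
    equality on all nine component integers (``per_char_sums`` holds four,
    in fixed ``a, c, g, t`` order).
    """

    total_sum: int          # Filter 1, on the plain string
    abs_dist_sum: int       # Filter 2, on the extended string
    dist_sum: int           # Filter 3, on the extended string (always 0 there)
    per_char_sums: tuple[int, int, int, int]  # Filter 4, indexed a,c,g,t
    mod_sum: int            # Filter 5, on the extended string
    xor_sum: int            # Filter 6, on the extended string

    def value(self, filter_id: int) -> int | tuple[int, int, int, int]:
        """The component checked by a given filter (1..6)."""
        return (
            self.total_sum,
            self.abs_dist_sum,
            self.dist_sum,
            self.per_char_sums,
            self.mod_sum,
            self.xor_sum,
        )[filter_id - 1]


def total_sum(s: NumericSequence) -> int:
    """Filter 1: the sum of numeric codes (empty string sums to 0)."""
    return sum(s.codes)


def _require_extended(e: ExtendedSequence) -> tuple[int, ...]:
    if not isinstance(e, ExtendedSequence):
        raise TypeError("pair filters are defined on extended sequences; call extend() first")
    return e.codes


def abs_total_distance(e: ExtendedSequence) -> int:
    """Filter 2: sum of |code[i] - code[i+1]| over consecutive pairs of ext(S)."""
    codes = _require_extended(e)
    return sum(abs(a - b) for a, b in zip(codes, codes[1:]))


def total_distance(e: ExtendedSequence) -> int:
    """Filter 3: signed sum of code[i] - code[i+1] over consecutive pairs.

    Telescopes to 0 on every extended string.
    """
    codes = _require_extended(e)
    return sum(a - b for a, b in zip(codes, codes[1:]))


def per_char_sums(s: NumericSequence) -> tuple[int, int, int, int]:
    """Filter 4: for each x in acgt, the sum of codes at positions holding x.

    Equals num(x) times the count of x, so this is a scaled base-composition
    vector.
    """
    out = [0, 0, 0, 0]
    for c in s.codes:
        if c:  # masked positions contribute nothing
            out[c - 1] += c
    return tuple(out)  # type: ignore[return-value]


def sum_modulo(e: ExtendedSequence) -> int:
    """Filter 5: sum of code[i] mod code[i+1] over consecutive pairs of ext(S)."""
    codes = _require_extended(e)
    return sum(a % b for a, b in zip(codes, codes[1:]))


def sum_xor(e: ExtendedSequence) -> int:
    """Filter 6: sum of code[i] XOR code[i+1] over consecutive pairs of ext(S)."""
    codes = _require_extended(e)
    return sum(a ^ b for a, b in zip(codes, codes[1:]))


def compute_signature(p: NumericSequence) -> PatternSignature:
    """All six filter values of the circular pattern, in one O(m) pass.

    The pair filters are accumulated over the cyclic pairs
    ``(p[i], p[(i+1) % m])``, which are exactly the consecutive pairs of
    ``ext(p)``; the result is therefore identical for every rotation of
    ``p``.

    Raises
    ------
    ValueError
        If the pattern is empty or contains masked (non-ACGT) positions —
        a pattern must be fully specified.
    """
    m = len(p)
    if m == 0:
        raise ValueError("pattern must be non-empty")
    if p.has_mask:
        raise ValueError("pattern contains non-ACGT characters; cannot build a signature")
    tot = 0
    per = [0, 0, 0, 0]
    abs_d = 0
    dist = 0
    mod = 0
    xor = 0
    codes = p.codes
    for i in range(m):
        a = codes[i]
        b = codes[(i + 1) % m]
        tot += a
        per[a - 1] += a
        abs_d += abs(a - b)
        dist += a - b
        mod += a % b
        xor += a ^ b
    return PatternSignature(tot, abs_d, dist, tuple(per), mod, xor)  # type: ignore[arg-type]


def signature_of(s: NumericSequence) -> PatternSignature:
    """Filter values of a plain window, via the module-level functions.

    A slow reference composition (plain-string filters on ``s``, pair
    filters on ``ext(s)``); the scanner maintains the same six values
    incrementally.
    """
    e = extend(s)
    return PatternSignature(
        total_sum(s),
        abs_total_distance(e),
        total_distance(e),
        per_char_sums(s),
        sum_modulo(e),
        sum_xor(e),
    )


assert len(ALPHABET) == 4  # per_char_sums layout depends on this
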