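"""DNA alphabet handling, numeric encoding, and string rotations.

Circular pattern matching works on the four-letter DNA alphabet
``{a, c, g, t}``.  Every character is mapped to a small integer code in
lexicographic order (``a=1, c=2, g=3, t=4``) so that the rotation-invariant
filter functions can be evaluated with plain integer arithmetic.

Positions outside the alphabet (``N`` and other IUPAC ambiguity codes in
real FASTA) are handled by a policy flag: the default ``"mask"`` assigns
them the sentinel code 0 — any scan window covering a masked position is
disqualified as a candidate — while ``"strict"`` raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "ALPHABET",
    "NUM",
    "MASK_CODE",
    "NumericSequence",
    "ExtendedSequence",
    "encode_sequence",
    "decode_codes",
    "rotation",
    "extend",
]

#: Alphabet in lexicographic (and code) order.
ALPHABET = "acgt"

#: Numeric code of each alphabet character: a=1, c=2, g=3, t=4.
NUM = {c: i + 1 for i, c in enumerate(ALPHABET)}

#: Sentinel code for masked (non-ACGT) positions under the "mask" policy.
MASK_CODE = 0


@dataclass(frozen=True)
class NumericSequence:
    """A (lowercased) DNA string together with its numeric code vector.

    ``codes[i]`` is 1..4 for ``acgt`` and :data:`MASK_CODE` (0) for masked
    positions.
    """

    chars: str
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.codes):
            raise ValueError("chars and codes must have equal length")

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self) -> Iterator[int]:
        return iter(self.codes)

    @property
    def masked_positions(self) -> tuple[int, ...]:
        """0-based positions carrying the mask sentinel."""
        return tuple(i for i, c in enumerate(self.codes) if c == MASK_CODE)

    @property
    def has_mask(self) -> bool:
        return MASK_CODE in self.codes


@dataclass(frozen=True)
class ExtendedSequence:
    """``ext(S) = S + S[0]``: the base string with its first character appended.

    Extension makes functions of consecutive character pairs rotation
    invariant: the pairs of ``ext(S)`` are exactly the cyclic pairs of ``S``,
    and a rotation of ``S`` permutes its cyclic pairs without changing the
    multiset.
    """

    base: NumericSequence
    chars: str = field(init=False)
    codes: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.base) == 0:
            raise ValueError("cannot extend an empty sequence")
        object.__setattr__(self, "chars", self.base.chars + self.base.chars[0])
        object.__setattr__(self, "codes", self.base.codes + (self.base.codes[0],))

    def __len__(self) -> int:
        return len(self.codes)


def encode_sequence(s: str, policy: str = "mask") -> NumericSequence:
    """Encode a DNA string into a :class:`NumericSequence`.

    The input is lowercased first (FASTA is mixed-case in practice).

    Parameters
    ----------
    s
        Input string.
    policy
        ``"mask"`` (default): non-ACGT characters get the sentinel code 0.
        ``"strict"``: a non-ACGT character raises :class:`ValueError`
        naming the offending (0-based) position.
    """
    if policy not in ("mask", "strict"):
        raise ValueError(f"unknown alphabet policy {policy!r}")
    folded = s.lower()
    codes = []
    for i, ch in enumerate(folded):
        code = NUM.get(ch)
        if code is None:
            if policy == "strict":
                raise ValueError(
                    f"character {ch!r} at position {i} is outside the alphabet 'acgt'"
                )
            code = MASK_CODE
        codes.append(code)
    return NumericSequence(folded, tuple(codes))


def decode_codes(codes: tuple[int, ...] | list[int]) -> str:
    """Inverse of encoding: codes back to characters (mask sentinel -> ``n``)."""
    return "".join("nacgt"[c] for c in codes)


def rotation(p: NumericSequence, i: int) -> NumericSequence:
    """The i-th rotation (conjugate) of ``p``: ``p[i:] + p[:i]``.

    ``rotation(p, 0)`` is ``p`` itself.
    """
    m = len(p)
    if m < 1:
        raise ValueError("cannot rotate an empty sequence")
    if not 0 <= i < m:
        raise IndexError(f"rotation index {i} out of range for length {m}")
    return NumericSequence(p.chars[i:] + p.chars[:i], p.codes[i:] + p.codes[:i])


def extend(s: NumericSequence) -> ExtendedSequence:
    """``ext(S)``: append the first character of ``S`` at its end."""
    return ExtendedSequence(s)
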