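"""Exact verification of candidate windows and the end-to-end matcher.

The filter stage only guarantees no false negatives; each surviving window
must still be checked exactly.  Because every candidate has exactly the
pattern's length m, verification reduces to a rotation test: w is a rotation
of P iff w occurs as a substring of the doubled pattern P·P at an offset
below m.  The offset is the rotation index, and taking the first occurrence
yields the smallest index for periodic patterns.

``circular_pattern_match`` runs the whole pipeline — encode, signature,
rolling scan, reduced text, verification — and is checked in the test suite
against ``brute_force_cpm``, a quadratic oracle that compares every window
against every rotation directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .filters import ALL_FILTERS, compute_signature
from .numeric_core import NumericSequence, encode_sequence
from .window_scan import ReducedText, build_reduced_text, scan_text

__all__ = [
    "Match",
    "is_rotation",
    "rotation_indices",
    "verify_candidates",
    "circular_pattern_match",
    "brute_force_cpm",
    "matches_to_tsv",
]


@dataclass(frozen=True)
class Match:
    """One occurrence of a rotation of the pattern in the text.

    ``position`` is the 1-based start in the text; ``rotation_index`` is the
    smallest i with window == P^i (P^0 = P).
    """

    position: int
    rotation_index: int
    factor: str = ""
    record_id: str = ""


def is_rotation(w: NumericSequence | str, p: NumericSequence | str) -> int | None:
    """Smallest rotation index i with ``w == p[i:] + p[:i]``, or None.

    Located by searching for w in the doubled pattern p+p.
    """
    wc = w.chars if isinstance(w, NumericSequence) else w.lower()
    pc = p.chars if isinstance(p, NumericSequence) else p.lower()
    if len(wc) != len(pc):
        raise ValueError(f"length mismatch: |w|={len(wc)}, |p|={len(pc)}")
    if not pc:
        raise ValueError("empty pattern")
    idx = (pc + pc).find(wc)
    return idx if 0 <= idx < len(pc) else None


def rotation_indices(w: NumericSequence | str, p: NumericSequence | str) -> list[int]:
    """All rotation indices i in [0, m) with ``w == p[i:] + p[:i]``.

    Non-empty only for periodic patterns beyond the first hit.
    """
    wc = w.chars if isinstance(w, NumericSequence) else w.lower()
    pc = p.chars if isinstance(p, NumericSequence) else p.lower()
    if len(wc) != len(pc):
        raise ValueError(f"length mismatch: |w|={len(wc)}, |p|={len(pc)}")
    doubled = pc + pc
    out = []
    i = doubled.find(wc)
    while 0 <= i < len(pc):
        out.append(i)
        i = doubled.find(wc, i + 1)
    return out


def verify_candidates(
    t: NumericSequence,
    candidates: Sequence[int],
    p: NumericSequence,
    reduced: ReducedText | None = None,
    all_rotations: bool = False,
    record_id: str = "",
) -> list[Match]:
    """Exact-check each candidate window; keep those that are rotations of p.

    When a :class:`ReducedText` is supplied the windows are read from it
    (each candidate lies inside one segment, so no read crosses a
    separator); otherwise they are sliced from the text directly.
    """
    m = len(p)
    out: list[Match] = []
    for start in candidates:
        window = reduced.window(start, m) if reduced is not None else t.chars[start : start + m]
        if all_rotations:
            for i in rotation_indices(window, p):
                out.append(Match(start + 1, i, window, record_id))
        else:
            i = is_rotation(window, p)
            if i is not None:
                out.append(Match(start + 1, i, window, record_id))
    return out


def circular_pattern_match(
    p: str,
    t: str,
    enabled_filters: frozenset[int] | Sequence[int] = ALL_FILTERS,
    alphabet_policy: str = "mask",
    all_rotations: bool = False,
    record_id: str = "",
) -> list[Match]:
    """Find every position of ``t`` where some rotation of ``p`` occurs.

    Full pipeline: encode, compute the pattern signature, rolling filter
    scan, reduced-text construction, exact verification.  Output is sorted
    by position.
    """
    if not p:
        raise ValueError("pattern must be non-empty")
    pat = encode_sequence(p, policy="strict")
    txt = encode_sequence(t, policy=alphabet_policy)
    if len(pat) > len(txt):
        warnings.warn(
            f"pattern (m={len(pat)}) longer than text (n={len(txt)}); no match possible",
            stacklevel=2,
        )
        return []
    sig = compute_signature(pat)
    candidates = scan_text(txt, sig, len(pat), enabled_filters)
    reduced = build_reduced_text(txt, candidates, len(pat))
    return verify_candidates(
        txt, candidates, pat, reduced=reduced, all_rotations=all_rotations, record_id=record_id
    )


def brute_force_cpm(p: str, t: str, all_rotations: bool = False) -> list[Match]:
    """Quadratic ground-truth oracle: every window against every rotation.

    Materialises all m rotations and compares characters directly; used by
    the test suite as the authoritative reference for the filter pipeline.
    """
    if not p:
        raise ValueError("pattern must be non-empty")
    pc = p.lower()
    tc = t.lower()
    m, n = len(pc), len(tc)
    if m > n:
        warnings.warn("pattern longer than text; no match possible", stacklevel=2)
        return []
    rots: dict[str, list[int]] = {}
    for i in range(m):
        rots.setdefault(pc[i:] + pc[:i], []).append(i)
    out: list[Match] = []
    for s in range(n - m + 1):
        window = tc[s : s + m]
        indices = rots.get(window)
        if indices:
            if all_rotations:
                out.extend(Match(s + 1, i, window) for i in indices)
            else:
                out.append(Match(s + 1, indices[0], window))
    return out


def matches_to_tsv(matches: Sequence[Match], one_based: bool = True) -> str:
    """Render matches as TSV rows: record_id, position, rotation_index, factor."""
    lines = []
    for mt in matches:
        pos = mt.position if one_based else mt.position - 1
        lines.append(f"{mt.record_id}\t{pos}\t{mt.rotation_index}\t{mt.factor}")
    return "".join(line + "\n" for line in lines)
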