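"""Sliding-window search-space reduction.

A length-m window slides across the text while all six filter values are
maintained in O(1) per step; windows whose values equal the pattern
signature on every enabled filter become candidates.  Candidates are then
merged into segments and concatenated — separated by a character outside
the alphabet (``'$'``) — into a *reduced text* on which exact verification
runs.

Rolling update: Filters 1 and 4 exchange the code of the outgoing character
for that of the incoming one.  The pair filters (2, 3, 5, 6) run over the
cyclic pairs of the window, so a slide from start ``s`` to ``s+1`` removes
the pair ``(t[s], t[s+1])`` and the old wrap pair ``(t[s+m-1], t[s])`` and
adds the pair ``(t[s+m-1], t[s+m])`` and the new wrap pair
``(t[s+m], t[s+1])``.

Masked (non-ACGT) positions carry the code 0; windows covering one are
marked invalid and can never be candidates.  The rolling arithmetic
substitutes an effective code of 1 at such positions so the update stays
well defined (0 would break the modulo filter); the values of an invalid
window are never compared to the signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .filters import ALL_FILTERS, PatternSignature
from .numeric_core import ALPHABET, MASK_CODE, NumericSequence

__all__ = [
    "SEPARATOR",
    "WindowState",
    "CandidateSegment",
    "ReducedText",
    "init_window_state",
    "slide_window",
    "iter_window_states",
    "scan_text",
    "build_reduced_text",
    "selectivity_report",
    "write_reduced_text",
]

#: Default segment separator; any character outside the alphabet is accepted.
SEPARATOR = "$"


@dataclass(frozen=True)
class WindowState:
    """Rolling filter values of the window ``t[start : start + m]``."""

    start: int
    m: int
    total_sum: int
    abs_dist_sum: int
    dist_sum: int
    per_char_sums: tuple[int, int, int, int]
    mod_sum: int
    xor_sum: int
    masked_count: int = 0

    @property
    def valid(self) -> bool:
        """False when the window covers a masked (non-ACGT) position."""
        return self.masked_count == 0

    def matches(self, sig: PatternSignature, enabled: frozenset[int] = ALL_FILTERS) -> bool:
        """Whether every enabled filter value equals the signature's.

        An empty filter set accepts every valid window (degenerate but
        well defined: no filter rejects).
        """
        if not self.valid:
            return False
        checks = (
            self.total_sum == sig.total_sum,
            self.abs_dist_sum == sig.abs_dist_sum,
            self.dist_sum == sig.dist_sum,
            self.per_char_sums == sig.per_char_sums,
            self.mod_sum == sig.mod_sum,
            self.xor_sum == sig.xor_sum,
        )
        return all(checks[f - 1] for f in enabled)


def _eff(code: int) -> int:
    # effective code for pair arithmetic at masked positions
    return code if code != MASK_CODE else 1


def init_window_state(t: NumericSequence, m: int) -> WindowState:
    """Filter values of the first window ``t[0:m]``, computed from scratch."""
    if m < 1:
        raise ValueError("window length must be >= 1")
    if m > len(t):
        raise ValueError(f"pattern longer than text ({m} > {len(t)})")
    return _state_at(t, 0, m)


def _state_at(t: NumericSequence, start: int, m: int) -> WindowState:
    codes = t.codes[start : start + m]
    tot = 0
    per = [0, 0, 0, 0]
    abs_d = dist = mod = xor = 0
    masked = 0
    for i in range(m):
        c = codes[i]
        if c == MASK_CODE:
            masked += 1
        else:
            tot += c
            per[c - 1] += c
        a = _eff(codes[i])
        b = _eff(codes[(i + 1) % m])
        abs_d += abs(a - b)
        dist += a - b
        mod += a % b
        xor += a ^ b
    return WindowState(start, m, tot, abs_d, dist, tuple(per), mod, xor, masked)  # type: ignore[arg-type]


def slide_window(state: WindowState, t: NumericSequence) -> WindowState:
    """Advance the window by one position in O(1)."""
    s, m = state.start, state.m
    if s + m >= len(t):
        raise ValueError("cannot slide past the end of the text")
    out_code = t.codes[s]          # leaves the window
    in_code = t.codes[s + m]       # enters the window

    tot = state.total_sum
    per = list(state.per_char_sums)
    masked = state.masked_count
    if out_code == MASK_CODE:
        masked -= 1
    else:
        tot -= out_code
        per[out_code - 1] -= out_code
    if in_code == MASK_CODE:
        masked += 1
    else:
        tot += in_code
        per[in_code - 1] += in_code

    # pair bookkeeping on effective codes
    first = _eff(out_code)                 # t[s]
    second = _eff(t.codes[s + 1])          # t[s+1], first char of the new window
    last = _eff(t.codes[s + m - 1])        # t[s+m-1], last char of the old window
    new_last = _eff(in_code)               # t[s+m]

    removed = ((first, second), (last, first))
    added = ((last, new_last), (new_last, second))

    abs_d, dist, mod, xor = state.abs_dist_sum, state.dist_sum, state.mod_sum, state.xor_sum
    for a, b in removed:
        abs_d -= abs(a - b)
        dist -= a - b
        mod -= a % b
        xor -= a ^ b
    for a, b in added:
        abs_d += abs(a - b)
        dist += a - b
        mod += a % b
        xor += a ^ b

    return WindowState(s + 1, m, tot, abs_d, dist, tuple(per), mod, xor, masked)  # type: ignore[arg-type]


def iter_window_states(t: NumericSequence, m: int) -> Iterator[WindowState]:
    """All ``len(t) - m + 1`` window states, in order, via rolling updates."""
    state = init_window_state(t, m)
    yield state
    for _ in range(len(t) - m):
        state = slide_window(state, t)
        yield state


def scan_text(
    t: NumericSequence,
    sig: PatternSignature,
    m: int,
    enabled_filters: frozenset[int] | Sequence[int] = ALL_FILTERS,
) -> list[int]:
    """0-based start positions of every window passing all enabled filters.

    With all six filters enabled the result is a superset of the true
    occurrence positions (the filters admit no false negatives).
    """
    enabled = frozenset(enabled_filters)
    if not enabled <= ALL_FILTERS:
        raise ValueError(f"unknown filter ids: {sorted(enabled - ALL_FILTERS)}")
    return [st.start for st in iter_window_states(t, m) if st.matches(sig, enabled)]


@dataclass(frozen=True)
class CandidateSegment:
    """A maximal run of overlapping candidate windows, as a text interval.

    ``[start, end)`` is 0-based half-open in the original text;
    ``offset`` is where the segment's first character sits in the reduced
    text.
    """

    start: int
    end: int
    window_starts: tuple[int, ...]
    offset: int


@dataclass(frozen=True)
class ReducedText:
    """Merged candidate factors joined by a separator outside the alphabet."""

    text: str
    segments: tuple[CandidateSegment, ...]
    separator: str = SEPARATOR

    def to_original(self, pos: int) -> int | None:
        """Original text position of a reduced-text position (None on a separator)."""
        for seg in self.segments:
            if seg.offset <= pos < seg.offset + (seg.end - seg.start):
                return seg.start + (pos - seg.offset)
        return None

    def window(self, candidate_start: int, m: int) -> str:
        """The length-m window at an original candidate start, read from
        the reduced text (never crossing a separator)."""
        for seg in self.segments:
            if seg.start <= candidate_start and candidate_start + m <= seg.end:
                off = seg.offset + (candidate_start - seg.start)
                return self.text[off : off + m]
        raise KeyError(f"position {candidate_start} is not inside any candidate segment")


def build_reduced_text(
    t: NumericSequence,
    candidates: Sequence[int],
    m: int,
    separator: str = SEPARATOR,
) -> ReducedText:
    """Merge overlapping candidate windows and emit the reduced text.

    Windows whose starts differ by less than ``m`` overlap and are merged
    into one segment (only the non-overlapped characters are appended);
    non-overlapping windows become separate segments joined by a single
    separator character.
    """
    if separator.lower() in ALPHABET or len(separator) != 1:
        raise ValueError("separator must be a single character outside the alphabet")
    if not candidates:
        return ReducedText("", (), separator)
    if list(candidates) != sorted(candidates):
        raise ValueError("candidate starts must be sorted ascending")

    groups: list[list[int]] = [[candidates[0]]]
    for c in candidates[1:]:
        if c - groups[-1][-1] < m:
            groups[-1].append(c)
        else:
            groups.append([c])

    pieces: list[str] = []
    segments: list[CandidateSegment] = []
    offset = 0
    for g in groups:
        start, end = g[0], g[-1] + m
        piece = t.chars[start:end]
        segments.append(CandidateSegment(start, end, tuple(g), offset))
        pieces.append(piece)
        offset += len(piece) + 1  # +1 for the separator
    return ReducedText(separator.join(pieces), tuple(segments), separator)


def selectivity_report(
    t: NumericSequence, sig: PatternSignature, m: int
) -> list[tuple[tuple[int, ...], int]]:
    """Candidate counts under the cumulative filter subsets {1}, {1,2}, ... {1..6}.

    Adding a filter can only intersect the candidate set, so the counts are
    monotonically non-increasing; this is the observable analogue of
    comparing filter-subset variants of the algorithm.
    """
    report = []
    states = list(iter_window_states(t, m))
    for k in range(1, 7):
        subset = frozenset(range(1, k + 1))
        count = sum(1 for st in states if st.matches(sig, subset))
        report.append((tuple(range(1, k + 1)), count))
    return report


def write_reduced_text(reduced: ReducedText, path: str, map_path: str | None = None) -> None:
    """Dump the reduced text, optionally with a TSV offset map.

    The map has one row per segment: reduced-text offset, original 1-based
    start, original 1-based end (inclusive).
    """
    with open(path, "w") as fh:
        fh.write(reduced.text + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            fh.write("reduced_offset\torig_start\torig_end\n")
            for seg in reduced.segments:
                fh.write(f"{seg.offset}\t{seg.start + 1}\t{seg.end}\n")
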