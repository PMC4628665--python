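import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circpm import (
    build_reduced_text,
    compute_signature,
    encode_sequence,
    init_window_state,
    iter_window_states,
    scan_text,
    selectivity_report,
    slide_window,
)
from circpm.window_scan import _state_at, write_reduced_text

from conftest import WORKED_PATTERN, WORKED_TEXT, random_dna

dna_text = st.text(alphabet="acgt", min_size=1, max_size=120)


def as_tuple(st_):
    return (
        st_.total_sum,
        st_.abs_dist_sum,
        st_.dist_sum,
        st_.per_char_sums,
        st_.mod_sum,
        st_.xor_sum,
    )


def test_init_matches_signature_values():
    t = encode_sequence(WORKED_TEXT)
    state = init_window_state(t, 7)
    assert as_tuple(state) == (18, 14, 0, (2, 2, 6, 8), 5, 28)


def test_init_constant_text():
    state = init_window_state(encode_sequence("aaaa"), 4)
    assert as_tuple(state) == (4, 0, 0, (4, 0, 0, 0), 0, 0)


@pytest.mark.parametrize("s", ["acgtgtca", "t", "ggccaatt"])
def test_full_length_window_equals_signature(s):
    """A window spanning the whole text carries exactly its signature."""
    seq = encode_sequence(s)
    state = init_window_state(seq, len(s))
    sig = compute_signature(seq)
    assert as_tuple(state) == (
        sig.total_sum,
        sig.abs_dist_sum,
        sig.dist_sum,
        sig.per_char_sums,
        sig.mod_sum,
        sig.xor_sum,
    )


def test_init_errors():
    t = encode_sequence("acgt")
    with pytest.raises(ValueError, match="longer than text"):
        init_window_state(t, 5)
    with pytest.raises(ValueError):
        init_window_state(t, 0)


def test_slide_reproduces_rolling_rows():
    """First slides of the worked scan: the rolling values after one step,
    and across the step from the 9th to the 10th window."""
    t = encode_sequence(WORKED_TEXT)
    states = list(iter_window_states(t, 7))
    assert len(states) == 13  # n - m + 1 = 19 - 7 + 1
    assert as_tuple(states[1]) == (15, 12, 0, (3, 2, 6, 4), 4, 18)
    assert as_tuple(states[9]) == (18, 10, 0, (2, 2, 6, 8), 6, 24)


def test_slide_past_end_rejected():
    t = encode_sequence("acgta")
    state = _state_at(t, 2, 3)
    with pytest.raises(ValueError):
        slide_window(state, t)


@given(dna_text, st.integers(1, 30))
@settings(max_examples=40)
def test_incremental_equals_from_scratch(s, m):
    """Every slid state equals a from-scratch recomputation at that start."""
    t = encode_sequence(s)
    m = min(m, len(t))
    for state in iter_window_states(t, m):
        assert state == _state_at(t, state.start, m)


def test_incremental_equals_from_scratch_with_masked_positions(rng):
    s = list(random_dna(rng, 80))
    for pos in (5, 6, 40, 77):
        s[pos] = "n"
    t = encode_sequence("".join(s))
    for state in iter_window_states(t, 9):
        assert state == _state_at(t, state.start, 9)
    # windows covering a masked position are invalid
    invalid = {st_.start for st_ in iter_window_states(t, 9) if not st_.valid}
    expected = set()
    for pos in (5, 6, 40, 77):
        expected |= {i for i in range(max(0, pos - 8), min(pos, 80 - 9) + 1)}
    assert invalid == expected


def test_scan_worked_example():
    t = encode_sequence(WORKED_TEXT)
    sig = compute_signature(encode_sequence(WORKED_PATTERN))
    assert scan_text(t, sig, 7) == [0, 12]


def test_scan_filter1_false_positive():
    """Filter 1 alone admits an anagram that is not a rotation."""
    t = encode_sequence("atagctg")
    sig = compute_signature(encode_sequence(WORKED_PATTERN))
    assert scan_text(t, sig, 7, enabled_filters={1}) == [0]


def test_scan_rejects_unknown_filter_ids():
    t = encode_sequence("acgt")
    sig = compute_signature(encode_sequence("ac"))
    with pytest.raises(ValueError):
        scan_text(t, sig, 2, enabled_filters={1, 7})


def test_empty_filter_set_admits_every_window():
    t = encode_sequence("acgtac")
    sig = compute_signature(encode_sequence("gg"))
    assert scan_text(t, sig, 2, enabled_filters=frozenset()) == list(range(5))


@given(dna_text, st.data())
@settings(max_examples=40)
def test_monotone_filtering(s, data):
    """Enabling more filters can only shrink the candidate set."""
    t = encode_sequence(s)
    m = data.draw(st.integers(1, len(s)))
    p = data.draw(st.text(alphabet="acgt", min_size=m, max_size=m))
    sig = compute_signature(encode_sequence(p))
    small = data.draw(st.sets(st.integers(1, 6), max_size=3))
    big = small | data.draw(st.sets(st.integers(1, 6), max_size=3))
    assert set(scan_text(t, sig, m, frozenset(big))) <= set(
        scan_text(t, sig, m, frozenset(small))
    )


def test_build_reduced_text_worked_example():
    t = encode_sequence(WORKED_TEXT)
    reduced = build_reduced_text(t, [0, 12], 7)
    assert reduced.text == "tgatcga$atcgatg"
    assert reduced.window(0, 7) == "tgatcga"
    assert reduced.window(12, 7) == "atcgatg"
    assert reduced.to_original(8) == 12
    assert reduced.to_original(7) is None  # the separator


def test_build_reduced_text_empty():
    reduced = build_reduced_text(encode_sequence("acgt"), [], 2)
    assert reduced.text == ""
    assert reduced.segments == ()


def test_build_reduced_text_merges_overlaps():
    t = encode_sequence("aaaaaaaa")
    reduced = build_reduced_text(t, [0, 1, 2], 6)
    assert reduced.text == "aaaaaaaa"
    assert len(reduced.segments) == 1
    assert reduced.segments[0].window_starts == (0, 1, 2)
    for s in (0, 1, 2):
        assert reduced.window(s, 6) == "aaaaaa"


def test_adjacent_nonoverlapping_windows_stay_separate():
    t = encode_sequence("acgtacgt")
    reduced = build_reduced_text(t, [0, 4], 4)
    assert reduced.text == "acgt$acgt"
    assert len(reduced.segments) == 2


def test_build_reduced_text_input_validation():
    t = encode_sequence("acgt")
    with pytest.raises(ValueError):
        build_reduced_text(t, [2, 0], 2)
    with pytest.raises(ValueError):
        build_reduced_text(t, [0], 2, separator="a")


@given(dna_text, st.data())
@settings(max_examples=40)
def test_reduced_text_soundness(s, data):
    """Every candidate window reads back verbatim from the reduced text,
    never crossing a separator."""
    t = encode_sequence(s)
    m = data.draw(st.integers(1, len(s)))
    starts = sorted(
        data.draw(st.sets(st.integers(0, len(s) - m), max_size=8))
    )
    reduced = build_reduced_text(t, starts, m)
    for c in starts:
        w = reduced.window(c, m)
        assert w == s[c : c + m]
        assert reduced.separator not in w


def test_selectivity_report_monotone(rng):
    text = random_dna(rng, 3000)
    pattern = text[100:120]
    t = encode_sequence(text)
    sig = compute_signature(encode_sequence(pattern))
    report = selectivity_report(t, sig, len(pattern))
    counts = [c for _, c in report]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[-1] >= 1  # the pattern itself is in the text


def test_write_reduced_text(tmp_path):
    t = encode_sequence(WORKED_TEXT)
    reduced = build_reduced_text(t, [0, 12], 7)
    out = tmp_path / "reduced.txt"
    write_reduced_text(reduced, out, tmp_path / "reduced.map.tsv")
    assert out.read_text().strip() == "tgatcga$atcgatg"
    rows = (tmp_path / "reduced.map.tsv").read_text().strip().splitlines()
    assert rows[0].split("\t") == ["reduced_offset", "orig_start", "orig_end"]
    assert rows[1].split("\t") == ["0", "1", "7"]
    assert rows[2].split("\t") == ["8", "13", "19"]
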