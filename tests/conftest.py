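import random

import pytest
from hypothesis import settings

from circpm import encode_sequence

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

WORKED_PATTERN = "atcgatg"
WORKED_TEXT = "tgatcgaaagtaatcgatg"


def random_dna(rng: random.Random, n: int, alphabet: str = "acgt") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


# Naive single-loop re-implementations of each filter, independent of the
# package's single-pass/rolling code paths; used as oracles throughout.

def naive_total_sum(s: str) -> int:
    return sum(encode_sequence(s).codes)


def naive_per_char(s: str) -> tuple[int, int, int, int]:
    num = {"a": 1, "c": 2, "g": 3, "t": 4}
    out = [0, 0, 0, 0]
    for ch in s.lower():
        out[num[ch] - 1] += num[ch]
    return tuple(out)


def _ext_codes(s: str) -> list[int]:
    codes = list(encode_sequence(s).codes)
    return codes + [codes[0]]


def naive_abs_dist(s: str) -> int:
    c = _ext_codes(s)
    return sum(abs(c[i] - c[i + 1]) for i in range(len(c) - 1))


def naive_dist(s: str) -> int:
    c = _ext_codes(s)
    return sum(c[i] - c[i + 1] for i in range(len(c) - 1))


def naive_mod(s: str) -> int:
    c = _ext_codes(s)
    return sum(c[i] % c[i + 1] for i in range(len(c) - 1))


def naive_xor(s: str) -> int:
    c = _ext_codes(s)
    return sum(c[i] ^ c[i + 1] for i in range(len(c) - 1))


NAIVE_FILTERS = {
    1: naive_total_sum,
    2: naive_abs_dist,
    3: naive_dist,
    4: naive_per_char,
    5: naive_mod,
    6: naive_xor,
}


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
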