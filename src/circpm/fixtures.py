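"""Deterministic synthetic instances: random DNA with planted rotations.

Every stage of the matcher is testable without external data: a uniform
(or composition-skewed) random background text, a random pattern, and k
rotations of the pattern planted at recorded positions.  Instances are
fully reproducible from their seed.

``generate_false_positive_probe`` searches for adversarial same-length
strings that pass a single filter without being a rotation — the windows a
lone filter would wrongly admit and verification must reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .numeric_core import ALPHABET, encode_sequence, rotation
from .filters import compute_signature
from .window_scan import init_window_state
from .verify_and_match import is_rotation

__all__ = [
    "PlantedInstance",
    "generate_instance",
    "generate_false_positive_probe",
]


@dataclass(frozen=True)
class PlantedInstance:
    """A synthetic text with known rotated occurrences of a pattern.

    ``planted`` holds 0-based start positions with the rotation index
    planted there.  Chance occurrences of other rotations in the random
    background are possible (and legitimate); the planted list is a lower
    bound on the true match set, not the whole of it.
    """

    pattern: str
    text: str
    planted: tuple[tuple[int, int], ...]
    seed: int
    params: dict = field(default_factory=dict, compare=False)

    def write(self, prefix: str | Path) -> None:
        """Write pattern/text FASTA files and a JSON truth sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.pattern.fa", "w") as fh:
            fh.write(f">pattern seed={self.seed}\n{self.pattern}\n")
        with open(f"{prefix}.text.fa", "w") as fh:
            fh.write(f">text seed={self.seed}\n{self.text}\n")
        truth = {
            "seed": self.seed,
            "pattern": self.pattern,
            "planted": [
                {"position_0based": p, "rotation_index": r} for p, r in self.planted
            ],
            "params": self.params,
        }
        with open(f"{prefix}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)


def _random_dna(rng: np.random.Generator, n: int, composition) -> str:
    idx = rng.choice(4, size=n, p=composition)
    return "".join(ALPHABET[i] for i in idx)


def generate_instance(
    m: int,
    n: int,
    k: int,
    seed: int,
    allow_overlap: bool = False,
    composition: tuple[float, float, float, float] | None = None,
) -> PlantedInstance:
    """Random background text of length n with k planted rotations of a
    random length-m pattern.

    Without ``allow_overlap`` the planted starts are at least m apart
    (requires k*m <= n).  ``composition`` optionally skews the background
    base frequencies (a, c, g, t); default uniform.
    """
    if m < 1:
        raise ValueError("pattern length must be >= 1")
    if n < m:
        raise ValueError("text must be at least as long as the pattern")
    if k < 0:
        raise ValueError("occurrence count must be >= 0")
    if not allow_overlap and k * m > n:
        raise ValueError(f"cannot pack {k} non-overlapping windows of {m} into length {n}")

    rng = np.random.default_rng(seed)
    comp = np.full(4, 0.25) if composition is None else np.asarray(composition, dtype=float)
    comp = comp / comp.sum()

    pattern = _random_dna(rng, m, comp)
    text = list(_random_dna(rng, n, comp))

    if allow_overlap:
        starts = sorted(int(x) for x in rng.integers(0, n - m + 1, size=k))
    else:
        # sorted sample with replacement, then spread by i*m: guarantees >= m apart
        slack = n - k * m
        ys = np.sort(rng.integers(0, slack + 1, size=k))
        starts = [int(y) + i * m for i, y in enumerate(ys)]

    pat_seq = encode_sequence(pattern)
    planted = []
    for s in starts:
        r = int(rng.integers(0, m))
        rotated = rotation(pat_seq, r).chars
        text[s : s + m] = rotated
        planted.append((s, r))

    # overlapping plants can overwrite earlier ones; re-derive each rotation index
    final_text = "".join(text)
    verified = []
    for s, _ in planted:
        idx = is_rotation(final_text[s : s + m], pattern)
        if idx is not None:
            verified.append((s, idx))

    return PlantedInstance(
        pattern,
        final_text,
        tuple(sorted(set(verified))),
        seed,
        params={"m": m, "n": n, "k": k, "allow_overlap": allow_overlap},
    )


def generate_false_positive_probe(
    pattern: str,
    filter_id: int,
    seed: int,
    max_attempts: int = 5000,
) -> str | None:
    """A same-length string that passes one filter but is not a rotation.

    Random permutations of the pattern's characters are tried (a
    permutation automatically preserves Filters 1 and 4, and frequently
    collides on the pair filters too); each returned probe is asserted to
    pass the requested filter and to fail the rotation test.  Returns None
    when no probe exists within the attempt budget — e.g. for unary
    patterns, whose permutations are all rotations.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if filter_id not in range(1, 7):
        raise ValueError("filter_id must be in 1..6")
    pat = encode_sequence(pattern, policy="strict")
    sig = compute_signature(pat)
    rng = np.random.default_rng(seed)
    chars = np.array(list(pat.chars))
    for _ in range(max_attempts):
        perm = "".join(rng.permutation(chars))
        if is_rotation(perm, pat) is not None:
            continue
        state = init_window_state(encode_sequence(perm), len(perm))
        if state.matches(sig, frozenset({filter_id})):
            return perm
    return None
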