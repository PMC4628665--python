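# Methods

## Problem and model

Exact circular pattern matching (CPM): report every position of a text `T`
(length n, alphabet `{a,c,g,t}`) where some rotation `P^i = P[i:] + P[:i]`
of a pattern `P` (length m) occurs.  The two-stage design is
filter-then-verify: a linear scan with rotation-invariant integer functions
shrinks the search space to candidate windows, and an exact check removes
the false positives.  Correctness rests on two facts:

1. **Filter soundness (no false negatives).**  Each filter value is a
   function of either the multiset of characters (F1, F4) or the multiset
   of *cyclic* adjacent pairs (F2, F3, F5, F6) of the window.  Rotation
   permutes characters and cyclic pairs without changing either multiset,
   so every rotation of `P` has the same six values; a window that differs
   on any value cannot be a rotation.  The extension trick — evaluating the
   pairwise functions on `ext(S) = S + S[0]` — is exactly what turns the
   linear pair sequence into the cyclic pair multiset.
2. **Verification exactness.**  A window `w` with `|w| = m` is a rotation
   of `P` iff `w` is a substring of the doubled pattern `P·P` at an offset
   in `[0, m)`; the offset is the rotation index.  Because every candidate
   window has exactly length m, a per-candidate rotation test suffices —
   no general CPM search over the reduced text is needed.  Python's
   built-in substring search does the doubling check; the first occurrence
   offset gives the smallest witnessing index for periodic patterns (all
   witnesses available behind the `all_rotations` flag).

## The filters

With codes `num(a)=1 … num(t)=4` and `e = ext(window)`:

| id | function | acts on | default |
|----|----------|---------|---------|
| 1 | `Σ num[i]` | window | on |
| 2 | `Σ abs(e[i] − e[i+1])` | extended window | on |
| 3 | `Σ (e[i] − e[i+1])` | extended window | on |
| 4 | `num(x) · count(x)` for each base | window | on |
| 5 | `Σ (e[i] mod e[i+1])` | extended window | on |
| 6 | `Σ (e[i] xor e[i+1])` | extended window | on |

All arithmetic is small-integer and exact; signature equality is exact
equality of all nine component integers, with no tolerance anywhere.

**F3 is provably inert.**  On an extended string the signed differences
telescope to `e[0] − e[−1]`, which extension forces to 0, so F3 holds for
*every* window and never rejects anything.  It is retained for fidelity to
the filter family (the property tests assert it is identically zero);
passing `enabled_filters` without 3 drops it at no cost to correctness.

**Filter subsets.**  Any subset of `{1..6}` may be enabled.  Fewer filters
can only enlarge the candidate set (monotonicity is property-tested), so
every subset is still sound; the empty set degenerates to "every window is
a candidate", which is documented behaviour, not an error.

## Rolling scan

The first window's values are computed from scratch in O(m).  A slide from
start `s` to `s+1` is O(1): F1/F4 exchange the outgoing character's code
for the incoming one's; the pair filters remove the pair
`(t[s], t[s+1])` and the old wrap pair `(t[s+m−1], t[s])` and add
`(t[s+m−1], t[s+m])` and the new wrap pair `(t[s+m], t[s+1])`.  Whole-scan
cost is O(n).  A property test asserts the rolled state equals a
from-scratch recomputation at every position.

## Coordinates, case, and degenerate inputs

- Internal coordinates are 0-based half-open; all reported positions are
  1-based by default (`--zero-based` switches the CLI).
- Input is lowercased before encoding; FASTA case is preserved only for
  display.
- Non-ACGT characters (N and other IUPAC codes) follow a policy flag:
  the default `mask` gives them a sentinel code and invalidates every
  window covering one (such a window can never be a candidate — a
  conservative choice: an ambiguity code is not an exact match).  The
  rolling arithmetic substitutes an effective code of 1 at masked
  positions purely to keep the modulo update defined; invalid windows are
  never compared to the signature.  `strict` raises instead, naming the
  offending position.  Patterns must always be pure ACGT.
- Empty pattern: error.  Pattern longer than text: empty result with a
  warning.  Empty text or `m = n`: handled by the same scan (1 window).

## Reduced text

Candidate windows whose starts differ by less than m overlap and are
merged into maximal segments; segments are concatenated, separated by a
single `$` (any character outside the alphabet is accepted).  Adjacent but
non-overlapping windows (gap exactly m) stay separate segments: the
separator only has to prevent spurious matches across segment boundaries,
and windows that share no characters need not be merged.  Each segment
records its original interval and its offset in the reduced string, so any
candidate window can be read back verbatim without crossing a separator.
Re-scanning an emitted reduced text reproduces the original matched
factors because `$` is masked by the encoder.

## Synthetic instances

`fixtures.generate_instance(m, n, k, seed)` draws a uniform random pattern
and background text (optionally composition-skewed, e.g. GC-rich, for
selectivity stress tests) and plants `k` uniformly chosen rotations at
recorded positions, at least m apart unless `allow_overlap` is set.
Non-overlapping placement uses the sorted-sample-plus-offset construction,
so it is exact, not rejection-based.  Instances are byte-reproducible from
the seed (`numpy.random.default_rng`).

What the generator emulates: random genome-like text with known rotated
occurrences, which is what the scan/verify stages see.  What it does not
emulate: real genomic repeat structure, skewed k-mer composition beyond a
global base-frequency vector, or texts near memory limits.  Passing tests
therefore demonstrate algorithmic correctness (soundness, exactness,
rolling-update fidelity) — not filter *selectivity* on real genomes, which
depends on sequence statistics.

`generate_false_positive_probe` searches random permutations of the
pattern for a same-length string that passes one chosen filter yet is not
a rotation (a permutation trivially preserves F1/F4 and often collides on
the pair filters).  Every returned probe is re-asserted at generation
time; unary patterns correctly yield none, since all their permutations
are rotations.

## Test design and problem sizes

The oracle for all end-to-end tests is `brute_force_cpm`, a quadratic
direct comparison of every window against every materialised rotation —
independent of the filter and rolling-update code paths.  Equivalence is
checked three ways: a *complete enumeration* over the two-letter
subalphabet `{a,t}` at tiny sizes (every pattern of length ≤ 3 against
every text of length ≤ 6 — full four-letter enumeration at larger sizes is
combinatorially impossible), seeded random coverage of every pattern
length up to 8 against texts up to length 64 over the full alphabet, and
100 seeded planted instances of length 10⁴ with 1–20 occurrences each.
These sizes exercise every code path (merging, periodic patterns, masked
characters, overlaps) while keeping the default suite fast; hypothesis
profiles are derandomised so runs are reproducible.

## Known limitations

- DNA alphabet only.  The numeric scheme is tied to |Σ| = 4; larger
  alphabets would increase xor/modulo collisions and are not supported.
  No reverse-complement matching, no protein sequences.
- Exact matching only; no k-mismatch or edit-distance variant.
- Single pattern per scan; texts are held in memory (no streaming).
- The filters bound *work*, not worst-case complexity: an adversarial text
  of near-anagram windows can make the candidate set large, and the
  verification stage then dominates.
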