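# circpm — filter-based exact circular pattern matching for DNA

Circular DNA is everywhere: viral genomes, bacterial chromosomes and
plasmids, mitochondria, archaea.  A sequenced circular molecule can be
linearised at any point, so searching for it in a text means searching for
*every rotation* (conjugate) of the pattern at once.  Circular pattern
matching (CPM) asks: given a pattern `P` of length `m` and a text `T` of
length `n`, report every position of `T` where some rotation
`P^i = P[i:] + P[:i]` occurs exactly.

`circpm` solves exact CPM with a filter-then-verify strategy:

1. **Encode.** Each base gets a numeric code in lexicographic order:
   `num(a)=1, num(c)=2, num(g)=3, num(t)=4`.
2. **Signature.** Six cheap integer functions of the pattern are computed
   in one O(m) pass.  Each is *rotation invariant*, so the signature
   identifies the whole conjugacy class `C(P)`:
   - F1 `sum(P) = Σ num(P[i])`
   - F2 `Σ |num[i] − num[i+1]|` over `ext(P) = P·P[0]`
   - F3 `Σ (num[i] − num[i+1])` over `ext(P)` (telescopes to 0 — see
     `docs/methods.md`)
   - F4 per-base sums `sum_x(P) = num(x)·count(x)` for `x ∈ {a,c,g,t}`
   - F5 `Σ (num[i] mod num[i+1])` over `ext(P)`
   - F6 `Σ (num[i] xor num[i+1])` over `ext(P)`

   The pairwise filters act on the *extended* string `ext(S) = S + S[0]`,
   whose consecutive pairs are exactly the cyclic pairs of `S` — that is
   what makes them rotation invariant.
3. **Scan.** A length-m window slides over `T`; all six values are
   maintained in O(1) per step, giving an O(n) pass.  A window whose values
   all equal the signature is a *candidate*.  The guarantee is one-sided:
   no true occurrence is ever filtered out; false positives are possible.
4. **Reduce.** Overlapping candidate windows are merged and the surviving
   factors concatenated with a `$` separator (a character outside the
   alphabet) into a reduced text with a map back to original coordinates.
5. **Verify.** Each candidate window `w` (length m) is checked exactly:
   `w` is a rotation of `P` iff `w` occurs in the doubled pattern `P·P`
   at an offset below m — and that offset is the rotation index.

The output is the sorted list of 1-based positions with, for each, the
smallest rotation index that witnesses the match.

## Worked example

Pattern `atcgatg`, text `tgatcgaaagtaatcgatg` (length 19, so the scanner
visits 19 − 7 + 1 = 13 windows):

```python
>>> from circpm import circular_pattern_match
>>> for m in circular_pattern_match("atcgatg", "tgatcgaaagtaatcgatg"):
...     print(m.position, m.rotation_index, m.factor)
1 5 tgatcga
13 0 atcgatg
```

The pattern's signature is `(18, 14, 0, {2,2,6,8}, 5, 28)`; only the
windows at positions 1 and 13 reproduce all six values, and both survive
verification — position 1 matches the 5th rotation `tgatcga`, position 13
the pattern itself.  The reduced text for this scan is
`tgatcga$atcgatg`.

Same thing from the shell:

```sh
$ printf '>demo\ntgatcgaaagtaatcgatg\n' > text.fa
$ circpm match --pattern-seq atcgatg --text text.fa
demo	1	5	tgatcga
demo	13	0	atcgatg
```

TSV columns: record id, 1-based position, rotation index, matched factor.
Useful flags: `--filters 1,2,4` (enable a filter subset),
`--emit-reduced PATH` (dump the reduced text plus a coordinate map),
`--zero-based`, `--all-rotations` (every witnessing rotation index of a
periodic pattern, not just the smallest).  `circpm generate` writes a
seeded synthetic instance (random text with planted rotations) as a FASTA
pair plus a JSON truth sidecar.

## Layout

- `src/circpm/numeric_core.py` — alphabet, numeric encoding, rotations,
  string extension
- `src/circpm/filters.py` — the six filter functions and the one-pass
  pattern signature
- `src/circpm/window_scan.py` — rolling window scan, candidate collection,
  reduced-text construction
- `src/circpm/verify_and_match.py` — rotation verification, end-to-end
  matcher, brute-force oracle
- `src/circpm/io_cli.py` — FASTA input, TSV output, the `circpm` CLI
- `src/circpm/fixtures.py` — seeded synthetic instances and adversarial
  filter probes
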