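# Methods

## Problem and model

Given a database of N molecule representations and a query A, a *threshold
query* asks for every database entry B with S_T(A, B) ≥ S_MIN, where S_T is
the Tanimoto coefficient. For bit-string fingerprints of common length n,

    S_T(A, B) = |A∧B| / |A∨B|,

with |·| the popcount. The coefficient lies in [0, 1], is 1 exactly for
equal bit-strings and 0 exactly for disjoint one-bit sets, and is undefined
when both strings are all-zero (the denominator vanishes). `simscreen`
treats that case as an error: `tanimoto` raises, and index builders and the
linear scan drop all-zero database entries with a logged warning rather
than assign them a sentinel similarity.

All accelerated query structures are *exact*: they return precisely the
linear-scan result set. They differ only in how much of the database they
can discard using upper bounds on S_T computed from cheap summaries.

## The bounds and why they dominate

* **COUNT-MAX** `min(|A|,|B|)/max(|A|,|B|)` — from |A∧B| ≤ min(|A|,|B|) and
  |A∨B| ≥ max(|A|,|B|).
* **XOR-MAX** `(|A|+|B|−|a⊕b|)/(|A|+|B|+|a⊕b|)` — rewrite S_T through the
  popcount identities |A∧B| = (|A|+|B|−|A⊕B|)/2 and |A∨B| =
  (|A|+|B|+|A⊕B|)/2, then replace |A⊕B| by the smaller |a⊕b|, where a, b
  are the XOR folds of the k equal-sized fragments of A and B. Folding can
  only cancel differing positions, so |a⊕b| ≤ |A⊕B| and the ratio can only
  grow. (The identities themselves are verified exhaustively over all
  6-bit pairs in the test suite.)
* **TRIE-MAX** `(|A_HEAD∧B_HEAD|+|A_TAIL|)/(|A_HEAD∨B_HEAD|+|A_TAIL|)` for
  a shared d-bit prefix: the unseen tail is scored optimistically — every
  tail one-bit of A matched, no extra one-bit of B.
* **GRID-MAX** `Σ min(|A_i|,|B_i|) / Σ max(|A_i|,|B_i|)` — COUNT-MAX applied
  per fragment; finer fragmentations are never looser, and k=1 is exactly
  COUNT-MAX. While descending the grid tree at level l only |B_1|…|B_l| are
  known, so fragments beyond l contribute |A_i| to both sums (optimistic),
  making the level bound non-increasing along any root-to-leaf path.
* **Bit-knowledge bound** `min(|A|−m10, |B|−m01) / max(|A|+m01, |B|+m10)`,
  where m_ij counts examined positions with query bit i and database bit j.
  With M_ij the true totals, S_T = M11/(M01+M10+M11); at best every
  unexamined position feeds M11, giving the numerator, while each side's
  popcount plus the other side's confirmed mismatches bounds the
  denominator from below. With no knowledge it collapses to COUNT-MAX; with
  every position revealed it equals S_T. The numerator is clipped at zero
  for the corner case m10 = |A| ≠ |B|.

Dominance of every bound over the exact coefficient is not only argued but
*enumerated*: the tests check all 4,095 defined pairs of 6-bit strings for
every bound, every prefix depth d, every k | 6, and sampled partial
reveals. Pruning comparisons use `bound ≥ S_MIN − ε` with ε = 1e−12 so
floating-point rounding can never discard a qualifying entry; the final
membership test `S_T ≥ S_MIN` is computed identically (integer
intersection/union, one division) in every method, which is why result
sets match bit-for-bit.

## Index structures

* **BinIndex** — entries binned by popcount; a bin is scanned only if
  COUNT-MAX passes.
* **XorFilterIndex** — popcount bins plus a stored per-entry XOR signature
  (requires k | n so fragments share one length); XOR-MAX is applied
  per-entry after the bin filter, so its exact-evaluation count never
  exceeds the BinIndex's on the same query.
* **KDGridTree** — a k-level tree over fragment popcounts with empty
  branches pruned; children are visited in increasing |B_i| (a fixed,
  deterministic order — no best-first heuristic). Leaf cells hold their
  entries as a plain list (per-entry GRID-MAX, then exact), or as a
  singlebit/multibit tree queried by bit-knowledge descent with the cell's
  total popcount as |B|. k=1 reproduces the popcount-bin method exactly
  (same entries touched); k=n degenerates into a per-bit trie, so no
  separate trie structure is maintained.
* **Singlebit/multibit trees** — built by recursively splitting a bin's
  entries on the bit whose set/clear counts are most nearly equal (ties:
  lowest bit index; the brute-force balance count is the test oracle).
  Recursion stops at ≤ 8 entries (configurable) or when no bit
  discriminates; the stopping rule is a design choice, as is treating the
  bin popcount and path knowledge as jointly available to the bound.
  Multibit nodes record as match bits every bit constant across their
  entries and not already matched higher up, so each node may reveal many
  positions at once; the query only counts match bits not seen higher on
  the path, keeping the m_ij counts consistent.

## LINGOsim

A LINGO is a length-q substring of a SMILES string; a string of length
n ≥ q has exactly n−q+1 of them, and the LINGO profile is their multiset.
LINGOsim is the multiset Tanimoto |P_A∩P_B| / |P_A∪P_B| with
intersection = Σ_g min(c_A(g), c_B(g)) and |P_A|+|P_B| = |∩|+|∪|. Default
q = 4 (the established optimum for SMILES; configurable).

Before profiling, ring-closure digits are rewritten to '0'
(`COc(c1)cccc1C#N` → `COc(c0)cccc0C#N`): ring numbering is an artefact of
writing order, not structure. This minimal rule is the only simplification
applied — two-letter elements (Cl, Br) and case are left untouched — and
it can be switched off. SMILES are otherwise opaque text: no validation or
canonicalisation, since LINGOsim is defined on the string.

Two routes compute the same integers:

* **sorted merge** — simultaneous iteration over the two lexicographically
  sorted LINGO lists, like the merge step of a merge-sort;
* **inverted index** — a database-wide preprocessing pass assigns each
  (LINGO, occurrence rank) pair a dense integer id in first-encounter
  order, turning multisets into id sets; postings map ids to molecules. A
  batch query bumps one counter per posting hit, after which counter[m] is
  exactly |P_query ∩ P_m|. Query ranks unseen in the database are dropped
  (they cannot intersect anything). Ties to nothing: the id assignment is
  deterministic, and an audit test inverts the index and reproduces every
  profile.

Division is the only floating-point step in either route, performed on
identical integers, so the routes agree exactly — asserted, not assumed,
on 500 synthetic strings in the acceptance tests.

## Synthetic data

The generators stand in for real chemical libraries in all tests:

* `gen_fingerprints(N, n, density, seed)` — i.i.d. Bernoulli(density) bits;
  all-zero draws are redrawn. Defaults used in benchmarks mirror the
  headline experimental shape: n = 1024 bits, S_MIN = 0.9, k ∈ {1,2,3,4}
  with `--k auto` reporting all four; density 0.1 gives the sparse,
  popcount-concentrated profile typical of hashed structural fingerprints.
  Database sizes are scaled to desk scale (10³–10⁴ entries; the published
  structures target 10⁵–10⁶), which is why benchmark output reports
  *evaluation counts*, the hardware-independent cost proxy, never
  wall-clock times.
* `gen_pair_with_similarity(n, c, u, seed)` — a pair with |A∧B| = c and
  |A∨B| = u exactly, hence S_T = c/u; used for threshold edge cases such as
  S_T = 0.9 precisely at S_MIN = 0.9.
* `gen_smiles` — strings over the organic-subset SMILES alphabet with
  balanced branches and paired ring digits, drawn from a small grammar.

What the synthetic data does *not* model: bit correlations of real
fingerprint generators (substructure bits co-occur), popcount
heavy-tailedness across heterogeneous libraries, and chemically meaningful
SMILES (the strings only have the right shape and alphabet). Passing tests
therefore demonstrate *correctness* (result-set equality, bound dominance)
on realistic sizes and densities — which is representation-independent —
but measured pruning ratios on real libraries will differ from those on
i.i.d. bits.

## Numerical and degenerate-input choices

* All set arithmetic is integer; similarities are one IEEE double division.
* Fragmenting: first k−1 fragments of ⌈n/k⌉ bits, remainder last, with
  boundaries clamped to n — so for k near n with k ∤ n trailing fragments
  may be empty (popcount 0); XOR signatures additionally require k | n and
  refuse unequal fragments.
* FPS hex dialect: two hex characters per byte, first byte = bits 0–7, bit
  0 least-significant within its byte; `#num_bits=<n>` header required;
  padding bits beyond n must be zero. Round-trips are bit-exact (this
  matters for the grid/trie equivalence tests).
* Thermometer encoding for counting vectors with a per-feature cap
  (default 4, saturating): it preserves count ordering under Tanimoto,
  which a plain threshold encoding would not.
* Empty structures: an empty entry list builds an empty leaf; a query
  against it returns no hits. All-zero queries return empty results (every
  similarity is 0 < S_MIN since S_MIN > 0).

## Known limitations

* Indexes are in-memory and rebuilt from text input; there is no on-disk
  serialization format.
* Single-query fingerprint search only (no fingerprint batching); LINGOsim
  batching is per-query-molecule against the whole database.
* The balanced-split heuristic for bit trees has no optimality guarantee;
  it is the standard practical choice and is what the determinism tests
  pin down.
* SMILES handling is textual; molecules written with different atom
  orderings are different strings and will not score 1.0.
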