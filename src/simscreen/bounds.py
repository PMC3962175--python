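"""Upper bounds on the Tanimoto coefficient used for search pruning.

Every function here returns a provable upper bound on S_T(A, B) computed
from a cheap summary of B (its popcount, fragment popcounts, XOR signature,
prefix, or partially revealed bits).  A threshold query with cutoff S_MIN
may therefore discard any database entry, bin or subtree whose bound falls
below S_MIN without ever computing the exact coefficient — the pruned search
provably returns the same result set as a linear scan.

The bounds, from coarsest to tightest knowledge:

* COUNT-MAX   — from popcounts alone: min(|A|,|B|) / max(|A|,|B|).
* XOR-MAX     — adds the XOR-signature distance |a⊕b| ≤ |A⊕B|:
                (|A|+|B|−|a⊕b|) / (|A|+|B|+|a⊕b|).
* TRIE-MAX    — from a shared d-bit prefix:
                (|A_HEAD∧B_HEAD|+|A_TAIL|) / (|A_HEAD∨B_HEAD|+|A_TAIL|).
* GRID-MAX    — from per-fragment popcounts:
                Σ min(|A_i|,|B_i|) / Σ max(|A_i|,|B_i|), with a level form
                for partial paths down the kD-grid tree.
* bit-knowledge — from counts m_ij of examined positions by (query-bit,
                database-bit) value, plus both popcounts:
                min(|A|−m10, |B|−m01) / max(|A|+m01, |B|+m10).

Pruning comparisons should use ``bound >= smin - PRUNE_EPS`` so that
floating-point rounding can never discard a qualifying entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fingerprint_core import Fingerprint, FragmentedFingerprint, intersection_union

__all__ = [
    "PRUNE_EPS",
    "PrefixSplit",
    "BitKnowledge",
    "count_max",
    "xor_max",
    "trie_max",
    "grid_max",
    "grid_level_bound",
    "bitknowledge_bound",
    "bitknowledge_bound_raw",
]

#: Slack subtracted from S_MIN in pruning comparisons; guards against a
#: bound that equals the threshold being lost to floating-point rounding.
PRUNE_EPS = 1e-12


@dataclass(frozen=True)
class PrefixSplit:
    """The query side of the trie bound: its first d bits and the popcount
    of the remaining tail."""

    head_a: Fingerprint
    tail_popcount_a: int
    d: int

    @classmethod
    def from_query(cls, a: Fingerprint, d: int) -> "PrefixSplit":
        if not 0 <= d <= a.n:
            raise ValueError(f"prefix depth d={d} out of range 0..{a.n}")
        head = (
            Fingerprint.empty()
            if d == 0
            else Fingerprint(a.bits[:d], _allow_empty=True)
        )
        return cls(head_a=head, tail_popcount_a=a.popcount - head.popcount, d=d)


@dataclass(frozen=True)
class BitKnowledge:
    """Counts m_ij of examined positions where the query bit is i and the
    database bit is j.  Walking down a singlebit or multibit tree reveals
    positions one node at a time; these counters accumulate that partial
    knowledge of the true totals M_ij."""

    m00: int = 0
    m01: int = 0
    m10: int = 0
    m11: int = 0

    def __post_init__(self):
        for name in ("m00", "m01", "m10", "m11"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def reveal(self, query_bit: bool, db_bit: bool) -> "BitKnowledge":
        """Return the knowledge after examining one more position."""
        key = f"m{int(query_bit)}{int(db_bit)}"
        return BitKnowledge(**{**self.__dict__, key: getattr(self, key) + 1})

    @property
    def total(self) -> int:
        return self.m00 + self.m01 + self.m10 + self.m11


def count_max(pa: int, pb: int) -> float:
    """COUNT-MAX: min(|A|,|B|) / max(|A|,|B|).

    Follows from |A∧B| ≤ min(|A|,|B|) and |A∨B| ≥ max(|A|,|B|); dominates
    the Tanimoto coefficient of every pair with these popcounts.
    """
    if pa < 0 or pb < 0:
        raise ValueError("popcounts must be non-negative")
    if pa + pb == 0:
        raise ValueError("COUNT-MAX is undefined for two all-zero fingerprints")
    return min(pa, pb) / max(pa, pb)


def xor_max(pa: int, pb: int, sig_xor_popcount: int) -> float:
    """XOR-MAX: (|A|+|B|−|a⊕b|) / (|A|+|B|+|a⊕b|).

    ``sig_xor_popcount`` is |a⊕b| for XOR signatures a, b of A and B.
    Because the XOR fold can only cancel differing bits, |a⊕b| ≤ |A⊕B|,
    and substituting the smaller value into the Tanimoto identity
    S_T = (|A|+|B|−|A⊕B|) / (|A|+|B|+|A⊕B|) can only increase the ratio.
    """
    if pa + pb == 0:
        raise ValueError("XOR-MAX is undefined for two all-zero fingerprints")
    if sig_xor_popcount < 0:
        raise ValueError("|a⊕b| must be non-negative")
    return max(pa + pb - sig_xor_popcount, 0) / (pa + pb + sig_xor_popcount)


def trie_max(p: PrefixSplit, head_b: Fingerprint) -> float:
    """TRIE-MAX: (|A_HEAD∧B_HEAD| + |A_TAIL|) / (|A_HEAD∨B_HEAD| + |A_TAIL|).

    Valid for every database fingerprint whose first d bits equal
    ``head_b``: in the unseen tail, at best every one of A's tail one-bits
    is matched and no extra one-bit of B appears.
    """
    if head_b.n != p.d:
        raise ValueError(f"head length mismatch: |head_b|={head_b.n}, d={p.d}")
    if p.d == 0:
        inter, union = 0, 0
    else:
        inter, union = intersection_union(p.head_a, head_b)
    num = inter + p.tail_popcount_a
    den = union + p.tail_popcount_a
    if den == 0:
        raise ValueError("TRIE-MAX undefined: no one-bit in heads or query tail")
    return num / den


def grid_max(fa: FragmentedFingerprint, frag_popcounts_b: Sequence[int]) -> float:
    """GRID-MAX: Σ_i min(|A_i|,|B_i|) / Σ_i max(|A_i|,|B_i|).

    The per-fragment COUNT-MAX argument applied piecewise; finer fragmenting
    gives a tighter (never looser) bound, and k=1 reduces to COUNT-MAX.
    """
    if len(frag_popcounts_b) != fa.k:
        raise ValueError(
            f"fragment count mismatch: query k={fa.k}, database k={len(frag_popcounts_b)}"
        )
    pa = fa.fragment_popcounts
    num = sum(min(x, y) for x, y in zip(pa, frag_popcounts_b))
    den = sum(max(x, y) for x, y in zip(pa, frag_popcounts_b))
    if den == 0:
        raise ValueError("GRID-MAX is undefined for two all-zero fingerprints")
    return num / den


def grid_level_bound(
    fa: FragmentedFingerprint, known_popcounts_b: Sequence[int], l: int
) -> float:
    """The kD-grid tree bound at level l, where only |B_1| .. |B_l| are known:

        (Σ_{i≤l} min(|A_i|,|B_i|) + Σ_{i>l} |A_i|)
        / (Σ_{i≤l} max(|A_i|,|B_i|) + Σ_{i>l} |A_i|)

    The unknown fragments are scored optimistically (full overlap, no
    excess), so the bound can only tighten as the walk descends; at l=k it
    equals GRID-MAX.
    """
    if not 0 <= l <= fa.k:
        raise ValueError(f"level l={l} out of range 0..{fa.k}")
    if len(known_popcounts_b) < l:
        raise ValueError(f"need {l} known popcounts, got {len(known_popcounts_b)}")
    pa = fa.fragment_popcounts
    tail = sum(pa[l:])
    num = sum(min(pa[i], known_popcounts_b[i]) for i in range(l)) + tail
    den = sum(max(pa[i], known_popcounts_b[i]) for i in range(l)) + tail
    if den == 0:
        raise ValueError("level bound undefined: no one-bit in any known fragment or query tail")
    return num / den


def bitknowledge_bound_raw(pa: int, pb: int, m01: int, m10: int) -> float:
    """min(|A|−m10, |B|−m01) / max(|A|+m01, |B|+m10), numerator clipped at 0.

    Internal fast path taking the only two knowledge counters the formula
    uses; see :func:`bitknowledge_bound` for the reasoning.
    """
    if m10 > pa:
        raise ValueError(f"inconsistent knowledge: m10={m10} > |A|={pa}")
    if m01 > pb:
        raise ValueError(f"inconsistent knowledge: m01={m01} > |B|={pb}")
    if pa + pb == 0:
        raise ValueError("bound undefined for two all-zero fingerprints")
    return max(min(pa - m10, pb - m01), 0) / max(pa + m01, pb + m10)


def bitknowledge_bound(bk: BitKnowledge, pa: int, pb: int) -> float:
    """Tanimoto upper bound from popcounts plus partially examined bits.

    With M_ij the true position counts, S_T = M11 / (M01 + M10 + M11).  At
    best every still-unexamined position contributes to M11, so
    M11 ≤ min(|A|−m10, |B|−m01), while M01+M10+M11 ≥ max(|A|+m01, |B|+m10)
    (each side counts its own one-bits plus the other's confirmed-mismatch
    positions).  With no knowledge this collapses to COUNT-MAX; with all n
    positions revealed it equals the exact coefficient.  A negative
    numerator (possible when m10 = |A| ≠ |B|) is clipped to 0.
    """
    return bitknowledge_bound_raw(pa, pb, bk.m01, bk.m10)
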