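"""Binary molecular fingerprints and the exact Tanimoto coefficient.

A fingerprint is a fixed-length bit-string encoding the presence or absence
of molecular features; the Tanimoto coefficient S_T(A,B) = |A∧B| / |A∨B|
quantifies the similarity of two fingerprints as a number in [0, 1].  This
module provides the in-memory :class:`Fingerprint` type (bits plus a cached
popcount), the exact coefficient, fragmenting into k pieces, XOR signatures
of fragmented fingerprints, and the thermometer conversion of feature
counting vectors into binary fingerprints.  Everything here is exact integer
arithmetic except the single final division of the Tanimoto ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Fingerprint",
    "FragmentedFingerprint",
    "XorSignature",
    "CountingVector",
    "UndefinedSimilarityError",
    "tanimoto",
    "intersection_union",
    "split",
    "xor_signature",
    "xor_distance",
    "counting_vector_to_binary",
]


class UndefinedSimilarityError(ValueError):
    """Raised when the Tanimoto coefficient is requested for two all-zero
    fingerprints, where it is undefined (the denominator |A∨B| is zero)."""


class Fingerprint:
    """A fixed-length bit-string with a cached popcount.

    Bit index 0 is the first (leftmost) position.  The bit array is made
    read-only on construction so the cached popcount can never go stale.

    Parameters
    ----------
    bits : array-like of bool/0-1
        The bit values, first position first.
    """

    __slots__ = ("bits", "popcount")

    def __init__(self, bits: Iterable[int] | np.ndarray, *, _allow_empty: bool = False):
        arr = np.array(bits, dtype=bool, copy=True)
        if arr.ndim != 1:
            raise ValueError(f"fingerprint bits must be one-dimensional, got shape {arr.shape}")
        if arr.size == 0 and not _allow_empty:
            raise ValueError("a fingerprint must contain at least one bit")
        arr.flags.writeable = False
        self.bits = arr
        self.popcount = int(np.count_nonzero(arr))

    @property
    def n(self) -> int:
        """Length in bits."""
        return self.bits.size

    @classmethod
    def from_binary_string(cls, s: str) -> "Fingerprint":
        """Parse a '0'/'1' string, first character = bit 0."""
        if not s or set(s) - {"0", "1"}:
            raise ValueError(f"not a binary string: {s!r}")
        return cls(np.frombuffer(s.encode("ascii"), dtype=np.uint8) == ord("1"))

    @classmethod
    def empty(cls) -> "Fingerprint":
        """The zero-length fingerprint (used for d=0 prefix heads)."""
        return cls(np.zeros(0, dtype=bool), _allow_empty=True)

    def to_binary_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __len__(self) -> int:
        return self.bits.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.n == other.n and bool(np.array_equal(self.bits, other.bits))

    def __hash__(self) -> int:
        return hash((self.n, self.bits.tobytes()))

    def __repr__(self) -> str:
        body = self.to_binary_string() if self.n <= 32 else f"{self.to_binary_string()[:29]}..."
        return f"Fingerprint({body!r}, n={self.n}, popcount={self.popcount})"


@dataclass(frozen=True)
class FragmentedFingerprint:
    """A fingerprint split into k ordered fragments A_1 .. A_k whose
    concatenation reproduces the original bit-string.

    When k does not divide n, the first k−1 fragments have ⌈n/k⌉ bits and the
    last holds the remainder; for k close to n this can leave trailing empty
    fragments, which the grid bounds treat as popcount-0 pieces.
    """

    fragments: tuple[Fingerprint, ...]

    @property
    def k(self) -> int:
        return len(self.fragments)

    @property
    def n(self) -> int:
        return sum(f.n for f in self.fragments)

    @property
    def fragment_popcounts(self) -> tuple[int, ...]:
        return tuple(f.popcount for f in self.fragments)

    def concatenate(self) -> Fingerprint:
        """Reassemble the original fingerprint bit-exactly."""
        return Fingerprint(np.concatenate([f.bits for f in self.fragments]))


@dataclass(frozen=True)
class XorSignature:
    """The XOR fold a = A_1 ⊕ A_2 ⊕ ··· ⊕ A_k of a fragmented fingerprint.

    The signature is ⌈n/k⌉ bits long — shorter than the fingerprint for
    k > 1 — and |a⊕b| lower-bounds |A⊕B| for any two fingerprints fragmented
    the same way, which is what makes it usable as a pruning filter.
    """

    bits: np.ndarray
    k: int
    popcount: int = field(init=False)

    def __post_init__(self):
        arr = np.array(self.bits, dtype=bool, copy=True)
        arr.flags.writeable = False
        object.__setattr__(self, "bits", arr)
        object.__setattr__(self, "popcount", int(np.count_nonzero(arr)))

    @property
    def n(self) -> int:
        return self.bits.size


@dataclass(frozen=True)
class CountingVector:
    """Integer feature-occurrence counts, convertible to a binary fingerprint.

    ``cap`` is the per-feature maximum encoded count; counts above it
    saturate in the binary conversion.
    """

    counts: tuple[int, ...]
    cap: int = 4

    def __post_init__(self):
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.cap < 1:
            raise ValueError(f"cap must be >= 1, got {self.cap}")
        for c in self.counts:
            if c < 0:
                raise ValueError(f"counts must be non-negative, got {c}")


def _check_same_length(a: Fingerprint, b: Fingerprint) -> None:
    if a.n != b.n:
        raise ValueError(f"fingerprint length mismatch: {a.n} != {b.n}")


def intersection_union(a: Fingerprint, b: Fingerprint) -> tuple[int, int]:
    """Return (|a∧b|, |a∨b|) as exact integers.

    Uses the popcount identity |A∨B| = |A| + |B| − |A∧B| so only one bitwise
    operation is needed.
    """
    _check_same_length(a, b)
    inter = int(np.count_nonzero(a.bits & b.bits))
    return inter, a.popcount + b.popcount - inter


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Exact Tanimoto coefficient |a∧b| / |a∨b| of two equal-length
    fingerprints.

    Symmetric, in [0, 1]; 1 iff the bit-strings are equal (given a one-bit),
    0 iff their one-bit sets are disjoint.  Undefined — and raised as
    :class:`UndefinedSimilarityError` — when both fingerprints are all-zero.
    """
    inter, union = intersection_union(a, b)
    if union == 0:
        raise UndefinedSimilarityError(
            "Tanimoto is undefined for two all-zero fingerprints"
        )
    return inter / union


def fragment_boundaries(n: int, k: int) -> list[int]:
    """Split points 0 = b_0 <= b_1 <= ... <= b_k = n of the k-fragment rule:
    first k−1 fragments of ⌈n/k⌉ bits, remainder last, clamped to n."""
    if not 1 <= k <= n:
        raise ValueError(f"fragment count k={k} out of range 1..{n}")
    width = math.ceil(n / k)
    return [min(i * width, n) for i in range(k + 1)]


def split(a: Fingerprint, k: int) -> FragmentedFingerprint:
    """Split ``a`` into k fragments A_1 .. A_k with A = A_1 A_2 ··· A_k."""
    bounds = fragment_boundaries(a.n, k)
    frags = tuple(
        Fingerprint(a.bits[lo:hi], _allow_empty=True)
        for lo, hi in zip(bounds[:-1], bounds[1:])
    )
    return FragmentedFingerprint(frags)


def xor_signature(f: FragmentedFingerprint) -> XorSignature:
    """XOR fold of the fragments: a = A_1 ⊕ A_2 ⊕ ··· ⊕ A_k.

    Requires equal-length fragments (i.e. k | n); raises ValueError
    otherwise, since XOR of unequal-length bit-strings is not defined.
    """
    lengths = {frag.n for frag in f.fragments}
    if len(lengths) != 1:
        raise ValueError(
            f"XOR signature requires equal-sized fragments (k | n); got lengths {sorted(lengths)}"
        )
    folded = np.bitwise_xor.reduce(np.stack([frag.bits for frag in f.fragments]))
    return XorSignature(folded, k=f.k)


def xor_distance(a: XorSignature, b: XorSignature) -> int:
    """|a⊕b|: popcount of the XOR of two signatures of equal length/k."""
    if a.n != b.n or a.k != b.k:
        raise ValueError(
            f"signature mismatch: lengths {a.n}/{b.n}, fragment counts {a.k}/{b.k}"
        )
    return int(np.count_nonzero(a.bits ^ b.bits))


def counting_vector_to_binary(v: CountingVector) -> Fingerprint:
    """Thermometer (unary) encoding of a counting vector.

    Each feature with count c contributes ``cap`` bits, of which the first
    min(c, cap) are one; the output has len(counts)·cap bits.  The encoding
    preserves count ordering under the Tanimoto coefficient: features that
    occur more often share more one-bits.
    """
    if not v.counts:
        raise ValueError("counting vector must have at least one feature")
    bits = np.zeros(len(v.counts) * v.cap, dtype=bool)
    for i, c in enumerate(v.counts):
        bits[i * v.cap : i * v.cap + min(c, v.cap)] = True
    return Fingerprint(bits)
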