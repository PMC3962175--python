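"""LINGO profiles and LINGOsim: q-gram similarity of SMILES strings.

A LINGO is a length-q substring of a (simplified) SMILES string; a string
of length n has exactly n−q+1 of them, counted with multiplicity.  The
multiset of LINGOs is the molecule's *LINGO profile*, and LINGOsim is the
Tanimoto coefficient between two profiles:

    LINGOsim = |P_A ∩ P_B| / |P_A ∪ P_B|
             = Σ_g min(c_A(g), c_B(g)) / (t_A + t_B − Σ_g min(c_A(g), c_B(g)))

with t the profile totals.  All counting is exact integer arithmetic; the
final division is the only floating-point step, and the merge and
inverted-index routes compute the identical integers, so their similarity
values agree bit-for-bit.

Two query routes are provided:

* :func:`lingosim_merge` — per-pair, iterating the two sorted LINGO lists
  simultaneously like the merge step of a merge-sort;
* :class:`InvertedIndex` + :func:`batch_lingosim` — each (LINGO, occurrence
  rank) pair database-wide gets an integer id, turning multisets into plain
  id sets; postings map each id to the molecules containing it, and one
  query pass increments a counter per posting hit, yielding all
  intersection sizes at once while never touching molecules that share no
  occurrence id with the query.

SMILES are treated as opaque character strings — LINGOsim is defined on
the text, so no chemistry validation or canonicalisation happens here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_Q",
    "LingoProfile",
    "InvertedIndex",
    "simplify_smiles",
    "lingo_profile",
    "lingo_intersection",
    "lingosim_merge",
    "build_inverted_index",
    "batch_lingosim",
    "allpairs_lingosim",
]

#: Default LINGO length; q = 4 is the established optimum for SMILES.
DEFAULT_Q = 4

_DIGITS = str.maketrans("123456789", "000000000")


def simplify_smiles(s: str, enabled: bool = True) -> str:
    """Replace every ring-closure digit with '0' so that ring numbering —
    an artefact of SMILES writing order, not of structure — does not
    differentiate LINGOs.  All other characters pass through unchanged; set
    ``enabled=False`` to disable.  Two-letter element symbols (Cl, Br) are
    left as-is."""
    if not s:
        raise ValueError("empty SMILES string")
    return s.translate(_DIGITS) if enabled else s


@dataclass
class LingoProfile:
    """Multiset of all length-q substrings of one string."""

    q: int
    counts: dict[str, int]
    total: int
    _sorted: list[tuple[str, int]] | None = field(default=None, repr=False, compare=False)

    def sorted_items(self) -> list[tuple[str, int]]:
        """LINGOs in lexicographic order with counts (cached; this is the
        sorted list the merge iterates over)."""
        if self._sorted is None:
            self._sorted = sorted(self.counts.items())
        return self._sorted


def lingo_profile(s: str, q: int = DEFAULT_Q) -> LingoProfile:
    """All n−q+1 length-q substrings of ``s``, counted with multiplicity."""
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    if len(s) < q:
        raise ValueError(f"string of length {len(s)} has no LINGOs of length {q}")
    counts = Counter(s[i : i + q] for i in range(len(s) - q + 1))
    return LingoProfile(q=q, counts=dict(counts), total=len(s) - q + 1)


def lingo_intersection(p1: LingoProfile, p2: LingoProfile) -> int:
    """|P1 ∩ P2| = Σ_g min(c1(g), c2(g)), by simultaneous iteration over the
    two sorted LINGO lists (the merge step of a merge-sort)."""
    if p1.q != p2.q:
        raise ValueError(f"LINGO length mismatch: q={p1.q} vs q={p2.q}")
    items1 = p1.sorted_items()
    items2 = p2.sorted_items()
    i = j = inter = 0
    while i < len(items1) and j < len(items2):
        g1, c1 = items1[i]
        g2, c2 = items2[j]
        if g1 == g2:
            inter += c1 if c1 < c2 else c2
            i += 1
            j += 1
        elif g1 < g2:
            i += 1
        else:
            j += 1
    return inter


def lingosim_merge(p1: LingoProfile, p2: LingoProfile) -> float:
    """LINGOsim of two profiles via the sorted merge.

    |P1 ∪ P2| follows from |P1| + |P2| = |P1 ∩ P2| + |P1 ∪ P2|; the division
    is the only floating-point step.
    """
    inter = lingo_intersection(p1, p2)
    union = p1.total + p2.total - inter
    if union == 0:
        raise ValueError("LINGOsim is undefined for two empty profiles")
    return inter / union


class InvertedIndex:
    """Occurrence-id inverted index over a SMILES database.

    Preprocessing assigns every (LINGO, occurrence rank) pair a dense
    integer id in first-encounter order — the first occurrence of a LINGO
    within a string gets one id, the second occurrence another, and so on —
    reducing multisets of LINGOs to ordinary sets of ids.  ``postings[id]``
    lists (as indices into ``identifiers``) every molecule containing that
    occurrence; a molecule appears on a posting list at most once.
    """

    def __init__(self, q: int, simplify: bool = True):
        self.q = q
        self.simplify = simplify
        self.id_table: dict[tuple[str, int], int] = {}
        self.postings: list[list[int]] = []
        self.identifiers: list[str] = []
        self.totals: list[int] = []

    def __len__(self) -> int:
        return len(self.identifiers)

    def _occurrence_ids(self, s: str, grow: bool) -> list[int]:
        """Ids of the (LINGO, rank) pairs of ``s`` in string order.  With
        ``grow=False`` (queries), ranks unseen in the database are dropped:
        they cannot contribute to any intersection."""
        seen: Counter[str] = Counter()
        ids = []
        for i in range(len(s) - self.q + 1):
            g = s[i : i + self.q]
            seen[g] += 1
            key = (g, seen[g])
            idx = self.id_table.get(key)
            if idx is None:
                if not grow:
                    continue
                idx = len(self.postings)
                self.id_table[key] = idx
                self.postings.append([])
            ids.append(idx)
        return ids

    def add(self, identifier: str, smiles: str) -> None:
        s = simplify_smiles(smiles, self.simplify)
        if len(s) < self.q:
            logger.warning(
                "InvertedIndex: skipping %r (length %d < q=%d)",
                identifier,
                len(s),
                self.q,
            )
            return
        mol = len(self.identifiers)
        self.identifiers.append(identifier)
        self.totals.append(len(s) - self.q + 1)
        for idx in self._occurrence_ids(s, grow=True):
            self.postings[idx].append(mol)

    def profile_of(self, mol: int) -> LingoProfile:
        """Rebuild molecule ``mol``'s profile from the index (used by the
        bijection audit: inverting the index must reproduce every profile)."""
        counts: Counter[str] = Counter()
        for (g, rank), idx in self.id_table.items():
            if mol in self.postings[idx]:
                counts[g] = max(counts[g], rank)
        return LingoProfile(q=self.q, counts=dict(counts), total=sum(counts.values()))


def build_inverted_index(
    db: Iterable[tuple[str, str]], q: int = DEFAULT_Q, simplify: bool = True
) -> InvertedIndex:
    """Index a database of (identifier, SMILES) pairs; entries shorter than
    q after simplification are skipped with a warning."""
    idx = InvertedIndex(q=q, simplify=simplify)
    for identifier, smiles in db:
        idx.add(identifier, smiles)
    logger.info(
        "InvertedIndex: %d molecules, %d occurrence ids (q=%d)",
        len(idx),
        len(idx.postings),
        q,
    )
    return idx


def batch_lingosim(
    idx: InvertedIndex, query: str, smin: float
) -> list[tuple[str, float]]:
    """All database molecules with LINGOsim ≥ smin against ``query``.

    One counter per molecule; every query occurrence id bumps the counter
    of each molecule on its posting list, after which counter[m] equals the
    exact multiset intersection size |P_query ∩ P_m|.  Molecules sharing no
    occurrence id are never touched (their similarity is 0 < smin).
    """
    if not 0.0 < smin <= 1.0:
        raise ValueError(f"S_MIN must be in (0, 1], got {smin}")
    s = simplify_smiles(query, idx.simplify)
    if len(s) < idx.q:
        raise ValueError(f"query length {len(s)} < q={idx.q}")
    total_q = len(s) - idx.q + 1
    counters = np.zeros(len(idx), dtype=np.int64)
    for oid in idx._occurrence_ids(s, grow=False):
        for mol in idx.postings[oid]:
            counters[mol] += 1
    hits = []
    for mol in np.flatnonzero(counters):
        inter = int(counters[mol])
        union = total_q + idx.totals[mol] - inter
        sim = inter / union
        if sim >= smin:
            hits.append((idx.identifiers[mol], sim))
    return hits


def allpairs_lingosim(
    db: Sequence[tuple[str, str]], q: int = DEFAULT_Q, simplify: bool = True
) -> tuple[list[str], np.ndarray]:
    """Symmetric all-pairs LINGOsim matrix with unit diagonal, by the
    sorted-merge route.  Entries too short for a profile are skipped with a
    warning; returns (identifiers, matrix) in database order."""
    profiles: list[LingoProfile] = []
    identifiers: list[str] = []
    for identifier, smiles in db:
        s = simplify_smiles(smiles, simplify)
        if len(s) < q:
            logger.warning(
                "allpairs_lingosim: skipping %r (length %d < q=%d)",
                identifier,
                len(s),
                q,
            )
            continue
        identifiers.append(identifier)
        profiles.append(lingo_profile(s, q))
    if not identifiers:
        raise ValueError("no molecule long enough for a LINGO profile")
    m = len(identifiers)
    sims = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sims[i, j] = sims[j, i] = lingosim_merge(profiles[i], profiles[j])
    return identifiers, sims
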