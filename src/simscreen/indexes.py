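"""Index structures for exact Tanimoto threshold queries.

All structures answer the same query — every database fingerprint B with
S_T(A, B) ≥ S_MIN — and all are provably equivalent in output to
:func:`linear_scan`; they differ only in how many exact Tanimoto
evaluations they avoid via the upper bounds in :mod:`simscreen.bounds`:

* :class:`BinIndex` — fingerprints binned by popcount |B|; a whole bin is
  skipped when COUNT-MAX(|A|, |B|) < S_MIN.
* :class:`XorFilterIndex` — popcount bins plus a per-entry XOR signature;
  after the bin filter, XOR-MAX must also pass before the exact coefficient
  is computed.
* :class:`KDGridTree` — fingerprints placed in a k-dimensional grid keyed by
  fragment popcounts (|B_1|, ..., |B_k|), implemented as a k-level tree with
  empty branches pruned; the level bound prunes whole subtrees.  Leaf bins
  are plain lists, singlebit trees or multibit trees.
* Singlebit / multibit trees — binary trees over the entries of one bin,
  splitting on the bit that most evenly balances the two sides; walking
  down accumulates partial bit knowledge (m_ij) that tightens the bound.

Every query returns a :class:`QueryResult` carrying the hit list and the
pruning statistics (#bounds computed, #exact evaluations, which entries
were examined), so the pruning behaviour itself is testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .bounds import (
    PRUNE_EPS,
    bitknowledge_bound_raw,
    count_max,
    grid_max,
    xor_max,
)
from .fingerprint_core import (
    Fingerprint,
    fragment_boundaries,
    split,
    xor_signature,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintDB",
    "QueryStats",
    "QueryResult",
    "BinIndex",
    "XorFilterIndex",
    "KDGridTree",
    "SinglebitNode",
    "MultibitNode",
    "linear_scan",
    "build_bin_index",
    "query_bin_index",
    "build_xor_index",
    "query_xor_index",
    "build_kdgrid",
    "query_kdgrid",
    "choose_split_bit",
    "build_singlebit_tree",
    "build_multibit_tree",
    "query_bit_tree",
]

Entry = tuple[str, Fingerprint]
BinStore = Literal["list", "singlebit", "multibit"]

#: Default recursion stop for singlebit/multibit trees: make a leaf once a
#: subset has at most this many entries (or no discriminating bit remains).
DEFAULT_LEAF_CAPACITY = 8


class FingerprintDB:
    """An ordered collection of (identifier, fingerprint) pairs sharing one
    bit length n, with identifiers unique."""

    def __init__(self, entries: Iterable[Entry]):
        self.entries: list[Entry] = list(entries)
        if not self.entries:
            raise ValueError("a fingerprint database must contain at least one entry")
        self.n = self.entries[0][1].n
        seen: set[str] = set()
        for ident, fp in self.entries:
            if fp.n != self.n:
                raise ValueError(
                    f"fingerprint length mismatch for {ident!r}: {fp.n} != {self.n}"
                )
            if ident in seen:
                raise ValueError(f"duplicate identifier {ident!r}")
            seen.add(ident)
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Entry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> Entry:
        return self.entries[i]

    @property
    def identifiers(self) -> list[str]:
        return [ident for ident, _ in self.entries]

    @property
    def matrix(self) -> np.ndarray:
        """All fingerprints stacked as an (N, n) boolean matrix (cached)."""
        if self._matrix is None:
            self._matrix = np.stack([fp.bits for _, fp in self.entries])
        return self._matrix

    @property
    def popcounts(self) -> np.ndarray:
        return np.array([fp.popcount for _, fp in self.entries], dtype=np.int64)


@dataclass
class QueryStats:
    """Pruning statistics of one threshold query."""

    n_exact: int = 0  # exact Tanimoto evaluations
    n_bound: int = 0  # upper-bound evaluations
    examined_ids: list[str] = field(default_factory=list)  # entries exactly evaluated


@dataclass
class QueryResult:
    """Hits of one threshold query (identifier, similarity) plus stats.

    Hit order follows traversal order and is not significant; compare as
    sets or via :meth:`sorted_hits`.
    """

    hits: list[tuple[str, float]]
    stats: QueryStats

    def sorted_hits(self) -> list[tuple[str, float]]:
        return sorted(self.hits)

    def identifiers(self) -> set[str]:
        return {ident for ident, _ in self.hits}


def _check_query(n_db: int, a: Fingerprint, smin: float) -> None:
    if a.n != n_db:
        raise ValueError(f"query length {a.n} != database length {n_db}")
    if not 0.0 < smin <= 1.0:
        raise ValueError(f"S_MIN must be in (0, 1], got {smin}")


def _nonzero_entries(entries: Sequence[Entry], context: str) -> list[Entry]:
    """Drop all-zero fingerprints (Tanimoto undefined against them)."""
    kept = [(i, f) for i, f in entries if f.popcount > 0]
    dropped = len(entries) - len(kept)
    if dropped:
        logger.warning(
            "%s: skipped %d all-zero fingerprint(s); Tanimoto is undefined for them",
            context,
            dropped,
        )
    return kept


def linear_scan(db: FingerprintDB, a: Fingerprint, smin: float) -> QueryResult:
    """Naive screening: evaluate S_T(A, B) for every database entry.

    This is the oracle against which every index query is verified; it is
    vectorised over the stacked bit matrix, so at moderate N it is also a
    perfectly serviceable query method.
    """
    _check_query(db.n, a, smin)
    pops = db.popcounts
    inter = db.matrix @ a.bits.astype(np.int64)
    nonzero = pops > 0
    n_skipped = int(len(db) - np.count_nonzero(nonzero))
    if n_skipped:
        logger.warning(
            "linear_scan: skipped %d all-zero fingerprint(s); Tanimoto is undefined for them",
            n_skipped,
        )
    union = pops + a.popcount - inter
    stats = QueryStats(
        n_exact=int(np.count_nonzero(nonzero)),
        n_bound=0,
        examined_ids=[db.entries[i][0] for i in np.flatnonzero(nonzero)],
    )
    sims = np.zeros(len(db))
    np.divide(inter, union, out=sims, where=nonzero)
    hits = [
        (db.entries[i][0], float(sims[i]))
        for i in np.flatnonzero(nonzero & (sims >= smin))
    ]
    return QueryResult(hits=hits, stats=stats)


def _exact_eval(
    ident: str,
    fp: Fingerprint,
    a_bits_int: np.ndarray,
    pa: int,
    smin: float,
    hits: list[tuple[str, float]],
    stats: QueryStats,
) -> None:
    """Evaluate one entry exactly; append to hits if it qualifies."""
    inter = int(fp.bits @ a_bits_int)
    union = fp.popcount + pa - inter
    stats.n_exact += 1
    stats.examined_ids.append(ident)
    sim = inter / union
    if sim >= smin:
        hits.append((ident, sim))


class BinIndex:
    """Popcount bins: only bins with COUNT-MAX(|A|, |B|) ≥ S_MIN are scanned."""

    def __init__(self, db: FingerprintDB):
        self.n = db.n
        self.bins: dict[int, list[Entry]] = {}
        for ident, fp in _nonzero_entries(db.entries, "BinIndex build"):
            self.bins.setdefault(fp.popcount, []).append((ident, fp))
        logger.info(
            "BinIndex: %d entries in %d popcount bins (n=%d)",
            sum(len(v) for v in self.bins.values()),
            len(self.bins),
            self.n,
        )

    def query(self, a: Fingerprint, smin: float) -> QueryResult:
        _check_query(self.n, a, smin)
        hits: list[tuple[str, float]] = []
        stats = QueryStats()
        a_int = a.bits.astype(np.int64)
        for pb in sorted(self.bins):
            stats.n_bound += 1
            if count_max(a.popcount, pb) < smin - PRUNE_EPS:
                continue
            for ident, fp in self.bins[pb]:
                _exact_eval(ident, fp, a_int, a.popcount, smin, hits, stats)
        return QueryResult(hits=hits, stats=stats)


class XorFilterIndex:
    """Popcount bins where each entry also stores its XOR signature; the
    exact coefficient is computed only when both COUNT-MAX and XOR-MAX pass.

    Requires k | n so all fragments (and hence signatures) share one length.
    """

    def __init__(self, db: FingerprintDB, k: int):
        if db.n % k != 0:
            raise ValueError(
                f"XOR signatures require k | n, got k={k}, n={db.n}"
            )
        self.n = db.n
        self.k = k
        self.bins: dict[int, list[tuple[str, Fingerprint, np.ndarray]]] = {}
        for ident, fp in _nonzero_entries(db.entries, "XorFilterIndex build"):
            sig = xor_signature(split(fp, k))
            self.bins.setdefault(fp.popcount, []).append((ident, fp, sig.bits))
        logger.info(
            "XorFilterIndex: %d entries, k=%d (signature length %d)",
            sum(len(v) for v in self.bins.values()),
            k,
            self.n // k,
        )

    def query(self, a: Fingerprint, smin: float) -> QueryResult:
        _check_query(self.n, a, smin)
        hits: list[tuple[str, float]] = []
        stats = QueryStats()
        sig_a = xor_signature(split(a, self.k)).bits
        a_int = a.bits.astype(np.int64)
        for pb in sorted(self.bins):
            stats.n_bound += 1
            if count_max(a.popcount, pb) < smin - PRUNE_EPS:
                continue
            for ident, fp, sig_b in self.bins[pb]:
                stats.n_bound += 1
                dist = int(np.count_nonzero(sig_a ^ sig_b))
                if xor_max(a.popcount, pb, dist) < smin - PRUNE_EPS:
                    continue
                _exact_eval(ident, fp, a_int, a.popcount, smin, hits, stats)
        return QueryResult(hits=hits, stats=stats)


# --------------------------------------------------------------------------
# Singlebit / multibit trees (bin stores)
# --------------------------------------------------------------------------


@dataclass
class SinglebitNode:
    """One node of a singlebit tree.  Internal nodes index a single bit:
    entries with that bit clear live in the left subtree, entries with it
    set in the right.  Leaves hold the entries themselves."""

    split_bit: int | None = None
    left: "SinglebitNode | None" = None
    right: "SinglebitNode | None" = None
    entries: list[Entry] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.entries is not None


@dataclass
class MultibitNode:
    """One node of a multibit tree.  ``match_bits`` are the (bit index,
    value) pairs on which *all* entries below this node agree and that are
    not already match bits further up the path; leaves hold entries."""

    match_bits: list[tuple[int, bool]]
    left: "MultibitNode | None" = None
    right: "MultibitNode | None" = None
    entries: list[Entry] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.entries is not None


def choose_split_bit(
    fingerprints: Sequence[Fingerprint], forbidden: set[int] | frozenset[int] = frozenset()
) -> int | None:
    """The balanced-split heuristic: among bits not in ``forbidden`` on which
    the entries actually differ, return the one minimising |#set − #clear|,
    ties broken by lowest bit index.  Returns None when no bit discriminates
    (the caller then makes a leaf)."""
    if not fingerprints:
        raise ValueError("cannot choose a split bit for an empty entry list")
    matrix = np.stack([fp.bits for fp in fingerprints])
    return _choose_split_bit_matrix(matrix, forbidden)


def _choose_split_bit_matrix(
    matrix: np.ndarray, forbidden: set[int] | frozenset[int] = frozenset()
) -> int | None:
    n_rows = matrix.shape[0]
    set_counts = matrix.sum(axis=0)
    allowed = (set_counts > 0) & (set_counts < n_rows)
    if forbidden:
        allowed[list(forbidden)] = False
    if not allowed.any():
        return None
    balance = np.abs(2 * set_counts - n_rows)
    balance = np.where(allowed, balance, n_rows + 1)
    return int(np.argmin(balance))  # argmin takes the lowest index on ties


def build_singlebit_tree(
    entries: Sequence[Entry], leaf_capacity: int = DEFAULT_LEAF_CAPACITY
) -> SinglebitNode:
    """Recursively split ``entries`` on the most balanced bit.

    Recursion stops when at most ``leaf_capacity`` entries remain or no bit
    discriminates.  Entries typically come from one popcount bin, so the
    bin's popcount is available to the query as |B|.
    """
    entries = list(entries)
    if not entries:
        return SinglebitNode(entries=[])
    matrix = np.stack([fp.bits for _, fp in entries])
    return _build_singlebit(entries, matrix, leaf_capacity)


def _build_singlebit(
    entries: list[Entry], matrix: np.ndarray, leaf_capacity: int
) -> SinglebitNode:
    if len(entries) <= leaf_capacity:
        return SinglebitNode(entries=entries)
    bit = _choose_split_bit_matrix(matrix)
    if bit is None:
        return SinglebitNode(entries=entries)
    mask = matrix[:, bit]
    left_idx = np.flatnonzero(~mask)
    right_idx = np.flatnonzero(mask)
    return SinglebitNode(
        split_bit=bit,
        left=_build_singlebit([entries[i] for i in left_idx], matrix[left_idx], leaf_capacity),
        right=_build_singlebit([entries[i] for i in right_idx], matrix[right_idx], leaf_capacity),
    )


def build_multibit_tree(
    entries: Sequence[Entry], leaf_capacity: int = DEFAULT_LEAF_CAPACITY
) -> MultibitNode:
    """Like the singlebit tree, but every node records *all* bits constant
    across its entries (and not recorded higher up) as match bits, so one
    node visit can reveal many positions at once."""
    entries = list(entries)
    if not entries:
        return MultibitNode(match_bits=[], entries=[])
    matrix = np.stack([fp.bits for _, fp in entries])
    matched_above = np.zeros(matrix.shape[1], dtype=bool)
    return _build_multibit(entries, matrix, matched_above, leaf_capacity)


def _build_multibit(
    entries: list[Entry],
    matrix: np.ndarray,
    matched_above: np.ndarray,
    leaf_capacity: int,
) -> MultibitNode:
    n_rows = matrix.shape[0]
    set_counts = matrix.sum(axis=0)
    constant = (set_counts == 0) | (set_counts == n_rows)
    new_match = constant & ~matched_above
    match_bits = [(int(i), bool(set_counts[i])) for i in np.flatnonzero(new_match)]
    if len(entries) <= leaf_capacity:
        return MultibitNode(match_bits=match_bits, entries=entries)
    bit = _choose_split_bit_matrix(matrix)
    if bit is None:
        return MultibitNode(match_bits=match_bits, entries=entries)
    mask = matrix[:, bit]
    left_idx = np.flatnonzero(~mask)
    right_idx = np.flatnonzero(mask)
    matched = matched_above | constant
    return MultibitNode(
        match_bits=match_bits,
        left=_build_multibit([entries[i] for i in left_idx], matrix[left_idx], matched, leaf_capacity),
        right=_build_multibit([entries[i] for i in right_idx], matrix[right_idx], matched, leaf_capacity),
    )


def query_bit_tree(
    root: SinglebitNode | MultibitNode,
    a: Fingerprint,
    smin: float,
    bin_popcount: int,
) -> QueryResult:
    """Threshold query over one bin's singlebit or multibit tree.

    ``bin_popcount`` is |B|, shared by every entry in the bin.  The walk
    accumulates m_ij knowledge (one bit per singlebit node, all match bits
    per multibit node) and prunes any subtree whose bit-knowledge bound
    falls below S_MIN; with zero knowledge the root check is exactly
    COUNT-MAX(|A|, |B|).
    """
    if not 0.0 < smin <= 1.0:
        raise ValueError(f"S_MIN must be in (0, 1], got {smin}")
    hits: list[tuple[str, float]] = []
    stats = QueryStats()
    a_bits = a.bits
    a_int = a.bits.astype(np.int64)
    pa = a.popcount

    def visit(node, m01: int, m10: int) -> None:
        if isinstance(node, MultibitNode):
            for idx, val in node.match_bits:
                if a_bits[idx] and not val:
                    m10 += 1
                elif val and not a_bits[idx]:
                    m01 += 1
        stats.n_bound += 1
        if bitknowledge_bound_raw(pa, bin_popcount, m01, m10) < smin - PRUNE_EPS:
            return
        if node.is_leaf:
            for ident, fp in node.entries:
                _exact_eval(ident, fp, a_int, pa, smin, hits, stats)
            return
        if isinstance(node, SinglebitNode):
            qbit = bool(a_bits[node.split_bit])
            # left child: db bit clear; right child: db bit set
            visit(node.left, m01, m10 + (1 if qbit else 0))
            visit(node.right, m01 + (0 if qbit else 1), m10)
        else:
            visit(node.left, m01, m10)
            visit(node.right, m01, m10)

    if (isinstance(root, SinglebitNode) and root.entries == []) or (
        isinstance(root, MultibitNode) and root.entries == []
    ):
        return QueryResult(hits=hits, stats=stats)
    visit(root, 0, 0)
    return QueryResult(hits=hits, stats=stats)


# --------------------------------------------------------------------------
# kD-grid
# --------------------------------------------------------------------------


class KDGridTree:
    """k-dimensional grid over fragment popcounts, implemented as a k-level
    tree with empty branches pruned.

    Level i branches on |B_i|.  A query walks down, maintaining the level
    bound; a subtree is descended only while the bound stays ≥ S_MIN.  Leaf
    cells are scanned by their configured store:

    * ``list`` — per-entry GRID-MAX check, then the exact coefficient;
    * ``singlebit`` / ``multibit`` — bit-knowledge-bound descent.

    k=1 reproduces the popcount-bin method; k=n is the per-bit trie.
    """

    def __init__(
        self,
        db: FingerprintDB,
        k: int,
        bin_store: BinStore = "list",
        leaf_capacity: int = DEFAULT_LEAF_CAPACITY,
    ):
        if not 1 <= k <= db.n:
            raise ValueError(f"k={k} out of range 1..{db.n}")
        if bin_store not in ("list", "singlebit", "multibit"):
            raise ValueError(f"unknown bin store {bin_store!r}")
        self.n = db.n
        self.k = k
        self.bin_store: BinStore = bin_store
        self.boundaries = fragment_boundaries(db.n, k)
        # nested dicts keyed by fragment popcount; level k maps to leaf cells
        self.root: dict = {}
        n_entries = 0
        for ident, fp in _nonzero_entries(db.entries, "KDGridTree build"):
            pops = tuple(
                int(np.count_nonzero(fp.bits[lo:hi]))
                for lo, hi in zip(self.boundaries[:-1], self.boundaries[1:])
            )
            node = self.root
            for p in pops[:-1]:
                node = node.setdefault(p, {})
            cell = node.setdefault(pops[-1], [])
            cell.append((ident, fp))
            n_entries += 1
        if bin_store != "list":
            build = build_singlebit_tree if bin_store == "singlebit" else build_multibit_tree
            self._build_leaf_trees(self.root, 1, build, leaf_capacity)
        logger.info(
            "KDGridTree: %d entries, k=%d, store=%s", n_entries, k, bin_store
        )

    def _build_leaf_trees(self, node: dict, level: int, build, leaf_capacity: int) -> None:
        for key in node:
            if level == self.k:
                node[key] = (node[key], build(node[key], leaf_capacity))
            else:
                self._build_leaf_trees(node[key], level + 1, build, leaf_capacity)

    def query(self, a: Fingerprint, smin: float) -> QueryResult:
        _check_query(self.n, a, smin)
        fa = split(a, self.k)
        pa_frags = fa.fragment_popcounts
        # suffix[l] = sum of |A_i| for i > l (0-based level l counts known fragments)
        suffix = [0] * (self.k + 1)
        for i in range(self.k - 1, -1, -1):
            suffix[i] = suffix[i + 1] + pa_frags[i]
        hits: list[tuple[str, float]] = []
        stats = QueryStats()
        a_int = a.bits.astype(np.int64)
        pa = a.popcount
        threshold = smin - PRUNE_EPS

        def descend(node, level: int, min_acc: int, max_acc: int) -> None:
            # node is a dict {popcount of fragment `level` -> child}
            for pb in sorted(node):
                nmin = min_acc + min(pa_frags[level], pb)
                nmax = max_acc + max(pa_frags[level], pb)
                num = nmin + suffix[level + 1]
                den = nmax + suffix[level + 1]
                stats.n_bound += 1
                if den == 0 or num / den < threshold:
                    continue
                child = node[pb]
                if level + 1 == self.k:
                    self._scan_leaf(child, a, a_int, pa, fa, smin, hits, stats)
                else:
                    descend(child, level + 1, nmin, nmax)

        descend(self.root, 0, 0, 0)
        return QueryResult(hits=hits, stats=stats)

    def _scan_leaf(self, cell, a, a_int, pa, fa, smin, hits, stats) -> None:
        if self.bin_store == "list":
            for ident, fp in cell:
                frag_pops = tuple(
                    int(np.count_nonzero(fp.bits[lo:hi]))
                    for lo, hi in zip(self.boundaries[:-1], self.boundaries[1:])
                )
                stats.n_bound += 1
                if grid_max(fa, frag_pops) < smin - PRUNE_EPS:
                    continue
                _exact_eval(ident, fp, a_int, pa, smin, hits, stats)
        else:
            entries, tree = cell
            if not entries:
                return
            pb = entries[0][1].popcount
            sub = query_bit_tree(tree, a, smin, pb)
            hits.extend(sub.hits)
            stats.n_bound += sub.stats.n_bound
            stats.n_exact += sub.stats.n_exact
            stats.examined_ids.extend(sub.stats.examined_ids)


# --------------------------------------------------------------------------
# Functional wrappers (build_*/query_* naming)
# --------------------------------------------------------------------------


def build_bin_index(db: FingerprintDB) -> BinIndex:
    return BinIndex(db)


def query_bin_index(idx: BinIndex, a: Fingerprint, smin: float) -> QueryResult:
    return idx.query(a, smin)


def build_xor_index(db: FingerprintDB, k: int) -> XorFilterIndex:
    return XorFilterIndex(db, k)


def query_xor_index(idx: XorFilterIndex, a: Fingerprint, smin: float) -> QueryResult:
    return idx.query(a, smin)


def build_kdgrid(
    db: FingerprintDB,
    k: int,
    bin_store: BinStore = "list",
    leaf_capacity: int = DEFAULT_LEAF_CAPACITY,
) -> KDGridTree:
    return KDGridTree(db, k, bin_store=bin_store, leaf_capacity=leaf_capacity)


def query_kdgrid(tree: KDGridTree, a: Fingerprint, smin: float) -> QueryResult:
    return tree.query(a, smin)
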