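"""Index structures: every accelerated query must return exactly the
linear-scan result set, while provably doing no more exact work."""

import numpy as np
import pytest

from simscreen import (
    Fingerprint,
    FingerprintDB,
    SyntheticSpec,
    build_bin_index,
    build_kdgrid,
    build_multibit_tree,
    build_singlebit_tree,
    build_xor_index,
    choose_split_bit,
    gen_fingerprints,
    linear_scan,
    query_bit_tree,
    tanimoto,
)
from conftest import assert_same_results


def small_db(seed=0, N=200, n=64, density=0.2):
    return gen_fingerprints(SyntheticSpec(N=N, n=n, density=density, seed=seed))


class TestFingerprintDB:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            FingerprintDB(
                [("a", Fingerprint.from_binary_string("10")),
                 ("b", Fingerprint.from_binary_string("100"))]
            )

    def test_duplicate_identifier_rejected(self):
        fp = Fingerprint.from_binary_string("10")
        with pytest.raises(ValueError, match="duplicate"):
            FingerprintDB([("a", fp), ("a", fp)])


class TestLinearScan:
    def test_query_present_at_smin_one(self):
        db = small_db()
        qid, q = db[3]
        res = linear_scan(db, q, 1.0)
        assert (qid, 1.0) in res.hits

    def test_matches_brute_force_enumeration(self):
        """Hand enumeration over a random db of 50 six-bit fingerprints."""
        rng = np.random.default_rng(5)
        entries = [
            (f"m{i}", Fingerprint(rng.random(6) < 0.5)) for i in range(50)
        ]
        db = FingerprintDB(entries)
        qid, q = next((i, f) for i, f in entries if f.popcount > 0)
        expected = sorted(
            (ident, tanimoto(q, fp))
            for ident, fp in entries
            if fp.popcount > 0 and tanimoto(q, fp) >= 0.5
        )
        res = linear_scan(db, q, 0.5)
        assert res.sorted_hits() == expected

    def test_all_zero_entries_skipped_with_warning(self, caplog):
        import logging
        entries = [
            ("live", Fingerprint.from_binary_string("1010")),
            ("dead", Fingerprint.from_binary_string("0000")),
        ]
        db = FingerprintDB(entries)
        logger = logging.getLogger("simscreen.indexes")
        old = logger.level
        logger.setLevel(logging.WARNING)
        try:
            with caplog.at_level(logging.WARNING, logger="simscreen.indexes"):
                res = linear_scan(db, db[0][1], 0.1)
        finally:
            logger.setLevel(old)
        assert res.identifiers() == {"live"}
        assert any("all-zero" in r.message for r in caplog.records)

    def test_smin_domain_checked(self):
        db = small_db()
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                linear_scan(db, db[0][1], bad)


class TestBinIndex:
    def test_smin_one_touches_only_matching_popcount_bin(self):
        db = small_db()
        idx = build_bin_index(db)
        _, q = db[0]
        res = idx.query(q, 1.0)
        touched_pops = {
            fp.popcount for ident, fp in db if ident in res.stats.examined_ids
        }
        assert touched_pops <= {q.popcount}

    def test_exact_evaluations_bounded_by_db_size(self):
        db = small_db()
        idx = build_bin_index(db)
        res = idx.query(db[0][1], 0.5)
        assert res.stats.n_exact <= len(db)

    def test_oracle_equality_1000_random_128bit(self):
        db = gen_fingerprints(SyntheticSpec(N=1000, n=128, density=0.15, seed=42))
        idx = build_bin_index(db)
        for i in (0, 500):
            q = db[i][1]
            assert_same_results(idx.query(q, 0.6), linear_scan(db, q, 0.6))


class TestXorFilterIndex:
    def test_k_must_divide_n(self):
        db = small_db(n=65)
        with pytest.raises(ValueError, match="require k"):
            build_xor_index(db, 8)

    def test_oracle_equality_1000_random_128bit_k8(self):
        db = gen_fingerprints(SyntheticSpec(N=1000, n=128, density=0.15, seed=43))
        idx = build_xor_index(db, 8)
        for i in (0, 999):
            q = db[i][1]
            assert_same_results(idx.query(q, 0.6), linear_scan(db, q, 0.6))

    def test_never_more_exact_work_than_bin_index(self):
        db = small_db(seed=9, N=500, n=64)
        bins = build_bin_index(db)
        xor = build_xor_index(db, 8)
        for i in range(5):
            q = db[i][1]
            for smin in (0.5, 0.7, 0.9):
                assert (
                    xor.query(q, smin).stats.n_exact
                    <= bins.query(q, smin).stats.n_exact
                )


class TestChooseSplitBit:
    def test_perfect_split_lowest_index(self):
        fps = [Fingerprint.from_binary_string(s) for s in ("10", "01")]
        assert choose_split_bit(fps) == 0

    def test_tie_broken_by_lowest_index(self):
        # bit 0: 2 set / 1 clear; bit 1: 1 set / 2 clear — both |diff|=1
        fps = [Fingerprint.from_binary_string(s) for s in ("11", "10", "00")]
        assert choose_split_bit(fps) == 0

    def test_identical_entries_signal_no_split(self):
        fps = [Fingerprint.from_binary_string("101")] * 3
        assert choose_split_bit(fps) is None

    def test_forbidden_bits_excluded(self):
        fps = [Fingerprint.from_binary_string(s) for s in ("10", "01")]
        assert choose_split_bit(fps, forbidden={0}) == 1

    def test_matches_brute_force_balance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            matrix = rng.random((9, 8)) < 0.5
            fps = [Fingerprint(row) for row in matrix]
            best = choose_split_bit(fps)
            balances = {
                bit: abs(int(matrix[:, bit].sum()) * 2 - 9)
                for bit in range(8)
                if 0 < matrix[:, bit].sum() < 9
            }
            if not balances:
                assert best is None
            else:
                expected = min(balances, key=lambda b: (balances[b], b))
                assert best == expected


def _bin_entries(seed, N=300, n=64):
    """Entries sharing one popcount, as they would inside a bin."""
    rng = np.random.default_rng(seed)
    pop = 16
    entries = []
    for i in range(N):
        bits = np.zeros(n, dtype=bool)
        bits[rng.choice(n, size=pop, replace=False)] = True
        entries.append((f"e{i}", Fingerprint(bits)))
    return entries, pop


class TestBitTrees:
    def test_single_entry_becomes_leaf(self):
        fp = Fingerprint.from_binary_string("1010")
        for build in (build_singlebit_tree, build_multibit_tree):
            root = build([("x", fp)])
            assert root.is_leaf and root.entries == [("x", fp)]

    def test_two_entries_split_on_their_differing_bit(self):
        a = Fingerprint.from_binary_string("1010")
        b = Fingerprint.from_binary_string("1000")
        root = build_singlebit_tree([("a", a), ("b", b)], leaf_capacity=1)
        assert root.split_bit == 2
        assert root.left.entries == [("b", b)]
        assert root.right.entries == [("a", a)]

    def test_multibit_match_bit_invariant_audit(self):
        """Every leaf entry must agree with all match bits on its
        root-to-leaf path, and no bit may be matched twice on a path."""
        rng = np.random.default_rng(21)
        entries = [
            (f"e{i}", Fingerprint(rng.random(64) < 0.3)) for i in range(200)
        ]
        root = build_multibit_tree(entries, leaf_capacity=4)

        def audit(node, path_bits):
            for idx, val in node.match_bits:
                assert idx not in path_bits, "bit matched twice on one path"
            constraints = dict(path_bits)
            constraints.update(dict(node.match_bits))
            if node.is_leaf:
                for _, fp in node.entries:
                    for idx, val in constraints.items():
                        assert bool(fp.bits[idx]) == val
            else:
                audit(node.left, constraints)
                audit(node.right, constraints)

        audit(root, {})

    def test_singlebit_children_respect_split_bit(self):
        entries, _ = _bin_entries(3, N=100)
        root = build_singlebit_tree(entries, leaf_capacity=4)

        def audit(node):
            if node.is_leaf:
                return
            for child, val in ((node.left, False), (node.right, True)):
                def leaves(nd):
                    if nd.is_leaf:
                        yield from nd.entries
                    else:
                        yield from leaves(nd.left)
                        yield from leaves(nd.right)
                for _, fp in leaves(child):
                    assert bool(fp.bits[node.split_bit]) == val
                audit(child)

        audit(root)

    def test_build_deterministic(self):
        entries, _ = _bin_entries(4, N=80)
        t1 = build_multibit_tree(entries)
        t2 = build_multibit_tree(entries)

        def shape(node):
            if node.is_leaf:
                return ("leaf", tuple(i for i, _ in node.entries), tuple(node.match_bits))
            return (tuple(node.match_bits), shape(node.left), shape(node.right))

        assert shape(t1) == shape(t2)

    def test_root_pruned_when_count_max_insufficient(self):
        entries, pop = _bin_entries(5, N=50)
        root = build_singlebit_tree(entries)
        q = Fingerprint(np.concatenate([np.ones(8, dtype=bool), np.zeros(56, dtype=bool)]))
        # count_max(8, 16) = 0.5; anything above that prunes at the root
        res = query_bit_tree(root, q, 0.6, pop)
        assert res.hits == [] and res.stats.n_exact == 0 and res.stats.n_bound == 1

    @pytest.mark.parametrize("build", [build_singlebit_tree, build_multibit_tree])
    def test_oracle_equality_one_bin(self, build):
        entries, pop = _bin_entries(6, N=1000)
        db = FingerprintDB(entries)
        root = build(entries)
        for i in (0, 1, 2):
            q = entries[i][1]
            assert_same_results(
                query_bit_tree(root, q, 0.6, pop), linear_scan(db, q, 0.6)
            )

    @pytest.mark.parametrize("build", [build_singlebit_tree, build_multibit_tree])
    def test_pruning_never_loses_a_hit_randomized(self, build):
        """Many small randomized trials: tree pruning must keep every
        qualifying entry."""
        rng = np.random.default_rng(31)
        for trial in range(300):
            n = int(rng.integers(8, 24))
            pop = int(rng.integers(1, n))
            entries = []
            for i in range(int(rng.integers(2, 30))):
                bits = np.zeros(n, dtype=bool)
                bits[rng.choice(n, size=pop, replace=False)] = True
                entries.append((f"e{i}", Fingerprint(bits)))
            db = FingerprintDB(entries)
            root = build(entries, leaf_capacity=2)
            q = Fingerprint(rng.random(n) < 0.5)
            if q.popcount == 0:
                continue
            smin = float(rng.choice([0.3, 0.5, 0.7, 0.9]))
            assert_same_results(
                query_bit_tree(root, q, smin, pop), linear_scan(db, q, smin)
            )


class TestKDGrid:
    def test_k1_list_matches_bin_index_exactly(self):
        db = small_db(seed=8, N=400)
        bins = build_bin_index(db)
        grid = build_kdgrid(db, 1)
        for i in (0, 7):
            q = db[i][1]
            for smin in (0.5, 0.8):
                rb = bins.query(q, smin)
                rg = grid.query(q, smin)
                assert_same_results(rb, rg)
                assert set(rb.stats.examined_ids) == set(rg.stats.examined_ids)

    def test_k_out_of_range(self):
        db = small_db()
        with pytest.raises(ValueError):
            build_kdgrid(db, 0)
        with pytest.raises(ValueError):
            build_kdgrid(db, db.n + 1)

    def test_kn_trie_behavior_oracle(self):
        """k = n: one level per bit, the grid degenerates to a trie."""
        db = small_db(seed=12, N=100, n=16, density=0.4)
        grid = build_kdgrid(db, 16)
        q = db[0][1]
        assert_same_results(grid.query(q, 0.5), linear_scan(db, q, 0.5))

    @pytest.mark.parametrize("store", ["list", "singlebit", "multibit"])
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_oracle_equality_all_k_and_stores(self, k, store):
        db = gen_fingerprints(SyntheticSpec(N=500, n=128, density=0.15, seed=k))
        grid = build_kdgrid(db, k, bin_store=store)
        for i, smin in ((0, 0.5), (1, 0.7), (2, 0.9)):
            q = db[i][1]
            assert_same_results(grid.query(q, smin), linear_scan(db, q, smin))

    def test_exact_work_ordering_grid_vs_bins(self):
        db = gen_fingerprints(SyntheticSpec(N=1000, n=128, density=0.15, seed=77))
        bins = build_bin_index(db)
        grids = {k: build_kdgrid(db, k) for k in (1, 2, 3)}
        for i in range(3):
            q = db[i][1]
            nb = bins.query(q, 0.7).stats.n_exact
            assert nb <= len(db)
            for k, grid in grids.items():
                assert grid.query(q, 0.7).stats.n_exact <= nb
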