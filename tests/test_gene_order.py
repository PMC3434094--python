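import itertools
import random
from collections import deque

import pytest

from mitoevo.gene_order import (
    GENE_ALPHABET, RearrangementOp, apply_operation, build_strong_interval_tree,
    canonicalize, common_intervals, crex_scenario, crex_scenario_records,
    decode, encode, group_identical, tdrl_lower_bound,
)
from mitoevo.io_formats import GeneOrderRecord


# ---------------------------------------------------------------------------
# Independent oracles

def brute_common_intervals(p, q):
    """Exhaustive: every subset of magnitudes contiguous in both orders."""
    def positions(perm):
        return {abs(x): i for i, x in enumerate(perm)}
    pp, qq = positions(p), positions(q)
    out = set()
    n = len(p)
    for i in range(n):
        for j in range(i, n):
            s = frozenset(abs(x) for x in p[i:j + 1])
            qpos = sorted(qq[g] for g in s)
            if qpos[-1] - qpos[0] == len(s) - 1:
                out.add(s)
    return out


def bfs_min_tdrls(perm):
    """Shortest whole-region TDRL sorting by breadth-first search."""
    n = len(perm)
    ident = tuple(range(1, n + 1))
    if perm == ident:
        return 0
    keeps = [frozenset(c) for r in range(1, n)
             for c in itertools.combinations(range(1, n + 1), r)]
    seen = {perm}
    queue = deque([(perm, 0)])
    while queue:
        cur, d = queue.popleft()
        for k1 in keeps:
            nxt = tuple(x for x in cur if x in k1) + \
                tuple(x for x in cur if x not in k1)
            if nxt == ident:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise AssertionError("unsortable permutation")


def random_signed(rnd, n):
    vals = list(range(1, n + 1))
    rnd.shuffle(vals)
    return tuple(rnd.choice([-1, 1]) * v for v in vals)


# ---------------------------------------------------------------------------

class TestCanonicalize:
    def test_rotation(self):
        rec = GeneOrderRecord("x", ("cox1", "-nad1", "rns"))
        assert canonicalize(rec).genes == ("rns", "cox1", "-nad1")

    def test_reflection_then_rotation(self):
        rec = GeneOrderRecord("x", ("-rns", "cox1", "nad1"))
        assert canonicalize(rec).genes == ("rns", "-nad1", "-cox1")

    def test_idempotent(self):
        rec = GeneOrderRecord("x", ("-rns", "cox1", "nad1"))
        once = canonicalize(rec)
        assert canonicalize(once).genes == once.genes

    def test_anchor_absent(self):
        with pytest.raises(ValueError, match="anchor"):
            canonicalize(GeneOrderRecord("x", ("cox1", "nad1")))

    def test_reflection_preserves_circular_identity(self):
        # the same circular molecule read from the other strand
        rec = GeneOrderRecord("x", ("rns", "cox1", "-nad1", "atp9"))
        flipped = GeneOrderRecord(
            "x", tuple(("-" + g if not g.startswith("-") else g[1:])
                       for g in reversed(rec.genes)))
        rotated = GeneOrderRecord(
            "x", flipped.genes[2:] + flipped.genes[:2])
        assert canonicalize(rotated).genes == canonicalize(rec).genes


class TestApplyOperation:
    def test_transposition(self):
        op = RearrangementOp("transposition", 0, 4, mid=2)
        assert apply_operation((1, 2, 3, 4), op) == (3, 4, 1, 2)

    def test_inversion(self):
        op = RearrangementOp("inversion", 1, 3)
        assert apply_operation((1, 2, 3, 4), op) == (1, -3, -2, 4)

    def test_tdrl_duplicate_then_lose(self):
        op = RearrangementOp("tdrl", 0, 4,
                             keep_first=frozenset({1, 2}),
                             keep_second=frozenset({3, 4}))
        assert apply_operation((3, 1, 4, 2), op) == (1, 2, 3, 4)

    def test_tdrl_keep_sets_must_partition(self):
        op = RearrangementOp("tdrl", 0, 4, keep_first=frozenset({1}),
                             keep_second=frozenset({3, 4}))
        with pytest.raises(ValueError, match="partition"):
            apply_operation((3, 1, 4, 2), op)

    def test_inverse_transposition(self):
        op = RearrangementOp("inverse_transposition", 0, 4, mid=2,
                             invert_first=True)
        assert apply_operation((1, 2, 3, 4), op) == (3, 4, -2, -1)


class TestCommonIntervals:
    def test_identity_n4_has_all_ten(self):
        p = (1, 2, 3, 4)
        assert len(common_intervals(p, p)) == 10

    def test_block_swap_example(self):
        got = common_intervals((1, 2, 3, 4), (3, 4, 1, 2))
        assert got == {frozenset(s) for s in
                       [{1}, {2}, {3}, {4}, {1, 2}, {3, 4}, {1, 2, 3, 4}]}

    def test_small_example(self):
        got = common_intervals((1, 2, 3), (2, 1, 3))
        assert got == {frozenset(s) for s in
                       [{1}, {2}, {3}, {1, 2}, {1, 2, 3}]}

    def test_symmetric(self):
        rnd = random.Random(1)
        for _ in range(25):
            n = rnd.randint(2, 8)
            p, q = random_signed(rnd, n), random_signed(rnd, n)
            assert common_intervals(p, q) == common_intervals(q, p)

    def test_matches_bruteforce_oracle(self):
        rnd = random.Random(2)
        for n in range(2, 7):
            for _ in range(20):
                p, q = random_signed(rnd, n), random_signed(rnd, n)
                assert common_intervals(p, q) == brute_common_intervals(p, q)

    def test_alphabet_mismatch(self):
        with pytest.raises(ValueError):
            common_intervals((1, 2), (1, 3))


class TestStrongIntervalTree:
    def test_identity_root_increasing(self):
        p = (1, 2, 3, 4)
        root = build_strong_interval_tree(p, p)
        assert root.node_class == "linear_increasing"
        assert all(c.is_leaf for c in root.children)

    def test_block_swap_decreasing_root(self):
        root = build_strong_interval_tree((1, 2, 3, 4), (3, 4, 1, 2))
        assert root.node_class == "linear_decreasing"
        assert [c.node_class for c in root.children] == \
            ["linear_increasing", "linear_increasing"]

    def test_simple_prime_root(self):
        root = build_strong_interval_tree((1, 2, 3, 4), (2, 4, 1, 3))
        assert root.node_class == "prime"
        assert all(c.is_leaf for c in root.children)

    def test_laminar_and_singleton_leaves(self):
        rnd = random.Random(3)
        for _ in range(25):
            n = rnd.randint(2, 9)
            p, q = random_signed(rnd, n), random_signed(rnd, n)
            root = build_strong_interval_tree(p, q)
            nodes = list(root.iter_nodes())
            leaves = [nd for nd in nodes if nd.is_leaf]
            assert sorted(min(nd.genes) for nd in leaves) == list(range(1, n + 1))
            for a in nodes:
                for b in nodes:
                    inter = a.genes & b.genes
                    assert not inter or a.genes <= b.genes or b.genes <= a.genes


class TestTdrlBound:
    @pytest.mark.parametrize("perm,expect", [
        ((1, 2, 3), 0),
        ((2, 1), 1),
        ((4, 3, 2, 1), 2),
        ((3, 1, 4, 2), 1),
    ])
    def test_examples(self, perm, expect):
        assert tdrl_lower_bound(perm) == expect

    def test_signed_input_rejected(self):
        with pytest.raises(ValueError):
            tdrl_lower_bound((1, -2))

    def test_matches_bfs_oracle_exhaustive(self):
        for n in range(1, 6):
            for perm in itertools.permutations(range(1, n + 1)):
                assert tdrl_lower_bound(perm) == bfs_min_tdrls(perm)

    def test_matches_bfs_oracle_n6_sample(self):
        rnd = random.Random(4)
        perms = list(itertools.permutations(range(1, 7)))
        for perm in rnd.sample(perms, 60):
            assert tdrl_lower_bound(perm) == bfs_min_tdrls(perm)


class TestCrexScenario:
    def test_equal_orders_empty_scenario(self):
        p = (1, -2, 3)
        assert len(crex_scenario(p, p)) == 0

    def test_single_transposition_recovered_exhaustively(self):
        n = 8
        ident = tuple(range(1, n + 1))
        for s in range(n):
            for m in range(s + 1, n):
                for e in range(m + 1, n + 1):
                    q = apply_operation(
                        ident, RearrangementOp("transposition", s, e, mid=m))
                    scn = crex_scenario(ident, q)
                    assert len(scn) == 1
                    assert scn.ops[0].kind == "transposition"

    def test_single_inversion_recovered_exhaustively(self):
        n = 8
        ident = tuple(range(1, n + 1))
        for s in range(n):
            for e in range(s + 1, n + 1):
                q = apply_operation(ident, RearrangementOp("inversion", s, e))
                scn = crex_scenario(ident, q)
                assert len(scn) == 1 and scn.ops[0].kind == "inversion"

    def test_single_op_recovery_from_random_source(self):
        rnd = random.Random(5)
        for _ in range(60):
            p = random_signed(rnd, 8)
            s = rnd.randrange(0, 7)
            e = rnd.randrange(s + 2, 9)
            m = rnd.randrange(s + 1, e)
            q = apply_operation(p, RearrangementOp("transposition", s, e, mid=m))
            if p == q:
                continue
            scn = crex_scenario(p, q)
            assert len(scn) == 1 and scn.ops[0].kind == "transposition"

    def test_inverse_transposition_and_tdrl_within_two_ops(self):
        rnd = random.Random(6)
        ident = tuple(range(1, 9))
        for _ in range(60):
            s = rnd.randrange(0, 7)
            e = rnd.randrange(s + 2, 9)
            m = rnd.randrange(s + 1, e)
            q = apply_operation(ident, RearrangementOp(
                "inverse_transposition", s, e, mid=m,
                invert_first=bool(rnd.getrandbits(1))))
            assert len(crex_scenario(ident, q)) <= 2
        for _ in range(60):
            s = rnd.randrange(0, 7)
            e = rnd.randrange(s + 2, 9)
            mags = list(range(s + 1, e + 1))
            rnd.shuffle(mags)
            cut = rnd.randrange(1, len(mags))
            q = apply_operation(ident, RearrangementOp(
                "tdrl", s, e, keep_first=frozenset(mags[:cut]),
                keep_second=frozenset(mags[cut:])))
            assert len(crex_scenario(ident, q)) <= 2

    def test_replay_validity_random_pairs(self):
        rnd = random.Random(7)
        for _ in range(300):
            n = rnd.randint(2, 17)
            p, q = random_signed(rnd, n), random_signed(rnd, n)
            scn = crex_scenario(p, q)
            assert scn.replay() == q

    def test_unequal_content_rejected(self):
        with pytest.raises(ValueError, match="unequal gene content"):
            crex_scenario((1, 2, 3), (1, 2, 4))

    def test_record_level_scenario(self):
        a = decode(tuple(range(1, 18)), GENE_ALPHABET, "a")
        perm = list(range(1, 18))
        perm[2:5], perm[5:8] = perm[5:8], perm[2:5]
        b = decode(tuple(perm), GENE_ALPHABET, "b")
        scn = crex_scenario_records(a, b)
        assert scn.replay() == scn.target


class TestGroupIdentical:
    def test_all_distinct(self):
        recs = [GeneOrderRecord("a", ("rns", "cox1", "nad1")),
                GeneOrderRecord("b", ("rns", "nad1", "cox1"))]
        assert group_identical(recs) == [["a"], ["b"]]

    def test_rotations_and_reflections_group_together(self):
        # same circular molecule presented three ways
        recs = [GeneOrderRecord("a", ("rns", "cox1", "-nad1")),
                GeneOrderRecord("b", ("cox1", "-nad1", "rns")),
                GeneOrderRecord("c", ("nad1", "-cox1", "-rns"))]
        assert group_identical(recs) == [["a", "b", "c"]]

    def test_stable_numbering_by_first_appearance(self):
        recs = [GeneOrderRecord("x", ("rns", "cox1", "nad1")),
                GeneOrderRecord("y", ("rns", "nad1", "cox1")),
                GeneOrderRecord("z", ("rns", "cox1", "nad1"))]
        assert group_identical(recs) == [["x", "z"], ["y"]]
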