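"""Signed reversal distance: breakpoint-graph computation against the BFS
oracle, order extraction from annotations, and metric properties."""

import numpy as np
import pytest

from plastrep.gene_order import (
    GeneOrder,
    extract_shared_order,
    reversal_distance,
    reversal_distance_perm,
)
from plastrep.genome import AnnotatedGenome, GeneFeature


def _order(*signed_names):
    return GeneOrder(tuple((n.lstrip("-"), -1 if n.startswith("-") else 1)
                           for n in signed_names))


class TestDistanceBasics:
    def test_identity_is_zero(self):
        a = _order("a", "b", "c")
        res = reversal_distance(a, a)
        assert res.distance == 0 and res.breakpoints == 0

    def test_single_block_reversal(self):
        a = _order("-c", "-b", "-a")
        b = _order("a", "b", "c")
        assert reversal_distance(a, b).distance == 1

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        names = [f"g{i}" for i in range(8)]
        for _ in range(10):
            pa = [(n, int(s)) for n, s in zip(rng.permutation(names), rng.choice([-1, 1], 8))]
            pb = [(n, int(s)) for n, s in zip(rng.permutation(names), rng.choice([-1, 1], 8))]
            a, b = GeneOrder(tuple(pa)), GeneOrder(tuple(pb))
            assert reversal_distance(a, b).distance == reversal_distance(b, a).distance

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        names = [f"g{i}" for i in range(6)]
        for _ in range(15):
            orders = []
            for _ in range(3):
                perm = [(n, int(s)) for n, s in zip(rng.permutation(names), rng.choice([-1, 1], 6))]
                orders.append(GeneOrder(tuple(perm)))
            dab = reversal_distance(orders[0], orders[1]).distance
            dbc = reversal_distance(orders[1], orders[2]).distance
            dac = reversal_distance(orders[0], orders[2]).distance
            assert dac <= dab + dbc

    def test_breakpoint_lower_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            vals = rng.permutation(np.arange(1, n + 1))
            signs = rng.choice([-1, 1], n)
            res = reversal_distance_perm([int(v * s) for v, s in zip(vals, signs)])
            assert res.distance >= res.breakpoints / 2 - 1
            assert (res.distance == 0) == (res.breakpoints == 0)

    def test_mismatched_symbol_sets_rejected(self):
        with pytest.raises(ValueError):
            reversal_distance(_order("a", "b"), _order("a", "c"))

    def test_unsigned_input_rejected(self):
        with pytest.raises(ValueError):
            GeneOrder((("a", 0), ("b", 1)))

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError):
            GeneOrder((("a", 1), ("a", -1)))


class TestAgainstBFS:
    def test_exhaustive_small_n(self, bfs_tables):
        """Breakpoint-graph distance equals breadth-first search over the
        reversal graph for every signed permutation with n <= 6."""
        for n, table in bfs_tables.items():
            for perm, d in table.items():
                assert reversal_distance_perm(list(perm)).distance == d, perm

    def test_sampled_n7(self, bfs_table_n7):
        table = bfs_table_n7
        rng = np.random.default_rng(3)
        keys = list(table)
        for i in rng.choice(len(keys), size=1000, replace=False):
            perm = keys[int(i)]
            assert reversal_distance_perm(list(perm)).distance == table[perm], perm


class TestHurdlesAndFortress:
    def test_hurdle_permutation(self):
        # all-positive (2,1)-type order needs 3 reversals: one unoriented hurdle
        res = reversal_distance_perm([2, 1])
        assert (res.distance, res.hurdles, res.fortress) == (3, 1, False)

    def test_fortress_flag_and_distance(self):
        """Three protected unoriented components: an odd number of hurdles,
        all superhurdles, costs one extra reversal (the fortress)."""
        gadget = [1, 3, 5, 4, 6, 2, 7]
        perm = []
        for k in range(3):
            perm += [x + 7 * k for x in gadget]
        res = reversal_distance_perm(perm)
        assert res.fortress
        assert res.hurdles == 3
        assert res.distance == len(perm) + 1 - res.cycles + res.hurdles + 1

    def test_fortress_distance_is_achievable_stepwise(self):
        """Greedy descent from the fortress permutation reaches the identity
        with every reversal lowering the computed distance by exactly 1 —
        the formula is consistent along an entire optimal sorting path."""
        gadget = [1, 3, 5, 4, 6, 2, 7]
        perm = tuple(x + 7 * k for k in range(3) for x in gadget)
        d = reversal_distance_perm(list(perm)).distance
        cur = perm
        while d > 0:
            best = None
            n = len(cur)
            for i in range(n):
                for j in range(i + 1, n + 1):
                    nb = cur[:i] + tuple(-x for x in reversed(cur[i:j])) + cur[j:]
                    nd = reversal_distance_perm(list(nb)).distance
                    assert nd >= d - 1, "distance dropped by more than 1 in one reversal"
                    if nd == d - 1 and best is None:
                        best = nb
            assert best is not None, f"no distance-reducing reversal at d={d}"
            cur, d = best, d - 1
        assert cur == tuple(range(1, len(perm) + 1))


class TestExtractSharedOrder:
    def _genome(self, entries, circular=True, gid="g"):
        feats = []
        pos = 10
        for name, strand in entries:
            feats.append(GeneFeature(name, "CDS", pos, pos + 50, strand))
            pos += 100
        return AnnotatedGenome(id=gid, sequence="A" * (pos + 50), circular=circular,
                               features=feats)

    def test_identical_genomes_identical_orders(self):
        g = self._genome([("a", "+"), ("b", "+"), ("c", "-")])
        oa, ob = extract_shared_order(g, g)
        assert oa == ob
        assert reversal_distance(oa, ob).distance == 0

    def test_single_strand_flip(self):
        ga = self._genome([("a", "+"), ("b", "+"), ("c", "+")])
        gb = self._genome([("a", "+"), ("b", "-"), ("c", "+")])
        oa, ob = extract_shared_order(ga, gb)
        signs_a = dict(oa.genes)
        signs_b = dict(ob.genes)
        flipped = [n for n in signs_a if signs_a[n] != signs_b[n]]
        assert flipped == ["b"]
        assert reversal_distance(oa, ob).distance == 1

    def test_shared_set_is_intersection_and_duplicates_drop(self):
        ga = self._genome([("a", "+"), ("b", "+"), ("dup", "+"), ("dup", "+"), ("c", "+")])
        gb = self._genome([("c", "+"), ("dup", "+"), ("a", "+"), ("x", "+"), ("b", "+")])
        oa, ob = extract_shared_order(ga, gb)
        assert oa.symbols == ob.symbols == frozenset({"a", "b", "c"})

    def test_too_few_shared_genes_rejected(self):
        ga = self._genome([("a", "+"), ("b", "+")])
        gb = self._genome([("x", "+"), ("y", "+")])
        with pytest.raises(ValueError, match="shared"):
            extract_shared_order(ga, gb)

    def test_circular_linearization_anchor_invariance(self):
        """Rotating a circular genome must not change the extracted order."""
        entries = [("d", "+"), ("a", "-"), ("c", "+"), ("b", "+")]
        ga = self._genome(entries)
        gb_rot = ga.rotated(230)
        oa, _ = extract_shared_order(ga, ga)
        ob, _ = extract_shared_order(gb_rot, gb_rot)
        assert oa == ob
        o1, o2 = extract_shared_order(ga, gb_rot)
        assert reversal_distance(o1, o2).distance == 0
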