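import math

import numpy as np
import pytest

from allelescan.phylo import (
    DISABLED,
    DistanceMatrix,
    DistanceError,
    FUNCTIONAL,
    TreeNode,
    min_independent_losses,
    nj_tree,
    p_distance,
    tn93_distance,
)


# ------------------------------------------------------- TN93 oracle

def tn93_oracle(a, b):
    """Independent evaluation from raw pair counts (textbook parametrization)."""
    used = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    L = len(used)
    n = {base: 0 for base in "ACGT"}
    P1 = P2 = Q = 0
    for x, y in used:
        n[x] += 1
        n[y] += 1
        if x != y:
            if {x, y} == {"A", "G"}:
                P1 += 1
            elif {x, y} == {"C", "T"}:
                P2 += 1
            else:
                Q += 1
    gA, gC, gG, gT = (n[b2] / (2 * L) for b2 in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = P1 / L, P2 / L, Q / L
    a1 = 1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR)
    a2 = 1 - gY * P2 / (2 * gC * gT) - Q / (2 * gY)
    b_ = 1 - Q / (2 * gR * gY)
    if a1 <= 0 or a2 <= 0 or b_ <= 0:
        return math.inf
    return (
        -(2 * gA * gG / gR) * math.log(a1)
        - (2 * gC * gT / gY) * math.log(a2)
        - 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(b_)
    )


def random_pair(rng, L=400, sub=0.1):
    a = rng.choice(list("ACGT"), size=L)
    b = a.copy()
    mut = rng.random(L) < sub
    b[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
    return "".join(a), "".join(b)


class TestTN93:
    def test_identical_sequences_have_zero_distance(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_transversions_only_reduces_to_k2p_term(self):
        # Equal base frequencies, no transitions: d = -ln(1-Q)/2 - ln(1-2Q)/4
        a = "ACGT" * 50
        b = "CAGT" * 10 + "ACGT" * 40  # A<->C swaps only: pure transversions
        used = sum(1 for x, y in zip(a, b) if x != y)
        Q = used / len(a)
        expected = -0.5 * math.log(1 - Q) - 0.25 * math.log(1 - 2 * Q)
        assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_formula_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_pair(rng)
        assert tn93_distance(a, b) == pytest.approx(tn93_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_correction_inflates_over_p_distance(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_pair(rng, sub=0.15)
        assert tn93_distance(a, b) >= p_distance(a, b) - 1e-12

    def test_gapped_sites_excluded_pairwise(self):
        assert tn93_distance("ACGT-ACGT", "ACGTTACGT") == 0.0

    def test_saturation_returns_infinity(self):
        # Every site a transversion: the log argument goes non-positive.
        assert tn93_distance("AAAAAAAA", "CCCCCCCC") == math.inf

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(DistanceError):
            tn93_distance("----", "AC--")


def additive_matrix_4taxa():
    # Tree: ((A:2,B:3):1,(C:4,D:5)); pairwise path lengths are additive.
    ids = ("A", "B", "C", "D")
    d = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
         ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
    m = np.zeros((4, 4))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i < j:
                m[i, j] = m[j, i] = d[(x, y)]
    return DistanceMatrix(ids=ids, matrix=m)


def splits(tree):
    """Non-trivial leaf bipartitions implied by internal edges."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()

    def walk(node):
        for child, _ in node.children:
            names = frozenset(child.leaf_names())
            if 1 < len(names) < len(all_leaves) - 1:
                out.add(names)
            walk(child)
    walk(tree)
    return {frozenset((s, all_leaves - s)) for s in out}


def tree_distances(tree):
    """Leaf-to-leaf path lengths (LCA over root-to-leaf edge paths)."""
    leaves = {}

    def collect(node, acc):
        if node.is_leaf:
            leaves[node.name] = acc
        for child, bl in node.children:
            collect(child, acc + [(id(child), bl)])
    collect(tree, [])
    dists = {}
    for x in leaves:
        for y in leaves:
            if x < y:
                px = leaves[x]
                py = leaves[y]
                shared = 0
                for (nx, _), (ny, _) in zip(px, py):
                    if nx == ny:
                        shared += 1
                    else:
                        break
                dists[(x, y)] = sum(bl for _, bl in px[shared:]) + \
                    sum(bl for _, bl in py[shared:])
    return dists


class TestNeighborJoining:
    def test_recovers_additive_4taxon_tree_exactly(self):
        tree = nj_tree(additive_matrix_4taxa())
        assert splits(tree) == {frozenset((frozenset("AB"), frozenset("CD")))}
        d = tree_distances(tree)
        dm = additive_matrix_4taxa()
        for (x, y), want in (((("A", "B")), 5), (("A", "C"), 7), (("A", "D"), 8),
                             (("B", "C"), 8), (("B", "D"), 9), (("C", "D"), 9)):
            assert d[(x, y)] == pytest.approx(want)

    def test_three_taxa_closed_form(self):
        m = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(DistanceMatrix(ids=("a", "b", "c"), matrix=m))
        bl = {child.name: l for child, l in tree.children}
        assert bl["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert bl["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert bl["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_tie_breaks_join_lowest_index_pair(self):
        # Fully symmetric matrix: every Q value ties; (0, 1) must join first.
        m = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(ids=("a", "b", "c", "d"), matrix=m))
        pairs = [frozenset(child.leaf_names()) for child, _ in tree.children
                 if not child.is_leaf]
        assert frozenset(("a", "b")) in pairs

    def test_fewer_than_three_taxa_rejected(self):
        m = np.zeros((2, 2))
        with pytest.raises(DistanceError):
            nj_tree(DistanceMatrix(ids=("a", "b"), matrix=m))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        # random binary tree via sequential joining, then its path metric
        nodes = [TreeNode(name=f"t{i}") for i in range(n)]
        lengths = {id(nd): 0.0 for nd in nodes}
        roots = nodes[:]
        while len(roots) > 1:
            i, j = sorted(rng.choice(len(roots), size=2, replace=False))
            a, b = roots[i], roots[j]
            parent = TreeNode(children=[
                (a, float(rng.uniform(0.5, 3))), (b, float(rng.uniform(0.5, 3)))])
            roots = [r for r in roots if r not in (a, b)] + [parent]
        true_tree = roots[0]
        d = tree_distances(true_tree)
        ids = tuple(sorted({x for pair in d for x in pair}))
        m = np.zeros((n, n))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    key = (x, y) if (x, y) in d else (y, x)
                    m[i, j] = m[j, i] = d[key]
        rec = nj_tree(DistanceMatrix(ids=ids, matrix=m))
        assert splits(rec) == splits(true_tree)

    def test_newick_output_parses_with_dendropy(self):
        import dendropy
        tree = nj_tree(additive_matrix_4taxa())
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("ABCD")


class TestIndependentLosses:
    def leaf(self, name):
        return TreeNode(name=name)

    def cherry(self, a, b):
        return TreeNode(children=[(self.leaf(a), 1.0), (self.leaf(b), 1.0)])

    def test_all_functional_means_zero_losses(self):
        tree = TreeNode(children=[(self.cherry("a", "b"), 1.0), (self.leaf("c"), 1.0)])
        calls = {"a": FUNCTIONAL, "b": FUNCTIONAL, "c": FUNCTIONAL}
        assert min_independent_losses(tree, calls) == 0

    def test_interleaved_losses_count_twice(self):
        tree = TreeNode(children=[(self.cherry("a", "b"), 1.0),
                                  (self.cherry("c", "d"), 1.0)])
        calls = {"a": FUNCTIONAL, "b": DISABLED, "c": FUNCTIONAL, "d": DISABLED}
        assert min_independent_losses(tree, calls) == 2

    def test_single_disabled_clade_counts_once(self):
        clade = TreeNode(children=[(self.cherry("c", "d"), 1.0), (self.leaf("e"), 1.0)])
        tree = TreeNode(children=[(self.cherry("a", "b"), 1.0), (clade, 1.0)])
        calls = {"a": FUNCTIONAL, "b": FUNCTIONAL,
                 "c": DISABLED, "d": DISABLED, "e": DISABLED}
        assert min_independent_losses(tree, calls) == 1

    def test_bounds_hold_on_random_labelings(self):
        rng = np.random.default_rng(42)
        tree = nj_tree(additive_matrix_4taxa())
        for _ in range(10):
            labels = rng.choice([FUNCTIONAL, DISABLED], size=4)
            calls = dict(zip("ABCD", labels))
            losses = min_independent_losses(tree, calls)
            n_dis = list(labels).count(DISABLED)
            assert losses <= n_dis
            assert (losses >= 1) == (n_dis >= 1)

    def test_missing_leaf_status_is_error(self):
        tree = TreeNode(children=[(self.cherry("a", "b"), 1.0), (self.leaf("c"), 1.0)])
        with pytest.raises(KeyError):
            min_independent_losses(tree, {"a": FUNCTIONAL, "b": FUNCTIONAL})


def test_distance_matrix_cross_checked_against_skbio_nj():
    import skbio

    rng = np.random.default_rng(7)
    seqs = {}
    base = rng.choice(list("ACGT"), size=300)
    for i in range(6):
        row = base.copy()
        mut = rng.random(300) < 0.05 * (i + 1) / 6
        row[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
        seqs[f"s{i}"] = "".join(row)
    dm = DistanceMatrix.from_records(seqs)
    ours = nj_tree(dm)
    sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=list(dm.ids)))
    sk_splits = set()
    for node in sk.non_tips():
        names = frozenset(t.name for t in node.tips())
        if 1 < len(names) < 5:
            sk_splits.add(frozenset((names, frozenset(dm.ids) - names)))
    assert splits(ours) == sk_splits
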