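"""Distance phylogenetics and gene-conversion classification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from poolscan import paralogconv as pc
from poolscan import synthio
from poolscan._seq import encode


def make_aln(seqs, labels=None, pops=None, annotations=None):
    ids = [f"s{i}" for i in range(len(seqs))]
    labels = labels or ["x"] * len(seqs)
    pops = pops or [""] * len(seqs)
    return pc.SeqAlignment(ids, labels, pops, np.vstack([encode(s) for s in seqs]), annotations)


def paralog_aln(n_a=30, n_b=20, n_converted=2, seed=1, **kw):
    records, truth = synthio.simulate_paralog_sequences(
        n_a=n_a, n_b=n_b, n_converted=n_converted, seed=seed, **kw
    )
    aln = pc.SeqAlignment(
        [r[0] for r in records],
        [r[1] for r in records],
        [r[2] for r in records],
        np.vstack([encode(r[3]) for r in records]),
    )
    labels = {r[0]: r[1] for r in records}
    return aln, labels, truth


class TestTrim:
    def _annotated(self, upstream=100, coding=1464, intron=50):
        ann = np.array(["upstream"] * upstream + ["coding"] * coding + ["intron"] * intron)
        rng = np.random.default_rng(0)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, len(ann))) for _ in range(3)]
        return make_aln(seqs, annotations=ann)

    def test_trims_to_1464_coding_columns(self):
        out = pc.trim_alignment(self._annotated())
        assert out.length == 1464
        assert (out.col_annotations == "coding").all()

    def test_already_trimmed_unchanged(self):
        aln = self._annotated(upstream=0, intron=0)
        out = pc.trim_alignment(aln)
        assert np.array_equal(out.matrix, aln.matrix)

    def test_unannotated_or_intron_only_rejected(self):
        aln = make_aln(["ACGT" * 10])
        with pytest.raises(ValueError):
            pc.trim_alignment(aln)
        intron_only = make_aln(["ACGT" * 10], annotations=np.array(["intron"] * 40))
        with pytest.raises(ValueError):
            pc.trim_alignment(intron_only)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        a = encode("ACGTACGT")
        assert pc.p_distance(a, a) == 0.0

    def test_mismatch_count_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 1464).astype(np.uint8)
        y = x.copy()
        flip = rng.choice(1464, size=146, replace=False)
        y[flip] = (y[flip] + 1) % 4
        assert pc.p_distance(x, y) == pytest.approx(146 / 1464)

    def test_gap_columns_excluded_pairwise(self):
        x = encode("ACGT----")
        y = encode("ACTTACGT")
        # shared ungapped columns: 4, one mismatch
        assert pc.p_distance(x, y) == pytest.approx(0.25)

    def test_no_comparable_columns_missing(self):
        assert math.isnan(pc.p_distance(encode("----"), encode("AC--")))

    def test_k2p_zero_and_closed_form(self):
        assert pc.k2p_distance(0.0, 0.0) == 0.0
        # -0.5 ln(0.75) - 0.25 ln(0.9)
        assert pc.k2p_distance(0.1, 0.05) == pytest.approx(0.170181, abs=1e-6)

    def test_k2p_saturation(self):
        assert pc.k2p_distance(0.5, 0.0) == math.inf

    def test_pairwise_matrix_matches_per_pair_oracle(self, rng):
        # 100 random pairs: matrix route equals the scalar implementations
        seqs = ["".join("ACGT-"[b] for b in rng.integers(0, 5, 200)) for _ in range(15)]
        aln = make_aln(seqs)
        dp = pc.pairwise_distances(aln, "p")
        dk = pc.pairwise_distances(aln, "k2p")
        checked = 0
        for i in range(15):
            for j in range(i + 1, 15):
                x, y = aln.matrix[i], aln.matrix[j]
                assert dp.d[i, j] == pytest.approx(pc.p_distance(x, y), abs=1e-6)
                ok = (x != 4) & (y != 4)
                ts = np.sum((x[ok] != y[ok]) & (x[ok] % 2 == y[ok] % 2))
                tv = np.sum((x[ok] != y[ok]) & (x[ok] % 2 != y[ok] % 2))
                expect = pc.k2p_distance(ts / ok.sum(), tv / ok.sum())
                if math.isinf(expect):
                    assert math.isinf(dk.d[i, j])
                else:
                    assert dk.d[i, j] == pytest.approx(expect, abs=1e-6)
                checked += 1
        assert checked == 105


class TestMDS:
    def test_two_points_on_first_axis(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        y = pc.classical_mds(d, k=1)
        assert sorted(y[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_three_equidistant_points_equilateral(self):
        d = np.ones((3, 3)) - np.eye(3)
        y = pc.classical_mds(d, k=2)
        from scipy.spatial.distance import pdist

        assert pdist(y) == pytest.approx([1, 1, 1], abs=1e-9)

    def test_euclidean_input_reconstructed(self, rng):
        from scipy.spatial.distance import cdist

        X = rng.normal(size=(10, 2))
        d = cdist(X, X)
        y = pc.classical_mds(d, k=2)
        assert np.abs(cdist(y, y) - d).max() < 1e-6

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            pc.classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNJ:
    def test_three_taxon_pendant_lengths(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = pc.nj_tree(d, ["A", "B", "C"])
        lengths = {child.name: bl for child, bl in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            pc.nj_tree(np.zeros((2, 2)), ["A", "B"])

    def test_additive_four_taxon_tree_recovered(self):
        # ((A:1,B:2):1,(C:3,D:4)) path-length matrix
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = pc.nj_tree(d, list("ABCD"))
        assert set(map(frozenset, tree.bipartitions())) == {frozenset({"A", "B"})}
        # recovered tree reproduces the input distances exactly
        assert _tree_distances(tree) == pytest.approx(d.flatten().tolist(), abs=1e-9)

    def test_random_additive_trees_recovered(self, rng):
        # additivity oracle over random trees up to 12 taxa
        for trial in range(30):
            n = int(rng.integers(4, 13))
            d, bips = _random_additive_matrix(rng, n)
            tree = pc.nj_tree(d, [f"t{i}" for i in range(n)])
            assert np.allclose(
                np.array(_tree_distances(tree)).reshape(n, n), d, atol=1e-9
            ), f"trial {trial}"
            got = {frozenset(b) for b in tree.bipartitions()}
            full = frozenset(f"t{i}" for i in range(n))
            assert _canon(got, full) == _canon(set(bips), full)

    def test_matches_scikit_bio_on_random_matrices(self, rng):
        # independent-library cross-check on non-additive random matrices
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        for _ in range(5):
            n = 7
            x = rng.random((n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            ids = [f"t{i}" for i in range(n)]
            mine = {frozenset(b) for b in pc.nj_tree(d, ids).bipartitions()}
            theirs = sknj(SkDM(d, ids))
            sk_bips = set()
            for node in theirs.non_tips():
                tips = frozenset(t.name for t in node.tips())
                if 1 < len(tips) < n - 1:
                    sk_bips.add(tips)
            full = frozenset(ids)
            assert _canon(mine, full) == _canon(sk_bips, full)


def _canon(bips, full):
    """Canonicalize bipartitions: smaller side, ties broken lexicographically."""
    out = set()
    for b in bips:
        other = full - b
        if (len(b), sorted(b)) <= (len(other), sorted(other)):
            out.add(b)
        else:
            out.add(other)
    return out


def _tree_distances(tree):
    """Leaf-to-leaf path lengths, flattened in leaf-name order."""
    leaves = sorted(tree.leaves(), key=lambda s: (len(s), s))
    # collect distances between all leaf pairs via lowest common ancestor walk
    n = len(leaves)
    dmat = np.zeros((n, n))

    def collect(node):
        groups = []
        for child, bl in node.children:
            sub = collect(child)
            groups.append([(name, d + bl) for name, d in sub])
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for na, da in groups[gi]:
                    for nb, db in groups[gj]:
                        i, j = leaves.index(na), leaves.index(nb)
                        dmat[i, j] = dmat[j, i] = da + db
        return [x for g in groups for x in g] or [(node.name, 0.0)]

    collect(tree)
    return dmat.flatten().tolist()


def _random_additive_matrix(rng, n):
    """Build a random binary tree, return its path-length matrix + bipartitions."""
    nodes = [(pc.TreeNode(name=f"t{i}"), {f"t{i}"}) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (a, sa), (b, sb) = nodes[i], nodes[j]
        parent = pc.TreeNode(
            children=[(a, float(rng.uniform(0.1, 2))), (b, float(rng.uniform(0.1, 2)))]
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [(parent, sa | sb)]
    root = pc.TreeNode(
        children=[(nd, float(rng.uniform(0.1, 2))) for nd, _ in nodes]
    )
    d = np.array(_tree_distances(root)).reshape(n, n)
    bips = [frozenset(b) for b in root.bipartitions()]
    return d, bips


class TestBootstrap:
    def test_deterministic_under_seed(self):
        aln, labels, _ = paralog_aln(n_a=8, n_b=6, n_converted=0, seed=3)
        _, s1 = pc.bootstrap_support(aln, n_reps=20, seed=5)
        _, s2 = pc.bootstrap_support(aln, n_reps=20, seed=5)
        assert s1 == s2

    def test_deep_separation_gets_full_support(self):
        aln, labels, _ = paralog_aln(n_a=10, n_b=8, n_converted=0, seed=7)
        tree, support = pc.bootstrap_support(aln, n_reps=50, seed=1)
        clades = pc._label_clades(tree.bipartitions(), labels, 0.9)
        sep = support.get(clades["paralog_a"]) or support.get(clades["paralog_b"])
        assert sep >= 98.0

    def test_star_like_data_low_support(self, rng):
        # a true star radiation (one ancestor, independent tips, no shared
        # internal edges): resolved internal edges are resampling artefacts
        from poolscan._seq import mutate, random_seq

        ancestor = random_seq(rng, 400)
        seqs = [mutate(ancestor, 0.02, rng) for _ in range(8)]
        aln = make_aln(seqs)
        _, support = pc.bootstrap_support(aln, n_reps=50, seed=2)
        assert support and np.median(list(support.values())) < 70.0

    def test_too_short_alignment_rejected(self):
        aln = make_aln(["ACGTA", "ACGTT", "ACGGA"])
        with pytest.raises(ValueError):
            pc.bootstrap_support(aln, n_reps=5)


class TestClassifyConversion:
    def test_converted_sequences_identified_exactly(self):
        aln, labels, truth = paralog_aln(n_a=30, n_b=20, n_converted=3, seed=11)
        tree = pc.nj_tree(pc.pairwise_distances(aln, "k2p"))
        calls = pc.classify_conversion(tree, labels)
        converted = sorted(c.seq_id for c in calls if c.converted)
        assert converted == sorted(truth.converted_ids)

    def test_no_conversion_no_flags(self):
        aln, labels, _ = paralog_aln(n_a=20, n_b=15, n_converted=0, seed=13)
        tree = pc.nj_tree(pc.pairwise_distances(aln, "k2p"))
        calls = pc.classify_conversion(tree, labels)
        assert not any(c.converted for c in calls)

    def test_perfect_recall_precision_in_long_branch_regime(self):
        # between-paralog distance >= 10x within-paralog diversity
        for seed in range(3):
            aln, labels, truth = paralog_aln(
                n_a=25, n_b=15, n_converted=2, seed=20 + seed,
                divergence=0.10, diversity=0.01,
            )
            tree = pc.nj_tree(pc.pairwise_distances(aln, "k2p"))
            calls = pc.classify_conversion(tree, labels)
            converted = sorted(c.seq_id for c in calls if c.converted)
            assert converted == sorted(truth.converted_ids)

    def test_identical_labels_rejected(self):
        aln, labels, _ = paralog_aln(n_a=5, n_b=3, n_converted=0, seed=1)
        with pytest.raises(ValueError):
            pc.classify_conversion(None, {k: "same" for k in labels})

    def test_embedding_route_flags_conversion_and_unplaced(self):
        aln, labels, truth = paralog_aln(n_a=30, n_b=20, n_converted=2, seed=17)
        coords = pc.classical_mds(pc.pairwise_distances(aln, "p").d, k=2)
        calls = pc.classify_conversion(None, labels, embedding=coords, ids=aln.ids)
        converted = sorted(c.seq_id for c in calls if c.converted)
        assert converted == sorted(truth.converted_ids)


class TestDepthRatio:
    def test_equal_depths_no_flag(self):
        a = np.ones(1000)
        out = pc.paralog_depth_ratio(a, a)
        assert not out.flagged and np.allclose(out.ratio, 1.0)

    def test_conversion_signature_flagged(self):
        # 50% of b-haplotypes carry the a exon: a gains what b loses
        a = np.ones(1000)
        b = np.ones(1000)
        a[:400] = 1.5
        b[:400] = 0.5
        out = pc.paralog_depth_ratio(a, b)
        assert out.flagged
        assert out.flagged_span[0] <= 200 and out.flagged_span[1] >= 300
        assert out.ratio[0] == pytest.approx(3.0)

    def test_global_depth_scaling_not_flagged(self):
        a = np.full(1000, 2.0)
        b = np.full(1000, 2.0)
        out = pc.paralog_depth_ratio(a, b)
        assert not out.flagged

    def test_gained_reads_without_loss_not_flagged(self):
        # ratio high but total depth rises: amplification, not re-assignment
        a = np.ones(1000)
        b = np.ones(1000)
        a[:400] = 3.0  # total 4.0 vs 2.0 elsewhere
        out = pc.paralog_depth_ratio(a, b)
        assert not out.flagged

    def test_zero_b_depth_capped(self):
        a = np.ones(300)
        b = np.zeros(300)
        out = pc.paralog_depth_ratio(a, b)
        assert (out.ratio >= 100).all()

    def test_flag_power_tracks_conversion_frequency(self):
        # expected exon ratio (1+q)/(1-q): 1.22 at q=0.1 (no flag), 3 at q=0.5
        for q, expect_flag in ((0.1, False), (0.5, True)):
            a = np.ones(1000) * 1.0
            b = np.ones(1000) * 1.0
            a[:400] += q
            b[:400] -= q
            out = pc.paralog_depth_ratio(a, b)
            assert out.flagged is expect_flag, q
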