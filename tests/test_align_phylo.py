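"""Pairwise/progressive alignment, block trimming, NJ and RF distances."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import TreeNode

from copatrace.align_phylo import (
    BlockParams,
    MultipleAlignment,
    global_align_pair,
    nj_tree,
    percent_identity,
    progressive_msa,
    robinson_foulds,
    tree_from_additive,
    trim_conserved_blocks,
)

from conftest import random_binary_tree, random_protein


class TestGlobalAlignPair:
    def test_self_alignment_diagonal_score(self):
        m = substitution_matrices.load("BLOSUM62")
        seq = "PAWHEAE"
        score, (a, b) = global_align_pair(seq, seq)
        assert a == b == seq
        assert score == sum(m[c, c] for c in seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align_pair("A", "")

    def test_invalid_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            global_align_pair("AK1PW", "AKPW")

    def test_linear_gap_oracle(self, rng):
        """With gap_open=0 the affine DP reduces to plain per-character gap
        costs; an independently coded simple DP must agree."""
        m = substitution_matrices.load("BLOSUM62")

        def simple_nw(a, b, g):
            n1, n2 = len(a), len(b)
            H = [[0.0] * (n2 + 1) for _ in range(n1 + 1)]
            for i in range(1, n1 + 1):
                H[i][0] = -g * i
            for j in range(1, n2 + 1):
                H[0][j] = -g * j
            for i in range(1, n1 + 1):
                for j in range(1, n2 + 1):
                    H[i][j] = max(
                        H[i - 1][j - 1] + m[a[i - 1], b[j - 1]],
                        H[i - 1][j] - g,
                        H[i][j - 1] - g,
                    )
            return H[n1][n2]

        for _ in range(15):
            a = random_protein(rng, rng.randint(10, 80))
            b = random_protein(rng, rng.randint(10, 80))
            score, _ = global_align_pair(a, b, gap_open=0.0, gap_extend=4.0)
            assert score == pytest.approx(simple_nw(a, b, 4.0))

    def test_affine_matches_biopython(self, rng):
        al = PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
        for _ in range(15):
            a = random_protein(rng, rng.randint(20, 90))
            b = random_protein(rng, rng.randint(20, 90))
            score, _ = global_align_pair(a, b, gap_open=10.0, gap_extend=1.0)
            assert score == pytest.approx(al.score(a, b))


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(("ACDE", "ACDE")) == 100.0

    def test_hand_count_with_gaps(self):
        assert percent_identity(("AB-C", "AB-D")) == pytest.approx(200 / 3)

    def test_disjoint_gaps_zero(self):
        assert percent_identity(("AC--", "--AC")) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_identity(("AA", "AAA"))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxa_exact_recovery(self):
        src = TreeNode.read(["((a:2,b:3):1,(c:1.5,d:2.5):2);"])
        D, names = tree_from_additive(src)
        tree = nj_tree(D, names)
        rf, _ = robinson_foulds(tree, src)
        assert rf == 0
        got, _ = tree_from_additive(tree)
        assert np.allclose(got, D)

    def test_identical_rows_zero_cherry(self):
        D = np.array(
            [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = nj_tree(D, ["a", "b", "c", "d"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == 0.0 and lengths["b"] == 0.0

    def test_random_additive_topology_recovery(self, rng):
        for _ in range(10):
            leaves = [f"t{i}" for i in range(8)]
            src = random_binary_tree(rng, leaves)
            D, names = tree_from_additive(src)
            rf, _ = robinson_foulds(nj_tree(D, names), src)
            assert rf == 0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(D, ["a", "b", "c"])


class TestProgressiveMSA:
    def test_identical_sequences_no_gaps(self):
        seqs = {f"s{i}": "MKLVWHEA" for i in range(4)}
        msa = progressive_msa(seqs)
        assert all(r == "MKLVWHEA" for r in msa.rows)

    def test_two_sequences_reduce_to_pairwise(self, rng):
        a, b = random_protein(rng, 40), random_protein(rng, 45)
        _, (ra, rb) = global_align_pair(a, b)
        msa = progressive_msa({"a": a, "b": b})
        assert msa.rows == [ra, rb]

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="nothing to align"):
            progressive_msa({"only": "MKWL"})

    def test_ungap_round_trip_and_width(self, rng):
        base = random_protein(rng, 60)
        seqs = {}
        for i in range(5):
            s = list(base)
            for p in range(len(s)):
                if rng.random() < 0.15:
                    s[p] = random_protein(rng, 1)
            if i == 2:
                del s[10:14]
            seqs[f"s{i}"] = "".join(s)
        msa = progressive_msa(seqs)
        for nm, seq in seqs.items():
            assert msa.ungapped(nm) == seq
        assert msa.n_cols >= max(len(s) for s in seqs.values())


class TestBlockTrimming:
    def test_fully_conserved(self):
        msa = MultipleAlignment(["a", "b", "c"], ["M" * 50] * 3)
        trimming, trimmed = trim_conserved_blocks(msa)
        assert trimming.blocks == [(0, 50)]
        assert trimmed.n_cols == 50

    def test_all_distinct_columns_no_blocks(self):
        rows = ["ACDEFGHIKLMNPQ", "CDEFGHIKLMNPQR", "DEFGHIKLMNPQRS", "EFGHIKLMNPQRST"]
        msa = MultipleAlignment(["a", "b", "c", "d"], rows)
        trimming, trimmed = trim_conserved_blocks(msa)
        assert trimming.blocks == []
        assert trimmed.n_cols == 0

    def test_two_blocks_around_long_junk_run(self):
        # 12 conserved + 9 all-distinct + 12 conserved columns
        cons1, cons2 = "MKLVWHEAPRST", "ACDEFGHIKLMN"
        junk = ["ACDEFGHIK", "CDEFGHIKL", "DEFGHIKLM", "EFGHIKLMN"]
        rows = [cons1 + junk[i] + cons2 for i in range(4)]
        msa = MultipleAlignment(list("abcd"), rows)
        trimming, trimmed = trim_conserved_blocks(msa)
        assert trimming.blocks == [(0, 12), (21, 33)]
        assert trimmed.n_cols == 24

    def test_monotone_in_cons_frac(self, rng):
        base = random_protein(rng, 40)
        rows = []
        for _ in range(6):
            s = list(base)
            for p in range(len(s)):
                if rng.random() < 0.3:
                    s[p] = random_protein(rng, 1)
            rows.append("".join(s))
        msa = MultipleAlignment([f"s{i}" for i in range(6)], rows)
        kept = []
        for frac in (0.3, 0.5, 0.7, 0.9):
            p = BlockParams(cons_frac=frac, strict_frac=max(frac, 0.85))
            trimming, _ = trim_conserved_blocks(msa, p)
            kept.append(trimming.n_cols_kept)
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestRobinsonFoulds:
    def test_identity_is_zero(self, quartet_trees):
        t1, _ = quartet_trees
        assert robinson_foulds(t1, t1.copy()) == (0, 0.0)

    def test_distinct_quartets_max_distance(self, quartet_trees):
        t1, t2 = quartet_trees
        assert robinson_foulds(t1, t2) == (2, 1.0)

    def test_star_counts_resolved_splits_only(self):
        star = TreeNode.read(["(a:1,b:1,c:1,d:1);"])
        resolved = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        rf, norm = robinson_foulds(star, resolved)
        assert rf == 1

    def test_symmetry_and_triangle_on_random_trees(self, rng):
        import itertools

        trees = [random_binary_tree(rng, list("abcdef")) for _ in range(6)]
        d = {}
        for i, j in itertools.combinations(range(6), 2):
            rf_ij, _ = robinson_foulds(trees[i], trees[j])
            rf_ji, _ = robinson_foulds(trees[j], trees[i])
            assert rf_ij == rf_ji
            d[(i, j)] = d[(j, i)] = rf_ij
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[(i, k)] <= d[(i, j)] + d[(j, k)]

    def test_oracle_against_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        from copatrace.align_phylo import tree_to_newick

        for _ in range(10):
            t1 = random_binary_tree(rng, list("abcdef"))
            t2 = random_binary_tree(rng, list("abcdef"))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=tree_to_newick(t1), schema="newick", taxon_namespace=tns
            )
            d2 = dendropy.Tree.get(
                data=tree_to_newick(t2), schema="newick", taxon_namespace=tns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert robinson_foulds(t1, t2)[0] == expected

    def test_leaf_mismatch_error(self):
        t1 = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        t2 = TreeNode.read(["((a:1,b:1):1,(c:1,e:1):1);"])
        with pytest.raises(ValueError, match="e"):
            robinson_foulds(t1, t2)
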