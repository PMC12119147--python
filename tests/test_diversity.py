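"""Faith PD, Rosauer PE, equal-branch comparison tree, diversity tables."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import phyloendemism as pe

from conftest import random_matrix


def pd_oracle(tree, community):
    """Brute-force rooted PD: union of root-to-tip edge sets."""
    t = tree.dendropy_tree
    edges = set()
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label not in community:
            continue
        node = leaf
        while node is not t.seed_node:
            edges.add(node)
            node = node.parent_node
    return sum(n.edge.length for n in edges)


def pe_oracle(tree, matrix, area):
    """Brute-force PE: per-branch range partition over areas."""
    t = tree.dendropy_tree
    comms = {a: set(matrix.area_species(a)) for a in matrix.areas}
    total = 0.0
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        occupied = [a for a in matrix.areas if comms[a] & below]
        if area in occupied:
            total += node.edge.length / len(occupied)
    return total


class TestSpeciesRichness:
    def test_column_sums(self, small_matrix):
        assert pe.species_richness(small_matrix, "west") == 2
        assert pe.species_richness(small_matrix, "east") == 2

    def test_unknown_area_raises(self, small_matrix):
        with pytest.raises(pe.MatrixError):
            pe.species_richness(small_matrix, "north")

    def test_random_matrix_matches_oracle(self):
        m = random_matrix([f"s{i}" for i in range(30)], list("abc"), seed=8)
        for a in m.areas:
            assert pe.species_richness(m, a) == int(m.df[a].to_numpy().sum())


class TestFaithPD:
    def test_star_tree_pendants_only(self, star_tree):
        assert pe.faith_pd(star_tree, {"t1", "t2"}) == pytest.approx(2.0)

    def test_all_tips_gives_total_length(self):
        t = pe.simulate_dated_tree(16, 8.0, seed=5)
        assert pe.faith_pd(t, t.tip_labels) == pytest.approx(t.total_length)

    def test_empty_community_zero(self, star_tree):
        assert pe.faith_pd(star_tree, []) == 0.0

    def test_unknown_species_raises(self, star_tree):
        with pytest.raises(pe.PhyloendemismError, match="zz"):
            pe.faith_pd(star_tree, ["zz"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_union_oracle(self, seed):
        t = pe.simulate_dated_tree(16, 10.0, seed=seed)
        rng = np.random.default_rng(seed + 100)
        comm = set(rng.choice(t.tip_labels, size=5, replace=False))
        assert pe.faith_pd(t, comm) == pytest.approx(pd_oracle(t, comm), abs=1e-9)

    def test_monotone_in_community(self):
        t = pe.simulate_dated_tree(20, 10.0, seed=6)
        tips = t.tip_labels
        prev = 0.0
        for k in range(1, len(tips) + 1):
            cur = pe.faith_pd(t, tips[:k])
            assert cur >= prev - 1e-12
            prev = cur

    def test_unrooted_variant_drops_root_path(self):
        t = pe.DatedTree.from_string("((A:1,B:1):3,C:4);")
        assert pe.faith_pd(t, {"A", "B"}) == pytest.approx(5.0)
        assert pe.faith_pd(t, {"A", "B"}, include_root=False) == pytest.approx(2.0)
        # single species has zero unrooted PD
        assert pe.faith_pd(t, {"A"}, include_root=False) == pytest.approx(0.0)

    def test_matches_picante_reference(self, tmp_path):
        """Cross-check rooted PD against picante::pd via Rscript."""
        t = pe.simulate_dated_tree(16, 20.0, seed=42)
        m = random_matrix(t.tip_labels, ["X", "Y", "Z"], seed=3, p=0.5)
        tree_path = tmp_path / "t.nwk"
        mat_path = tmp_path / "m.csv"
        t.write_newick(tree_path)
        m.to_csv(mat_path)
        script = textwrap.dedent(f"""
            suppressMessages(library(picante))
            tr <- read.tree('{tree_path}')
            m <- read.csv('{mat_path}', row.names=1)
            res <- pd(t(m), tr, include.root=TRUE)
            cat(sprintf('%.10f\\n', res$PD))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_vals = [float(x) for x in out.stdout.split()]
        ours = [pe.faith_pd(t, m.area_species(a)) for a in m.areas]
        np.testing.assert_allclose(ours, r_vals, atol=1e-6)


class TestPhyloEndemism:
    def test_single_occupied_area_gets_total_length(self):
        t = pe.simulate_dated_tree(10, 5.0, seed=1)
        df = pd.DataFrame(
            {"only": 1, "empty": 0}, index=t.tip_labels, dtype=np.int8
        )
        m = pe.CommunityMatrix(df)
        assert pe.phylo_endemism(t, m, "only") == pytest.approx(t.total_length)
        assert pe.phylo_endemism(t, m, "empty") == 0.0

    def test_identical_areas_split_pd_evenly(self):
        t = pe.simulate_dated_tree(10, 5.0, seed=2)
        df = pd.DataFrame({"x": 1, "y": 1}, index=t.tip_labels, dtype=np.int8)
        m = pe.CommunityMatrix(df)
        pd_all = pe.faith_pd(t, t.tip_labels)
        assert pe.phylo_endemism(t, m, "x") == pytest.approx(pd_all / 2)

    @pytest.mark.parametrize("seed", range(4))
    def test_pe_sums_to_pd_of_union(self, seed):
        t = pe.simulate_dated_tree(20, 12.0, seed=seed)
        m = random_matrix(t.tip_labels, list("wxyz"), seed=seed + 50)
        total_pe = sum(pe.phylo_endemism(t, m, a) for a in m.areas)
        union = set().union(*(m.area_species(a) for a in m.areas))
        assert total_pe == pytest.approx(pe.faith_pd(t, union), abs=1e-9)

    def test_matches_range_partition_oracle(self):
        t = pe.simulate_dated_tree(14, 9.0, seed=21)
        m = random_matrix(t.tip_labels, list("pqr"), seed=22)
        for a in m.areas:
            assert pe.phylo_endemism(t, m, a) == pytest.approx(
                pe_oracle(t, m, a), abs=1e-9
            )

    def test_pe_never_exceeds_pd(self):
        t = pe.simulate_dated_tree(18, 7.0, seed=30)
        m = random_matrix(t.tip_labels, list("abcde"), seed=31)
        for a in m.areas:
            assert (
                pe.phylo_endemism(t, m, a)
                <= pe.faith_pd(t, m.area_species(a)) + 1e-12
            )


class TestEqualBranchTree:
    def test_uniform_lengths_and_total_preserved(self):
        t = pe.simulate_dated_tree(12, 6.0, seed=8)
        alt = pe.make_equal_branch_tree(t)
        dt = alt.dendropy_tree
        lengths = [
            n.edge.length for n in dt.preorder_node_iter() if n is not dt.seed_node
        ]
        assert np.allclose(lengths, lengths[0])
        assert alt.total_length == pytest.approx(t.total_length, abs=1e-9)

    def test_already_uniform_identity(self, star_tree):
        alt = pe.make_equal_branch_tree(star_tree)
        assert alt.total_length == pytest.approx(4.0)
        dt = alt.dendropy_tree
        for n in dt.preorder_node_iter():
            if n is not dt.seed_node:
                assert n.edge.length == pytest.approx(1.0)


class TestDiversityTable:
    def test_uniform_tree_rpd_one(self, star_tree):
        m = random_matrix(star_tree.tip_labels, ["u", "v"], seed=1)
        table = pe.diversity_table(star_tree, m)
        assert np.allclose(table["RPD"], 1.0)

    def test_identical_areas_identical_rows(self):
        t = pe.simulate_dated_tree(10, 5.0, seed=3)
        df = pd.DataFrame({"x": 1, "y": 1}, index=t.tip_labels, dtype=np.int8)
        table = pe.diversity_table(t, pe.CommunityMatrix(df))
        assert table.loc["x"].equals(table.loc["y"])

    def test_cells_match_component_functions(self):
        t = pe.simulate_dated_tree(18, 14.0, seed=9)
        m = random_matrix(t.tip_labels, list("abcd"), seed=10)
        table = pe.diversity_table(t, m)
        alt = pe.make_equal_branch_tree(t)
        for a in m.areas:
            comm = m.area_species(a)
            assert table.loc[a, "SR"] == len(comm)
            assert table.loc[a, "PD"] == pytest.approx(pe.faith_pd(t, comm), abs=1e-9)
            assert table.loc[a, "PE"] == pytest.approx(
                pe.phylo_endemism(t, m, a), abs=1e-9
            )
            assert table.loc[a, "PD_alt"] == pytest.approx(
                pe.faith_pd(alt, comm), abs=1e-9
            )
            assert table.loc[a, "RPD"] == pytest.approx(
                table.loc[a, "PD"] / table.loc[a, "PD_alt"]
            )
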