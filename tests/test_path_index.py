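"""Path table construction, pruning-path retrieval and the naive oracle."""

import numpy as np
import pytest

from conftest import naive_pruned_lengths, random_tree_set
from ercov.path_index import PathIndex, PathLookupError
from ercov.tree_io import GeneTreeSet, read_newick, restrict


@pytest.fixture
def toy_index(toy_master):
    genes = {
        "full": toy_master,
        "abc": restrict(toy_master, {"A", "B", "C"}),
        "abd": restrict(toy_master, {"A", "B", "D"}),
    }
    return PathIndex(GeneTreeSet(master=toy_master, genes=genes))


class TestPathTable:
    def test_full_gene_has_one_path_per_ancestor_pair(self, toy_index):
        # 6 non-root nodes x each proper ancestor on a balanced 4-leaf tree
        row = toy_index.matrix[toy_index._gene_pos["full"]]
        assert int(np.sum(~np.isnan(row))) == 10

    def test_leaf_to_root_path_length(self, toy_index, toy_master):
        col = toy_index._col[(toy_master.leaf_id("A"), toy_master.root)]
        assert toy_index.matrix[toy_index._gene_pos["full"], col] == pytest.approx(2.0)

    def test_two_leaf_tree_has_two_paths(self):
        t = read_newick("(A:1,B:2);")
        idx = PathIndex(GeneTreeSet(master=t, genes={"g": t}))
        row = idx.matrix[0]
        vals = sorted(row[~np.isnan(row)])
        assert vals == [1.0, 2.0]

    def test_incongruent_gene_rejected(self, toy_master):
        bad = read_newick("((A:1,C:1):1,B:1);")
        with pytest.raises(ValueError, match="incongruent"):
            PathIndex(GeneTreeSet(master=toy_master, genes={"bad": bad}))


class TestPruneEdges:
    def test_three_species_pruning(self, toy_index, toy_master):
        edges = toy_index.prune_edges({"A", "C", "D"})
        assert len(edges) == 4  # 2|S| - 2
        vec = toy_index.branch_vector("full", edges)
        by_leafset = {
            toy_master.leafset(d) & frozenset("ACD"): v for (d, a), v in zip(edges, vec)
        }
        assert by_leafset[frozenset("A")] == pytest.approx(2.0)
        assert by_leafset[frozenset("C")] == pytest.approx(3.0)
        assert by_leafset[frozenset("D")] == pytest.approx(1.0)
        assert by_leafset[frozenset("CD")] == pytest.approx(2.0)

    def test_full_leaf_set_gives_original_edges(self, toy_index, toy_master):
        edges = toy_index.prune_edges(toy_master.leaf_labels)
        expected = {
            (v, toy_master.parent[v])
            for v in range(toy_master.n_nodes)
            if v != toy_master.root
        }
        assert set(edges) == expected

    def test_single_species_errors(self, toy_index):
        with pytest.raises(ValueError, match="at least 2"):
            toy_index.prune_edges({"A"})

    def test_unknown_species_errors(self, toy_index):
        with pytest.raises(ValueError, match="not in master"):
            toy_index.prune_edges({"A", "Z"})

    def test_cache_purity(self, toy_index):
        first = toy_index.prune_edges({"A", "B", "D"})
        second = toy_index.prune_edges({"A", "B", "D"})
        assert first == second


class TestBranchVector:
    def test_own_species_set_returns_own_lengths(self, toy_index):
        gene = toy_index
        edges = gene.prune_edges({"A", "B", "C"})
        vec = gene.branch_vector("abc", edges)
        naive = naive_pruned_lengths(
            restrict(read_newick("((A:1,B:2):1,(C:3,D:1):2);"), {"A", "B", "C"}),
            {"A", "B", "C"},
        )
        assert sorted(vec) == pytest.approx(sorted(naive.values()))

    def test_missing_species_raises(self, toy_index):
        edges = toy_index.prune_edges({"A", "C", "D"})
        with pytest.raises(PathLookupError):
            toy_index.branch_vector("abc", edges)  # abc lacks D

    def test_non_strict_returns_nan(self, toy_index):
        edges = toy_index.prune_edges({"A", "C", "D"})
        vec = toy_index.branch_vector("abc", edges, strict=False)
        assert np.isnan(vec).any()


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,n_leaves", [(5, 5), (6, 12), (7, 24), (8, 40)])
    def test_branch_vectors_match_naive_prune(self, seed, n_leaves):
        gts = random_tree_set(seed, n_leaves, n_genes=3)
        idx = PathIndex(gts)
        rng = np.random.default_rng(seed + 1000)
        for gid, gene in gts.genes.items():
            species = sorted(gene.leaf_labels)
            for _ in range(4):
                k = int(rng.integers(2, len(species) + 1))
                keep = set(rng.choice(species, size=k, replace=False))
                edges = idx.prune_edges(keep)
                vec = idx.branch_vector(gid, edges)
                naive = naive_pruned_lengths(gene, keep)
                assert len(edges) == len(naive)
                for (d, a), v in zip(edges, vec):
                    ls = idx.master.leafset(d) & keep
                    assert v == pytest.approx(naive[ls], abs=1e-9)

    def test_lazy_and_precomputed_paths_agree(self):
        gts = random_tree_set(9, 18, n_genes=2)
        idx = PathIndex(gts)
        for gid, gene in gts.genes.items():
            row = idx.matrix[idx._gene_pos[gid]]
            cols = np.flatnonzero(~np.isnan(row))
            for c in cols[:: max(1, len(cols) // 25)]:
                d, a = idx.path_ids[c]
                assert idx.path_length_naive(gene, d, a) == pytest.approx(
                    row[c], abs=1e-12
                )


class TestSerialization:
    def test_npz_round_trip(self, tmp_path, toy_index):
        path = tmp_path / "index.npz"
        toy_index.save(path)
        back = PathIndex.load(path)
        assert back.gene_ids == toy_index.gene_ids
        np.testing.assert_array_equal(back.matrix, toy_index.matrix)
        assert back.prune_edges({"A", "C", "D"}) == toy_index.prune_edges(
            {"A", "C", "D"}
        )
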