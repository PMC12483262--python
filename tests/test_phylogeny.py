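"""Supermatrix assembly, neighbor joining, bootstrap, Newick round trips."""

import itertools

import dendropy
import numpy as np
import pytest

from mitocomp.divergence import SaturationError
from mitocomp.phylogeny import (PCG_ORDER, bootstrap, concatenate_pcgs,
                                k2p_matrix, nj_tree, root_with_outgroup,
                                supermatrix_from_records, tree_splits,
                                write_newick, write_partitions, write_phylip)
from mitocomp.synthetic_data import SimConfig, evolve, make_ancestor


def _additive_matrix(newick, ids):
    """Independent oracle: exact path lengths on a known tree (dendropy)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tax = {x.label: x for x in tree.taxon_namespace}
    return np.array([[pdm.distance(tax[a], tax[b]) for b in ids] for a in ids])


def _splits_from_newick(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    taxa = frozenset(x.label for x in tree.taxon_namespace)
    anchor = min(taxa)
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        splits.add(side if anchor not in side else taxa - side)
    return splits


class TestConcatenation:
    def test_column_arithmetic(self):
        per_gene = {g: {t: "ACGTACGTAC" * 3 for t in "ABC"} for g in PCG_ORDER}
        sm = concatenate_pcgs(per_gene)
        assert sm.n_columns == 13 * 30
        assert sm.taxa == ("A", "B", "C")

    def test_partitions_tile_and_round_trip(self, small_panel):
        sm = concatenate_pcgs(small_panel.per_gene)
        covered = 0
        prev_end = 0
        for g in sm.gene_order:
            s, e = sm.partitions[g]
            assert s == prev_end + 1
            covered += e - s + 1
            prev_end = e
            assert sm.gene_alignment(g) == {
                t: small_panel.per_gene[g][t] for t in sm.taxa}
        assert covered == sm.n_columns

    def test_reference_layout_single_taxon_extent(self, ancestor):
        sm = supermatrix_from_records([ancestor])
        assert sm.n_columns == 11191

    def test_canonical_gene_order(self, small_panel):
        sm = concatenate_pcgs(small_panel.per_gene)
        assert sm.gene_order == PCG_ORDER

    def test_taxon_missing_a_gene_dropped_with_warning(self):
        per_gene = {g: {t: "ACG" * 10 for t in "ABC"} for g in PCG_ORDER}
        del per_gene["cox1"]["C"]
        with pytest.warns(UserWarning, match="dropped"):
            sm = concatenate_pcgs(per_gene)
        assert sm.taxa == ("A", "B")


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(("a", "b", "c"), D)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_four_taxon_additive_recovery(self):
        ids = ("A", "B", "C", "D")
        D = _additive_matrix("((A:1,B:2):1,C:3,D:4);", ids)
        tree = nj_tree(ids, D)
        assert tree_splits(tree) == _splits_from_newick("((A:1,B:2):1,C:3,D:4);")
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_five_taxon_additive_recovery_with_branch_lengths(self):
        newick = "((A:1,B:2):1,C:3,(D:4,E:5):2);"
        ids = ("A", "B", "C", "D", "E")
        tree = nj_tree(ids, _additive_matrix(newick, ids))
        assert tree_splits(tree) == _splits_from_newick(newick)
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4, "E": 5})
        # internal edges: recompute from the recovered tree's path lengths
        back = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        pdm = back.phylogenetic_distance_matrix()
        tax = {x.label: x for x in back.taxon_namespace}
        want = _additive_matrix(newick, ids)
        got = np.array([[pdm.distance(tax[a], tax[b]) for b in ids] for a in ids])
        assert np.allclose(got, want)

    def test_matches_independent_nj_on_random_additive_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(4)
        ids = tuple("ABCDEFGH")
        for _ in range(10):
            # random binary tree with distinct branch lengths -> additive matrix
            pool = [f"{i}:{rng.uniform(0.5, 3):.4f}" for i in ids]
            while len(pool) > 3:
                a = pool.pop(int(rng.integers(len(pool))))
                b = pool.pop(int(rng.integers(len(pool))))
                pool.append(f"({a},{b}):{rng.uniform(0.5, 3):.4f}")
            newick = f"({pool[0]},{pool[1]},{pool[2]});"
            D = _additive_matrix(newick, ids)
            ours = tree_splits(nj_tree(ids, D))
            theirs = _splits_from_newick(str(skbio_nj(DistanceMatrix(D, ids))))
            assert ours == _splits_from_newick(newick)
            assert ours == theirs

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(("a", "b", "c"), np.array([[0, 1], [1, 0]], float))
        bad = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(("a", "b", "c"), bad)
        neg = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(("a", "b", "c"), neg)

    def test_topology_recovery_under_simulation(self):
        """NJ on K2P distances recovers a known 10-taxon topology."""
        rng = np.random.default_rng(12)
        ids = tuple(f"t{i}" for i in range(10))
        hits = 0
        runs = 100
        for run in range(runs):
            pool = [f"{t}:{rng.uniform(0.01, 0.03):.5f}" for t in ids]
            while len(pool) > 3:
                a = pool.pop(int(rng.integers(len(pool))))
                b = pool.pop(int(rng.integers(len(pool))))
                pool.append(f"({a},{b}):{rng.uniform(0.01, 0.03):.5f}")
            newick = f"({pool[0]},{pool[1]},{pool[2]});"
            anc = "".join(rng.choice(list("ACGT"), size=3000,
                                     p=[0.395, 0.105, 0.105, 0.395]))
            leaves, _ = evolve(anc, newick, kappa=4.0, seed=5000 + run)
            mat_ids, D = k2p_matrix(leaves)
            if tree_splits(nj_tree(mat_ids, D)) == _splits_from_newick(newick):
                hits += 1
        assert hits >= 95


@pytest.fixture(scope="module")
def clean_supermatrix():
    """4 taxa, two tight pairs separated by a long internal edge."""
    rng = np.random.default_rng(8)
    anc = "".join(rng.choice(list("ACGT"), size=5000,
                             p=[0.395, 0.105, 0.105, 0.395]))
    newick = "((a1:0.005,a2:0.005):0.1,(b1:0.005,b2:0.005):0.1);"
    leaves, _ = evolve(anc, newick, kappa=4.0, seed=77)
    return concatenate_pcgs({"cox1": leaves}, gene_order=("cox1",))


class TestBootstrap:
    def test_clean_signal_gets_full_support(self, clean_supermatrix):
        res = bootstrap(clean_supermatrix, n_replicates=100, seed=3)
        supports = [n.support for n in res.tree.postorder()
                    if n.support is not None]
        assert supports == [100.0]
        assert res.n_used == 100

    def test_single_replicate_supports_are_binary(self, clean_supermatrix):
        res = bootstrap(clean_supermatrix, n_replicates=1, seed=9)
        for node in res.tree.postorder():
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_same_seed_reproduces_newick(self, clean_supermatrix):
        n1 = write_newick(bootstrap(clean_supermatrix, 25, seed=42).tree)
        n2 = write_newick(bootstrap(clean_supermatrix, 25, seed=42).tree)
        assert n1 == n2

    def test_spawned_streams_stable_under_replicate_growth(self, clean_supermatrix):
        # growing the replicate count must not reshuffle earlier replicates:
        # supports from the first 10 replicates are a prefix computation
        r10 = bootstrap(clean_supermatrix, 10, seed=5)
        r20 = bootstrap(clean_supermatrix, 20, seed=5)
        assert r10.n_used == 10 and r20.n_used == 20


class TestNewick:
    def test_three_taxon_shape(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        text = write_newick(nj_tree(("A", "B", "C"), D))
        assert text.startswith("(") and text.strip().endswith(");")
        import re
        assert set(re.findall(r"[ABC]", text)) == {"A", "B", "C"}

    def test_round_trip_isomorphism(self, small_panel):
        sm = concatenate_pcgs(small_panel.per_gene)
        ids, D = k2p_matrix(sm)
        tree = nj_tree(ids, D)
        text = write_newick(tree)
        assert tree_splits(tree) == _splits_from_newick(text)
        back = dendropy.Tree.get(data=text, schema="newick")
        assert {l.taxon.label for l in back.leaf_node_iter()} == set(ids)

    def test_supports_preserved_on_round_trip(self, tmp_path, small_panel):
        sm = concatenate_pcgs(small_panel.per_gene)
        res = bootstrap(sm, 10, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(res.tree, path)
        back = dendropy.Tree.get(path=str(path), schema="newick")
        want = sorted(round(n.support) for n in res.tree.postorder()
                      if n.support is not None)
        got = sorted(int(n.label) for n in back.preorder_node_iter()
                     if n.label and not n.is_leaf())
        assert got == want

    def test_outgroup_listed_first(self, small_panel):
        sm = concatenate_pcgs(small_panel.per_gene)
        ids, D = k2p_matrix(sm)
        tree = root_with_outgroup(nj_tree(ids, D), "tax3")
        assert "tax3" in tree.children[0].leaf_names()

    def test_exports(self, tmp_path, small_panel):
        sm = concatenate_pcgs(small_panel.per_gene)
        write_phylip(sm, tmp_path / "sm.phy")
        write_partitions(sm, tmp_path / "parts.tsv")
        header = (tmp_path / "sm.phy").read_text().splitlines()[0]
        assert header == f"{len(sm.taxa)} {sm.n_columns}"
        lines = (tmp_path / "parts.tsv").read_text().splitlines()
        assert len(lines) == 1 + 13
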