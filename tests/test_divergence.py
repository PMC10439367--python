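"""Fisher divergence scan, Venn partition, NJ tree, F_ST clustering."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from ghostflow import (GenotypeMatrix, fisher_scan, fst_matrix_and_clustering,
                       nei_nj_tree, venn_partition)
from ghostflow.divergence import nei_distance_matrix, _nj_newick


def _matrix(geno, groups, chrom=None, pos=None):
    geno = np.asarray(geno, np.int8)
    n, s = geno.shape
    sites = pd.DataFrame({
        "chrom": chrom or ["chr1"] * s,
        "pos": pos or list(np.arange(1, s + 1) * 10),
        "ref": ["A"] * s, "alt": ["T"] * s})
    indiv = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                          "population": groups, "group": groups})
    return GenotypeMatrix(genotypes=geno, sites=sites, individuals=indiv)


class TestFisherScan:
    def test_fixed_difference_p_by_enumeration(self):
        # 5 diploids fixed alt vs 5 diploids fixed ref: table [[10,0],[0,10]]
        gm = _matrix([[2]] * 5 + [[0]] * 5, ["X"] * 5 + ["Y"] * 5)
        scan = fisher_scan(gm, "X", "Y", alpha=0.001)
        # full hypergeometric enumeration: p = 2 / C(20,10)
        assert scan.table["p"].iloc[0] == pytest.approx(2 / 184756, rel=1e-9)
        assert scan.significant_ids() == {("chr1", 10)}

    def test_identical_counts_give_p_one(self):
        gm = _matrix([[1], [0]] * 3, ["X", "X", "X", "Y", "Y", "Y"])
        scan = fisher_scan(gm, "X", "Y")
        assert scan.table["p"].iloc[0] == pytest.approx(1.0)

    def test_single_copy_each_side_not_significant(self):
        # table [[1,0],[0,1]]: the two-sided exact p is 1
        from scipy.stats import fisher_exact
        assert fisher_exact([[1, 0], [0, 1]])[1] == pytest.approx(1.0)

    def test_monomorphic_site_never_significant(self):
        gm = _matrix([[0, 2]] * 4, ["X", "X", "Y", "Y"])
        scan = fisher_scan(gm, "X", "Y", alpha=0.5)
        assert (scan.table["p"] == 1.0).all()
        assert scan.significant_ids() == set()

    def test_group_swap_exchangeability(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, (12, 40)).astype(np.int8)
        gm = _matrix(geno, ["X"] * 6 + ["Y"] * 6)
        a = fisher_scan(gm, "X", "Y").table["p"]
        b = fisher_scan(gm, "Y", "X").table["p"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_null_type_one_error_control(self):
        """A panmictic pool split at random: ~alpha of sites significant."""
        from ghostflow import SampleConfig, ScenarioParams, simulate_snps

        p = ScenarioParams(scenario="CI", N_A=10000, N_B=10000, N_anc=0.5,
                           T_div=1.0)
        gm = simulate_snps(p, SampleConfig(n_snps=5000), seed=77)
        scan = fisher_scan(gm, "TaiA", "TaiB", alpha=0.001)
        frac = len(scan.significant) / gm.n_sites
        assert frac <= 0.003


class TestVenn:
    def test_hand_enumeration(self):
        v = venn_partition({1, 2, 3}, {2, 3, 4}, {3, 5})
        assert v.regions["100"] == {1}
        assert v.regions["010"] == {4}
        assert v.regions["001"] == {5}
        assert v.regions["110"] == {2}
        assert v.regions["101"] == set()
        assert v.regions["011"] == set()
        assert v.regions["111"] == {3}

    def test_disjoint_sets_have_empty_intersections(self):
        v = venn_partition({1}, {2}, {3})
        assert all(len(v.regions[k]) == 0 for k in ("110", "101", "011",
                                                    "111"))

    def test_regions_partition_the_union(self):
        rng = np.random.default_rng(3)
        sets = [set(rng.integers(0, 50, 20).tolist()) for _ in range(3)]
        v = venn_partition(*sets)
        regions = list(v.regions.values())
        union = set().union(*sets)
        assert v.union() == union
        assert sum(len(r) for r in regions) == len(union)
        for i, r in enumerate(regions):
            for q in regions[i + 1:]:
                assert not (r & q)

    def test_sympatric_subset_pattern(self):
        # every sympatrically diverged site also diverges in both
        # allopatric comparisons -> the "AB only" region is empty
        ab = {1, 2}
        ra = {1, 2, 3}
        rb = {1, 2, 4}
        v = venn_partition(ab, ra, rb)
        assert v.regions["100"] == set()
        assert v.focal_unique == ab & rb


class TestNeiNJ:
    def test_identical_individuals_distance_zero(self):
        gm = _matrix([[0, 1, 2, 1]] * 2 + [[2, 1, 0, 0]] * 2,
                     ["X", "X", "Y", "Y"])
        D, ids = nei_distance_matrix(gm)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] > 0

    def test_disjoint_pair_is_error(self):
        geno = np.array([[1, -1], [-1, 1], [0, 1], [1, 0]], dtype=np.int8)
        gm = _matrix(geno, ["X", "X", "Y", "Y"])
        with pytest.raises(ValueError, match="i0.*i1"):
            nei_distance_matrix(gm)

    def test_nj_recovers_additive_four_taxon_split(self):
        # additive distances with split {A,B}|{C,D}
        import skbio

        D = np.array([
            [0.0, 0.3, 1.1, 1.2],
            [0.3, 0.0, 1.2, 1.3],
            [1.1, 1.2, 0.0, 0.5],
            [1.2, 1.3, 0.5, 0.0]])
        newick = _nj_newick(D, ["A", "B", "C", "D"])
        tree = skbio.TreeNode.read(io.StringIO(newick))
        # the unique internal edge separates {A,B} from {C,D}
        sides = [frozenset(t.name for t in n.tips()) for n in tree.non_tips()]
        assert any(s in ({"A", "B"}, {"C", "D"}) for s in map(set, sides))

    def test_diverged_groups_get_full_bootstrap_support(self):
        """Two simulated groups at high F_ST: the split is supported."""
        from ghostflow import SampleConfig, ScenarioParams, simulate_snps

        p = ScenarioParams(scenario="CI", N_A=2000, N_B=2000, N_anc=1.0,
                           T_div=60000)
        from ghostflow.divergence import _canon_split

        hits = 0
        for s in range(5):
            gm = simulate_snps(p, SampleConfig(n_A=5, n_B=5, n_snps=300),
                               seed=900 + s)
            newick, support = nei_nj_tree(gm, n_boot=60, seed=s)
            taxa = frozenset(gm.individuals["id"])
            split = _canon_split(
                frozenset(gm.individuals.loc[
                    gm.individuals["group"] == "TaiB", "id"]), taxa)
            if support.get(split, 0.0) == 1.0:
                hits += 1
        assert hits >= 4


class TestFstClustering:
    def test_exchangeable_units_star_matrix(self):
        # three units drawn from one panmictic pool are exchangeable:
        # all pairwise F_ST near zero, dendrogram essentially star-like
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 200)
        geno = rng.binomial(2, p, size=(30, 200)).astype(np.int8)
        gm = _matrix(geno, ["X"] * 10 + ["Y"] * 10 + ["Z"] * 10)
        M, Z, newick = fst_matrix_and_clustering(gm, ["X", "Y", "Z"])
        off = M.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05
        assert np.allclose(M, M.T, atol=1e-12)
        assert newick.count("(") == 2

    def test_outlier_unit_joins_last(self):
        from ghostflow import SampleConfig, ScenarioParams, simulate_snps

        # TaiB strongly diverged from TaiA; split TaiA into two pseudo-units
        p = ScenarioParams(scenario="CI", N_A=5000, N_B=5000, N_anc=1.0,
                           T_div=150000)
        gm = simulate_snps(p, SampleConfig(n_A=10, n_B=5, n_snps=400),
                           seed=31)
        labels = (["A1"] * 5 + ["A2"] * 5 + ["B"] * 5)
        gm.individuals["group"] = labels
        M, Z, _ = fst_matrix_and_clustering(gm, ["A1", "A2", "B"])
        # the last merge (root) attaches the diverged unit
        merged_last = int(Z[-1, 0]), int(Z[-1, 1])
        assert 2 in merged_last or 4 in merged_last  # index 2 = B or its node
        assert M.loc["A1", "B"] > 5 * M.loc["A1", "A2"]
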