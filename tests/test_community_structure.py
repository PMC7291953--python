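import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.ordination import pcoa as skbio_pcoa

import ecoassembly as ea
from ecoassembly.community_structure import covariate_distance
from ecoassembly.tables_io import ValidationError, ZotuTable

from conftest import random_table, random_tree
from _oracles import (
    anosim_r_bruteforce,
    bray_curtis_pair,
    mantel_r_bruteforce,
    unweighted_unifrac_pair,
)


def table_from(counts, taxa=None, samples=None):
    counts = np.asarray(counts, dtype=np.int64)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return ZotuTable(pd.DataFrame(counts, index=taxa, columns=samples))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = ea.bray_curtis(table_from([[3, 3], [1, 1]]))
        assert dm.data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = ea.bray_curtis(table_from([[3, 0], [0, 5]]))
        assert dm.data[0, 1] == 1.0

    def test_direct_formula(self):
        dm = ea.bray_curtis(table_from([[1, 3], [2, 2], [3, 1]]))
        assert dm.data[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValidationError, match="s1"):
            ea.bray_curtis(table_from([[1, 0], [1, 0]]))

    def test_matches_bruteforce_on_random_tables(self, rng):
        for _ in range(10):
            table = random_table(rng, n_taxa=7, n_samples=5)
            dm = ea.bray_curtis(table)
            X = table.matrix
            for a in range(5):
                for b in range(a + 1, 5):
                    assert dm.data[a, b] == pytest.approx(
                        bray_curtis_pair(X[:, a], X[:, b]), abs=1e-10
                    )


class TestUnweightedUnifrac:
    def test_identical_presence_zero(self, small_tree):
        dm = ea.unweighted_unifrac(
            table_from([[1, 9], [2, 1], [0, 0]], taxa=list("ABC")),
            small_tree,
        )
        assert dm.data[0, 1] == pytest.approx(0.0)

    def test_no_shared_lineage_gives_one(self):
        # effectively a star: unit tip branches, zero-length root edges
        from skbio import TreeNode
        star = TreeNode.read(["((A:1,B:1):0,(C:1,D:1):0);"])
        dm = ea.unweighted_unifrac(
            table_from([[1, 0], [1, 0], [0, 1], [0, 1]], taxa=list("ABCD")),
            star,
        )
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_hand_enumerated_example(self, small_tree):
        dm = ea.unweighted_unifrac(
            table_from([[1, 0], [0, 1], [0, 0]], taxa=list("ABC")),
            small_tree,
        )
        assert dm.data[0, 1] == pytest.approx(2 / 3)

    def test_matches_bruteforce_on_random_trees(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 10))
            tree = random_tree(rng, n)
            taxa = [t.name for t in tree.tips()]
            table = random_table(rng, n_taxa=n, n_samples=4)
            table = ZotuTable(
                table.counts.set_axis(taxa, axis=0)
            )
            dm = ea.unweighted_unifrac(table, tree.copy())
            mat = table.matrix
            for a in range(4):
                for b in range(a + 1, 4):
                    pa = [t for t, c in zip(taxa, mat[:, a]) if c > 0]
                    pb = [t for t, c in zip(taxa, mat[:, b]) if c > 0]
                    assert dm.data[a, b] == pytest.approx(
                        unweighted_unifrac_pair(pa, pb, tree), abs=1e-10
                    )


class TestPCoA:
    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(8, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(8)])
        res = ea.pcoa(dm)
        rec = squareform(pdist(res.coordinates.to_numpy()[:, :2]))
        assert np.abs(rec - dm.data).max() < 1e-8

    def test_two_samples_closed_form(self):
        dm = DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["a", "b"])
        res = ea.pcoa(dm)
        assert len(res.eigenvalues) == 1
        coords = np.sort(res.coordinates.to_numpy().ravel())
        assert coords == pytest.approx([-1.5, 1.5])

    def test_eigenvalue_sum_equals_centered_trace(self, rng):
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        dm = DistanceMatrix(D, ids=[f"s{i}" for i in range(6)])
        res = ea.pcoa(dm)
        J = np.eye(6) - np.ones((6, 6)) / 6
        B = -0.5 * J @ (D**2) @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-8)

    def test_eigenvalues_non_increasing_and_match_skbio(self, rng):
        table = random_table(rng, n_taxa=9, n_samples=6)
        dm = ea.bray_curtis(table)
        res = ea.pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        ref = skbio_pcoa(dm, method="eigh")
        ref_pos = ref.eigvals[ref.eigvals > 1e-10].to_numpy()
        assert res.eigenvalues == pytest.approx(ref_pos, abs=1e-8)

    def test_asymmetric_input_errors(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        dm.data[0, 1] = 0.5  # corrupt after construction
        with pytest.raises(ValidationError):
            ea.pcoa(dm)


class TestNMDS:
    def test_euclidean_input_reaches_near_zero_stress(self, rng):
        pts = rng.normal(size=(10, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(10)])
        res = ea.nmds(dm, k=2, seed=0)
        assert res.stress < 0.01

    def test_stress_history_non_increasing(self, rng):
        table = random_table(rng, n_taxa=10, n_samples=8)
        dm = ea.bray_curtis(table)
        res = ea.nmds(dm, k=2, seed=1)
        hist = np.asarray(res.stress_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_seed_determinism_and_multistart_improvement(self, rng):
        table = random_table(rng, n_taxa=10, n_samples=8)
        dm = ea.bray_curtis(table)
        a = ea.nmds(dm, k=2, seed=5)
        b = ea.nmds(dm, k=2, seed=5)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        few = ea.nmds(dm, k=2, seed=5, n_starts=1)
        many = ea.nmds(dm, k=2, seed=5, n_starts=8)
        assert many.stress <= few.stress + 1e-12


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        d = np.array([
            [0, .1, .9, .8], [.1, 0, .85, .95],
            [.9, .85, 0, .12], [.8, .95, .12, 0],
        ])
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = ea.anosim(dm, {"a": "x", "b": "x", "c": "y", "d": "y"})
        assert res.statistic == pytest.approx(1.0)

    def test_matches_bruteforce_r(self, rng):
        for _ in range(10):
            table = random_table(rng, n_taxa=8, n_samples=6)
            dm = ea.bray_curtis(table)
            labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
            res = ea.anosim(dm, dict(zip(dm.ids, labels)))
            assert res.statistic == pytest.approx(
                anosim_r_bruteforce(dm.data, labels), abs=1e-10
            )

    def test_matches_skbio_statistic(self, rng):
        table = random_table(rng, n_taxa=10, n_samples=8)
        dm = ea.bray_curtis(table)
        labels = ["a"] * 4 + ["b"] * 4
        mine = ea.anosim(dm, dict(zip(dm.ids, labels)))
        ref = skbio_anosim(dm, grouping=list(labels), permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"],
                                               abs=1e-10)

    def test_null_r_centred_on_zero(self, rng):
        """Random labels: mean R over 500 label draws ~ 0 within 3 SE."""
        table = random_table(rng, n_taxa=10, n_samples=8)
        dm = ea.bray_curtis(table)
        stats = []
        for _ in range(500):
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            stats.append(
                ea.anosim(dm, dict(zip(dm.ids, labels)),
                          n_permutations=1, exact=False, seed=0).statistic
            )
        se = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert abs(np.mean(stats)) <= 3 * se

    def test_singleton_group_errors(self, rng):
        table = random_table(rng, n_taxa=5, n_samples=3)
        dm = ea.bray_curtis(table)
        with pytest.raises(ValidationError):
            ea.anosim(dm, dict(zip(dm.ids, ["a", "a", "b"])))


class TestMantel:
    def test_proportional_matrices_give_r_one(self, rng):
        table = random_table(rng, n_taxa=6, n_samples=5)
        dm = ea.bray_curtis(table)
        dm2 = DistanceMatrix(2.5 * dm.data, ids=dm.ids)
        res = ea.mantel(dm, dm2)
        assert res.statistic == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_bruteforce_r_and_skbio(self, rng):
        for _ in range(5):
            t1 = random_table(rng, n_taxa=7, n_samples=6)
            t2 = random_table(rng, n_taxa=7, n_samples=6)
            d1 = ea.bray_curtis(t1)
            d2 = DistanceMatrix(ea.bray_curtis(t2).data, ids=d1.ids)
            res = ea.mantel(d1, d2)
            assert res.statistic == pytest.approx(
                mantel_r_bruteforce(d1.data, d2.data), abs=1e-10
            )
            ref_r, _, _ = skbio_mantel(d1, d2, permutations=0)
            assert res.statistic == pytest.approx(ref_r, abs=1e-10)

    def test_null_r_centred_on_zero(self, rng):
        stats = []
        for _ in range(500):
            d1 = squareform(rng.random(15))
            d2 = squareform(rng.random(15))
            res = ea.mantel(
                DistanceMatrix(d1, ids=list("abcdef")),
                DistanceMatrix(d2, ids=list("abcdef")),
                n_permutations=1, exact=False, seed=0,
            )
            stats.append(res.statistic)
        se = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert abs(np.mean(stats)) <= 3 * se

    def test_size_mismatch_errors(self, rng):
        d1 = DistanceMatrix(squareform(rng.random(3)), ids=list("abc"))
        d2 = DistanceMatrix(squareform(rng.random(6)), ids=list("abcd"))
        with pytest.raises(ValidationError):
            ea.mantel(d1, d2)

    def test_spearman_option(self, rng):
        table = random_table(rng, n_taxa=6, n_samples=5)
        dm = ea.bray_curtis(table)
        # monotone transform: spearman r stays 1
        dm2 = DistanceMatrix(dm.data**3, ids=dm.ids)
        res = ea.mantel(dm, dm2, method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_covariate_distance_helper(self):
        vals = pd.Series({"a": 1.0, "b": 3.0, "c": 6.0})
        dm = covariate_distance(vals)
        assert dm["a", "c"] == pytest.approx(5.0)


class TestSimper:
    def test_absent_taxon_contributes_zero(self):
        table = table_from([[4, 2], [0, 0]], samples=["x", "y"])
        rec, _ = ea.simper(table, {"x": "A", "y": "B"})
        assert rec.loc["t1", "average_contribution"] == 0.0

    def test_decomposition_identity(self, rng):
        """Sum of per-taxon average contributions equals the average
        between-group Bray-Curtis dissimilarity."""
        for _ in range(5):
            table = random_table(rng, n_taxa=9, n_samples=6)
            labels = dict(zip(table.sample_ids,
                              ["A", "A", "A", "B", "B", "B"]))
            rec, overall = ea.simper(table, labels)
            dm = ea.bray_curtis(table)
            between = [
                dm[i, j]
                for i in table.sample_ids for j in table.sample_ids
                if labels[i] == "A" and labels[j] == "B"
            ]
            assert rec["average_contribution"].sum() == pytest.approx(
                overall, abs=1e-12
            )
            assert overall == pytest.approx(np.mean(between), abs=1e-10)
            assert rec["percent_contribution"].sum() == pytest.approx(
                100.0, abs=1e-9
            )

    def test_two_taxon_example_splits_evenly(self):
        table = table_from([[4, 0], [0, 4]], samples=["x", "y"])
        rec, overall = ea.simper(table, {"x": "A", "y": "B"})
        assert overall == pytest.approx(1.0)
        assert rec["percent_contribution"].tolist() == [50.0, 50.0]

    def test_sorted_by_decreasing_contribution(self, rng):
        table = random_table(rng, n_taxa=10, n_samples=4)
        rec, _ = ea.simper(
            table, dict(zip(table.sample_ids, ["A", "A", "B", "B"]))
        )
        contrib = rec["average_contribution"].to_numpy()
        assert (np.diff(contrib) <= 1e-15).all()
        assert rec["cumulative_percent"].iloc[-1] == pytest.approx(100.0)

    def test_empty_group_errors(self, rng):
        table = random_table(rng, n_taxa=5, n_samples=2)
        with pytest.raises(ValidationError):
            ea.simper(table, dict(zip(table.sample_ids, ["A", "A"])),
                      group_a="A", group_b="B")


class TestHabitatStructureDetection:
    def test_anosim_detects_habitat_selection(self):
        """Selection scenarios with distinct habitat optima: ANOSIM on
        habitat labels gives R > 0.5 at p <= 0.001, across 500 scenarios."""
        from ecoassembly.synthetic_community import (
            ScenarioConfig,
            simulate_scenario,
        )

        for seed in range(500):
            cfg = ScenarioConfig(regime="selection", n_taxa=40,
                                 n_samples_per_group=8, depth_mean=1000,
                                 seed=seed)
            table, _, meta, _ = simulate_scenario(cfg)
            dm = ea.bray_curtis(table)
            res = ea.anosim(dm, meta.loc[list(dm.ids), "habitat"],
                            n_permutations=9999, exact=False, seed=seed)
            assert res.statistic > 0.5, f"seed {seed}: R={res.statistic}"
            assert res.p_value <= 0.001, f"seed {seed}: p={res.p_value}"

    def test_salinity_outranks_uncorrelated_covariate_in_mantel(self):
        """On habitat-structured communities, the salinity Mantel r^2
        exceeds that of an uncorrelated covariate in >=95% of 200 seeds."""
        from ecoassembly.synthetic_community import (
            ScenarioConfig,
            simulate_scenario,
        )

        rng = np.random.default_rng(1)
        wins = 0
        for seed in range(200):
            cfg = ScenarioConfig(regime="selection", n_taxa=40,
                                 n_samples_per_group=5, depth_mean=1000,
                                 seed=seed)
            table, _, meta, _ = simulate_scenario(cfg)
            dm = ea.bray_curtis(table)
            sal = covariate_distance(meta["salinity"], ids=dm.ids)
            noise = pd.Series(rng.normal(size=len(dm.ids)),
                              index=list(dm.ids))
            r_sal = ea.mantel(sal, dm, n_permutations=1,
                              exact=False).r_squared
            r_noise = ea.mantel(covariate_distance(noise), dm,
                                n_permutations=1, exact=False).r_squared
            wins += r_sal > r_noise
        assert wins >= 190


class TestSharedTaxa:
    def test_identical_group_tables_all_shared(self):
        table = table_from([[1, 1], [2, 2]], samples=["x", "y"])
        regions = ea.shared_taxa(table, {"x": "A", "y": "B"})
        assert regions == {("A", "B"): 2}

    def test_disjoint_supports_no_shared(self):
        table = table_from([[1, 0], [0, 2]], samples=["x", "y"])
        regions = ea.shared_taxa(table, {"x": "A", "y": "B"})
        assert regions.get(("A", "B"), 0) == 0
        assert regions[("A",)] == 1 and regions[("B",)] == 1

    def test_set_arithmetic_example(self):
        # group A taxa {1,2,3}, group B {2,3,4}
        table = table_from(
            [[1, 0], [1, 1], [1, 1], [0, 1]], samples=["x", "y"]
        )
        regions = ea.shared_taxa(table, {"x": "A", "y": "B"})
        assert regions[("A",)] == 1
        assert regions[("B",)] == 1
        assert regions[("A", "B")] == 2

    def test_counts_sum_to_observed_taxa(self, rng):
        table = random_table(rng, n_taxa=12, n_samples=6)
        labels = dict(zip(table.sample_ids, ["A", "A", "B", "B", "C", "C"]))
        regions = ea.shared_taxa(table, labels)
        observed = (table.matrix.sum(axis=1) > 0).sum()
        assert sum(regions.values()) == observed
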