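import numpy as np
import pytest

from retroprev import pgls, simulate
from retroprev.benchmarks import brute_force_closest, brute_force_genic_count
from retroprev.proximity import closest_distances, genic_insertion_count
from retroprev.repeats import count_active


class TestTree:
    def test_two_taxa_cherry_equal_branches(self):
        tree = simulate.simulate_tree(2, seed=0)
        lengths = [l.edge.length for l in tree.leaf_node_iter()]
        assert len(lengths) == 2
        assert lengths[0] == pytest.approx(lengths[1])

    @pytest.mark.parametrize("n", [2, 5, 37])
    def test_ultrametric_unit_depth(self, n):
        cov = pgls.vcv_from_tree(simulate.simulate_tree(n, seed=3))
        d = np.diag(cov.C)
        assert np.ptp(d) < 1e-9
        assert d[0] == pytest.approx(1.0)

    def test_seed_determinism(self):
        a = simulate.simulate_tree(20, seed=9).as_string(schema="newick")
        b = simulate.simulate_tree(20, seed=9).as_string(schema="newick")
        c = simulate.simulate_tree(20, seed=10).as_string(schema="newick")
        assert a == b and a != c

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate.simulate_tree(1, seed=0)


class TestTraits:
    def test_degenerate_noise_returns_mean_exactly(self, yule_cov_50, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = simulate.simulate_traits(yule_cov_50.C * 0, 1.0, 0.0, [1.0, 2.0], X, None, seed=1)
        assert np.array_equal(y, X @ [1.0, 2.0])

    def test_empirical_covariance_matches_target(self):
        tree = simulate.simulate_tree(5, seed=4)
        C = pgls.vcv_from_tree(tree).C
        lam, s2 = 0.7, 2.0
        w = np.full(5, 0.5)
        target = s2 * pgls.lambda_transform(C, lam) + np.diag(w**2)
        X = np.ones((5, 1))
        draws = np.stack([
            simulate.simulate_traits(C, lam, s2, [0.0], X, w, seed=i)
            for i in range(5000)
        ])
        emp = np.cov(draws.T)
        assert np.abs(emp - target).max() <= 0.05 * np.abs(target).max()

    def test_lambda_zero_kills_offdiagonal_covariance(self):
        tree = simulate.simulate_tree(5, seed=4)
        C = pgls.vcv_from_tree(tree).C
        X = np.ones((5, 1))
        draws = np.stack([
            simulate.simulate_traits(C, 0.0, 1.0, [0.0], X, None, seed=i)
            for i in range(5000)
        ])
        emp = np.cov(draws.T)
        off = emp[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.08


class TestNecropsies:
    def test_prevalence_extremes(self):
        neo, mal = simulate.simulate_necropsies([0.0, 1.0], [50, 50], seed=0,
                                                malignant_fraction=1.0)
        assert neo[0] == 0 and neo[1] == 50
        assert mal[0] == 0 and mal[1] == 50

    def test_binomial_concentration(self):
        neo, _ = simulate.simulate_necropsies([0.25], [10_000], seed=1)
        assert abs(neo[0] / 10_000 - 0.25) < 0.02

    def test_count_nesting_holds(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 40)
        n = rng.integers(1, 200, 40)
        neo, mal = simulate.simulate_necropsies(p, n, seed=3, malignant_fraction=0.4)
        assert np.all(mal <= neo) and np.all(neo <= n)

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            simulate.simulate_necropsies([1.2], [10], seed=0)


class TestLandscape:
    def test_zero_active_fraction_yields_zero_counts(self):
        reps, _, truth = simulate.simulate_repeat_landscape(
            genome_length=400_000, n_genes=10, n_l1=20, n_sine=30,
            active_frac_l1=0.0, active_frac_sine=0.0, seed=5,
        )
        counts = count_active(reps, "sp")
        assert counts.n_combined == 0 == truth.n_active_l1 + truth.n_active_sine

    @pytest.mark.parametrize("seed", range(8))
    def test_pipeline_counts_equal_truth(self, seed):
        reps, genes, truth = simulate.simulate_repeat_landscape(
            genome_length=600_000, n_genes=20, n_l1=40, n_sine=60,
            active_frac_l1=0.4, active_frac_sine=0.25, seed=seed,
        )
        counts = count_active(reps, "sp")
        assert counts.n_active_l1 == truth.n_active_l1
        assert counts.n_active_sine == truth.n_active_sine

    def test_truth_distances_match_closest_distance(self):
        reps, genes, truth = simulate.simulate_repeat_landscape(seed=11)
        from retroprev.repeats import is_active_l1, is_active_sine

        active = [
            r for r in reps
            if (r.superfamily == "L1" and is_active_l1(r))
            or (r.superfamily == "SINE" and is_active_sine(r))
        ]
        dists, n_skipped = closest_distances(active, genes)
        assert list(dists) == list(truth.distances)
        assert genic_insertion_count(active, genes) == truth.genic_insertions
        assert genic_insertion_count(active, genes) == brute_force_genic_count(active, genes)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_repeat_landscape(genome_length=50_000, n_chroms=1, seed=0)


class TestStudy:
    def test_study_is_seed_deterministic(self, tmp_path):
        t1 = simulate.simulate_study(tmp_path / "a", seed=5, n_species=8,
                                     landscape_kwargs={"genome_length": 400_000, "n_genes": 10})
        t2 = simulate.simulate_study(tmp_path / "b", seed=5, n_species=8,
                                     landscape_kwargs={"genome_length": 400_000, "n_genes": 10})
        assert (tmp_path / "a" / "cohort.tsv").read_text() == (
            tmp_path / "b" / "cohort.tsv"
        ).read_text()
        assert (tmp_path / "a" / "tree.nwk").read_text() == (
            tmp_path / "b" / "tree.nwk"
        ).read_text()
        assert t1.extras["truth_counts"] == t2.extras["truth_counts"]

    def test_study_emits_complete_file_set(self, tmp_path):
        truth = simulate.simulate_study(tmp_path, seed=2, n_species=6,
                                        landscape_kwargs={"genome_length": 400_000, "n_genes": 10})
        for name in ("tree.nwk", "cohort.tsv", "config.yaml", "Orthogroups.tsv",
                     "Orthogroups.GeneCount.tsv", "cancer_genes.tsv", "cgo_flags.tsv"):
            assert (tmp_path / name).exists()
        species = truth.extras["species"]
        assert len(species) == 6
        for sp in species:
            assert (tmp_path / "repeats" / f"{sp}.bed").exists()
            assert (tmp_path / "genes" / f"{sp}.bed").exists()
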