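"""Consensus clustering: consensus matrix semantics, PAC, reference null,
k selection, subpopulation labeling and population statistics."""

import numpy as np
import pytest

from prism_ms import WorkflowError
from prism_ms.m3c import (
    HOMOGENEOUS,
    M3C,
    M3CConfig,
    assign_subpopulations,
    consensus_cluster,
    pac_score,
    population_statistics,
    run_m3c,
    simulate_reference,
)

FAST = dict(max_k=4, real_iterations=25, reference_iterations=100, seed=42)


def two_point_masses(n_per=20):
    return np.concatenate([np.zeros(n_per), np.full(n_per, 10.0)])


class TestConsensusCluster:
    def test_separated_point_masses_consensus_binary(self):
        values = two_point_masses()
        c = consensus_cluster(values, k=2, iterations=50, rng=0)
        within = c[:20, :20]
        between = c[:20, 20:]
        assert np.all(within[within > 0] == 1.0) or np.allclose(within, 1.0)
        np.testing.assert_allclose(between, 0.0)
        # any sane clustering separates them every co-sampled iteration
        assert np.all((within == 1.0) | (within == 0.0))

    def test_full_resample_deterministic_entries_binary(self, rng):
        values = rng.normal(size=30)
        c = consensus_cluster(values, k=3, iterations=20, resample_fraction=1.0, rng=1)
        assert set(np.round(np.unique(c), 12)) <= {0.0, 1.0}

    def test_symmetry_and_unit_diagonal(self, rng):
        c = consensus_cluster(rng.normal(size=(25, 2)), k=3, iterations=30, rng=2)
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c.min() >= 0 and c.max() <= 1

    def test_k_larger_than_objects_refused(self):
        with pytest.raises(WorkflowError, match="exceeds"):
            consensus_cluster(np.arange(5.0), k=6, rng=0)


class TestPac:
    def test_binary_consensus_has_zero_pac(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 1.0
        assert pac_score(c) == 0.0

    def test_all_ambiguous_has_pac_one(self):
        c = np.full((5, 5), 0.5)
        np.fill_diagonal(c, 1.0)
        assert pac_score(c) == 1.0

    def test_matches_double_loop_oracle(self, rng):
        c = rng.uniform(size=(30, 30))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        n_amb = n_pairs = 0
        for i in range(30):
            for j in range(i + 1, 30):
                n_pairs += 1
                n_amb += 0.1 < c[i, j] < 0.9
        assert pac_score(c, 0.1, 0.9) == pytest.approx(n_amb / n_pairs)

    def test_degenerate_matrix_refused(self):
        with pytest.raises(WorkflowError):
            pac_score(np.array([[1.0]]))


class TestSimulateReference:
    def test_univariate_moments_preserved(self):
        rng = np.random.default_rng(0)
        values = rng.normal(3.0, 2.0, 10_000)
        ref = simulate_reference(values, rng=1)
        assert ref.shape == (10_000, 1)
        assert ref.mean() == pytest.approx(values.mean(), abs=0.1)
        assert ref.std() == pytest.approx(values.std(), abs=0.1)

    def test_multivariate_covariance_scale_preserved(self):
        rng = np.random.default_rng(0)
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        values = rng.multivariate_normal([0, 0], cov, size=5000)
        ref = simulate_reference(values, rng=1)
        np.testing.assert_allclose(np.cov(ref, rowvar=False), cov, atol=0.15)

    def test_bimodal_input_yields_less_stable_reference(self):
        """The null erases the two modes: real data cluster far more
        stably at k=2 than its reference draw."""
        values = two_point_masses(25) + np.random.default_rng(5).normal(0, 0.5, 50)
        ref = simulate_reference(values, rng=6).ravel()
        pac_real = pac_score(consensus_cluster(values, 2, iterations=40, rng=7))
        pac_ref = pac_score(consensus_cluster(ref, 2, iterations=40, rng=8))
        assert pac_ref > pac_real + 0.1

    def test_fixed_seed_reproducible(self):
        values = np.arange(20.0)
        np.testing.assert_array_equal(simulate_reference(values, rng=3),
                                      simulate_reference(values, rng=3))

    def test_permutation_null_preserves_marginals(self, rng):
        values = rng.normal(size=(50, 3))
        ref = simulate_reference(values, rng=4, method="permute")
        for j in range(3):
            np.testing.assert_allclose(np.sort(ref[:, j]), np.sort(values[:, j]))


class TestRunM3c:
    def test_two_population_mixture_selects_k2(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        res = run_m3c(values, M3CConfig(**FAST))
        assert res.selected_k == 2
        assert res.per_k[2].p_value < 0.01
        assert res.per_k[2].rcsi > 0

    def test_single_gaussian_is_homogeneous(self):
        values = np.random.default_rng(7).normal(size=80)
        res = run_m3c(values, M3CConfig(**FAST))
        assert res.is_homogeneous
        assert res.assignments is None

    def test_three_separated_clusters_select_k3(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 1.0, 35), rng.normal(4, 1.0, 35),
                                 rng.normal(8, 1.0, 35)])
        res = run_m3c(values, M3CConfig(**FAST))
        assert res.selected_k == 3

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(4, 1, 30)])
        cfg = M3CConfig(max_k=3, real_iterations=15, reference_iterations=15, seed=9)
        a, b = run_m3c(values, cfg), run_m3c(values, cfg)
        assert a.selected_k == b.selected_k
        for k in a.per_k:
            np.testing.assert_array_equal(a.per_k[k].consensus, b.per_k[k].consensus)
            np.testing.assert_array_equal(a.per_k[k].pac_reference,
                                          b.per_k[k].pac_reference)

    def test_selected_k_invariant_to_object_order(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        cfg = M3CConfig(max_k=3, real_iterations=20, reference_iterations=20, seed=42)
        base = run_m3c(values, cfg)
        perm = rng.permutation(len(values))
        shuffled = run_m3c(values[perm], cfg)
        assert base.selected_k == shuffled.selected_k
        if base.assignments is not None:
            np.testing.assert_array_equal(shuffled.assignments, base.assignments[perm])

    def test_p_value_never_zero(self):
        values = two_point_masses(15)
        res = run_m3c(values, M3CConfig(max_k=3, real_iterations=12,
                                        reference_iterations=12, seed=0))
        for d in res.per_k.values():
            assert 0 < d.p_value <= 1

    def test_too_few_objects_refused(self):
        with pytest.raises(WorkflowError, match="objects"):
            M3C(np.arange(5.0), M3CConfig(max_k=8))

    def test_summary_table_shape(self):
        values = two_point_masses(15)
        res = run_m3c(values, M3CConfig(max_k=3, real_iterations=12,
                                        reference_iterations=12, seed=0))
        table = res.summary()
        assert list(table.index) == [2, 3]
        assert {"pac_real", "rcsi", "p_value", "selected"} <= set(table.columns)

    def test_majority_vote_across_repeats(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(6, 1, 30)])
        cfg = M3CConfig(max_k=3, real_iterations=15, reference_iterations=100,
                        seed=42, repeats=3)
        res = run_m3c(values, cfg)
        assert res.repeat_votes is not None and len(res.repeat_votes) == 3
        assert res.selected_k == 2

    def test_type_one_error_controlled_under_null(self):
        """Single-Gaussian data should rarely be called structured."""
        cfg = M3CConfig(max_k=3, real_iterations=15, reference_iterations=100, seed=0)
        false_calls = 0
        reps = 20
        for rep in range(reps):
            values = np.random.default_rng(100 + rep).normal(size=50)
            cfg_rep = M3CConfig(**{**cfg.__dict__, "seed": rep})
            res = run_m3c(values, cfg_rep)
            false_calls += not res.is_homogeneous
        assert false_calls / reps <= 0.1


class TestLabeling:
    def _fit(self, values, seed=42):
        return run_m3c(values, M3CConfig(max_k=3, real_iterations=20,
                                         reference_iterations=100, seed=seed))

    def test_homogeneous_marker_labels_all_negative(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(size=60)
        res = self._fit(flat)
        labels = assign_subpopulations({"Ita": flat}, {"Ita": res})
        assert all(lab == "Ita-" for lab in labels.labels)
        assert labels.omitted.all()

    def test_positive_cluster_has_higher_mean(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(6, 1, 40)])
        res = self._fit(values)
        labels = assign_subpopulations({"Ita": values}, {"Ita": res})
        pos = labels.positive["Ita"]
        assert values[pos].mean() > values[~pos].mean()

    def test_anticorrelated_markers_recover_planted_labels(self):
        """Activation pattern: marker up in activated cells, quiescence
        marker down; planted labels recovered >=95%."""
        rng = np.random.default_rng(2)
        n = 120
        activated = np.arange(n) < 60
        ita = np.where(activated, 5.0, 0.0) + rng.normal(0, 0.7, n)
        taur = np.where(activated, 0.0, 5.0) + rng.normal(0, 0.7, n)
        results = {"Ita": self._fit(ita), "Taur": self._fit(taur)}
        labels = assign_subpopulations({"Ita": ita, "Taur": taur}, results)
        want = np.where(activated, "Ita+Taur-", "Ita-Taur+")
        agreement = np.mean(np.asarray(labels.labels) == want)
        assert agreement >= 0.95
        double_pos = np.mean([lab == "Ita+Taur+" for lab in labels.labels])
        assert double_pos < 0.05

    def test_k_above_two_refused_for_labeling(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 1.0, 35), rng.normal(4, 1.0, 35),
                                 rng.normal(8, 1.0, 35)])
        res = run_m3c(values, M3CConfig(max_k=4, real_iterations=25,
                                        reference_iterations=100, seed=42))
        assert res.selected_k == 3
        with pytest.raises(WorkflowError, match="binary"):
            assign_subpopulations({"X": values}, {"X": res})


class TestPopulationStatistics:
    def _labels(self, labs, omitted=None):
        from prism_ms.m3c import SubpopulationLabels
        labs = list(labs)
        n = len(labs)
        omitted = np.zeros(n, bool) if omitted is None else np.asarray(omitted)
        return SubpopulationLabels(["X"], {"X": ~omitted}, labs, omitted)

    def test_single_label_fraction_one(self):
        stats = population_statistics(self._labels(["X+"] * 5), ["c"] * 5)
        assert stats.loc["c", "X+"] == 1.0

    def test_fractions_sum_to_one_per_condition(self, rng):
        labs = rng.choice(["A+B-", "A-B+", "A+B+"], size=200)
        groups = rng.choice(["veh", "lps"], size=200)
        stats = population_statistics(self._labels(labs), groups)
        np.testing.assert_allclose(stats.sum(axis=1), 1.0)

    def test_omitted_cells_excluded(self):
        labs = ["X+", "X+", "X-", "X-"]
        omitted = [False, False, True, True]
        stats = population_statistics(self._labels(labs, omitted), ["c"] * 4)
        assert stats.loc["c", "X+"] == 1.0
        assert "X-" not in stats.columns

    def test_planted_60_40_recovered(self, rng):
        labs = np.array(["A+"] * 300 + ["B+"] * 200)
        stats = population_statistics(self._labels(labs), ["c"] * 500)
        assert stats.loc["c", "A+"] == pytest.approx(0.6)
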