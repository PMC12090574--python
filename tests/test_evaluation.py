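import itertools

import numpy as np
import pytest

from crossmeth import (CombinationMeanMatrix, ConditionLabels, SampleMatrix,
                       assign_variance_quartiles, compute_combination_means,
                       generate_compendium, individual_to_individual_variability,
                       label_signal_auc, paired_method_comparison,
                       probe_variance_profile, probe_wise_agreement,
                       remove_species_signal, sample_wise_agreement)
from crossmeth.evaluation import pairwise_label_scores


def combos_from(values, keys, probes=None):
    probes = probes or [f"p{i}" for i in range(np.asarray(values).shape[1])]
    return CombinationMeanMatrix(np.asarray(values, dtype=float),
                                 keys=keys, probe_ids=probes)


class TestSampleWiseAgreement:
    def test_identity_gives_perfect_scores(self):
        obs = combos_from([[0.1, 0.5, 0.9], [0.3, 0.2, 0.6]],
                          [("a", "x"), ("b", "y")])
        rep = sample_wise_agreement(obs, obs)
        assert np.allclose(rep.per_sample["r"], 1.0)
        assert (rep.per_sample["mse"] == 0.0).all()

    def test_anticorrelation(self):
        obs = combos_from([[0.1, 0.5, 0.9]], [("a", "x")])
        imp = combos_from([[0.9, 0.5, 0.1]], [("a", "x")])
        rep = sample_wise_agreement(imp, obs)
        assert rep.per_sample["r"][0] == pytest.approx(-1.0)

    def test_known_mse(self):
        obs = combos_from([[0.2, 0.4]], [("a", "x")])
        imp = combos_from([[0.3, 0.5]], [("a", "x")])
        rep = sample_wise_agreement(imp, obs)
        assert rep.per_sample["mse"][0] == pytest.approx(0.01)

    def test_constant_row_flagged_but_mse_kept(self):
        obs = combos_from([[0.5, 0.5], [0.1, 0.9]], [("a", "x"), ("b", "y")])
        imp = combos_from([[0.4, 0.6], [0.2, 0.8]], [("a", "x"), ("b", "y")])
        rep = sample_wise_agreement(imp, obs)
        assert rep.summary["sample_r"]["n_undefined"] == 1
        assert np.isfinite(rep.per_sample["mse"]).all()

    def test_single_probe_errors(self):
        obs = combos_from([[0.5]], [("a", "x")])
        with pytest.raises(ValueError):
            sample_wise_agreement(obs, obs)


class TestProbeWiseAgreement:
    def test_two_point_positive_slope(self):
        obs = combos_from([[0.1], [0.9]], [("a", "x"), ("b", "y")])
        imp = combos_from([[0.2], [0.8]], [("a", "x"), ("b", "y")])
        rep = probe_wise_agreement(imp, obs)
        assert rep.per_probe["r"][0] == pytest.approx(1.0)

    def test_constant_probe_flagged(self):
        obs = combos_from([[0.5, 0.1], [0.5, 0.9]], [("a", "x"), ("b", "y")])
        imp = combos_from([[0.4, 0.2], [0.6, 0.8]], [("a", "x"), ("b", "y")])
        rep = probe_wise_agreement(imp, obs)
        assert rep.summary["probe_r"]["n_undefined"] == 1

    def test_mean_mse_equality_on_complete_grid(self):
        rng = np.random.default_rng(5)
        keys = [(s, t) for s in "abcd" for t in "xyz"]
        obs = combos_from(rng.random((12, 7)), keys)
        imp = combos_from(rng.random((12, 7)), keys)
        sw = sample_wise_agreement(imp, obs)
        pw = probe_wise_agreement(imp, obs)
        assert sw.summary["sample_mse"]["mean"] == pytest.approx(
            pw.summary["probe_mse"]["mean"], abs=1e-12)


class TestVarianceProfile:
    def test_two_combo_population_variance(self):
        matrix = SampleMatrix([[0.2], [0.4]], ["s1", "s2"], ["p1"])
        labels = ConditionLabels(["A", "A"], ["x", "y"])
        prof = probe_variance_profile(matrix, labels)
        assert prof.inter_combination[0] == pytest.approx(0.01)
        assert prof.mean_inter_tissue[0] == pytest.approx(0.01)

    def test_one_species_extreme_tissues(self):
        matrix = SampleMatrix([[0.0], [1.0]], ["s1", "s2"], ["p1"])
        labels = ConditionLabels(["A", "A"], ["x", "y"])
        prof = probe_variance_profile(matrix, labels)
        assert prof.mean_inter_tissue[0] == pytest.approx(0.25)
        assert prof.mean_inter_species is None  # no tissue in >1 species

    def test_constant_probe_all_zero(self):
        matrix = SampleMatrix(np.full((4, 1), 0.3), [f"s{i}" for i in range(4)],
                              ["p1"])
        labels = ConditionLabels(["A", "A", "B", "B"], ["x", "y", "x", "y"])
        prof = probe_variance_profile(matrix, labels)
        assert prof.inter_combination[0] == pytest.approx(0.0, abs=1e-15)
        assert prof.mean_inter_tissue[0] == pytest.approx(0.0, abs=1e-15)
        assert prof.mean_inter_species[0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_nested_loop_oracle(self):
        """Staged variance formulas vs a naive oracle on a random fixture."""
        matrix, labels, _ = generate_compendium(S=5, T=4, M=6, seed=77)
        prof = probe_variance_profile(matrix, labels)
        combos = compute_combination_means(matrix, labels)

        cv = np.var(combos.values, axis=0)  # oracle: inter-combination
        np.testing.assert_allclose(prof.inter_combination, cv, atol=1e-12)

        species = sorted({s for s, _ in combos.keys})
        per_species = []
        for sp in species:
            rows = [combos.values[i] for i, (s, _) in enumerate(combos.keys)
                    if s == sp]
            if len(rows) > 1:
                per_species.append(np.var(np.vstack(rows), axis=0))
        np.testing.assert_allclose(prof.mean_inter_tissue,
                                   np.mean(per_species, axis=0), atol=1e-12)

        tissues = sorted({t for _, t in combos.keys})
        per_tissue = []
        for ti in tissues:
            rows = [combos.values[i] for i, (_, t) in enumerate(combos.keys)
                    if t == ti]
            if len(rows) > 1:
                per_tissue.append(np.var(np.vstack(rows), axis=0))
        np.testing.assert_allclose(prof.mean_inter_species,
                                   np.mean(per_tissue, axis=0), atol=1e-12)


class TestVarianceQuartiles:
    def _profile(self, variances):
        class P:
            probe_ids = [f"p{i}" for i in range(len(variances))]

            def metric(self, name):
                return np.asarray(variances)
        return P()

    def test_even_split(self):
        labels = assign_variance_quartiles(self._profile([1, 2, 3, 4, 5, 6, 7, 8]),
                                           "inter_combination")
        sizes = [list(labels.values()).count(f"Q{q}") for q in range(1, 5)]
        assert sizes == [2, 2, 2, 2]
        assert labels["p0"] == "Q1" and labels["p7"] == "Q4"

    def test_remainder_rule_five_probes(self):
        labels = assign_variance_quartiles(self._profile([5, 1, 4, 2, 3]),
                                           "inter_combination")
        sizes = [list(labels.values()).count(f"Q{q}") for q in range(1, 5)]
        assert sizes == [2, 1, 1, 1]
        assert labels["p1"] == "Q1"  # smallest variance

    def test_all_ties_stable_order(self):
        labels = assign_variance_quartiles(self._profile([1.0] * 6),
                                           "inter_combination")
        sizes = [list(labels.values()).count(f"Q{q}") for q in range(1, 5)]
        assert max(sizes) - min(sizes) <= 1
        assert labels["p0"] == "Q1"  # ties broken by probe id


class TestRemoveSpeciesSignal:
    def test_species_mean_row_becomes_zero(self, toy_matrix):
        matrix, labels = toy_matrix
        combos = compute_combination_means(matrix, labels)
        delta = remove_species_signal(combos, matrix, labels)
        i = combos.keys.index(("human", "blood"))
        np.testing.assert_allclose(delta[i], 0.0, atol=1e-12)
        assert (np.abs(delta) <= 1.0 + 1e-12).all()

    def test_known_subtraction(self):
        training = SampleMatrix([[0.5]], ["s1"], ["p1"])
        labels = ConditionLabels(["A"], ["x"])
        combos = combos_from([[0.7]], [("A", "y")], ["p1"])
        delta = remove_species_signal(combos, training, labels)
        assert delta[0, 0] == pytest.approx(0.2)

    def test_missing_species_errors(self):
        training = SampleMatrix([[0.5]], ["s1"], ["p1"])
        labels = ConditionLabels(["A"], ["x"])
        combos = combos_from([[0.7]], [("B", "y")], ["p1"])
        with pytest.raises(ValueError, match="B"):
            remove_species_signal(combos, training, labels)


class TestLabelSignalAuc:
    def test_perfect_separation(self):
        # same-species rows identical, cross-species rows uncorrelated
        rng = np.random.default_rng(1)
        a = rng.random(10)
        b = rng.random(10)
        combos = combos_from([a, a, b, b],
                             [("A", "x"), ("A", "y"), ("B", "x"), ("B", "y")])
        assert label_signal_auc(combos, "species") == 1.0

    def test_label_independent_scores_give_half(self):
        rng = np.random.default_rng(2)
        row = rng.random(8)
        combos = combos_from([row + 0.001 * i for i in range(4)],
                             [("A", "x"), ("A", "y"), ("B", "x"), ("B", "y")])
        # all pair correlations ~1 (ties): AUC collapses to 0.5
        assert label_signal_auc(combos, "species") == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_mann_whitney(self):
        rng = np.random.default_rng(3)
        combos = combos_from(rng.random((5, 9)),
                             [("A", "x"), ("A", "y"), ("B", "x"), ("B", "z"),
                              ("C", "x")])
        scores, positive = pairwise_label_scores(combos, "species")
        pos = scores[positive]
        neg = scores[~positive]
        wins = sum((p > n) + 0.5 * (p == n)
                   for p, n in itertools.product(pos, neg))
        oracle = wins / (len(pos) * len(neg))
        assert label_signal_auc(combos, "species") == pytest.approx(oracle,
                                                                    abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        combos = combos_from(rng.random((6, 9)),
                             [("A", "x"), ("A", "y"), ("B", "x"), ("B", "y"),
                              ("C", "x"), ("C", "y")])
        auc = label_signal_auc(combos, "tissue")
        scores, positive = pairwise_label_scores(combos, "tissue")
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(positive, np.exp(3 * scores)) == pytest.approx(auc)

    def test_single_class_errors(self):
        combos = combos_from(np.random.default_rng(0).random((2, 5)),
                             [("A", "x"), ("A", "y")])
        with pytest.raises(ValueError):
            label_signal_auc(combos, "species")


class TestPairedComparison:
    def test_uniform_shift_significant(self):
        rng = np.random.default_rng(0)
        b = rng.random(10)
        out = paired_method_comparison(b + 0.1, b)
        assert out["fraction_a_better"] == 1.0
        assert out["p_value"] < 0.05

    def test_equal_scores_flagged(self):
        b = np.linspace(0, 1, 8)
        out = paired_method_comparison(b, b)
        assert out["fraction_a_better"] == 0.0
        assert np.isnan(out["p_value"])

    def test_matches_exhaustive_signed_rank_enumeration(self):
        a = np.array([0.31, 0.55, 0.42, 0.77, 0.60, 0.18, 0.93, 0.12])
        b = np.array([0.25, 0.60, 0.40, 0.70, 0.52, 0.30, 0.90, 0.20])
        out = paired_method_comparison(a, b)
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        stat = min(w_plus, w_minus)
        # exhaustive null: all 2^8 sign assignments
        n = len(d)
        null = []
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for r, s in zip(sorted(ranks), signs) if s)
            null.append(min(w, ranks.sum() - w))
        p_oracle = sum(x <= stat for x in null) / len(null)
        assert out["statistic"] == pytest.approx(stat, abs=1e-10)
        assert out["p_value"] == pytest.approx(p_oracle, abs=1e-10)


class TestIndividualVariability:
    def test_identical_individuals_give_unit_correlation(self):
        row = np.linspace(0.1, 0.9, 6)
        matrix = SampleMatrix(np.vstack([row, row]), ["s1", "s2"],
                              [f"p{i}" for i in range(6)])
        labels = ConditionLabels(["A", "A"], ["x", "x"])
        out = individual_to_individual_variability(matrix, labels)
        assert out["mean_pairwise_r"][0] == pytest.approx(1.0)

    def test_three_individuals_average_of_three_pairs(self):
        rng = np.random.default_rng(6)
        vals = rng.random((3, 7))
        matrix = SampleMatrix(vals, ["s1", "s2", "s3"],
                              [f"p{i}" for i in range(7)])
        labels = ConditionLabels(["A"] * 3, ["x"] * 3)
        out = individual_to_individual_variability(matrix, labels)
        oracle = np.mean([np.corrcoef(vals[i], vals[j])[0, 1]
                          for i, j in [(0, 1), (0, 2), (1, 2)]])
        assert out["mean_pairwise_r"][0] == pytest.approx(oracle, abs=1e-12)

    def test_singletons_excluded(self, toy_matrix):
        out = individual_to_individual_variability(*toy_matrix)
        assert set(zip(out["species"], out["tissue"])) == {("horse", "liver")}
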