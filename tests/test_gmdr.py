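"""GMDR scores, cell classification, cross-validation and the screen."""

import numpy as np
import pytest
from sklearn.base import clone

from qtsmap import (
    GmdrScreen,
    PhenotypeTable,
    classify_cells,
    compute_score_residuals,
    evaluate_combo,
    screen,
)
from conftest import make_genotypes


def table(values, envs=1):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    return PhenotypeTable([f"L{k}" for k in range(n)], [f"E{h}" for h in range(values.shape[1])], values)


class TestScores:
    def test_single_env_residuals(self):
        s = compute_score_residuals(table([1.0, 3.0, 5.0, 7.0]))
        assert np.allclose(s.ravel(), [-3, -1, 1, 3])

    def test_scores_sum_to_zero_within_env(self, rng):
        y = table(rng.normal(5, 2, size=(30, 3)))
        s = compute_score_residuals(y)
        assert np.allclose(s.sum(axis=0), 0.0, atol=1e-9)

    def test_constant_phenotype_zero_scores(self):
        s = compute_score_residuals(table([[4.0, 2.0]] * 10))
        assert np.allclose(s, 0.0)

    def test_tiny_environment_rejected(self):
        y = PhenotypeTable(["a", "b"], ["E1", "E2"], np.array([[1.0, 2.0], [3.0, np.nan]]))
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_score_residuals(y)


class TestClassifyCells:
    def test_all_positive_scores_all_high(self, balanced_genotypes):
        labels = classify_cells(np.ones(60), balanced_genotypes, ("m0",))
        assert set(labels.values()) == {"HIGH"}

    def test_one_locus_example(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        G = make_genotypes(X)
        labels = classify_cells(np.array([-3.0, -1.0, 1.0, 3.0]), G, ("m0",))
        assert labels == {(1.0,): "HIGH", (-1.0,): "LOW"}

    def test_absent_genotype_class_not_labeled(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        G = make_genotypes(X)
        labels = classify_cells(np.array([1.0, 2.0, -0.5, 0.25]), G, ("m0",))
        assert (-1.0,) not in labels

    def test_exact_zero_sum_unclassified(self):
        X = np.array([[1.0], [1.0]])
        G = make_genotypes(X)
        labels = classify_cells(np.array([1.0, -1.0]), G, ("m0",))
        assert labels[(1.0,)] == "UNCLASSIFIED"

    def test_environment_specific_cells(self):
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        G = make_genotypes(X)
        scores = np.array([[2.0, -2.0], [1.0, -1.0], [-1.0, 1.0], [-2.0, 2.0]])
        labels = classify_cells(scores, G, ("m0",))
        # effect reverses across environments: cells disagree by environment
        assert labels[(1.0, 0)] == "HIGH" and labels[(1.0, 1)] == "LOW"
        assert labels[(-1.0, 0)] == "LOW" and labels[(-1.0, 1)] == "HIGH"


class TestEvaluateCombo:
    def test_perfect_separator(self, rng):
        n = 40
        x = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        G = make_genotypes(x[:, None])
        scores = x * (1.0 + 0.1 * rng.random(n))
        res = evaluate_combo(scores, G, ("m0",), k_folds=5, seed=0)
        assert res.mean_accuracy == pytest.approx(1.0)
        assert res.consistency == 5

    def test_noise_near_chance(self, rng):
        accs = []
        for draw in range(30):
            X = rng.choice([-1.0, 1.0], size=(200, 1))
            scores = rng.normal(size=200)
            res = evaluate_combo(scores, make_genotypes(X), ("m0",), k_folds=10, seed=draw)
            accs.append(res.mean_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_deterministic_given_seed(self, rng):
        X = rng.choice([-1.0, 1.0], size=(50, 2))
        scores = rng.normal(size=50)
        G = make_genotypes(X)
        a = evaluate_combo(scores, G, ("m0", "m1"), seed=42)
        b = evaluate_combo(scores, G, ("m0", "m1"), seed=42)
        assert a.mean_accuracy == b.mean_accuracy
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies, equal_nan=True)


class TestScreen:
    def test_perfect_marker_selected(self, rng):
        n = 60
        X = rng.choice([-1.0, 1.0], size=(n, 5))
        y = X[:, 3] * 3.0 + rng.normal(0, 0.3, n)
        G = make_genotypes(X)
        cand = screen(G, y, max_order=1, retain_m=1, k_folds=5, seed=0, expand_markers=0)
        assert cand.representatives == ["m3"]
        assert "m3" in cand.markers

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized exhaustive search equals a per-combo oracle on 6 markers."""
        n, p = 50, 6
        X = rng.choice([-1.0, 1.0], size=(n, p))
        signal = X[:, 1] * 1.2 - (X[:, 2] * X[:, 4]) * 0.8
        yv = signal[:, None] + rng.normal(0, 1.0, size=(n, 2))
        y = table(yv)
        G = make_genotypes(X)
        seed = 7
        scores = compute_score_residuals(y)
        for order in (1, 2, 3):
            from itertools import combinations

            oracle = [
                evaluate_combo(scores, G, combo, k_folds=5, seed=seed)
                for combo in combinations(G.marker_ids, order)
            ]
            oracle.sort(
                key=lambda m: (-(m.mean_accuracy if np.isfinite(m.mean_accuracy) else -np.inf),
                               -m.consistency, m.combo)
            )
            got = [
                m
                for m in screen(
                    G, y, max_order=order, retain_m=4, k_folds=5, seed=seed,
                    clump_window_cm=None, expand_markers=0,
                ).models
                if m.order == order
            ]
            for o, g in zip(oracle[:4], got):
                assert o.combo == g.combo
                assert g.mean_accuracy == pytest.approx(o.mean_accuracy, abs=1e-12)
                assert g.consistency == o.consistency

    def test_budget_guard(self, rng):
        X = rng.choice([-1.0, 1.0], size=(30, 60))
        with pytest.raises(ValueError, match="budget"):
            screen(make_genotypes(X), rng.normal(size=30), max_order=3, combo_budget=1000)

    def test_exhaustive_counts(self, rng):
        """The search visits C(p, order) combos per order."""
        import math

        n, p = 40, 7
        X = rng.choice([-1.0, 1.0], size=(n, p))
        y = rng.normal(size=n)
        cand = screen(make_genotypes(X), y, max_order=2, retain_m=10**6,
                      clump_window_cm=None, expand_markers=0, seed=0)
        by_order = {o: sum(1 for m in cand.models if m.order == o) for o in (1, 2)}
        assert by_order == {1: p, 2: math.comb(p, 2)}

    def test_expansion_adds_neighbours(self):
        from qtsmap import GeneticMap, simulate_ril_genotypes, simulate_phenotypes
        from qtsmap import AdditiveTerm, QTSEffectSet

        gmap = GeneticMap.uniform(1, 50, 1.0)
        G = simulate_ril_genotypes(gmap, 100, seed=1)
        truth = QTSEffectSet(additive=[AdditiveTerm("chr1_snp25", 2.0, np.zeros(1))],
                             sigma2_eps=0.5, n_env=1)
        y = simulate_phenotypes(G, truth, seed=1)
        cand = screen(G, y, max_order=1, retain_m=1, seed=0, expand_markers=3)
        rep = cand.representatives[0]
        j = G.marker_index(rep)
        expect = {G.marker_ids[k] for k in range(max(0, j - 3), min(50, j + 4))}
        assert set(cand.markers) == expect


class TestGmdrScreenEstimator:
    def test_fit_transform_selects_markers(self, rng):
        n = 60
        X = rng.choice([-1.0, 1.0], size=(n, 6))
        y = X[:, 2] * 2.0 + rng.normal(0, 0.5, n)
        est = GmdrScreen(max_order=1, retain_m=1, k_folds=5, expand_markers=0, random_state=0)
        est.fit(X, y)
        assert est.support_.sum() == len(est.candidates_.markers)
        reduced = est.transform(X)
        assert reduced.shape == (n, est.support_.sum())

    def test_sklearn_clone_and_params(self):
        est = GmdrScreen(max_order=2, retain_m=3)
        params = est.get_params()
        assert params["retain_m"] == 3
        assert clone(est).get_params() == params
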