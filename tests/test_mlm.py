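"""Scan F statistics, permutation thresholds and the REML term fit."""

import numpy as np
import numpy.linalg as la
import pytest
from scipy import stats

from qtsmap import MixedModelScan, fit_term_model, permutation_threshold, scan

from conftest import make_genotypes


def partial_f(y, X0, block):
    """Classical partial F of adding ``block`` to the regression on ``X0``."""
    X1 = np.column_stack([X0, block])
    r0 = y - X0 @ la.lstsq(X0, y, rcond=None)[0]
    r1 = y - X1 @ la.lstsq(X1, y, rcond=None)[0]
    df1 = block.shape[1] if block.ndim > 1 else 1
    df2 = len(y) - X1.shape[1]
    return ((r0 @ r0 - r1 @ r1) / df1) / ((r1 @ r1) / df2)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(11)
    n, p = 40, 8
    X = rng.choice([-1.0, 1.0], size=(n, p))
    beta = np.zeros(p)
    beta[[1, 4]] = [0.9, -0.7]
    y = 2.0 + X @ beta + rng.normal(0, 1, n)
    return make_genotypes(X), y, X


class TestSingleEnvironmentOracle:
    """In one environment every statistic reduces to exact OLS."""

    def test_fit_term_model_equals_partial_f(self, data):
        G, y, X = data
        for j, cof in [(1, ["m0", "m4"]), (4, ["m1"]), (6, [])]:
            fit = fit_term_model(G, y, f"m{j}", cofactors=cof)
            X0 = np.column_stack([np.ones(len(y))] + [X[:, int(c[1])] for c in cof])
            ref = partial_f(y, X0, X[:, j : j + 1])
            assert fit.F == pytest.approx(ref, abs=1e-6)
            assert fit.df2 == len(y) - X0.shape[1] - 1

    def test_scan_equals_cofactor_adjusted_ols(self, data):
        G, y, X = data
        res = scan(G, y, list(G.marker_ids), thresholds={"1d": 4.0, "2d": 8.0},
                   cofactor_window_cm=10.0)
        t = res.table
        row = t[(t.family == "1d") & (t.markers == "m4")].iloc[0]
        cof = [j for j in range(8) if j != 4]  # markers 50 cM apart: all are cofactors
        X0 = np.column_stack([np.ones(len(y))] + [X[:, j] for j in cof])
        ref = partial_f(y, X0, X[:, 4:5])
        assert row["F"] == pytest.approx(ref, rel=1e-9)
        assert row["p"] == pytest.approx(stats.f.sf(ref, 1, row["df2"]), rel=1e-9)

    def test_pair_statistic_matches_manual_partial_f(self, data):
        G, y, X = data
        res = scan(G, y, list(G.marker_ids), thresholds={"1d": 4.0, "2d": 8.0})
        t = res.table
        row = t[(t.family == "2d") & (t.markers == "m1:m4")]
        assert len(row) == 1
        X0 = np.column_stack([np.ones(len(y))] + [X[:, j] for j in range(8)])
        ref = partial_f(y, X0, (X[:, 1] * X[:, 4])[:, None])
        assert row["F"].iloc[0] == pytest.approx(ref, rel=1e-9)


class TestFitTermModel:
    def test_null_p_values_uniform(self):
        """Under the null the single-environment F p-values are U(0,1)."""
        rng = np.random.default_rng(5)
        n = 30
        X = rng.choice([-1.0, 1.0], size=(n, 3))
        G = make_genotypes(X)
        pvals = []
        for _ in range(800):
            y = rng.normal(size=n)
            pvals.append(fit_term_model(G, y, "m0", cofactors=["m1"]).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_marker_rejected(self, rng):
        X = rng.choice([-1.0, 1.0], size=(30, 2))
        X[:, 1] = 1.0
        G = make_genotypes(X)
        with pytest.raises(ValueError, match="zero variance"):
            fit_term_model(G, rng.normal(size=30), "m1")

    def test_term_cannot_be_cofactor(self, rng):
        X = rng.choice([-1.0, 1.0], size=(30, 2))
        with pytest.raises(ValueError, match="cofactor"):
            fit_term_model(make_genotypes(X), rng.normal(size=30), "m0", cofactors=["m0"])

    def test_two_environment_fit_runs_and_df_bounded(self, rng):
        n = 50
        X = rng.choice([-1.0, 1.0], size=(n, 4))
        y = np.column_stack([X[:, 0] * 1.5 + rng.normal(0, 1, n) + 1,
                             X[:, 0] * 0.5 + rng.normal(0, 1, n) - 1])
        fit = fit_term_model(make_genotypes(X), y, "m0", cofactors=["m1"])
        N, p = 2 * n, 1 + 1 + 1
        assert np.isfinite(fit.F) and fit.F > 0
        assert 1.0 <= fit.df2 <= N - p
        assert set(fit.beta) == {"mu", "a[m1]", "a[m0]"}


class TestPermutationThreshold:
    def test_minimum_permutations_enforced(self, balanced_genotypes, rng):
        with pytest.raises(ValueError, match="19"):
            permutation_threshold(
                balanced_genotypes, rng.normal(size=60), ["m0", "m1"], n_permutations=5
            )

    def test_b19_threshold_is_largest_maximum(self, balanced_genotypes, rng):
        """With alpha=0.05 and B=19 the order statistic is the largest maximum."""
        y = rng.normal(size=60)
        thr19 = permutation_threshold(
            balanced_genotypes, y, list(balanced_genotypes.marker_ids[:4]),
            n_permutations=19, alpha=0.05, seed=3, families=("1d",),
        )
        thr50 = permutation_threshold(
            balanced_genotypes, y, list(balanced_genotypes.marker_ids[:4]),
            n_permutations=19, alpha=0.5, seed=3, families=("1d",),
        )
        assert thr19["1d"] >= thr50["1d"]  # 19th vs 10th smallest of the same maxima

    def test_max_statistic_dominates_pointwise_quantile(self, rng):
        n = 50
        X = rng.choice([-1.0, 1.0], size=(n, 6))
        G = make_genotypes(X)
        y = rng.normal(size=n)
        thr = permutation_threshold(G, y, list(G.marker_ids), n_permutations=500,
                                    seed=1, families=("1d",))
        # pointwise 95th percentile F for a single marker under permutation
        from qtsmap._data import as_phenotype_table
        from qtsmap.mlm import _make_engine

        engine, vals = _make_engine(
            G, as_phenotype_table(y, G), list(G.marker_ids), None, 30.0, "auto", 2e5
        )
        rng2 = np.random.default_rng(1)
        perms = np.array([rng2.permutation(n) for _ in range(500)])
        Yw = np.transpose(vals[perms], (1, 2, 0))
        _, F = engine.f_1d(Yw)
        pointwise = np.quantile(F[0], 0.95)
        assert thr["1d"] >= pointwise

    def test_experimentwise_error_calibrated(self, rng):
        """Per-family proportion of null datasets with any significant term ~ alpha.

        The 1D and 2D scans carry separate experiment-wise thresholds, so
        each family's error rate is controlled at alpha individually.
        """
        n, p = 40, 6
        hits_1d = hits_2d = 0
        n_sets = 150
        for d in range(n_sets):
            X = rng.choice([-1.0, 1.0], size=(n, p))
            G = make_genotypes(X)
            y = rng.normal(size=(n, 2))
            res = scan(G, y, list(G.marker_ids), n_permutations=100, alpha=0.05, seed=d)
            hits_1d += bool(res.significant_markers())
            hits_2d += bool(res.significant_pairs())
        assert 0.02 <= hits_1d / n_sets <= 0.08
        assert 0.02 <= hits_2d / n_sets <= 0.08

    def test_line_profiles_permuted_jointly(self, rng):
        """Permutation preserves each line's multi-environment profile."""
        n = 30
        vals = np.column_stack([np.arange(n, dtype=float), np.arange(n, dtype=float) + 100])
        perms = np.array([np.random.default_rng(0).permutation(n)])
        moved = vals[perms][0]
        assert np.allclose(moved[:, 1] - moved[:, 0], 100.0)


class TestScan:
    def test_affine_invariance(self, rng):
        n = 50
        X = rng.choice([-1.0, 1.0], size=(n, 5))
        G = make_genotypes(X)
        y = np.column_stack([X[:, 1] + rng.normal(0, 1, n), rng.normal(0, 1, n)])
        thr = {"1d": 5.0, "2d": 9.0}
        a = scan(G, y, list(G.marker_ids), thresholds=thr)
        b = scan(G, 3.0 * y - 7.0, list(G.marker_ids), thresholds=thr)
        assert np.allclose(a.table["F"], b.table["F"], atol=1e-9, equal_nan=True)

    def test_bit_reproducible(self, rng):
        n = 40
        X = rng.choice([-1.0, 1.0], size=(n, 5))
        G = make_genotypes(X)
        y = rng.normal(size=(n, 2))
        a = scan(G, y, list(G.marker_ids), n_permutations=50, seed=9)
        b = scan(G, y, list(G.marker_ids), n_permutations=50, seed=9)
        assert a.table.equals(b.table)
        assert a.thresholds == b.thresholds

    def test_significance_flag_matches_threshold(self, rng):
        n = 60
        X = rng.choice([-1.0, 1.0], size=(n, 4))
        G = make_genotypes(X)
        y = X[:, 2] * 2.0 + rng.normal(0, 0.5, n)
        res = scan(G, y, list(G.marker_ids), thresholds={"1d": 6.0, "2d": 10.0})
        t = res.table
        assert (t["significant"] == (t["F"] >= t["threshold"])).all()
        assert "m2" in res.significant_markers()

    def test_monomorphic_candidate_skipped(self, rng, caplog):
        X = rng.choice([-1.0, 1.0], size=(40, 3))
        X[:, 1] = -1.0
        G = make_genotypes(X)
        y = rng.normal(size=40)
        res = scan(G, y, list(G.marker_ids), thresholds={"1d": 5.0, "2d": 9.0})
        assert "m1" not in res.candidates

    def test_estimator_wrapper(self, rng):
        n = 50
        X = rng.choice([-1.0, 1.0], size=(n, 4))
        y = X[:, 0] * 1.5 + rng.normal(0, 1, n)
        est = MixedModelScan(n_permutations=30, random_state=1).fit(X, y)
        assert est.thresholds_.keys() == {"1d", "2d"}
        assert set(est.results_.table["family"]) <= {"1d", "2d"}
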