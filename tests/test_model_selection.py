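"""LOO/p-fold tuning: brute-force oracles, leakage sentinels, determinism."""

import numpy as np
import pandas as pd
import pytest

from kernelfuse import SyntheticConfig, generate_two_view
from kernelfuse.dataio import VariableSchema, VariableDef
from kernelfuse.model_selection import (
    SearchGrid,
    build_folds,
    default_grid,
    grid_search,
    loo_scores,
)


def _toy_views(rng, n=6, n_genes=12, n_clin=3):
    clinical = rng.normal(size=(n, n_clin))
    expression = rng.normal(size=(n, n_genes))
    y = np.array([1, -1] * (n // 2) + [1] * (n % 2))
    schema = VariableSchema(
        tuple(VariableDef(f"v{j}", "continuous") for j in range(n_clin))
    )
    return clinical, expression, schema, y


def brute_force_loo_weighted(clinical, expression, y, sigma1, sigma2, gamma, var_pct=10.0):
    """Independent LOO loop: per fold, re-standardize, re-filter, build RBF
    kernels from scratch, center with the fold's formulas, solve the bordered
    system with numpy, and score the held-out sample."""
    n = y.shape[0]
    out = np.empty(n)
    for i in range(n):
        tr = np.array([j for j in range(n) if j != i])
        # expression: variance filter on raw fold-train data, then standardize
        v = expression[tr].var(axis=0, ddof=1)
        kv = v >= np.percentile(v, var_pct)
        E_raw_tr, E_raw_ho = expression[tr][:, kv], expression[[i]][:, kv]
        mu, sd = E_raw_tr.mean(0), E_raw_tr.std(0, ddof=1)
        E_tr = (E_raw_tr - mu) / sd
        E_ho = (E_raw_ho - mu) / sd
        # clinical: z-score on fold-train
        cmu, csd = clinical[tr].mean(0), clinical[tr].std(0, ddof=1)
        C_tr = (clinical[tr] - cmu) / csd
        C_ho = (clinical[[i]] - cmu) / csd

        def rbf(X, Z, s):
            d2 = ((X[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
            return np.exp(-d2 / (2 * s**2))

        def center(Ktt, Kht):
            col, grand = Ktt.mean(0), Ktt.mean()
            return (
                Ktt - col[None] - col[:, None] + grand,
                Kht - Kht.mean(1, keepdims=True) - col[None] + grand,
            )

        K1, K1h = center(rbf(C_tr, C_tr, sigma1), rbf(C_ho, C_tr, sigma1))
        K2, K2h = center(rbf(E_tr, E_tr, sigma2), rbf(E_ho, E_tr, sigma2))
        m = n - 1
        M = np.zeros((m + 1, m + 1))
        M[0, 1:] = 1.0
        M[1:, 0] = 1.0
        M[1:, 1:] = K1 + K2 / gamma
        sol = np.linalg.solve(M, np.concatenate([[0.0], y[tr].astype(float)]))
        b, alpha = sol[0], sol[1:]
        out[i] = ((K1h + K2h / gamma) @ alpha + b)[0]
    return out


class TestLooScores:
    def test_matches_brute_force_oracle(self, rng):
        clinical, expression, schema, y = _toy_views(rng)
        got = loo_scores(clinical, expression, schema, y, sigma1=1.5, sigma2=3.0, gamma=0.7)
        expected = brute_force_loo_weighted(clinical, expression, y, 1.5, 3.0, 0.7)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        clinical, expression, schema, y = _toy_views(rng, n=8)
        perm = rng.permutation(8)
        a = loo_scores(clinical, expression, schema, y, 1.0, 2.0, 1.0)
        b = loo_scores(clinical[perm], expression[perm], schema, y[perm], 1.0, 2.0, 1.0)
        np.testing.assert_allclose(b, a[perm], atol=1e-10)

    def test_duplicated_samples_still_finite(self, rng):
        clinical, expression, schema, y = _toy_views(rng)
        clin2 = np.vstack([clinical, clinical])
        expr2 = np.vstack([expression, expression])
        y2 = np.concatenate([y, y])
        scores = loo_scores(clin2, expr2, schema, y2, 1.0, 2.0, 1.0)
        assert np.isfinite(scores).all()

    def test_single_view_methods_match_direct_loop(self, rng):
        """Clinical-view LS-SVM held-out scores cross-checked against an
        independent per-fold loop built from the public classifier API."""
        from kernelfuse.classifiers import decision_lssvm, fit_lssvm
        from kernelfuse.kernels import rbf_kernel

        clinical, expression, schema, y = _toy_views(rng, n=8)
        got = loo_scores(
            clinical, expression, schema, y, sigma1=1.2, sigma2=None,
            gamma=2.0, method="cl_lssvm",
        )
        n = y.shape[0]
        for i in range(n):
            tr = np.array([j for j in range(n) if j != i])
            mu, sd = clinical[tr].mean(0), clinical[tr].std(0, ddof=1)
            C_tr, C_ho = (clinical[tr] - mu) / sd, (clinical[[i]] - mu) / sd
            model = fit_lssvm(rbf_kernel(C_tr, C_tr, 1.2), y[tr], 2.0)
            s = decision_lssvm(model, rbf_kernel(C_ho, C_tr, 1.2))
            assert got[i] == pytest.approx(s[0], abs=1e-10)


class TestLeakageSentinel:
    def test_heldout_sample_never_shapes_its_fold_model(self, rng):
        """Perturbing sample i leaves fold i's training-side preprocessing and
        Gram matrices bitwise unchanged (standardization, variance filter and
        clinical scaling are all fold-internal)."""
        clinical, expression, schema, y = _toy_views(rng, n=7)
        folds_a = build_folds(clinical, expression, schema, y)
        clinical2, expression2 = clinical.copy(), expression.copy()
        clinical2[3] += 100.0
        expression2[3] -= 50.0
        folds_b = build_folds(clinical2, expression2, schema, y)
        fold_a = next(f for f in folds_a if f.heldout_idx[0] == 3)
        fold_b = next(f for f in folds_b if f.heldout_idx[0] == 3)
        np.testing.assert_array_equal(fold_a.expr.G_tt, fold_b.expr.G_tt)
        np.testing.assert_array_equal(fold_a.clin.G_tt, fold_b.clin.G_tt)


class TestGridSearch:
    @pytest.fixture(scope="class")
    def separable(self):
        ds = generate_two_view(
            SyntheticConfig(
                n_samples=40, n_genes=50, class_fraction=0.4,
                effect_expression=3.0, n_informative_genes=25,
                effect_clinical=3.0, n_informative_clinical=4, seed=3,
            )
        )
        return ds

    def test_single_point_grid_selected(self, rng):
        clinical, expression, schema, y = _toy_views(rng, n=8)
        grid = SearchGrid((1.0,), (2.0,), (1.0,))
        rep = grid_search(clinical, expression, schema, y, grid)
        assert rep.selected["sigma1"] == 1.0
        assert rep.selected["sigma2"] == 2.0
        assert rep.selected["gamma"] == 1.0
        assert len(rep.table) == 1

    def test_deterministic_report(self, rng):
        clinical, expression, schema, y = _toy_views(rng, n=8)
        grid = SearchGrid((0.5, 1.0), (2.0,), (0.1, 1.0))
        a = grid_search(clinical, expression, schema, y, grid)
        b = grid_search(clinical, expression, schema, y, grid)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.selected == b.selected

    def test_table_covers_cartesian_product_and_bounds(self, rng):
        clinical, expression, schema, y = _toy_views(rng, n=8)
        grid = SearchGrid((0.5, 1.0), (2.0, 4.0), (0.1, 1.0, 10.0))
        rep = grid_search(clinical, expression, schema, y, grid)
        assert len(rep.table) == 2 * 2 * 3
        assert rep.table["cv_auc"].between(0, 1).all()
        assert rep.selected["cv_auc"] == rep.table["cv_auc"].max()

    def test_separable_instance_reaches_perfect_cv_auc(self, separable):
        ds = separable
        grid = default_grid(
            ds.clinical, ds.expression, ds.schema,
            sigma_multipliers=(0.5, 1.0, 2.0), gamma_values=(0.01, 1.0, 100.0),
        )
        rep = grid_search(ds.clinical, ds.expression, ds.schema, ds.labels, grid)
        assert rep.table["cv_auc"].max() == pytest.approx(1.0)

    def test_tie_break_prefers_small_gamma_then_large_sigmas(self):
        # hand-built report path: all-equal AUCs collapse to the documented order
        table = pd.DataFrame(
            [
                {"sigma1": 1.0, "sigma2": 1.0, "gamma": 1.0, "cv_auc": 0.8},
                {"sigma1": 2.0, "sigma2": 1.0, "gamma": 0.1, "cv_auc": 0.8},
                {"sigma1": 1.0, "sigma2": 2.0, "gamma": 0.1, "cv_auc": 0.8},
            ]
        )
        # replicate selection logic through the public function on a dataset
        # whose AUCs tie is fragile; assert the rule directly instead
        best = table[table.cv_auc >= table.cv_auc.max()].copy()
        best = best.sort_values(
            by=["gamma", "sigma1", "sigma2"], ascending=[True, False, False]
        )
        sel = best.iloc[0]
        assert (sel.gamma, sel.sigma1, sel.sigma2) == (0.1, 2.0, 1.0)

    def test_pfold_mode_runs_and_is_seeded(self, rng):
        clinical, expression, schema, y = _toy_views(rng, n=12)
        grid = SearchGrid((1.0,), (2.0,), (1.0,), cv=3, cv_seed=11)
        a = grid_search(clinical, expression, schema, y, grid)
        b = grid_search(clinical, expression, schema, y, grid)
        assert a.selected == b.selected

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SearchGrid((), (1.0,), (1.0,))

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SearchGrid((1.0,), (1.0,), (0.0,))
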