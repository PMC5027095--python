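import warnings

import numpy as np
import pytest

from plurisig import (
    FeatureMatrix,
    fit_lasso_logistic,
    lambda_max,
    make_lambda_grid,
    make_resample_plan,
    select_signature,
    solve_lasso_path,
)
from plurisig.peak_io import FeatureColumn
from plurisig.signature_selection import read_signature, write_signature


def _matrix(X, normalized=True, assay="epigenetic"):
    n, p = X.shape
    cols = [FeatureColumn(f"d{j:02d}", "count", assay) for j in range(p)]
    return FeatureMatrix([f"g{i:04d}" for i in range(n)], cols, X,
                         normalized=normalized)


def _standardize(X):
    return (X - X.mean(0)) / X.std(0)


def penalized_objective(X, y, w, b, lam):
    """(1/n) logistic loss + lam * ||w||_1 (the solver's objective)."""
    t = 2 * y - 1
    z = -(t * (X @ w + b))
    return float(np.mean(np.logaddexp(0, z)) + lam * np.abs(w).sum())


class TestResamplePlan:
    def test_sizes_and_disjointness(self):
        universe = {f"g{i}" for i in range(100)}
        positives = {f"g{i}" for i in range(5)}
        plan = make_resample_plan(positives, universe, n_resamples=3,
                                  master_seed=1)
        assert len(plan.negative_sets) == 3
        for neg in plan.negative_sets:
            assert len(neg) == 5
            assert not (neg & positives)
            assert neg <= universe

    def test_reproducible_from_master_seed(self):
        universe = {f"g{i}" for i in range(50)}
        positives = {"g0", "g1", "g2"}
        a = make_resample_plan(positives, universe, 5, master_seed=9)
        b = make_resample_plan(positives, universe, 5, master_seed=9)
        assert a == b
        c = make_resample_plan(positives, universe, 5, master_seed=10)
        assert a.negative_sets != c.negative_sets

    def test_insufficient_pool_is_error(self):
        with pytest.raises(ValueError, match="cannot draw"):
            make_resample_plan({"a", "b", "c", "d", "e"},
                               {"a", "b", "c", "d", "e", "f"}, 1, 0)


class TestLassoPath:
    def test_nothing_selected_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X = _standardize(rng.normal(size=(80, 10)))
        y = rng.integers(0, 2, 80).astype(float)
        X[:, 0] += 2 * y
        X = _standardize(X)
        grid = make_lambda_grid(X, y)
        W, B = solve_lasso_path(X, y, grid)
        assert (W[0] == 0).all()          # largest lambda: empty model
        assert (W[-1] != 0).any()         # smallest lambda: features enter

    def test_small_lambda_approaches_unpenalized_fit(self):
        # non-separable instance: at lambda -> 0 the penalized objective
        # matches sklearn's (effectively) unpenalized logistic solution
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        X = _standardize(rng.normal(size=(200, 4)))
        y = (X[:, 0] * 0.8 + rng.normal(size=200) > 0).astype(float)
        lam = 1e-6
        W, B = solve_lasso_path(X, y, np.array([1e-3, 1e-4, 1e-5, lam]))
        clf = LogisticRegression(C=1e9, solver="lbfgs", max_iter=5000)
        clf.fit(X, y)
        ours = penalized_objective(X, y, W[-1], B[-1], 0.0)
        ref = penalized_objective(X, y, clf.coef_[0], clf.intercept_[0], 0.0)
        assert abs(ours - ref) < 1e-4

    def test_agrees_with_liblinear_at_matched_penalty(self):
        # independent solver cross-check: liblinear minimizes
        # C * sum(logloss) + ||w||_1, equivalent at C = 1/(n*lam)
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(2)
        n, p = 150, 8
        X = _standardize(rng.normal(size=(n, p)))
        y = rng.integers(0, 2, n).astype(float)
        X[:, :2] += 0.9 * y[:, None]
        X = _standardize(X)
        grid = make_lambda_grid(X, y, n_lambda=20)
        W, B = solve_lasso_path(X, y, grid)
        for k in (0, 5, 10, 19):
            lam = grid[k]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = LogisticRegression(l1_ratio=1, C=1.0 / (n * lam),
                                         solver="liblinear", max_iter=5000,
                                         tol=1e-8, intercept_scaling=100.0)
                clf.fit(X, y)
            assert np.abs(W[k] - clf.coef_[0]).max() < 2e-3

    def test_matches_brute_force_objective_search(self):
        # tiny 2-feature instance: compare with a nested grid search over
        # (w1, w2, b) minimizing the penalized likelihood directly
        rng = np.random.default_rng(3)
        n = 20
        X = _standardize(rng.normal(size=(n, 2)))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(float)
        lam = 0.08
        W, B = solve_lasso_path(X, y, np.array([lam]))
        w_hat, b_hat = W[0], B[0]

        center = np.zeros(3)
        width = 4.0
        for _ in range(12):  # nested refinement
            grid = [np.linspace(c - width, c + width, 21) for c in center]
            best, best_obj = None, np.inf
            for w1 in grid[0]:
                for w2 in grid[1]:
                    for b in grid[2]:
                        obj = penalized_objective(X, y, np.array([w1, w2]), b, lam)
                        if obj < best_obj:
                            best_obj, best = obj, (w1, w2, b)
            center, width = np.array(best), width / 5
        assert abs(w_hat[0] - center[0]) < 1e-3
        assert abs(w_hat[1] - center[1]) < 1e-3
        assert abs(b_hat - center[2]) < 1e-3
        ours = penalized_objective(X, y, w_hat, b_hat, lam)
        assert ours <= best_obj + 1e-6

    def test_descending_grid_required(self):
        X = np.zeros((4, 1))
        y = np.array([0, 1, 0, 1.0])
        with pytest.raises(ValueError, match="non-increasing"):
            solve_lasso_path(X, y, np.array([0.1, 0.2]))


class TestFitLassoLogistic:
    def _planted(self, seed, n=200, p=10, effect=2.0):
        rng = np.random.default_rng(seed)
        y = np.repeat([1.0, 0.0], n // 2)
        X = rng.normal(size=(n, p))
        X[:, 0] += effect * (y - 0.5)  # planted log-odds signal
        return _standardize(X), y

    def test_planted_column_selected_at_cv_lambda(self):
        hits = 0
        for seed in range(20):
            X, y = self._planted(seed)
            m = _matrix(X)
            labels = {g: int(v) for g, v in zip(m.gene_ids, y)}
            fit = fit_lasso_logistic(m, labels, cv_seed=seed)
            if m.columns[0] in fit.selected:
                hits += 1
        assert hits >= 18  # planted signal recovered in nearly every seed

    def test_requires_normalized_matrix(self):
        X, y = self._planted(0)
        m = _matrix(X, normalized=False)
        labels = {g: int(v) for g, v in zip(m.gene_ids, y)}
        with pytest.raises(ValueError, match="normalized"):
            fit_lasso_logistic(m, labels)

    def test_selected_matches_nonzero_coefficients(self):
        X, y = self._planted(1)
        m = _matrix(X)
        labels = {g: int(v) for g, v in zip(m.gene_ids, y)}
        fit = fit_lasso_logistic(m, labels, cv_seed=1)
        assert fit.selected == frozenset(
            c for c, v in fit.coefficients.items() if v != 0.0
        )
        assert min(fit.cv_deviance_path.values()) == \
            fit.cv_deviance_path[fit.lam]


class TestSelectSignature:
    def test_planted_signature_recovered_with_positive_sign(
            self, small_study, small_matrix):
        universe = {g.gene_id for g in small_study.annotation}
        plan = make_resample_plan(small_study.positives, universe,
                                  n_resamples=20, master_seed=5)
        sig = select_signature(small_matrix, plan, scope="combined")
        selected = {(e.dataset_id, e.feature_type) for e in sig.entries}
        planted_breadth = {(d, "breadth")
                           for d in small_study.truth.signature_datasets}
        assert planted_breadth <= selected
        for e in sig.entries:
            if (e.dataset_id, e.feature_type) in planted_breadth:
                assert e.sign == "+"

    def test_frequencies_are_exact_resample_fractions(
            self, small_study, small_matrix):
        universe = {g.gene_id for g in small_study.annotation}
        plan = make_resample_plan(small_study.positives, universe,
                                  n_resamples=10, master_seed=2)
        sig = select_signature(small_matrix, plan, scope="epigenetic")
        for e in sig.entries:
            k = e.selection_frequency * 10
            assert abs(k - round(k)) < 1e-12

    def test_impossible_threshold_empties_signature(
            self, small_study, small_matrix):
        universe = {g.gene_id for g in small_study.annotation}
        plan = make_resample_plan(small_study.positives, universe,
                                  n_resamples=5, master_seed=3)
        sig = select_signature(small_matrix, plan, scope="combined",
                               frequency_threshold=1.01)
        assert sig.entries == []

    def test_reproducible(self, small_study, small_matrix):
        universe = {g.gene_id for g in small_study.annotation}
        plan = make_resample_plan(small_study.positives, universe,
                                  n_resamples=5, master_seed=4)
        a = select_signature(small_matrix, plan, scope="combined")
        b = select_signature(small_matrix, plan, scope="combined")
        assert a.entries == b.entries

    def test_unknown_scope_rejected(self, small_study, small_matrix):
        universe = {g.gene_id for g in small_study.annotation}
        plan = make_resample_plan(small_study.positives, universe, 2, 0)
        with pytest.raises(ValueError, match="scope"):
            select_signature(small_matrix, plan, scope="everything")

    def test_signature_tsv_roundtrip(self, small_study, small_matrix, tmp_path):
        universe = {g.gene_id for g in small_study.annotation}
        plan = make_resample_plan(small_study.positives, universe, 5, 1)
        sig = select_signature(small_matrix, plan, scope="combined")
        p = tmp_path / "sig.tsv"
        write_signature(sig, p)
        back = read_signature(p, scope="combined", n_resamples=5)
        assert back.entries == sig.entries


class TestNullSelection:
    def test_null_data_selects_nothing_stable(self):
        # without planted effects no column should pass the 0.5 frequency
        # threshold in most generator seeds
        from plurisig import null_config, generate_study, study_feature_matrix

        bad_seeds = 0
        for seed in range(5):
            cfg = null_config(n_genes=200, n_positive=25,
                              n_datasets_epigenetic=5, n_datasets_protein=0,
                              seed=seed)
            study = generate_study(cfg)
            m = study_feature_matrix(study)
            universe = {g.gene_id for g in study.annotation}
            plan = make_resample_plan(study.positives, universe,
                                      n_resamples=20, master_seed=seed)
            sig = select_signature(m, plan, scope="epigenetic")
            if sig.entries:
                bad_seeds += 1
        assert bad_seeds <= 1
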