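import json
import subprocess

import numpy as np
import pytest

from regimeshift import build_pcnm, fit_rda, forward_select, hellinger, lc_scores
from regimeshift import test_axes as run_axis_tests


def run_r(script: str) -> dict:
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    return json.loads(out.stdout)


@pytest.fixture(scope="module")
def irregular_times():
    return np.sort(np.random.default_rng(7).uniform(0, 200, 25))


class TestBuildPcnm:
    def test_three_point_worked_example(self):
        # times (0,1,2): truncation 1, distances >1 replaced by 4;
        # Gower-centered matrix has eigenvalues (8, 0, -2), one positive
        basis = build_pcnm(np.array([0.0, 1.0, 2.0]))
        assert basis.truncation == 1.0
        assert basis.k == 1
        assert basis.eigenvalues[0] == pytest.approx(8.0)
        np.testing.assert_allclose(
            np.abs(basis.vectors[:, 0]), [1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
            atol=1e-12,
        )

    def test_sine_wave_property_on_regular_times(self):
        basis = build_pcnm(np.arange(30.0))

        def sign_changes(v):
            s = np.sign(v[np.abs(v) > 1e-10])
            return int(np.sum(s[:-1] != s[1:]))

        changes = [sign_changes(basis.vectors[:, j]) for j in range(basis.k)]
        assert changes[0] == 1  # leading PCNM models the longest frequency
        assert all(b >= a for a, b in zip(changes, changes[1:]))

    def test_matches_vegan_pcnm(self, irregular_times):
        basis = build_pcnm(irregular_times)
        r = run_r(
            "suppressMessages(library(vegan));"
            f"t <- c({','.join('%.12f' % x for x in irregular_times)});"
            "p <- pcnm(dist(t));"
            "cat(jsonlite::toJSON(list(values=as.numeric(p$values),"
            "thresh=p$threshold), digits=14))"
        )
        vals = np.array(r["values"])
        vals = vals[vals > 1e-8 * vals.max()]
        assert basis.k == len(vals)
        assert basis.truncation == pytest.approx(r["thresh"][0])
        np.testing.assert_allclose(basis.eigenvalues, vals, rtol=1e-8)

    def test_orthonormal_and_bitwise_stable(self, irregular_times):
        a = build_pcnm(irregular_times)
        b = build_pcnm(irregular_times)
        np.testing.assert_array_equal(a.vectors, b.vectors)
        gram = a.vectors.T @ a.vectors
        np.testing.assert_allclose(gram, np.eye(a.k), atol=1e-10)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_pcnm(np.array([0.0, 1.0, 1.0, 2.0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            build_pcnm(np.array([0.0, 1.0]))


class TestHellinger:
    def test_single_taxon_row(self):
        out = hellinger(np.array([[100.0, 0.0, 0.0]]))
        np.testing.assert_allclose(out, [[1.0, 0.0, 0.0]])

    def test_hand_computed_row(self):
        out = hellinger(np.array([[80.0, 20.0]]))
        np.testing.assert_allclose(out, [[0.8944, 0.4472]], atol=1e-4)

    def test_unit_row_norms(self, rng):
        Y = rng.uniform(0, 10, (20, 7))
        out = hellinger(Y)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_names_step(self):
        Y = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="step 1"):
            hellinger(Y)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            hellinger(np.array([[1.0, -2.0]]))


class TestForwardSelect:
    def test_single_perfect_predictor_recovered(self, irregular_times):
        basis = build_pcnm(irregular_times)
        Y = 2.0 * basis.vectors[:, [2]]
        sel = forward_select(Y, basis, alpha=0.05, n_perm=99, seed=1)
        assert sel.selected[:1] == [2]
        assert sel.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_two_signal_variables_recovered(self):
        # small temporally structured noise (inside the PCNM span): with
        # white noise the global adjusted-R^2 ceiling of the double
        # stopping rule is dragged down by the k/n penalty and legitimately
        # halts selection early, so structured noise is the regime in
        # which full recovery is the correct expectation
        times = np.sort(np.random.default_rng(5).uniform(0, 400, 60))
        basis = build_pcnm(times)
        rng = np.random.default_rng(0)
        found = 0
        n_seeds = 10
        for seed in range(n_seeds):
            coef = 0.15 * rng.standard_normal((basis.k, 1))
            Y = (basis.vectors[:, [0]] + basis.vectors[:, [4]]
                 + basis.vectors @ coef)
            sel = forward_select(Y, basis, alpha=0.05, n_perm=199, seed=seed)
            found += {0, 4} <= set(sel.selected)
        assert found >= 0.9 * n_seeds

    def test_null_gives_empty_selection(self):
        times = np.sort(np.random.default_rng(2).uniform(0, 300, 40))
        basis = build_pcnm(times)
        empty = 0
        n_seeds = 10
        for seed in range(n_seeds):
            Y = np.random.default_rng(100 + seed).standard_normal((40, 5))
            sel = forward_select(Y, basis, alpha=0.05, n_perm=99, seed=seed)
            empty += len(sel.selected) == 0
        assert empty >= 0.9 * n_seeds

    def test_greedy_order_matches_exhaustive_search(self, irregular_times):
        # with alpha=1 the double stopping reduces to greedy R^2 ordering;
        # oracle: exhaustively score every candidate addition by lstsq
        basis = build_pcnm(irregular_times)
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((len(irregular_times), 3))
        sel = forward_select(Y, basis, alpha=1.0, n_perm=99, seed=0)

        Yc = Y - Y.mean(axis=0)
        sst = np.sum(Yc**2)
        chosen: list[int] = []
        for _ in range(len(sel.selected)):
            best, best_r2 = None, -1.0
            for j in range(basis.k):
                if j in chosen:
                    continue
                X = basis.vectors[:, chosen + [j]]
                resid = Yc - X @ np.linalg.lstsq(X, Yc, rcond=None)[0]
                r2 = 1 - np.sum(resid**2) / sst
                if r2 > best_r2 + 1e-12:
                    best, best_r2 = j, r2
            chosen.append(best)
        assert sel.selected == chosen

    def test_row_mismatch_rejected(self, irregular_times):
        basis = build_pcnm(irregular_times)
        with pytest.raises(ValueError, match="rows"):
            forward_select(np.ones((10, 2)), basis)

    def test_deterministic_given_seed(self, irregular_times):
        basis = build_pcnm(irregular_times)
        Y = np.random.default_rng(4).standard_normal((25, 4))
        a = forward_select(Y, basis, n_perm=99, seed=7)
        b = forward_select(Y, basis, n_perm=99, seed=7)
        assert a.selected == b.selected and a.pvalues == b.pvalues


class TestFitRda:
    def test_saturated_model_explains_everything(self, rng):
        n = 12
        # n-1 orthogonal non-constant predictors span the centered space
        X = np.linalg.qr(rng.standard_normal((n, n - 1)) -
                         rng.standard_normal((1, n - 1)))[0]
        X = X - X.mean(axis=0)
        Y = rng.uniform(0, 5, (n, 4))
        model = fit_rda(Y, X)
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert model.residual_eigenvalues.sum() == pytest.approx(0.0, abs=1e-8)

    def test_identical_single_columns(self, rng):
        x = rng.standard_normal(15)
        model = fit_rda(x[:, None].copy(), x[:, None])
        assert len(model.canonical_eigenvalues) == 1
        assert model.variance_fraction[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_matches_projection_oracle(self, rng):
        Y = rng.uniform(0, 3, (10, 4))
        X = rng.standard_normal((10, 2))
        model = fit_rda(Y, X)
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)  # regression with intercept
        Yhat = Xc @ np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        expect = np.trace(Yhat.T @ Yhat) / 9
        assert model.canonical_eigenvalues.sum() == pytest.approx(expect)

    def test_variance_decomposition_conserved(self, rng):
        Y = rng.uniform(0, 8, (30, 6))
        X = rng.standard_normal((30, 3))
        model = fit_rda(Y, X)
        total = model.canonical_eigenvalues.sum() + model.residual_eigenvalues.sum()
        assert total == pytest.approx(model.total_variance, rel=1e-8)

    def test_matches_vegan_rda(self):
        rng = np.random.default_rng(3)
        Y = rng.uniform(0.5, 10, (12, 5))
        Yh = hellinger(Y)
        times = np.sort(rng.uniform(0, 100, 12))
        X = build_pcnm(times).vectors[:, :2]
        model = fit_rda(Yh, X)
        ys = ";".join(",".join("%.12f" % v for v in row) for row in Yh)
        xs = ";".join(",".join("%.12f" % v for v in row) for row in X)
        r = run_r(
            "suppressMessages(library(vegan));"
            f'Y <- do.call(rbind, lapply(strsplit(strsplit("{ys}",";")[[1]],","), as.numeric));'
            f'X <- do.call(rbind, lapply(strsplit(strsplit("{xs}",";")[[1]],","), as.numeric));'
            "m <- rda(Y ~ X[,1] + X[,2]);"
            "cat(jsonlite::toJSON(list(eig=as.numeric(m$CCA$eig), tot=m$tot.chi), digits=14))"
        )
        np.testing.assert_allclose(model.canonical_eigenvalues, r["eig"], rtol=1e-8)
        assert model.total_variance == pytest.approx(r["tot"][0])

    def test_rank_deficient_predictors_reported(self, rng):
        x = rng.standard_normal(10)
        X = np.column_stack([x, 2 * x, rng.standard_normal(10)])
        with pytest.raises(ValueError, match="collinear"):
            fit_rda(rng.uniform(0, 1, (10, 3)), X)


class TestTestAxes:
    def test_perfect_association_maximally_significant(self, irregular_times):
        basis = build_pcnm(irregular_times)
        X = basis.vectors[:, :2]
        Y = X @ np.array([[1.0, 0.2], [0.3, -1.0]])
        model = fit_rda(Y, X)
        pvals, n_sig = run_axis_tests(model, Y, X, n_perm=99, alpha=0.05, seed=0)
        assert pvals[0] == pytest.approx(1 / 100)
        assert n_sig >= 1

    def test_pure_noise_yields_no_significant_axes(self, irregular_times):
        basis = build_pcnm(irregular_times)
        X = basis.vectors[:, :3]
        none = 0
        n_seeds = 10
        for seed in range(n_seeds):
            Y = np.random.default_rng(50 + seed).standard_normal((25, 6))
            model = fit_rda(Y, X)
            _, n_sig = run_axis_tests(model, Y, X, n_perm=99, alpha=0.05, seed=seed)
            none += n_sig == 0
        assert none >= 0.9 * n_seeds

    def test_scan_stops_at_first_nonsignificant(self, irregular_times):
        basis = build_pcnm(irregular_times)
        X = basis.vectors[:, :4]
        rng = np.random.default_rng(1)
        Y = X[:, [0]] @ np.array([[5.0, -5.0]]) + 0.1 * rng.standard_normal((25, 2))
        model = fit_rda(Y, X)
        pvals, n_sig = run_axis_tests(model, Y, X, n_perm=99, alpha=0.05, seed=3)
        assert n_sig < len(pvals) and np.isnan(pvals[n_sig + 1:]).all()


class TestLcScores:
    def test_columns_orthogonal_and_centered(self, irregular_times):
        basis = build_pcnm(irregular_times)
        X = basis.vectors[:, :3]
        Y = np.random.default_rng(8).uniform(0, 4, (25, 5))
        model = fit_rda(Y, X)
        lc = lc_scores(model).to_numpy()
        np.testing.assert_allclose(lc.mean(axis=0), 0.0, atol=1e-10)
        gram = lc.T @ lc
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_single_pcnm_model_proportional_to_it(self, irregular_times):
        basis = build_pcnm(irregular_times)
        x = basis.vectors[:, [1]]
        Y = np.random.default_rng(2).uniform(0, 4, (25, 3))
        model = fit_rda(Y, x)
        lc1 = lc_scores(model).to_numpy()[:, 0]
        corr = np.corrcoef(lc1, x[:, 0])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
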