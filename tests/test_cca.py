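"""CCA: closed-form and permutation oracles, Wilks' F approximation,
loadings, feature-set assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covnet.cca import (
    BEHAVIOR_COLUMNS,
    build_feature_sets,
    cca,
    run_cca,
    subject_edge_correlations,
    variate_loadings,
    wilks_test,
)


def _xy(rng, n=60, p=3, q=4, shared=0.0):
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    if shared:
        Y[:, 0] = shared * X[:, 0] + np.sqrt(1 - shared**2) * rng.standard_normal(n)
    return X, Y


class TestCca:
    def test_y_equals_x_gives_unit_correlations(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        res = cca(X, X.copy())
        np.testing.assert_allclose(res.correlations, 1.0, atol=1e-10)

    def test_correlations_sorted_and_bounded(self):
        rng = np.random.default_rng(1)
        X, Y = _xy(rng, shared=0.6)
        res = cca(X, Y)
        assert np.all(np.diff(res.correlations) <= 1e-12)
        assert np.all((res.correlations >= 0) & (res.correlations <= 1))

    def test_matches_statsmodels_cancorr(self):
        from statsmodels.multivariate.cancorr import CanCorr

        rng = np.random.default_rng(2)
        X, Y = _xy(rng, n=80, p=4, q=5, shared=0.5)
        res = cca(X, Y)
        sm = CanCorr(Y, X)
        np.testing.assert_allclose(res.correlations, sm.cancorr, atol=1e-8)

    def test_variates_are_unit_variance_and_correlate_at_r(self):
        rng = np.random.default_rng(3)
        X, Y = _xy(rng, n=100, shared=0.7)
        res = cca(X, Y)
        np.testing.assert_allclose(res.x_scores.std(0, ddof=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.y_scores.std(0, ddof=1), 1.0, atol=1e-8)
        for k in range(res.n_modes):
            r = np.corrcoef(res.x_scores[:, k], res.y_scores[:, k])[0, 1]
            assert r == pytest.approx(res.correlations[k], abs=1e-8)

    def test_affine_recoding_invariance(self):
        rng = np.random.default_rng(4)
        X, Y = _xy(rng, n=70, shared=0.5)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        B = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        res1 = cca(X, Y)
        res2 = cca(X @ A + 1.5, Y @ B - 0.7)
        np.testing.assert_allclose(res1.correlations, res2.correlations, atol=1e-8)

    def test_planted_latent_recovered(self):
        rng = np.random.default_rng(5)
        X, Y = _xy(rng, n=500, p=3, q=3, shared=0.6)
        res = cca(X, Y)
        assert res.correlations[0] == pytest.approx(0.6, abs=0.05)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(6)
        X, Y = _xy(rng, n=100, shared=0.8)
        res = cca(X, Y)
        Xs = (X - X.mean(0)) / X.std(0)
        load = (Xs.T @ res.x_scores) / (res.n - 1)
        for k in range(res.n_modes):
            j = np.argmax(np.abs(load[:, k]))
            assert load[j, k] > 0

    def test_overfit_regime_refused_then_allowed(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 6))
        Y = rng.standard_normal((10, 6))
        with pytest.raises(ValueError, match="allow_overfit"):
            cca(X, Y)
        res = cca(X, Y, allow_overfit=True)
        # degenerate regime: perfect canonical correlation by construction
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        Y = rng.standard_normal((40, 2))
        with pytest.raises(ValueError, match="singular"):
            cca(X, Y)


class TestWilks:
    def test_zero_correlations_give_lambda_one_p_one(self):
        table = wilks_test(np.zeros(3), n=50, p=3, q=3)
        np.testing.assert_allclose(table["wilks_lambda"], 1.0)
        np.testing.assert_allclose(table["F"], 0.0)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_reduces_to_simple_correlation_f_test_when_p_q_one(self):
        rng = np.random.default_rng(9)
        n = 40
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        r = abs(np.corrcoef(x, y)[0, 1])
        table = wilks_test(np.array([r]), n=n, p=1, q=1)
        # closed form: F = r^2/(1-r^2) * (n-2), df (1, n-2)
        f_expected = r**2 / (1 - r**2) * (n - 2)
        assert table.loc[0, "F"] == pytest.approx(f_expected, rel=1e-10)
        assert table.loc[0, "p"] == pytest.approx(
            stats.f.sf(f_expected, 1, n - 2), rel=1e-10
        )

    def test_matches_statsmodels_corr_test(self):
        from statsmodels.multivariate.cancorr import CanCorr

        rng = np.random.default_rng(10)
        X, Y = _xy(rng, n=90, p=3, q=4, shared=0.5)
        res = run_cca(pd.DataFrame(X), pd.DataFrame(Y))
        sm_table = CanCorr(Y, X).corr_test().stats
        # Wilks' Lambda is convention-free and must agree exactly;
        # the F approximation df differ slightly (symmetric Rao form here
        # vs the SAS/MANOVA form in statsmodels), so p-values agree only
        # to a small tolerance
        np.testing.assert_allclose(
            res.wilks["wilks_lambda"],
            sm_table["Wilks' lambda"].astype(float),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            res.wilks["F"], sm_table["F Value"].astype(float), rtol=0.05
        )
        np.testing.assert_allclose(
            res.wilks["p"], sm_table["Pr > F"].astype(float), atol=0.01
        )

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(11)
        X, Y = _xy(rng, n=40, p=2, q=2, shared=0.55)
        res = cca(X, Y)
        table = wilks_test(res.correlations, 40, 2, 2)
        lam_obs = table.loc[0, "wilks_lambda"]
        n_perm = 2000
        hits = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(40)]
            rp = cca(X, Yp).correlations
            if np.prod(1 - rp**2) <= lam_obs:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(table.loc[0, "p"] - p_perm) < max(4 * se, 0.01)

    def test_significance_chain_is_monotone(self):
        # raw sequential p-values need not be ordered, but the significance
        # labels must form a prefix: once a mode fails, later modes fail
        rng = np.random.default_rng(12)
        for trial in range(5):
            X, Y = _xy(rng, n=80, p=3, q=4, shared=0.7)
            res = run_cca(pd.DataFrame(X), pd.DataFrame(Y))
            sig = res.wilks["significant"].to_numpy()
            assert np.all(sig[1:] <= sig[:-1])

    def test_sequential_significance_rule(self):
        # mode 2 cannot be significant if mode 1 is not
        table = wilks_test(np.array([0.1, 0.9]), n=100, p=2, q=2)
        assert not table.loc[0, "significant"] or table["significant"].all()


class TestLoadings:
    def test_identical_and_orthogonal_variables(self):
        rng = np.random.default_rng(13)
        X, Y = _xy(rng, n=60, shared=0.9)
        res = run_cca(pd.DataFrame(X), pd.DataFrame(Y))
        full, _ = variate_loadings(X, Y, res, modes=[1])
        # variable equal to the variate itself loads 1
        X2 = np.column_stack([res.x_scores[:, 0], X[:, 1], X[:, 2]])
        res2 = run_cca(pd.DataFrame(X2), pd.DataFrame(Y))
        full2, _ = variate_loadings(X2, Y, res2, modes=[1])
        top = full2[(full2["set"] == "X") & (full2["mode"] == 1)]["loading"].abs().max()
        assert top == pytest.approx(1.0, abs=1e-6)

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(14)
        X, Y = _xy(rng, n=60, shared=0.9)
        res = run_cca(pd.DataFrame(X), pd.DataFrame(Y))
        full, reported = variate_loadings(X, Y, res, threshold=0.2, modes=[1])
        assert (reported["loading"].abs() > 0.2).all()
        # an exact-boundary loading would be excluded: emulate by filtering
        boundary = full.copy()
        boundary.loc[boundary.index[0], "loading"] = 0.2
        kept = boundary[boundary["loading"].abs() > 0.2]
        assert boundary.index[0] not in kept.index


class TestFeatureSets:
    def test_structural_incidence_and_functional_edge_columns(self, atlas):
        from covnet.extract import StructuralMatrix, TimeSeriesSet
        from covnet.groupdiff import EdgeDifferenceResult

        rng = np.random.default_rng(15)
        subjects = [f"s{i:02d}" for i in range(20)]
        pairs = atlas.pairs()
        flags = np.zeros(171, dtype=np.int8)
        flags[pairs.index(("ACC", "AI-L"))] = -1
        gmm = EdgeDifferenceResult(
            modality="GMM",
            roi_names=list(atlas.roi_names),
            victim_pcorr=np.zeros(171),
            lo=np.zeros(171),
            hi=np.zeros(171),
            flags=flags,
            alpha_sig=1e-5,
            alpha_effective=2e-4,
            n_boot=100,
            seed=0,
        )
        flags_rs = np.zeros(171, dtype=np.int8)
        flags_rs[pairs.index(("MPFC", "PCUN"))] = 1
        rs = EdgeDifferenceResult(
            modality="RS",
            roi_names=list(atlas.roi_names),
            victim_pcorr=np.zeros(171),
            lo=np.zeros(171),
            hi=np.zeros(171),
            flags=flags_rs,
            alpha_sig=1e-5,
            alpha_effective=2e-4,
            n_boot=100,
            seed=0,
        )
        structural = {
            "GMM": StructuralMatrix(
                values=pd.DataFrame(
                    rng.standard_normal((20, 19)),
                    index=subjects,
                    columns=atlas.roi_names,
                ),
                measure="GMM",
            )
        }
        ts = TimeSeriesSet(
            series={s: rng.standard_normal((30, 19)) for s in subjects},
            roi_names=list(atlas.roi_names),
            tr=1.6,
        )
        behavior = pd.DataFrame(
            rng.standard_normal((20, len(BEHAVIOR_COLUMNS))),
            index=subjects,
            columns=BEHAVIOR_COLUMNS,
        )
        behavior.iloc[3, 0] = np.nan  # one incomplete subject
        X, Y = build_feature_sets([gmm, rs], structural, ts, behavior, atlas)
        assert "GMM SN.ACC" in X.columns
        assert "GMM SN.AI-L" in X.columns
        assert "RS MPFC-PCUN" in X.columns
        assert X.shape[1] == 3
        assert len(X) == 19  # incomplete subject dropped
        assert list(X.index) == list(Y.index)
        # functional column equals the per-subject series correlation
        s0 = X.index[0]
        i, j = atlas.roi_names.index("MPFC"), atlas.roi_names.index("PCUN")
        expected = np.corrcoef(ts.series[s0][:, i], ts.series[s0][:, j])[0, 1]
        assert X.loc[s0, "RS MPFC-PCUN"] == pytest.approx(expected)

    def test_structural_only_switch_drops_functional(self, atlas):
        # reuse the subject_edge_correlations helper directly
        rng = np.random.default_rng(16)
        from covnet.extract import TimeSeriesSet

        ts = TimeSeriesSet(
            series={"a": rng.standard_normal((25, 19))},
            roi_names=list(atlas.roi_names),
            tr=1.6,
        )
        out = subject_edge_correlations(ts, [("ACC", "AI-L")])
        assert out.shape == (1, 1)
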