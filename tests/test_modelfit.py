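from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bipindex.config import BipConfig
from bipindex.modelfit import (
    DriverModel,
    compute_vif,
    driver_score,
    find_collinear_sets,
    fit_driver,
    pca_substitute,
    stepwise_mra,
)


def best_subset_r2(X: pd.DataFrame, y: pd.Series, size: int) -> float:
    """Exhaustive all-subsets oracle: best R^2 among subsets of one size."""
    best = 0.0
    yv = y.to_numpy(dtype=float)
    for combo in combinations(X.columns, size):
        A = np.column_stack([np.ones(len(X)), X[list(combo)].to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        resid = yv - A @ coef
        r2 = 1.0 - (resid @ resid) / (((yv - yv.mean()) ** 2).sum())
        best = max(best, r2)
    return best


class TestStepwise:
    def test_perfect_univariate_fit(self):
        x = pd.Series(np.linspace(0, 1, 20))
        res = stepwise_mra(pd.DataFrame({"x": x}), x.copy())
        assert res.terms == ["x"]
        assert res.coefs["x"] == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_signal_selected_noise_rejected(self, rng):
        n = 200
        x1 = rng.uniform(size=n)
        x2 = rng.uniform(size=n)
        y = 2.0 * x1 + rng.normal(0, 0.01, n)
        res = stepwise_mra(pd.DataFrame({"x1": x1, "x2": x2}), pd.Series(y))
        assert res.terms == ["x1"]
        assert res.coefs["x1"] == pytest.approx(2.0, abs=0.05)

    def test_empty_model_when_nothing_significant(self, rng):
        n = 60
        X = pd.DataFrame({f"x{i}": rng.uniform(size=n) for i in range(3)})
        y = pd.Series(rng.uniform(size=n))
        res = stepwise_mra(X, y, alpha_enter=1e-6)
        assert res.terms == []
        assert res.r2 == 0.0

    def test_close_to_best_subset_at_same_size(self, rng):
        for _ in range(10):
            n, p = 120, 6
            X = pd.DataFrame({f"x{i}": rng.uniform(size=n) for i in range(p)})
            beta = np.array([1.5, 1.0, 0.0, 0.0, 0.0, 0.0])
            y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 0.2, n))
            res = stepwise_mra(X, y)
            if not res.terms:
                continue
            oracle = best_subset_r2(X, y, len(res.terms))
            assert res.r2 >= oracle - 0.02

    def test_listwise_skips_short_candidates(self, rng, caplog):
        n = 30
        x_ok = rng.uniform(size=n)
        x_sparse = np.full(n, np.nan)
        x_sparse[:2] = [0.1, 0.9]
        y = pd.Series(2 * x_ok + rng.normal(0, 0.05, n))
        with caplog.at_level("WARNING"):
            res = stepwise_mra(pd.DataFrame({"a_ok": x_ok, "b_sparse": x_sparse}), y)
        assert res.terms == ["a_ok"]
        assert "b_sparse" in res.skipped

    def test_deterministic_given_inputs(self, rng):
        n = 100
        X = pd.DataFrame({f"x{i}": rng.uniform(size=n) for i in range(4)})
        y = pd.Series(X["x0"] + 0.5 * X["x1"] + rng.normal(0, 0.1, n))
        r1 = stepwise_mra(X, y)
        r2 = stepwise_mra(X.copy(), y.copy())
        assert r1.terms == r2.terms
        assert r1.coefs == r2.coefs

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"x": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError, match="constant"):
            stepwise_mra(X, pd.Series(np.ones(10)))


class TestVif:
    def test_orthogonal_columns(self):
        n = 50
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        design = pd.DataFrame({"a": np.sin(t), "b": np.cos(t)})
        vifs = compute_vif(design)
        assert vifs["a"] == pytest.approx(1.0, abs=1e-10)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_is_infinite(self, rng):
        x = rng.uniform(size=30)
        vifs = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_matches_brute_force_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            n, p = 50, 5
            base = rng.normal(size=(n, p))
            base[:, 1] = base[:, 0] * 0.8 + rng.normal(0, 0.5, n)
            design = pd.DataFrame(base, columns=[f"c{i}" for i in range(p)])
            vifs = compute_vif(design)
            for i, col in enumerate(design.columns):
                others = [c for c in design.columns if c != col]
                fit = sm.OLS(design[col],
                             sm.add_constant(design[others])).fit()
                oracle = 1.0 / (1.0 - fit.rsquared)
                assert vifs[col] == pytest.approx(oracle, abs=1e-10)

    def test_single_term_rejected(self):
        with pytest.raises(ValueError, match="two terms"):
            compute_vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestCollinearSets:
    def test_groups_by_correlation_graph(self, rng):
        n = 80
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        design = pd.DataFrame({
            "a1": f1 + rng.normal(0, 0.05, n),
            "a2": f1 + rng.normal(0, 0.05, n),
            "b1": f2 + rng.normal(0, 0.05, n),
            "b2": f2 + rng.normal(0, 0.05, n),
            "solo": rng.normal(size=n),
        })
        vifs = compute_vif(design)
        sets = find_collinear_sets(design, vifs)
        members = sorted(tuple(s.members) for s in sets)
        assert members == [("a1", "a2"), ("b1", "b2")]


class TestPcaSubstitute:
    def test_identical_columns_symmetric_loadings(self, rng):
        x = rng.uniform(size=30)
        comp = pca_substitute(pd.DataFrame({"a": x, "b": x.copy()}))
        assert comp.explained_ratio == pytest.approx(1.0)
        assert abs(comp.loadings["a"]) == pytest.approx(abs(comp.loadings["b"]), abs=1e-12)

    def test_anticorrelated_columns_opposite_signs(self, rng):
        x = rng.uniform(size=30)
        y = pd.Series(x, dtype=float)
        comp = pca_substitute(pd.DataFrame({"a": x, "b": -x}), response=y)
        assert np.sign(comp.loadings["a"]) == -np.sign(comp.loadings["b"])
        vals = comp.transform(pd.DataFrame({"a": x, "b": -x}))
        assert np.corrcoef(vals, x)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_composite_beats_single_members_on_factor_model(self, rng):
        n = 200
        latent = rng.uniform(size=n)
        members = pd.DataFrame({
            f"m{i}": latent + rng.normal(0, 0.3, n) for i in range(3)
        })
        comp = pca_substitute(members, response=pd.Series(latent))
        composite = comp.transform(members)
        r_comp = abs(np.corrcoef(composite, latent)[0, 1])
        r_single = max(abs(np.corrcoef(members[c], latent)[0, 1]) for c in members)
        assert r_comp >= r_single

    def test_too_few_rows_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="complete rows"):
            pca_substitute(df)

    def test_flexible_transform_with_missing_member(self, rng):
        x = rng.uniform(size=20)
        frame = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 20)})
        comp = pca_substitute(frame, response=pd.Series(x))
        partial = frame.copy()
        partial.loc[0, "b"] = np.nan
        vals = comp.transform(partial)
        assert not np.isnan(vals.iloc[0])      # one member still available
        allgone = frame.copy()
        allgone.loc[0, ["a", "b"]] = np.nan
        assert np.isnan(comp.transform(allgone).iloc[0])


class TestFitDriver:
    def test_single_perfect_predictor_no_pc_terms(self, rng):
        y = pd.Series(rng.uniform(size=40))
        X = pd.DataFrame({"only": y * 1.0})
        model = fit_driver("BIO", "DAT", X, y)
        assert [v for v, _ in model.direct_terms] == ["only"]
        assert model.pc_terms == []
        assert model.fit_stats["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_near_duplicates_collapse_to_one_pc(self, rng):
        # both duplicates carry (tiny) independent signal, so stepwise retains
        # both; their mutual correlation then forces the PC substitution
        n = 150
        latent = rng.uniform(size=n)
        X = pd.DataFrame({
            "dup1": latent + rng.normal(0, 0.02, n),
            "dup2": latent + rng.normal(0, 0.02, n),
        })
        y = pd.Series(X["dup1"] + X["dup2"] + rng.normal(0, 0.001, n))
        assert X.corr().loc["dup1", "dup2"] > 0.99
        model = fit_driver("BIO", "DAT", X, y)
        assert len(model.pc_terms) == 1
        assert model.direct_terms == []
        assert sorted(model.pc_terms[0][0].members) == ["dup1", "dup2"]

    def test_substitution_soundness_vif_below_threshold(self, rng):
        from bipindex.modelfit import _term_columns

        n = 200
        f1 = rng.uniform(size=n)
        f2 = rng.uniform(size=n)
        y = pd.Series(f1 + f2 + rng.normal(0, 0.05, n))
        X = pd.DataFrame({
            "a1": f1 + rng.normal(0, 0.02, n),
            "a2": f1 + rng.normal(0, 0.02, n),
            "b1": f2 + rng.normal(0, 0.02, n),
            "b2": f2 + rng.normal(0, 0.02, n),
        })
        cfg = BipConfig()
        model = fit_driver("BIO", "DAT", X, y, cfg)
        composites = {c.name: c for c, _ in model.pc_terms}
        terms = [v for v, _ in model.direct_terms] + list(composites)
        if len(terms) >= 2:
            design = _term_columns(X, terms, composites)
            assert (compute_vif(design) <= cfg.vif_max).all()

    def test_empty_pool_returns_none(self):
        y = pd.Series(np.linspace(0, 1, 20))
        assert fit_driver("BIO", "DAT", pd.DataFrame(index=y.index), y) is None

    def test_roundtrip_through_dict(self, rng):
        n = 100
        latent = rng.uniform(size=n)
        y = pd.Series(latent + rng.normal(0, 0.05, n))
        X = pd.DataFrame({
            "p1": latent + rng.normal(0, 0.01, n),
            "p2": latent + rng.normal(0, 0.01, n),
            "q": rng.uniform(size=n),
        })
        model = fit_driver("BIO", "DAT", X, y)
        clone = DriverModel.from_dict(model.to_dict())
        pd.testing.assert_series_equal(driver_score(model, X), driver_score(clone, X))


class TestDriverScore:
    def make_model(self):
        return DriverModel(
            driver="BIO", dimension="DAT",
            direct_terms=[("u", 1.0), ("v", 1.0)],
            pc_terms=[], fit_stats={},
        )

    def test_flexible_average_arithmetic(self):
        model = self.make_model()
        table = pd.DataFrame({"u": [0.5], "v": [0.5]}, index=["AAA"])
        assert driver_score(model, table).iloc[0] == pytest.approx(0.5)

    def test_missing_term_shrinks_denominator(self):
        model = self.make_model()
        table = pd.DataFrame({"u": [0.5], "v": [np.nan]}, index=["AAA"])
        assert driver_score(model, table).iloc[0] == pytest.approx(0.5)

    def test_all_missing_gives_missing(self):
        model = self.make_model()
        table = pd.DataFrame({"u": [np.nan], "v": [np.nan]}, index=["AAA"])
        assert np.isnan(driver_score(model, table).iloc[0])

    def test_missing_locality_across_countries(self, rng):
        model = self.make_model()
        table = pd.DataFrame(rng.uniform(size=(5, 2)), columns=["u", "v"],
                             index=[f"C{i:02d}A"[:3] for i in range(5)])
        base = driver_score(model, table)
        poked = table.copy()
        poked.iloc[0, 0] = np.nan
        after = driver_score(model, poked)
        pd.testing.assert_series_equal(base.iloc[1:], after.iloc[1:])

    def test_fitted_scores_track_response_direction(self, rng):
        n = 120
        latent = rng.uniform(size=n)
        y = pd.Series(latent + rng.normal(0, 0.05, n))
        X = pd.DataFrame({
            "p1": latent + rng.normal(0, 0.1, n),
            "p2": -latent + rng.normal(0, 0.1, n),
        })
        model = fit_driver("BIO", "DAT", X, y)
        from scipy import stats
        scores = driver_score(model, X)
        assert stats.spearmanr(scores, y).statistic > 0.8
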