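"""Standardization, VIF, model battery, guild contrasts, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from nfixdiv import (
    RandomInterceptLM,
    cube_root,
    fit_all_models,
    guild_pairwise,
    influence_report,
    standardize,
    vif,
)
from nfixdiv.analysis import fit_change_model, results_table


class TestStandardize:
    def test_closed_form(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, params = standardize(df, ["x"])
        np.testing.assert_allclose(out["x"], [-1, 0, 1])
        assert params.loc["x", "mean"] == 2.0 and params.loc["x", "sd"] == 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(3, 2, 100)})
        once, _ = standardize(df, ["x"])
        twice, _ = standardize(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_moments_on_random_columns(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 7, size=(200, 3)), columns=list("abc"))
        out, _ = standardize(df, ["a", "b", "c"])
        for c in "abc":
            assert abs(out[c].mean()) < 1e-12
            assert out[c].std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), ["x"])


class TestCubeRoot:
    def test_odd_monotone(self):
        x = np.array([-8.0, -1.0, 0.0, 1.0, 27.0])
        np.testing.assert_allclose(cube_root(x), [-2, -1, 0, 1, 3])
        assert (np.sign(cube_root(x)) == np.sign(x)).all()


class TestVIF:
    def test_orthogonal_is_one(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        assert (vif(X) < 1.05).all()

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="collinear"):
            v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(4)
        n = 40000
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        v = vif(pd.DataFrame({"a": a, "b": b}))
        assert v["a"] == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_matches_statsmodels(self):
        smo = pytest.importorskip("statsmodels.stats.outliers_influence")
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        X["b"] += 0.5 * X["a"]
        ours = vif(X)
        design = np.column_stack([np.ones(len(X)), X.to_numpy()])
        for j, c in enumerate("abc"):
            ref = smo.variance_inflation_factor(design, j + 1)
            assert ours[c] == pytest.approx(ref, rel=1e-8)


def _synthetic_change_table(rng, n_sites=15, per=10, beta_n=0.0):
    sites = np.repeat([f"s{i}" for i in range(n_sites)], per)
    n = n_sites * per
    cum_n = np.repeat(rng.uniform(5, 40, n_sites), per)
    dt = np.repeat(rng.normal(1, 0.3, n_sites), per)
    dai = np.repeat(rng.normal(0, 0.05, n_sites), per)
    base = rng.uniform(0, 0.2, n)
    u = np.repeat(rng.normal(0, 0.02, n_sites), per)
    y = beta_n * (cum_n - cum_n.mean()) / cum_n.std() + u + rng.normal(0, 0.05, n)
    return pd.DataFrame(
        {
            "site": sites, "delta_prop_rich": y, "delta_pd": y * 100,
            "delta_prop_pd": y / 2, "cum_n": cum_n, "delta_t": dt,
            "delta_ai": dai, "baseline_prop_rich": base,
            "baseline_pd": base * 500, "baseline_prop_pd": base / 4,
        }
    )


class TestModelBattery:
    def test_fits_are_independent_of_requested_variants(self):
        rng = np.random.default_rng(6)
        tbl = _synthetic_change_table(rng)
        solo = fit_all_models(tbl, responses=("delta_prop_rich",))
        full = fit_all_models(tbl, transform=True)
        np.testing.assert_allclose(
            solo["delta_prop_rich"].params.to_numpy(),
            full["delta_prop_rich"].params.to_numpy(),
            atol=1e-12,
        )
        assert "delta_prop_rich_cuberoot" in full

    def test_transform_changes_response_scale_only(self):
        rng = np.random.default_rng(7)
        tbl = _synthetic_change_table(rng)
        raw = fit_change_model(tbl, "delta_pd")
        cr = fit_change_model(tbl, "delta_pd", transform=True)
        assert raw.n_obs == cr.n_obs
        assert abs(cr.params["cum_n"]) < abs(raw.params["cum_n"]) + 100

    def test_results_table_shape(self):
        rng = np.random.default_rng(8)
        tbl = _synthetic_change_table(rng)
        fits = fit_all_models(tbl)
        long = results_table(fits)
        assert set(long["response"]) == {
            "delta_prop_rich", "delta_pd", "delta_prop_pd"
        }
        # 1 intercept + 3 env + 1 baseline per response
        assert (long.groupby("response").size() == 5).all()

    def test_effect_sign_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            tbl = _synthetic_change_table(rng, beta_n=-0.02)
            res = fit_change_model(tbl, "delta_prop_rich")
            hits += res.params["cum_n"] < 0
        assert hits >= 19


def _guild_table(rng, n_sites=25, shift_lost=0.0):
    rows = []
    for s in range(n_sites):
        site_eff = rng.normal(0, 10)
        for p in range(8):
            for guild in ("conserved", "lost", "gained"):
                pd_val = 100 + site_eff + rng.normal(0, 25)
                if guild == "lost":
                    pd_val += shift_lost
                rows.append(
                    {"plot": f"s{s}_p{p}", "site": f"s{s}", "guild": guild,
                     "faith_pd": pd_val}
                )
    return pd.DataFrame(rows)


class TestGuildPairwise:
    def test_reference_refits_agree_on_shared_contrast(self):
        rng = np.random.default_rng(9)
        tbl = _guild_table(rng)
        # conserved - gained from the ref=gained model must equal the
        # difference of coefficients in the ref=lost model
        work = tbl.copy()
        for g in ("conserved", "gained"):
            work[f"g_{g}"] = (work["guild"] == g).astype(float)
        ref_lost = RandomInterceptLM.from_dataframe(
            work, "faith_pd", ["g_conserved", "g_gained"], "site"
        ).fit()
        via_diff = ref_lost.params["g_conserved"] - ref_lost.params["g_gained"]
        direct = guild_pairwise(tbl).set_index("comparison")
        assert direct.loc["conserved - gained", "value"] == pytest.approx(
            via_diff, abs=1e-10
        )
        assert direct.loc["conserved - lost", "value"] == pytest.approx(
            ref_lost.params["g_conserved"], abs=1e-10
        )

    def test_null_rejection_rate(self):
        rejections = []
        for seed in range(60):
            rng = np.random.default_rng(2000 + seed)
            tbl = _guild_table(rng, n_sites=12)
            out = guild_pairwise(tbl)
            rejections.extend(out["p"] < 0.05)
        rate = np.mean(rejections)
        assert 0.005 <= rate <= 0.12  # ~5% with binomial noise

    def test_shift_recovered(self):
        rng = np.random.default_rng(10)
        tbl = _guild_table(rng, shift_lost=30.0)
        out = guild_pairwise(tbl).set_index("comparison")
        assert out.loc["conserved - lost", "value"] == pytest.approx(-30, abs=6)
        assert out.loc["gained - lost", "value"] == pytest.approx(-30, abs=6)

    def test_absent_guild_omitted_with_warning(self):
        rng = np.random.default_rng(11)
        tbl = _guild_table(rng)
        tbl = tbl[tbl["guild"] != "gained"]
        with pytest.warns(UserWarning, match="gained"):
            out = guild_pairwise(tbl)
        assert set(out["comparison"]) == {"conserved - lost"}


class TestInfluence:
    def test_report_flags_injected_outlier(self):
        rng = np.random.default_rng(12)
        tbl = _synthetic_change_table(rng)
        tbl.loc[3, "delta_prop_rich"] += 1.0  # a wild residual
        res = fit_change_model(tbl, "delta_prop_rich")
        rep = influence_report(res)
        assert rep["n_flagged_residuals"] >= 1
        assert rep["max_std_resid"] > 4
        assert len(rep["leave_one_site_out"]) > 0
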