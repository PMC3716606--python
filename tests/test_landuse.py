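"""Mixed-model contrasts, Holm adjustment, and the Spearman screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from socchrono import (
    LandUseMixedModel,
    fit_landuse_model,
    holm_adjust,
    spearman_screen,
    spearman_test,
)
from socchrono.landuse import significance_stars

INTERVALS = ["0-0.15", "0.15-0.3", "0.3-0.6", "0.6-0.9", "0.9-1.2"]


def _paired_long_table(seed, lu_effects, noise_sd=1.0, n_clusters=7):
    """Balanced one-rubber-per-cluster table with known per-depth effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        c_eff = rng.normal(0, 3)
        for land_use in ("forest", "rubber"):
            for d, iv in enumerate(INTERVALS):
                y = 40 + c_eff - 4 * d + rng.normal(0, noise_sd)
                if land_use == "rubber":
                    y += lu_effects[d]
                rows.append(
                    {"cluster_id": f"C{c}", "plot_id": f"C{c}{land_use[0]}",
                     "land_use": land_use, "interval": iv, "y": y}
                )
    return pd.DataFrame(rows)


class TestHolm:
    def test_hand_computation(self):
        adj = holm_adjust([0.01, 0.02, 0.20])
        assert np.allclose(adj, [0.03, 0.04, 0.20])

    def test_all_ones(self):
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0, 1.0]), 1.0)

    def test_family_of_one(self):
        assert holm_adjust([0.123])[0] == pytest.approx(0.123)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force(self, pvals):
        """Brute force: sort, scale by (m - i), running max, cap at 1."""
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        m = len(p)
        scaled = p[order] * (m - np.arange(m))
        stepped = np.minimum(np.maximum.accumulate(scaled), 1.0)
        brute = np.empty(m)
        brute[order] = stepped
        assert np.allclose(holm_adjust(p), brute)

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.08) == "†"
        assert significance_stars(0.5) == ""


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p, n = spearman_test([1, 2, 3, 5, 9], [10, 20, 21, 22, 100])
        assert rho == pytest.approx(1.0)
        assert p <= 0.05

    def test_hand_rank_value(self):
        rho, _, _ = spearman_test([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    # deadline off: the first small-n case builds the permutation table once
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rho_equals_pearson_on_midranks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        x = rng.integers(0, 6, n).astype(float)  # ties are likely
        y = rng.normal(size=n)
        rho, _, _ = spearman_test(x, y)
        if np.isnan(rho):
            assert np.ptp(x) == 0 or np.ptp(y) == 0
        else:
            expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
            assert rho == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_large_n(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p, n = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        # n=4, rho=1: only 1 of 4! permutations reaches |rho| = 1 on each tail
        _, p, _ = spearman_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(2 / 24)

    def test_constant_column_reported_missing(self):
        rho, p, n = spearman_test([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(rho)

    def test_missing_pairs_dropped(self):
        rho, _, n = spearman_test([1, 2, np.nan, 4, 5], [2, 4, 5, 8, np.nan])
        assert n == 3

    def test_screen_shapes(self):
        idx = [f"P{i}" for i in range(8)]
        rng = np.random.default_rng(1)
        responses = pd.DataFrame({"r1": rng.normal(size=8)}, index=idx)
        covs = pd.DataFrame(
            {"c1": rng.normal(size=8), "c2": rng.normal(size=8)}, index=idx
        )
        rows = spearman_screen(responses, covs)
        assert len(rows) == 2
        assert all(abs(r.rho) <= 1 for r in rows)


class TestMixedModel:
    def test_balanced_contrasts_equal_paired_cluster_means(self):
        effects = [-10, -6, -3, -1, 0]
        data = _paired_long_table(3, effects, noise_sd=1.0)
        res = fit_landuse_model(data, "y")
        wide = data.pivot_table(index=["cluster_id", "interval"], columns="land_use", values="y")
        paired = (wide["rubber"] - wide["forest"]).groupby("interval").mean()
        for con in res.contrasts(holm=False):
            assert con.estimate == pytest.approx(paired[con.interval], abs=1e-6)

    def test_constant_response_gives_zero_effects(self):
        data = _paired_long_table(0, [0] * 5, noise_sd=0.0)
        data["y"] = 7.0
        res = fit_landuse_model(data, "y")
        for con in res.contrasts(holm=False):
            assert con.estimate == pytest.approx(0.0, abs=1e-8)

    def test_depth_dependent_losses_yield_significant_interaction(self):
        """Large topsoil loss, null subsoil loss -> land-use x depth interaction."""
        data = _paired_long_table(5, [-12, -8, -2, 0, 0], noise_sd=1.0)
        res = fit_landuse_model(data, "y")
        names = list(res.fe_params.index)
        idx = [i for i, n in enumerate(names) if n.startswith("rubber:depth")]
        L = np.zeros((len(idx), len(names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        b = L @ res.fe_params.to_numpy()
        V = L @ res.cov_fe.to_numpy() @ L.T
        chi2 = float(b @ np.linalg.solve(V, b))
        p = stats.chi2.sf(chi2, len(idx))
        assert p < 0.001

    def test_uniform_effect_has_no_interaction(self):
        data = _paired_long_table(6, [-8] * 5, noise_sd=1.0)
        res = fit_landuse_model(data, "y")
        inter = [n for n in res.fe_params.index if n.startswith("rubber:depth")]
        se = np.sqrt(np.diag(res.cov_fe.to_numpy()))
        for name in inter:
            i = list(res.fe_params.index).index(name)
            z = res.fe_params.iloc[i] / se[i]
            assert abs(z) < 3.5  # no spurious interaction signal

    def test_single_cluster_rejected(self):
        data = _paired_long_table(0, [0] * 5, n_clusters=1)
        with pytest.raises(ValueError, match="cluster"):
            fit_landuse_model(data, "y")

    def test_heteroscedastic_fit_matches_mixedlm_when_homoscedastic(self):
        data = _paired_long_table(9, [-8, -5, -2, -1, 0], noise_sd=1.5)
        default = fit_landuse_model(data, "y")
        het = fit_landuse_model(data, "y", variance_by="land_use")
        for c_def, c_het in zip(default.contrasts(holm=False), het.contrasts(holm=False)):
            assert c_het.estimate == pytest.approx(c_def.estimate, abs=0.05)
            assert c_het.se == pytest.approx(c_def.se, rel=0.2)
        # both residual variances near the generating 1.5^2
        for v in het.resid_var.values():
            assert 0.5 < v < 5.0

    def test_heteroscedastic_fit_separates_variances(self):
        rng = np.random.default_rng(12)
        data = _paired_long_table(12, [0] * 5, noise_sd=0.0)
        sd = np.where(data["land_use"] == "rubber", 4.0, 0.5)
        data["y"] = data["y"] + rng.normal(0, sd)
        het = fit_landuse_model(data, "y", variance_by="land_use")
        assert het.resid_var["rubber"] > 4 * het.resid_var["forest"]

    def test_requested_interval_must_exist(self, bundle, profiles):
        from socchrono.pipeline import landuse_long_table

        long = landuse_long_table(bundle, profiles)
        res = LandUseMixedModel(long, "stock").fit()
        with pytest.raises(ValueError):
            res.contrast("1.2-1.5")

    def test_summary_renders(self):
        data = _paired_long_table(1, [-5] * 5)
        text = fit_landuse_model(data, "y").summary()
        assert "cluster random intercept" in text and "contrast" in text
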