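"""Null model, kernel score test, calibration and per-site perturbation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from sigdriver.association import (
    NoCarrierError,
    bonferroni_adjust,
    build_genotype_matrix,
    eligibility_check,
    fit_null_model,
    inflation_lambda,
    kernel_association_test,
    perturb_sites,
    resample_calibrate,
    variant_site_weights,
)
from sigdriver.pruning import HotspotRegion
from sigdriver.quadform import quadratic_form_tail, ruben_tail


def _hotspot(sites):
    frame = pd.DataFrame(sites, columns=["pos", "alt", "carriers"])
    frame["recurrence"] = frame["carriers"].map(len)
    return HotspotRegion(chrom="chr1", start=1, end=2000,
                         sites=frame[["pos", "alt", "recurrence", "carriers"]])


class TestEligibility:
    def test_single_site_recurrence_six(self):
        hs = _hotspot([(10, "T", tuple(f"t{i}" for i in range(6)))])
        assert eligibility_check(hs)

    def test_ten_variants_with_recurrence_three(self):
        sites = [(10, "T", ("a", "b", "c"))] + [(20 + i, "G", (f"x{i}",)) for i in range(7)]
        assert eligibility_check(_hotspot(sites))

    def test_nine_variants_max_five_not_eligible(self):
        sites = [(10, "T", tuple(f"t{i}" for i in range(5)))] + [
            (20 + i, "G", (f"x{i}",)) for i in range(4)
        ]
        assert not eligibility_check(_hotspot(sites))


class TestSiteWeights:
    @pytest.fixture()
    def profiles(self):
        return pd.DataFrame(
            {
                "tumor_id": ["a", "b", "c", "d", "e"],
                "entity": "E",
                "sex": "female",
                "total_load": [100, 200, 300, 10, 20],
            }
        )

    def test_recurrence_times_median_load(self, profiles):
        hs = _hotspot([(10, "T", ("a", "b", "c")), (20, "G", ("a",)), (30, "C", ("d", "e"))])
        w = variant_site_weights(hs, profiles)
        assert w[0] == pytest.approx(3 * 200)  # R=3, median(100,200,300)
        assert w[1] == pytest.approx(100)      # R=1, load 100 ("a")
        assert w[2] == pytest.approx(2 * 15)   # even count: midpoint median


class TestNullModel:
    def test_constant_response_zero_residuals(self, profiles_300):
        y = pd.Series(0.3, index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        np.testing.assert_allclose(null.residuals, 0, atol=1e-12)

    def test_single_entity_factor_dropped(self, profiles_300):
        profiles = profiles_300.assign(entity="only")
        y = pd.Series(np.random.default_rng(0).random(len(profiles)),
                      index=profiles["tumor_id"])
        null = fit_null_model(y, profiles)
        assert not any(c.startswith("entity") for c in null.columns)

    def test_nvar_coefficient_recovered(self, profiles_300):
        rng = np.random.default_rng(1)
        nvar = profiles_300["total_load"].values.astype(float)
        y = pd.Series(0.3 + 0.001 * nvar + rng.normal(0, 0.05, len(nvar)),
                      index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        coef = dict(zip(null.columns, null.coef))["nvar"]
        se = np.sqrt(null.sigma2 * np.linalg.inv(null.design.T @ null.design)[
            null.columns.index("nvar"), null.columns.index("nvar")])
        assert abs(coef - 0.001) < 3 * se

    def test_residuals_sum_to_zero(self, profiles_300):
        y = pd.Series(np.random.default_rng(2).random(300), index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        assert abs(null.residuals.sum()) < 1e-8


class TestQuadraticFormTail:
    @pytest.mark.parametrize("df", [1, 2, 3, 4, 5])
    def test_chi_square_oracle(self, df):
        q = chi2.isf(0.05, df)
        assert quadratic_form_tail([1.0] * df, q) == pytest.approx(0.05, abs=1e-6)

    def test_q_nonpositive_returns_one(self):
        assert quadratic_form_tail([1.0, 2.0], 0.0) == 1.0
        assert quadratic_form_tail([1.0], -3.0) == 1.0

    def test_monotone_in_q(self):
        lam = [3.0, 1.0, 0.4]
        qs = np.linspace(0.1, 30, 60)
        ps = [quadratic_form_tail(lam, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("lam", [[2.0, 1.0, 0.5], [5.0, 1.0, 0.2, 0.05]])
    def test_matches_ruben_series(self, lam):
        for q in (1.0, 5.0, 12.0):
            assert quadratic_form_tail(lam, q) == pytest.approx(
                ruben_tail(lam, q, n_terms=20000), abs=1e-6
            )


class TestKernelTest:
    def test_single_site_matches_permutation(self, profiles_300):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        g = (rng.random(300) < 0.05).astype(float)[:, None]
        w = np.array([600.0])
        p, _ = kernel_association_test(g, null, w)
        Z = null.project_out(g * w)[:, 0]
        s_obs = float(Z @ null.residuals)
        n_perm = 20000
        perm = np.array([Z @ rng.permutation(null.residuals) for _ in range(n_perm)])
        p_perm = ((perm**2 >= s_obs**2).sum() + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 3 * se + 1e-12

    def test_weight_scaling_leaves_p_unchanged(self, profiles_300):
        rng = np.random.default_rng(10)
        y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        G = (rng.random((300, 4)) < 0.05).astype(float)
        w = rng.uniform(100, 1000, 4)
        p1, _ = kernel_association_test(G, null, w)
        p2, _ = kernel_association_test(G, null, 10 * w)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_all_zero_genotypes_raise(self, profiles_300):
        y = pd.Series(np.random.default_rng(0).random(300), index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        with pytest.raises(NoCarrierError):
            kernel_association_test(np.zeros((300, 2)), null, np.array([1.0, 1.0]))

    def test_direction_tracks_burden_sign(self, profiles_300):
        rng = np.random.default_rng(11)
        y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
        carriers = rng.choice(300, 20, replace=False)
        null0 = fit_null_model(y, profiles_300)
        shift = 3 * np.std(null0.residuals)
        G = np.zeros((300, 1))
        G[carriers, 0] = 1
        up = y.copy(); up.iloc[carriers] += shift
        down = y.copy(); down.iloc[carriers] -= shift
        _, d_up = kernel_association_test(G, fit_null_model(up, profiles_300), np.array([1.0]))
        _, d_down = kernel_association_test(G, fit_null_model(down, profiles_300), np.array([1.0]))
        assert (d_up, d_down) == ("positive", "negative")


class TestResampling:
    def test_floor_and_bounds(self, profiles_300):
        rng = np.random.default_rng(12)
        y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
        carriers = rng.choice(300, 30, replace=False)
        null0 = fit_null_model(y, profiles_300)
        y.iloc[carriers] += 5 * np.std(null0.residuals)
        null = fit_null_model(y, profiles_300)
        G = np.zeros((300, 1)); G[carriers, 0] = 1
        p_raw, _ = kernel_association_test(G, null, np.array([500.0]))
        p_res = resample_calibrate(p_raw, G, null, np.array([500.0]), B=999, seed=0,
                                   b_max=9999)
        assert p_res == pytest.approx(1 / 10000)  # adaptive escalation floor

    def test_seeded_reproducibility(self, profiles_300):
        rng = np.random.default_rng(13)
        y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        G = (rng.random((300, 3)) < 0.05).astype(float)
        w = np.array([100.0, 300.0, 200.0])
        p_raw, _ = kernel_association_test(G, null, w)
        a = resample_calibrate(p_raw, G, null, w, B=999, seed=7)
        b = resample_calibrate(p_raw, G, null, w, B=999, seed=7)
        assert a == b

    def test_null_calibration_tracks_p_raw(self, profiles_300):
        """Under the null, calibrated and raw p agree on average."""
        rng = np.random.default_rng(14)
        diffs = []
        for _ in range(40):
            y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
            null = fit_null_model(y, profiles_300)
            G = (rng.random((300, 3)) < 0.05).astype(float)
            if not G.any(axis=0).all():
                continue
            w = rng.uniform(100, 1000, 3)
            p_raw, _ = kernel_association_test(G, null, w)
            p_res = resample_calibrate(p_raw, G, null, w, B=999, seed=rng)
            diffs.append(abs(p_res - p_raw))
        assert np.mean(diffs) < 0.05


class TestCorrections:
    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni_adjust([0.0005], 100), [0.05])
        np.testing.assert_allclose(bonferroni_adjust([0.02], 100), [1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.3], 1), [0.3])

    def test_bonferroni_m_too_small_raises(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)

    def test_lambda_exact_at_half(self):
        assert inflation_lambda([0.5] * 20) == pytest.approx(1.0)

    def test_lambda_uniform_near_one(self):
        p = np.random.default_rng(15).uniform(size=100_000)
        assert 0.95 <= inflation_lambda(p) <= 1.05

    def test_lambda_flags_tiny_p(self):
        assert inflation_lambda([1e-10] * 20) > 1.5

    def test_lambda_domain_errors(self):
        with pytest.raises(ValueError):
            inflation_lambda([0.5] * 5)
        with pytest.raises(ValueError):
            inflation_lambda([0.0] * 20)


class TestPerturbation:
    def test_single_site_trivial_profile(self, profiles_300):
        hs = _hotspot([(10, "T", tuple(profiles_300["tumor_id"][:6]))])
        y = pd.Series(np.random.default_rng(16).random(300),
                      index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        G = build_genotype_matrix(hs, list(profiles_300["tumor_id"]))
        prof = perturb_sites(hs, G, null, np.array([600.0]))
        assert prof["ratio"].tolist() == [1.0]

    def test_identical_sites_have_equal_ratios(self, profiles_300):
        carriers = tuple(profiles_300["tumor_id"][:8])
        hs = _hotspot([(10, "T", carriers), (40, "T", carriers),
                       (900, "G", tuple(profiles_300["tumor_id"][200:206]))])
        rng = np.random.default_rng(17)
        y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
        null = fit_null_model(y, profiles_300)
        G = build_genotype_matrix(hs, list(profiles_300["tumor_id"]))
        w = variant_site_weights(hs, profiles_300)
        prof = perturb_sites(hs, G, null, w)
        assert prof["ratio"].iloc[0] == pytest.approx(prof["ratio"].iloc[1], rel=1e-6)

    def test_causal_site_attains_max_ratio(self, profiles_300):
        rng = np.random.default_rng(18)
        wins = 0
        for trial in range(10):
            y = pd.Series(rng.beta(2, 5, 300), index=profiles_300["tumor_id"])
            carriers = rng.choice(300, 15, replace=False)
            null0 = fit_null_model(y, profiles_300)
            y.iloc[carriers] += 3 * np.std(null0.residuals)
            null = fit_null_model(y, profiles_300)
            ids = profiles_300["tumor_id"].values
            sites = [(100, "T", tuple(ids[carriers]))]
            for j in range(5):  # passenger singletons
                sites.append((200 + j * 31, "G", (ids[rng.integers(300)],)))
            hs = _hotspot(sites)
            G = build_genotype_matrix(hs, list(ids))
            w = variant_site_weights(hs, profiles_300)
            prof = perturb_sites(hs, G, null, w)
            wins += bool(prof.loc[prof["ratio"].idxmax(), "pos"] == 100)
        assert wins >= 9
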