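import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosel.genetics import (
    FamilyRanking,
    MixedModelSpec,
    VarianceComponents,
    family_breeding_values,
    family_covariance,
    fit_variance_components,
    genetic_correlation,
    genetic_gain,
    heritability,
)
from phenosel.synthdata import TrialConfig, simulate_trial


def balanced_data(B=12, F=8, s_b=0.5, s_f=0.8, s_e=1.0, seed=0):
    """Fully balanced complete design: each family once in each block."""
    rng = np.random.default_rng(seed)
    blk = np.repeat(np.arange(B), F)
    fam = np.tile(np.arange(F), B)
    y = (
        rng.normal(0, s_b, B)[blk]
        + rng.normal(0, s_f, F)[fam]
        + rng.normal(0, s_e, B * F)
    )
    return pd.DataFrame({"y": y, "block": blk, "family": fam})


def anova_components(d):
    """Closed-form expected-mean-square estimators for the balanced design."""
    y = d["y"].to_numpy()
    B, F = d["block"].nunique(), d["family"].nunique()
    fm = d.groupby("family")["y"].mean()
    bm = d.groupby("block")["y"].mean()
    MSf = B * ((fm - y.mean()) ** 2).sum() / (F - 1)
    MSb = F * ((bm - y.mean()) ** 2).sum() / (B - 1)
    SSE = (
        (y - fm[d["family"]].to_numpy() - bm[d["block"]].to_numpy() + y.mean()) ** 2
    ).sum()
    MSe = SSE / ((B - 1) * (F - 1))
    return (MSf - MSe) / B, (MSb - MSe) / F, MSe


def dense_rll(y, Zb, Zf, s2b, s2f, s2e):
    """Independent restricted log-likelihood via the dense covariance matrix."""
    n = len(y)
    V = s2b * Zb @ Zb.T + s2f * Zf @ Zf.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return -0.5 * (
        (n - 1) * math.log(2 * math.pi)
        + np.linalg.slogdet(V)[1]
        + math.log(XVX[0, 0])
        + float(y @ P @ y)
    )


class TestFitVarianceComponents:
    def test_balanced_matches_anova_oracle(self):
        for seed in range(3):
            d = balanced_data(seed=seed)
            vc = fit_variance_components(
                MixedModelSpec("y", d), tol=1e-13, max_iter=20000
            )
            f, b, e = anova_components(d)
            assert vc.sigma2_f == pytest.approx(f, abs=1e-6)
            assert vc.sigma2_b == pytest.approx(b, abs=1e-6)
            assert vc.sigma2_e == pytest.approx(e, abs=1e-6)

    def test_tiny_dataset_beats_grid_oracle(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(
            {
                "y": rng.normal(size=6),
                "block": [0, 0, 0, 1, 1, 1],
                "family": [0, 1, 2, 0, 1, 2],
            }
        )
        vc = fit_variance_components(MixedModelSpec("y", d), tol=1e-12, max_iter=5000)
        Zb = np.eye(2)[d["block"]]
        Zf = np.eye(3)[d["family"]]
        y = d["y"].to_numpy()
        vary = y.var()
        grid = np.geomspace(1e-4 * vary, 4 * vary, 50)
        best = -np.inf
        for sb in grid:
            for sf in grid:
                for se in grid:
                    best = max(best, dense_rll(y, Zb, Zf, sb, sf, se))
        at_opt = dense_rll(
            y, Zb, Zf, max(vc.sigma2_b, 1e-12), max(vc.sigma2_f, 1e-12), vc.sigma2_e
        )
        assert at_opt >= best - 1e-6

    def test_rll_matches_dense_oracle(self):
        d = balanced_data(B=10, F=8, s_b=0.9, s_f=1.1, seed=4)
        vc = fit_variance_components(MixedModelSpec("y", d), tol=1e-12, max_iter=20000)
        assert vc.sigma2_b > 0 and vc.sigma2_f > 0  # interior optimum
        Zb = np.eye(10)[d["block"]]
        Zf = np.eye(8)[d["family"]]
        expected = dense_rll(
            d["y"].to_numpy(),
            Zb,
            Zf,
            max(vc.sigma2_b, 1e-12),
            max(vc.sigma2_f, 1e-12),
            vc.sigma2_e,
        )
        assert vc.rll == pytest.approx(expected, abs=1e-6)

    def test_pure_noise_family_variance_vanishes(self):
        rng = np.random.default_rng(5)
        B, F = 40, 20
        d = pd.DataFrame(
            {
                "y": rng.normal(size=B * F),
                "block": np.repeat(np.arange(B), F),
                "family": np.tile(np.arange(F), B),
            }
        )
        vc = fit_variance_components(MixedModelSpec("y", d))
        assert vc.sigma2_f <= 0.05 * vc.sigma2_e

    def test_rll_monotone_over_iterations(self):
        d = balanced_data(seed=6)
        vc = fit_variance_components(MixedModelSpec("y", d))
        hist = np.asarray(vc.rll_history)
        assert (np.diff(hist) >= -1e-9).all()

    def test_rejects_single_family(self):
        d = pd.DataFrame({"y": [1.0, 2.0], "block": [0, 1], "family": [0, 0]})
        with pytest.raises(ValueError, match="famil"):
            fit_variance_components(MixedModelSpec("y", d))

    def test_rejects_all_missing(self):
        d = pd.DataFrame(
            {"y": [np.nan, np.nan], "block": [0, 1], "family": [0, 1]}
        )
        with pytest.raises(ValueError, match="missing"):
            fit_variance_components(MixedModelSpec("y", d))

    def test_site_fixed_option(self, default_dataset):
        sl = default_dataset.analysis_frame().query("month == 'Jul'")
        vc = fit_variance_components(MixedModelSpec("height_m", sl, site_fixed=True))
        assert vc.converged
        assert vc.sigma2_f > 0


class TestHeritability:
    @pytest.mark.parametrize(
        "f,b,e,expected",
        [(1.0, 1.0, 8.0, 0.25), (0.0, 1.0, 9.0, 0.0), (4.0, 0.0, 6.0, 1.0)],
    )
    def test_substitution(self, f, b, e, expected):
        vc = VarianceComponents(f, b, e, True, 1)
        assert heritability(vc).h2 == pytest.approx(expected)

    def test_all_zero_components_warn(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, True, 1)
        with pytest.warns(RuntimeWarning):
            assert heritability(vc).h2 == 0.0

    def test_bounded_by_coefficient(self):
        vc = VarianceComponents(5.0, 0.0, 0.0, True, 1)
        h = heritability(vc)
        assert 0 <= h.h2 <= h.coefficient

    def test_exclude_block_option(self):
        vc = VarianceComponents(1.0, 1.0, 3.0, True, 1)
        assert heritability(vc, include_block=False).h2 == pytest.approx(2.5 / 4)


class TestGeneticCorrelation:
    def test_zero_covariance(self):
        vi = VarianceComponents(2.0, 0.0, 1.0, True, 1)
        vj = VarianceComponents(2.0, 0.0, 1.0, True, 1)
        assert genetic_correlation(vi, vj, 0.0) == 0.0

    def test_perfect_correlation(self):
        vi = VarianceComponents(2.0, 0.0, 1.0, True, 1)
        vj = VarianceComponents(2.0, 0.0, 1.0, True, 1)
        assert genetic_correlation(vi, vj, 2.0) == pytest.approx(1.0)

    def test_outside_unit_interval_clipped_with_warning(self):
        vi = VarianceComponents(1.0, 0.0, 1.0, True, 1)
        vj = VarianceComponents(1.0, 0.0, 1.0, True, 1)
        with pytest.warns(RuntimeWarning, match="clipped"):
            assert genetic_correlation(vi, vj, 1.5) == 1.0

    def test_zero_family_variance_nan(self):
        vi = VarianceComponents(0.0, 0.0, 1.0, True, 1)
        vj = VarianceComponents(1.0, 0.0, 1.0, True, 1)
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert math.isnan(genetic_correlation(vi, vj, 0.5))

    def test_sum_trait_identity_on_constructed_data(self):
        # two traits sharing the exact same family effects -> r_g ~ 1
        rng = np.random.default_rng(8)
        B, F = 40, 20
        blk = np.repeat(np.arange(B), F)
        fam = np.tile(np.arange(F), B)
        f_eff = rng.normal(0, 1.0, F)
        d = pd.DataFrame(
            {
                "t1": f_eff[fam] + rng.normal(0, 1, B * F),
                "t2": f_eff[fam] + rng.normal(0, 1, B * F),
                "block": blk,
                "family": fam,
            }
        )
        vi, vj, cov = family_covariance(d, "t1", "t2")
        r = genetic_correlation(vi, vj, cov)
        assert r > 0.8


class TestBreedingValues:
    def test_balanced_closed_form_shrinkage(self):
        d = balanced_data(seed=1)
        B = d["block"].nunique()
        spec = MixedModelSpec("y", d)
        vc = fit_variance_components(spec, tol=1e-13, max_iter=20000)
        rk = family_breeding_values(spec, tol=1e-13, max_iter=20000)
        lam = B * vc.sigma2_f / (B * vc.sigma2_f + vc.sigma2_e)
        fm = d.groupby("family")["y"].mean()
        closed = lam * (fm - d["y"].mean())
        got = rk.table.set_index("family")["blup"]
        np.testing.assert_allclose(got.to_numpy(), closed.to_numpy(), atol=1e-8)

    def test_blups_sum_to_zero_balanced(self):
        rk = family_breeding_values(MixedModelSpec("y", balanced_data(seed=3)))
        assert rk.table["blup"].sum() == pytest.approx(0.0, abs=1e-6)

    def test_zero_family_signal_full_shrinkage(self):
        rng = np.random.default_rng(4)
        B, F = 10, 6
        blk = np.repeat(np.arange(B), F)
        d = pd.DataFrame(
            {
                "y": rng.normal(0, 1, B)[blk],  # block-only signal
                "block": blk,
                "family": np.tile(np.arange(F), B),
            }
        )
        rk = family_breeding_values(MixedModelSpec("y", d))
        np.testing.assert_allclose(rk.table["blup"].to_numpy(), 0.0, atol=1e-3)

    def test_ranks_are_permutation(self, default_dataset):
        sl = default_dataset.analysis_frame().query("month == 'Jul'")
        rk = family_breeding_values(MixedModelSpec("height_m", sl))
        assert sorted(rk.table["rank"]) == list(range(1, 21))

    def test_ranking_recovers_truth(self, strong_dataset):
        sl = strong_dataset.analysis_frame().query("month == 'Jul'")
        rk = family_breeding_values(MixedModelSpec("height_m", sl))
        truth = strong_dataset.truth["family_effects"]["height"]
        merged = rk.table.set_index("family").join(truth.rename("true"))
        rho = stats.spearmanr(merged["blup"], merged["true"]).statistic
        assert rho >= 0.8


class TestGeneticGain:
    @staticmethod
    def ranking(bvs):
        tab = pd.DataFrame(
            {"family": [f"F{i:02d}" for i in range(len(bvs))], "blup": bvs}
        )
        tab["deviation"] = tab["blup"]
        tab["rank"] = tab["blup"].rank(ascending=False).astype(int)
        return FamilyRanking(table=tab)

    def test_top_ten_percent_of_1_to_10(self):
        assert genetic_gain(self.ranking(list(range(1, 11))), 0.1) == pytest.approx(4.5)

    def test_top_thirty_percent_of_1_to_10(self):
        assert genetic_gain(self.ranking(list(range(1, 11))), 0.3) == pytest.approx(3.5)

    def test_select_everything_is_zero_gain(self):
        assert genetic_gain(self.ranking([3.0, 1.0, 2.0]), 1.0) == pytest.approx(0.0)

    def test_monotone_non_increasing_in_ratio(self, rng):
        rk = self.ranking(rng.normal(size=20).tolist())
        gains = [genetic_gain(rk, r) for r in (0.1, 0.2, 0.3, 0.5, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(gains, gains[1:]))

    def test_invalid_ratio_rejected(self):
        rk = self.ranking([1.0, 2.0])
        for r in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                genetic_gain(rk, r)

    def test_literal_form_flag(self):
        rk = self.ranking(list(range(1, 11)))
        assert genetic_gain(rk, 0.1, literal_form=True) == pytest.approx(
            10 * 0.1 - 5.5
        )


class TestRecovery:
    def test_rg_recovery_short(self):
        # fuller 50-replicate version lives in the acceptance suite
        rg = ((1.0, 0.8, 0.7), (0.8, 1.0, 0.7), (0.7, 0.7, 1.0))
        est = []
        for seed in range(10):
            data = simulate_trial(TrialConfig(seed=seed, rg_matrix=rg))
            sl = data.analysis_frame().query("month == 'Jul'")
            vi, vj, cov = family_covariance(sl, "height_m", "crown_area_m2")
            est.append(genetic_correlation(vi, vj, cov))
        assert abs(np.nanmean(est) - 0.8) < 0.15
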