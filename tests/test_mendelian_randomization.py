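import numpy as np
import pandas as pd
import pytest

from atriumkit.mendelian_randomization import (
    MRInstrumentSet,
    bonferroni_threshold,
    cochran_q,
    harmonize,
    mr_egger,
    mr_ivw,
    mr_median,
    pleiotropy_screen,
    run_mr,
    select_instruments,
)
from atriumkit.synthetic_data import MRSimSpec, make_mr_dataset


def _iv(bx, sy, by, sx=None):
    bx = np.asarray(bx, float)
    return MRInstrumentSet(
        pd.DataFrame(
            {
                "rsid": [f"s{i}" for i in range(len(bx))],
                "beta_exp": bx,
                "se_exp": np.full(len(bx), 0.001) if sx is None else np.asarray(sx),
                "beta_out": np.asarray(by, float),
                "se_out": np.asarray(sy, float),
            }
        )
    )


def _summary(rows):
    return pd.DataFrame(rows, columns=["rsid", "chr", "bp", "ea", "oa", "beta", "se", "p"])


class TestSelectInstruments:
    def test_single_cluster_yields_one_instrument(self):
        rows = [
            ("a", "1", 1_000_000, "A", "G", 0.1, 0.01, 1e-9),
            ("b", "1", 2_000_000, "A", "G", 0.1, 0.01, 1e-8),
            ("c", "1", 3_000_000, "A", "G", 0.1, 0.01, 1e-7),
        ]
        leads = select_instruments(_summary(rows))
        assert len(leads) == 1
        assert leads.iloc[0]["rsid"] == "a"

    def test_threshold_excludes_weak_snps(self):
        rows = [("a", "1", 1_000_000, "A", "G", 0.1, 0.01, 1e-5)]
        with pytest.raises(ValueError, match="no variants"):
            select_instruments(_summary(rows))

    def test_synthetic_25_cluster_genome(self):
        from atriumkit.synthetic_data import make_leadsnp_table

        table = make_leadsnp_table(25, snps_per_cluster=3, inter_gap_kb=11_000, seed=5)
        assert len(select_instruments(table, p_thresh=1e-6, window_kb=5000)) == 25


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = _summary([("a", "1", 1, "G", "A", 0.2, 0.01, 1e-9)])
        out = _summary([("a", "1", 1, "G", "A", 0.1, 0.02, 1e-4)])
        iv = harmonize(exp, out)
        assert iv.table.iloc[0]["beta_out"] == pytest.approx(0.1)

    def test_palindromic_snp_removed(self):
        exp = _summary(
            [
                ("a", "1", 1, "A", "T", 0.2, 0.01, 1e-9),
                ("b", "1", 2, "G", "A", 0.2, 0.01, 1e-9),
            ]
        )
        out = _summary(
            [
                ("a", "1", 1, "A", "T", 0.1, 0.02, 1e-4),
                ("b", "1", 2, "G", "A", 0.1, 0.02, 1e-4),
            ]
        )
        iv = harmonize(exp, out)
        assert list(iv.table["rsid"]) == ["b"]

    def test_swapped_alleles_flip_outcome_sign(self):
        exp = _summary([("a", "1", 1, "G", "A", 0.2, 0.01, 1e-9)])
        out = _summary([("a", "1", 1, "A", "G", 0.1, 0.02, 1e-4)])
        iv = harmonize(exp, out)
        assert iv.table.iloc[0]["beta_out"] == pytest.approx(-0.1)

    def test_mismatched_alleles_dropped_with_warning(self, caplog):
        exp = _summary(
            [
                ("a", "1", 1, "G", "A", 0.2, 0.01, 1e-9),
                ("b", "1", 2, "C", "A", 0.2, 0.01, 1e-9),
            ]
        )
        out = _summary(
            [
                ("a", "1", 1, "G", "C", 0.1, 0.02, 1e-4),
                ("b", "1", 2, "C", "A", 0.1, 0.02, 1e-4),
            ]
        )
        import logging

        with caplog.at_level(logging.WARNING):
            iv = harmonize(exp, out)
        assert list(iv.table["rsid"]) == ["b"]
        assert "mismatch" in caplog.text

    def test_no_overlap_raises(self):
        exp = _summary([("a", "1", 1, "G", "A", 0.2, 0.01, 1e-9)])
        out = _summary([("z", "1", 1, "G", "A", 0.1, 0.02, 1e-4)])
        with pytest.raises(ValueError):
            harmonize(exp, out)


class TestIVW:
    def test_collinear_instruments_recover_slope_exactly(self):
        bx = np.array([0.1, 0.2, 0.15, 0.08])
        res = mr_ivw(_iv(bx, [0.01, 0.02, 0.015, 0.01], 0.7 * bx))
        assert res.estimate == pytest.approx(0.7)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_matches_weighted_regression_oracle(self):
        bx = np.array([0.10, 0.20, 0.15])
        by = np.array([0.05, 0.11, 0.07])
        sy = np.array([0.01, 0.02, 0.015])
        res = mr_ivw(_iv(bx, sy, by))
        # independent oracle: least squares on sqrt-weight-scaled data
        sw = 1.0 / sy
        theta, *_ = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)
        assert res.estimate == pytest.approx(float(theta[0]), abs=1e-12)

    def test_fewer_than_two_instruments_rejected(self):
        with pytest.raises(ValueError, match="Wald"):
            mr_ivw(_iv([0.1], [0.01], [0.05]))

    def test_random_effects_widens_not_narrows(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3])
        by = np.array([0.08, 0.02, 0.11, 0.30])  # heterogeneous
        sy = np.full(4, 0.01)
        fe = mr_ivw(_iv(bx, sy, by), random_effects=False)
        re = mr_ivw(_iv(bx, sy, by), random_effects=True)
        assert re.se >= fe.se
        assert re.estimate == fe.estimate

    def test_simulated_recovery_of_log_odds_effect(self):
        theta = np.log(1.77)
        estimates = []
        for seed in range(60):
            exp, out = make_mr_dataset(
                MRSimSpec(k=50, theta=theta, seed=seed, swap_frac=0.0)
            )
            iv = _iv(exp["beta"], out["se"], out["beta"], sx=exp["se"])
            estimates.append(mr_ivw(iv).estimate)
        assert np.mean(estimates) == pytest.approx(theta, abs=0.01)


class TestEgger:
    def test_two_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(_iv([0.1, 0.2], [0.01, 0.01], [0.05, 0.1]))

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        bx = np.abs(rng.normal(0.1, 0.03, 8))
        by = 0.4 * bx + 0.02 + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.01, 0.03, 8)
        res = mr_egger(_iv(bx, sy, by))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert res.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        intercepts = []
        for seed in range(30):
            exp, out = make_mr_dataset(
                MRSimSpec(
                    k=50, theta=0.3, pleiotropy="balanced", pleiotropy_scale=0.03,
                    seed=seed, swap_frac=0.0,
                )
            )
            iv = _iv(exp["beta"], out["se"], out["beta"], sx=exp["se"])
            intercepts.append(mr_egger(iv).intercept)
        assert abs(np.mean(intercepts)) < 0.005

    def test_bootstrap_se_close_to_analytic(self):
        exp, out = make_mr_dataset(MRSimSpec(k=50, theta=0.4, seed=2, swap_frac=0.0))
        iv = _iv(exp["beta"], out["se"], out["beta"], sx=exp["se"])
        analytic = mr_egger(iv)
        boot = mr_egger(iv, n_boot=400, seed=1)
        assert boot.estimate == pytest.approx(analytic.estimate)
        assert boot.se == pytest.approx(analytic.se, rel=0.6)


class TestMedian:
    def test_homogeneous_ratios_give_common_slope(self):
        bx = np.array([0.1, 0.2, 0.15, 0.12])
        iv = _iv(bx, np.full(4, 1e-8), 0.9 * bx, sx=np.full(4, 1e-8))
        for weighted in (False, True):
            res = mr_median(iv, weighted=weighted, n_boot=200, seed=0)
            assert res.estimate == pytest.approx(0.9)
            assert res.se < 1e-6  # negligible spread for a degenerate set

    def test_simple_median_robust_to_outlier(self):
        bx = np.ones(5) * 0.1
        ratios = np.array([1.0, 1.0, 1.0, 1.0, 9.0])
        iv = _iv(bx, np.full(5, 0.01), ratios * bx)
        res = mr_median(iv, weighted=False, n_boot=100, seed=0)
        assert res.estimate == pytest.approx(1.0)

    def test_dominant_weight_instrument_wins(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.09])
        sy = np.array([0.005, 0.05, 0.05])  # first ratio carries >50% weight
        w = bx**2 / sy**2
        assert w[0] / w.sum() > 0.5
        res = mr_median(_iv(bx, sy, by), weighted=True, n_boot=100, seed=0)
        assert res.estimate == pytest.approx(0.1)  # ratio of the dominant SNP

    def test_zero_exposure_beta_dropped(self, caplog):
        import logging

        bx = np.array([0.0, 0.1, 0.2, 0.15])
        iv = _iv(bx, np.full(4, 0.01), np.array([0.5, 0.05, 0.1, 0.07]))
        with caplog.at_level(logging.WARNING):
            res = mr_median(iv, weighted=False, n_boot=100, seed=0)
        assert res.n_instruments == 3
        assert "zero exposure" in caplog.text


class TestCochranQ:
    def test_homogeneous_q_zero(self):
        bx = np.array([0.1, 0.2, 0.15])
        iv = _iv(bx, np.full(3, 0.01), 0.5 * bx)
        q, p = cochran_q(iv, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_instrument_hand_computation(self):
        # ratios 0.5 and 1.0; weights bx^2/sy^2 = 100 and 400
        iv = _iv([0.1, 0.2], [0.01, 0.01], [0.05, 0.2])
        est = 0.9  # arbitrary reference value
        q, _ = cochran_q(iv, est)
        assert q == pytest.approx(100 * (0.5 - 0.9) ** 2 + 400 * (1.0 - 0.9) ** 2)

    def test_homogeneous_simulation_mean_q_near_df(self):
        rng = np.random.default_rng(0)
        qs = []
        k = 20
        for _ in range(200):
            bx = rng.normal(0.2, 0.02, k)
            sy = np.full(k, 0.02)
            by = 0.5 * bx + rng.normal(0, sy)
            q, _ = cochran_q(_iv(bx, sy, by), mr_ivw(_iv(bx, sy, by)).estimate)
            qs.append(q / (k - 1))
        assert np.mean(qs) == pytest.approx(1.0, abs=0.1)


class TestPleiotropyScreen:
    def test_bonferroni_threshold_19_by_7(self):
        assert bonferroni_threshold(19, 7) == pytest.approx(0.05 / 133)

    def test_planted_association_flagged(self):
        rng = np.random.default_rng(1)
        n = 300
        dosages = pd.DataFrame({"snp1": rng.integers(0, 3, n).astype(float),
                                "snp2": rng.integers(0, 3, n).astype(float)})
        factors = pd.DataFrame({
            "height": 10.0 * dosages["snp1"] + rng.normal(0, 1, n),
            "weight": rng.normal(0, 1, n),
        })
        report = pleiotropy_screen(dosages, factors)
        planted = report[(report.snp == "snp1") & (report.risk_factor == "height")]
        assert bool(planted.iloc[0]["flagged"])
        assert report["threshold"].iloc[0] == pytest.approx(0.05 / 4)

    def test_null_familywise_flag_rate_controlled(self):
        rng = np.random.default_rng(2)
        n = 120
        any_flagged = 0
        reps = 40
        for _ in range(reps):
            dosages = pd.DataFrame(
                {f"s{i}": rng.integers(0, 3, n).astype(float) for i in range(5)}
            )
            factors = pd.DataFrame(
                {f"f{i}": rng.normal(0, 1, n) for i in range(7)}
            )
            any_flagged += pleiotropy_screen(dosages, factors)["flagged"].any()
        assert any_flagged / reps < 0.15  # familywise ~5%

    def test_collinear_design_rejected(self):
        n = 50
        dosages = pd.DataFrame({"snp1": np.ones(n)})  # collinear with intercept
        factors = pd.DataFrame({"f": np.random.default_rng(0).normal(size=n)})
        with pytest.raises(ValueError, match="rank"):
            pleiotropy_screen(dosages, factors)


class TestSignEquivariance:
    def test_negating_exposure_negates_every_estimator(self):
        exp, out = make_mr_dataset(MRSimSpec(k=30, theta=0.4, seed=9, swap_frac=0.0))
        iv = _iv(exp["beta"], out["se"], out["beta"], sx=exp["se"])
        neg = _iv(-exp["beta"], out["se"], out["beta"], sx=exp["se"])
        assert mr_ivw(neg).estimate == pytest.approx(-mr_ivw(iv).estimate)
        assert mr_egger(neg).estimate == pytest.approx(-mr_egger(iv).estimate)
        for weighted in (False, True):
            a = mr_median(iv, weighted=weighted, n_boot=50, seed=3).estimate
            b = mr_median(neg, weighted=weighted, n_boot=50, seed=3).estimate
            assert b == pytest.approx(-a, rel=1e-6)


class TestRunMR:
    def test_full_report_from_synthetic_tables(self):
        exp, out = make_mr_dataset(
            MRSimSpec(k=40, theta=0.5, seed=21, palindromic_frac=0.1)
        )
        report = run_mr(exp, out, n_boot=200, seed=1)
        assert set(report["method"]) == {"ivw", "egger", "simple_median", "weighted_median"}
        assert (report["n_snps"] <= 40).all()
        for est in report["estimate"]:
            assert est == pytest.approx(0.5, abs=0.15)
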