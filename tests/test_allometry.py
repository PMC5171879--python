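"""Allometric regression, residual-variance indices, and the printed-summary
statistics around them."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from stasiscope import allometry as alm
from stasiscope.reference_data import RESIDUAL_VARIANCES
from conftest import make_morph_config
from stasiscope.synthetic_data import gen_morphometry


def table_from_points(xs, ys, pop="P1", nest="n1"):
    rows = []
    for i, (x, y) in enumerate(zip(xs, ys)):
        rows.append((pop, nest, f"w{i}", "HW", float(np.exp(x))))
        rows.append((pop, nest, f"w{i}", "HTL", float(np.exp(y))))
    return pd.DataFrame(
        rows, columns=["population", "nest", "individual", "character", "length_mm"]
    )


class TestLnTransform:
    def test_known_values(self):
        t = table_from_points([0.0], [1.0])
        out = alm.ln_transform(t)
        assert out.loc[out["character"] == "HW", "ln_length"].iloc[0] == 0.0
        assert out.loc[out["character"] == "HTL", "ln_length"].iloc[0] == pytest.approx(1.0)
        assert out.attrs["original_unit"] == "mm"

    def test_nonpositive_length_error_names_row(self):
        t = table_from_points([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        t.loc[2, "length_mm"] = 0.0
        with pytest.raises(ValueError, match="w1"):
            alm.ln_transform(t)


class TestFitAllometry:
    def test_exact_line(self):
        t = alm.ln_transform(table_from_points([0, 1, 2], [0, 2, 4]))
        fit = alm.fit_allometry(t, "HTL")[0]
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-24)

    def test_residuals_sum_to_zero_and_match_normal_equations(self, rng):
        x = rng.normal(0.5, 0.3, size=30)
        y = 1.2 * x + rng.normal(0, 0.05, size=30)
        t = alm.ln_transform(table_from_points(x, y))
        fit = alm.fit_allometry(t, "HTL")[0]
        assert abs(fit.residuals.sum()) < 1e-10
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert fit.residual_variance == pytest.approx(
            np.sum(fit.residuals**2) / 28, abs=1e-15
        )

    def test_degenerate_covariate_and_small_group_errors(self):
        t = alm.ln_transform(table_from_points([1, 1, 1], [0, 1, 2]))
        with pytest.raises(ValueError, match="zero variance"):
            alm.fit_allometry(t, "HTL")
        t2 = alm.ln_transform(table_from_points([0, 1], [0, 1]))
        with pytest.raises(ValueError, match=">= 3"):
            alm.fit_allometry(t2, "HTL")

    def test_scaling_lengths_changes_only_intercept(self):
        cfg = make_morph_config(n_pops=2, seed=13)
        raw = gen_morphometry(cfg)
        scaled = raw.copy()
        scaled["length_mm"] *= 3.7
        f1 = alm.fit_allometry(alm.ln_transform(raw), "HTSL")
        f2 = alm.fit_allometry(alm.ln_transform(scaled), "HTSL")
        for a, b in zip(f1, f2):
            assert a.slope == pytest.approx(b.slope, abs=1e-10)
            assert a.residual_variance == pytest.approx(b.residual_variance, abs=1e-12)


class TestResidualVarianceTable:
    def test_published_margins_reproduced(self):
        # across-population mean +/- SD from the printed per-population values
        tbl = RESIDUAL_VARIANCES
        stat = alm.summarize_across_populations(tbl.loc["FTSL"])
        assert stat.mean == pytest.approx(17.0, abs=0.05)
        assert stat.sd == pytest.approx(6.98, abs=0.005)
        assert alm.summarize_across_populations(tbl.loc["HTL"]).mean == pytest.approx(
            6.9, abs=0.05
        )

    def test_zero_residuals_give_zero_variance(self):
        t = alm.ln_transform(table_from_points([0, 1, 2, 3], [0, 1, 2, 3]))
        fits = {"HTL": alm.fit_allometry(t, "HTL")}
        out = alm.residual_variance_by_population(fits)
        assert out.loc["HTL", "P1"] == pytest.approx(0.0, abs=1e-20)


class TestSlopeVariance:
    def test_hand_values(self):
        def fake(slope):
            return alm.AllometricFit(
                group="x", level="population", character="A", slope=slope,
                intercept=0.0, residuals=np.zeros(3), residual_variance=0.0, n=3,
            )

        assert alm.slope_variance_across_populations(
            [fake(1.0), fake(2.0), fake(3.0)]
        ) == pytest.approx(1.0)
        assert alm.slope_variance_across_populations(
            [fake(1.5), fake(1.5)]
        ) == 0.0
        with pytest.raises(ValueError):
            alm.slope_variance_across_populations([fake(1.0)])


class TestVarianceRatio:
    def test_equal_variances(self):
        f, p = alm.variance_ratio_test(2.0, 10, 2.0, 10)
        assert f == 1.0 and p == 1.0

    def test_zero_denominator_reports_infinite_f(self):
        f, p = alm.variance_ratio_test(1.0, 5, 0.0, 5)
        assert np.isinf(f) and p == 0.0

    @pytest.mark.parametrize("f,df1,df2", [(6.658, 7, 7), (2.5, 4, 9), (0.3, 8, 3)])
    def test_two_sided_p_matches_numerical_cdf_integration(self, f, df1, df2):
        _, p = alm.variance_ratio_test(f, df1, 1.0, df2)
        cdf, _ = integrate.quad(lambda x: stats.f.pdf(x, df1, df2), 0, f)
        assert p == pytest.approx(2 * min(cdf, 1 - cdf), abs=1e-6)

    def test_bonferroni_wrapper(self):
        assert alm.bonferroni(0.02, 3) == pytest.approx(0.06)
        assert alm.bonferroni(0.5, 3) == 1.0


class TestPairedT:
    def test_identical_vectors_give_zero_t(self):
        t, df, p = alm.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_constant_nonzero_differences_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            alm.paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_hand_oracle(self):
        a = np.array([1.0, 1.0, 1.0, 1.001])
        b = np.zeros(4)
        t, df, _ = alm.paired_t_test(a, b)
        d = a - b
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        assert t == pytest.approx(expect, abs=1e-10)
        assert df == 3

    def test_published_residual_variance_contrasts(self):
        # recomputed from printed (rounded) per-population cells: statistics
        # land close to the published 4.379 / 4.884 / 4.504 with the same
        # significance ordering
        tbl = RESIDUAL_VARIANCES
        t1, _, p1 = alm.paired_t_test(tbl.loc["FTSL"], tbl.loc["HTL"])
        t2, _, p2 = alm.paired_t_test(tbl.loc["HTSL"], tbl.loc["HTL"])
        t3, _, p3 = alm.paired_t_test(tbl.loc["HTSL"], tbl.loc["FTSL"])
        assert t1 == pytest.approx(4.379, rel=0.03)
        assert t2 == pytest.approx(4.884, rel=0.03)
        assert t3 == pytest.approx(4.504, rel=0.03)
        assert p2 < p3 < p1  # same ordering as the published P values


class TestTwoSampleTFromSummary:
    def test_published_frequency_of_use_contrast(self):
        from stasiscope.reference_data import FTS_USE, HTS_USE

        t, df, p = alm.two_sample_t_from_summary(FTS_USE, HTS_USE)
        assert df == 18
        assert t == pytest.approx(19.931, rel=0.001)
        assert p < 0.0001

    def test_equal_summaries_and_moment_matched_oracle(self, rng):
        s = alm.SummaryStat(mean=5.0, sd=1.0, n=8)
        t, _, _ = alm.two_sample_t_from_summary(s, s)
        assert t == 0.0
        # reconstruct raw vectors with exactly the stated moments
        for _ in range(3):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 2, 9)
            a = (a - a.mean()) / a.std(ddof=1)
            b = (b - b.mean()) / b.std(ddof=1) * 2.0 + 0.5
            ta, df, pa = alm.two_sample_t_from_summary(
                alm.SummaryStat(0.0, 1.0, 12), alm.SummaryStat(0.5, 2.0, 9)
            )
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert ta == pytest.approx(ref.statistic, abs=1e-8)
            assert pa == pytest.approx(ref.pvalue, abs=1e-8)


class TestSlopeHomogeneity:
    def test_distinct_slopes_detected(self):
        cfg = make_morph_config(
            n_pops=2, nests=1, workers=300,
            residual_sd={"A": 0.02}, seed=31,
        )
        # overwrite slopes: 0.8 vs 1.2
        pops = []
        for pop, slope in zip(cfg.populations, (0.8, 1.2)):
            pops.append(
                type(pop)(
                    id=pop.id, latitude=pop.latitude, slopes={"A": slope},
                    intercepts={"A": -0.5}, residual_sd={"A": 0.02},
                )
            )
        cfg = type(cfg)(populations=tuple(pops), nests_per_population=1,
                        workers_per_nest=300, seed=31)
        table = alm.ln_transform(gen_morphometry(cfg))
        f, (df1, df2), p = alm.slope_homogeneity_test(table, "A")
        assert df1 == 1
        assert p < 1e-6

    def test_single_population_rejected(self):
        cfg = make_morph_config(n_pops=1, seed=2)
        table = alm.ln_transform(gen_morphometry(cfg))
        with pytest.raises(ValueError, match="2 populations"):
            alm.slope_homogeneity_test(table, "HTL")

    def test_equal_true_slopes_usually_not_rejected(self):
        # shared generating slope: the interaction F should not be extreme
        ps = []
        for seed in range(5):
            cfg = make_morph_config(
                n_pops=4, nests=2, workers=50,
                residual_sd={"A": 0.03},
                slopes={"A": 1.0}, seed=100 + seed,
            )
            table = alm.ln_transform(gen_morphometry(cfg))
            ps.append(alm.slope_homogeneity_test(table, "A")[2])
        assert min(ps) > 1e-4
        assert max(ps) > 0.1


class TestSlopeLatitude:
    def fits_from(self, slopes):
        return [
            alm.AllometricFit(
                group=f"P{i}", level="population", character="A", slope=s,
                intercept=0.0, residuals=np.zeros(3), residual_variance=0.0, n=3,
            )
            for i, s in enumerate(slopes)
        ]

    def test_perfect_linear_relation(self):
        fits = self.fits_from([1.0, 1.1, 1.2, 1.3])
        lats = {f"P{i}": 30.0 + 2 * i for i in range(4)}
        r, p = alm.slope_latitude_correlation(fits, lats)
        assert r == pytest.approx(1.0)

    def test_zero_variance_is_an_error(self):
        fits = self.fits_from([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            alm.slope_latitude_correlation(
                fits, {"P0": 30.0, "P1": 32.0, "P2": 34.0}
            )

    def test_definition_oracle(self, rng):
        slopes = rng.normal(1.0, 0.1, 8)
        lats = rng.uniform(30, 45, 8)
        fits = self.fits_from(slopes)
        r, _ = alm.slope_latitude_correlation(
            fits, {f"P{i}": lats[i] for i in range(8)}
        )
        expect = np.cov(slopes, lats, ddof=1)[0, 1] / (
            slopes.std(ddof=1) * lats.std(ddof=1)
        )
        assert r == pytest.approx(expect, abs=1e-10)
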