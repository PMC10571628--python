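"""Mixed-effects group statistics, post hoc contrasts, FDR and correlations."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ifw import (
    CohortDesign,
    compare_correlations,
    fdr_adjust,
    fit_lme,
    posthoc_pairwise,
    run_longitudinal,
    simulate_cohort,
    spearman_assoc,
    subject_slopes,
)


@pytest.fixture(scope="module")
def noisy_cohort():
    design = CohortDesign(
        n_per_group=(20, 25, 12),
        baseline_offsets=(0.0, 0.008, 0.010),
        slopes=(0.001, 0.001, 0.012),
        schedule=(0.0, 1.0, 2.0),
    )
    table, truth = simulate_cohort(design, seed=77)
    return table, design


class TestFitLme:
    def test_noiseless_interaction_recovered_exactly(self):
        d = CohortDesign(
            n_per_group=(8, 9, 7),
            residual_sd=0.0,
            intercept_sd=0.0,
            slopes=(0.001, 0.001, 0.004),
        )
        table, _ = simulate_cohort(d, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(table, "ifw", "MPFC")
        assert fit.singular  # zero variance flagged, not silently returned
        est = fit.fe_params["C(group, Treatment('HC'))[T.CHR-P]:time"]
        assert abs(est - 0.003) < 1e-8

    def test_single_timepoint_inestimable(self):
        d = CohortDesign(n_per_group=(5, 5, 5), schedule=(0.0,))
        table, _ = simulate_cohort(d, seed=12)
        with pytest.raises(ValueError, match="rank deficient|schedule"):
            fit_lme(table, "ifw", "MPFC")

    def test_too_few_subjects_per_group_rejected(self):
        d = CohortDesign(n_per_group=(5, 5, 5))
        table, _ = simulate_cohort(d, seed=13)
        table = table[table["group"] != "CHR-P"]
        with pytest.raises(ValueError, match="CHR-P"):
            fit_lme(table, "ifw", "MPFC")

    def test_injected_interaction_detected(self, noisy_cohort):
        table, design = noisy_cohort
        fit = fit_lme(table, "ifw", "MPFC")
        assert fit.interaction_test.pvalue < 0.01
        assert fit.interaction_test.df_num == 2
        assert fit.n_subjects == sum(design.n_per_group)

    def test_missing_rows_dropped(self, noisy_cohort):
        table, _ = noisy_cohort
        table = table.copy()
        table.loc[table.index[:5], "value"] = np.nan
        fit = fit_lme(table, "ifw", "MPFC")
        assert fit.n_obs == len(table) - 5

    def test_agrees_with_lme4_reml(self, noisy_cohort):
        """Independent oracle: R's lme4 on the identical table."""
        table, _ = noisy_cohort
        fit = fit_lme(table, "ifw", "MPFC")
        df = table[(table.measure_name == "ifw") & (table.roi == "MPFC")].copy()
        # replicate the internal conditioning so coefficients are comparable
        for col in ("age", "icv"):
            x = df[col]
            df[col + "_z"] = (x - x.mean()) / x.std(ddof=0)
        csv = df.to_csv(index=False)
        rscript = """
        df <- read.csv("stdin")
        df$group <- relevel(factor(df$group), ref = "HC")
        m <- lme4::lmer(
          value ~ group * timepoint_years + age_z + sex + icv_z + (1 | subject_id),
          data = df, REML = TRUE)
        b <- lme4::fixef(m)
        write.table(data.frame(name = names(b), value = unname(b)),
                    row.names = FALSE, col.names = FALSE)
        """
        out = subprocess.run(
            ["Rscript", "-e", rscript], input=csv, capture_output=True, text=True,
            check=True,
        )
        coefs = {}
        for line in out.stdout.splitlines():
            name, value = line.split()
            coefs[name.strip('"')] = float(value)
        r_p = coefs["groupCHR-P:timepoint_years"]
        r_np = coefs["groupCHR-NP:timepoint_years"]
        ours_p = fit.fe_params["C(group, Treatment('HC'))[T.CHR-P]:time"]
        ours_np = fit.fe_params["C(group, Treatment('HC'))[T.CHR-NP]:time"]
        assert ours_p == pytest.approx(r_p, abs=5e-6)
        assert ours_np == pytest.approx(r_np, abs=5e-6)


class TestPosthoc:
    def test_three_contrasts_with_antisymmetric_estimates(self, noisy_cohort):
        table, _ = noisy_cohort
        fit = fit_lme(table, "ifw", "MPFC")
        con = posthoc_pairwise(fit, "interaction")
        assert list(con["contrast"]) == [
            "CHR-P vs HC", "CHR-NP vs HC", "CHR-P vs CHR-NP",
        ]
        p_hc = con.loc[con.contrast == "CHR-P vs HC", "estimate"].iloc[0]
        np_hc = con.loc[con.contrast == "CHR-NP vs HC", "estimate"].iloc[0]
        p_np = con.loc[con.contrast == "CHR-P vs CHR-NP", "estimate"].iloc[0]
        assert p_np == pytest.approx(p_hc - np_hc, abs=1e-12)

    def test_identical_groups_give_null_contrast(self):
        d = CohortDesign(
            n_per_group=(25, 25, 25),
            baseline_offsets=(0.0, 0.0, 0.0),
            slopes=(0.001, 0.001, 0.001),
        )
        table, _ = simulate_cohort(d, seed=21)
        fit = fit_lme(table, "ifw", "MPFC")
        con = posthoc_pairwise(fit, "group")
        row = con[con.contrast == "CHR-NP vs HC"].iloc[0]
        assert abs(row["estimate"]) < 0.01
        assert row["p_tukey"] > 0.05

    def test_isolated_chrp_slope_matches_expected_pattern(self):
        # only CHR-P deviates: its two contrasts significant, CHR-NP vs HC null
        d = CohortDesign(
            n_per_group=(40, 40, 30),
            baseline_offsets=(0.0, 0.0, 0.0),
            slopes=(0.001, 0.001, 0.015),
        )
        table, _ = simulate_cohort(d, seed=22)
        fit = fit_lme(table, "ifw", "MPFC")
        con = posthoc_pairwise(fit, "interaction").set_index("contrast")
        assert con.loc["CHR-P vs HC", "p_tukey"] < 0.01
        assert con.loc["CHR-P vs CHR-NP", "p_tukey"] < 0.01
        assert con.loc["CHR-NP vs HC", "p_tukey"] > 0.05

    def test_tukey_adjusted_p_at_least_unadjusted(self, noisy_cohort):
        table, _ = noisy_cohort
        fit = fit_lme(table, "ifw", "MPFC")
        for effect in ("group", "interaction"):
            con = posthoc_pairwise(fit, effect)
            p_raw = 2 * sps.t.sf(np.abs(con["tstat"]), con["df"])
            assert np.all(con["p_tukey"] >= p_raw - 1e-12)


class TestFdr:
    def test_step_up_definition(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.2, 0.5, 0.7, 0.9])
        adj, _ = fdr_adjust(p)
        m = len(p)
        expected = [min((m * p[j] / (j + 1) for j in range(i, m))) for i in range(m)]
        assert np.allclose(adj, np.minimum(expected, 1.0), atol=1e-12)

    def test_all_ones(self):
        adj, reject = fdr_adjust(np.ones(8))
        assert np.all(adj == 1.0) and not reject.any()

    def test_single_p_unchanged(self):
        adj, _ = fdr_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 8)
        adj, _ = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])


class TestSubjectSlopes:
    def test_two_point_slope(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "roi": ["PC"] * 2,
                "measure_name": ["ifw"] * 2,
                "timepoint_years": [0.0, 1.0],
                "value": [1.0, 1.2],
            }
        )
        out = subject_slopes(table, "ifw", "PC")
        assert out["slope"].iloc[0] == pytest.approx(0.2)

    def test_constant_series_zero_slope(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "roi": ["PC"] * 3,
                "measure_name": ["ifw"] * 3,
                "timepoint_years": [0.0, 1.0, 2.0],
                "value": [0.5] * 3,
            }
        )
        assert subject_slopes(table, "ifw", "PC")["slope"].iloc[0] == pytest.approx(0.0)

    def test_irregular_series_matches_closed_form(self, rng):
        t = np.array([0.0, 0.3, 1.7, 2.4])
        y = rng.normal(size=4)
        table = pd.DataFrame(
            {
                "subject_id": ["a"] * 4,
                "roi": ["PC"] * 4,
                "measure_name": ["ifw"] * 4,
                "timepoint_years": t,
                "value": y,
            }
        )
        expected = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        got = subject_slopes(table, "ifw", "PC")["slope"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_timepoint_subject_excluded(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b", "b"],
                "roi": ["PC"] * 3,
                "measure_name": ["ifw"] * 3,
                "timepoint_years": [0.0, 0.0, 1.0],
                "value": [0.1, 0.2, 0.3],
            }
        )
        out = subject_slopes(table, "ifw", "PC")
        assert list(out["subject_id"]) == ["b"]


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.normal(size=10)
        rho, _ = spearman_assoc(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_assoc(x, -np.exp(x))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        y[2] = y[3]  # introduce a tie
        rho, _ = spearman_assoc(x, y)
        expected = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_assoc([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(rho)

    def test_pairwise_complete_and_min_n(self):
        with pytest.raises(ValueError, match="at least 4"):
            spearman_assoc([1, 2, np.nan, 4], [1, 2, 3, np.nan])


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.5, 30, 0.5, 50)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_under_swap(self):
        z1, p1 = compare_correlations(0.8, 17, 0.4, 66)
        z2, p2 = compare_correlations(0.4, 66, 0.8, 17)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_matches_hand_formula(self):
        r1, n1, r2, n2 = 0.8, 17, 0.4, 66
        expected = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
            1 / (n1 - 3) + 1 / (n2 - 3)
        )
        z, p = compare_correlations(r1, n1, r2, n2)
        assert z == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(expected)), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="<"):
            compare_correlations(1.0, 20, 0.3, 20)
        with pytest.raises(ValueError, match="at least 4"):
            compare_correlations(0.5, 3, 0.3, 20)


class TestRunLongitudinal:
    def test_fdr_across_eight_rois_and_bundle_shape(self):
        from ifw.roi import LOBES

        d = CohortDesign(n_per_group=(10, 10, 8), schedule=(0.0, 1.0))
        table, _ = simulate_cohort(d, seed=31, rois=LOBES)
        res = run_longitudinal(table, "ifw")
        assert len(res.effects) == 16  # 8 ROIs x {group, interaction}
        assert (res.effects["p_fdr"] >= res.effects["p"] - 1e-15).all()
        assert len(res.contrasts) == 48  # 3 contrasts x 2 effects x 8 ROIs
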