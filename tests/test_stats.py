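"""Agreement-statistics tests: printed-table reproduction at the unit
level is covered by the acceptance suite; here the focus is oracles
(scipy raw-data routes, brute-force formulas) and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrdeye import (
    CohortError,
    CohortSimSpec,
    agreement_report,
    anova_from_moments,
    apply_exclusions,
    bland_altman,
    ci_from_moments,
    describe,
    generate_cohort,
    linear_fit,
    one_way_anova,
    pearson_matrix,
    scheffe_posthoc,
    se_from_moments,
)
from mrdeye.reference import FOUR_METHOD_SUMMARY


class TestDescribe:
    def test_se_from_published_moments(self):
        # manual-method row of the published summary: n=56, sd=1.03859
        assert se_from_moments(56, 1.03859) == pytest.approx(0.13879, abs=0.001)

    def test_ci_from_published_moments(self):
        lo, hi = ci_from_moments(56, 2.8450, 1.07324)
        assert lo == pytest.approx(2.5576, abs=0.001)
        assert hi == pytest.approx(3.1324, abs=0.001)

    def test_constant_vector_collapses_ci(self):
        d = describe([2.5] * 10)
        assert d.sd == 0.0 and d.ci_low == d.ci_high == d.mean == 2.5

    def test_describe_matches_moment_helpers(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 1, 40)
        d = describe(x)
        assert d.se == pytest.approx(se_from_moments(d.n, d.sd), abs=1e-12)
        assert (d.ci_low, d.ci_high) == pytest.approx(ci_from_moments(d.n, d.mean, d.sd))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            describe([1.0])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        table = one_way_anova([g, g, g, g])
        assert table.ss_between == pytest.approx(0.0, abs=1e-12)
        assert table.f == pytest.approx(0.0, abs=1e-12)

    def test_moments_variant_equals_raw_variant(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(rng.uniform(2, 4), rng.uniform(0.5, 1.5), rng.integers(10, 60))
                  for _ in range(4)]
        raw = one_way_anova(groups)
        mom = anova_from_moments([(len(g), float(np.mean(g)), float(np.std(g, ddof=1)))
                                  for g in groups])
        assert mom.f == pytest.approx(raw.f, abs=1e-10)
        assert mom.ss_within == pytest.approx(raw.ss_within, abs=1e-10)

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 1, 25), rng.normal(1, 2, 40)]
        table = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert table.f == pytest.approx(f, rel=1e-10)
        assert table.p == pytest.approx(p, rel=1e-8)

    def test_zero_within_variance_flagged(self):
        table = one_way_anova([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        assert table.infinite_f and np.isinf(table.f) and table.p == 0.0


class TestScheffe:
    @pytest.fixture()
    def published(self):
        anova = anova_from_moments(list(FOUR_METHOD_SUMMARY.values()))
        pairs = scheffe_posthoc(FOUR_METHOD_SUMMARY, anova.ms_within, anova.df_within)
        return {(p.method_i, p.method_j): p for p in pairs}

    def test_identical_groups(self):
        pairs = scheffe_posthoc({"a": (10, 2.0, 0.5), "b": (10, 2.0, 0.5)}, 0.25, 18)
        assert pairs[0].diff == 0.0
        assert pairs[0].p_adj == pytest.approx(1.0)

    def test_ci_centered_on_diff(self, published):
        for p in published.values():
            assert (p.ci_low + p.ci_high) / 2 == pytest.approx(p.diff, abs=1e-12)

    def test_symmetric_table(self, published):
        p_ij = published[("manual", "dl")]
        p_ji = published[("dl", "manual")]
        assert p_ij.diff == -p_ji.diff
        assert p_ij.p_adj == p_ji.p_adj

    def test_adjusted_p_against_direct_formula(self, published):
        anova = anova_from_moments(list(FOUR_METHOD_SUMMARY.values()))
        p = published[("manual", "rgb")]
        expect = sps.f.sf((p.diff / p.se) ** 2 / 3.0, 3, anova.df_within)
        assert p.p_adj == pytest.approx(expect, abs=1e-14)


class TestPearson:
    def test_exact_line_r_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        r, p = pearson_matrix(df, ["a", "b"])
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=200), rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": y})
        r, _ = pearson_matrix(df, ["a", "b"])
        brute = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r.loc["a", "b"] == pytest.approx(brute, abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        r, _ = pearson_matrix(df, ["a", "b"])
        assert abs(r.loc["a", "b"]) < 0.05

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        r, _ = pearson_matrix(df, ["a", "b"])
        assert np.isnan(r.loc["a", "b"])


class TestBlandAltman:
    def test_identical_series_all_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == ba.sd_diff == ba.delta_loa == 0.0

    def test_mean_diff_is_difference_of_means(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(3, 1, 57), rng.normal(2.8, 1, 57)
        ba = bland_altman(x, y)
        assert ba.mean_diff == pytest.approx(x.mean() - y.mean(), abs=1e-14)

    def test_delta_loa_identity(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        ba = bland_altman(x, y)
        assert ba.delta_loa == pytest.approx(2 * 1.96 * ba.sd_diff, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(0, 5, 20)
        fit = linear_fit(x, 0.82 * x + 0.3)
        assert fit.slope == pytest.approx(0.82, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(3, 1, 500)
        y = 0.8 * x + rng.normal(0, 0.5, 500)
        fit = linear_fit(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_pure_noise_r_squared_small(self):
        rng = np.random.default_rng(8)
        fit = linear_fit(rng.normal(size=10_000), rng.normal(size=10_000))
        assert fit.r_squared < 0.01

    def test_zero_variance_x(self):
        with pytest.raises(ValueError, match="var"):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestExclusions:
    def base_table(self, n=8):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "mrd1_manual": [2.5] * n,
                "mrd1_dl": [2.6] * n,
                "mrd1_rgb": [2.4] * n,
                "mrd1_ir": [2.7] * n,
            }
        )

    def test_rule2_nonpositive_manual(self):
        t = self.base_table()
        t.loc[0, "mrd1_manual"] = 0.0
        _, rep = apply_exclusions(t)
        assert rep.counts[2] == 1 and rep.n_retained == len(t) - 1

    def test_rule4_discrepancy_threshold(self):
        t = self.base_table()
        t.loc[1, "mrd1_manual"] = 2.0
        t.loc[1, "mrd1_rgb"] = 3.2  # |delta| = 1.2 > 1.0
        retained, rep = apply_exclusions(t, reference_method="rgb")
        assert rep.counts[4] == 1
        assert 1 not in retained.index

    def test_first_match_attribution_and_bookkeeping(self):
        t = self.base_table(10)
        t.loc[0, "mrd1_manual"] = np.nan          # rule 1
        t.loc[1, "mrd1_manual"] = -0.5            # rule 2
        t["rgb_boundary_indistinct"] = False
        t.loc[2, "rgb_boundary_indistinct"] = True  # rule 3
        t.loc[3, "mrd1_rgb"] = 4.0                # rule 4
        t.loc[4, "mrd1_dl"] = np.nan              # rule 5
        t["recent_surgery"] = False
        t.loc[5, "recent_surgery"] = True         # rule 6
        t.loc[6, "mrd1_manual"] = 0.0             # rule 2 again
        _, rep = apply_exclusions(t)
        assert rep.counts == {1: 1, 2: 2, 3: 1, 4: 1, 5: 1, 6: 1}
        assert rep.n_excluded + rep.n_retained == rep.n_input == 10

    def test_unknown_reference(self):
        with pytest.raises(CohortError):
            apply_exclusions(self.base_table(), reference_method="penlight")


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSimSpec(n_eyes=80, seed=9))


class TestAgreementReport:

    def test_row_order_invariance(self, cohort):
        rep1 = agreement_report(cohort)
        rep2 = agreement_report(cohort.sample(frac=1, random_state=0))
        assert rep1.anova.f == pytest.approx(rep2.anova.f, abs=1e-12)
        for pair in rep1.bland_altman:
            assert rep1.bland_altman[pair].mean_diff == pytest.approx(
                rep2.bland_altman[pair].mean_diff, abs=1e-12)

    def test_internal_identities(self, cohort):
        rep = agreement_report(cohort)
        for (a, b), fit in rep.regressions.items():
            assert fit.r_squared == pytest.approx(rep.pearson_r.loc[a, b] ** 2, abs=1e-10)
        for (a, b), ba in rep.bland_altman.items():
            assert ba.mean_diff == pytest.approx(
                rep.descriptives[a].mean - rep.descriptives[b].mean, abs=1e-10)
            assert ba.delta_loa == pytest.approx(2 * 1.96 * ba.sd_diff, abs=1e-10)

    def test_serializable(self, cohort):
        import json

        doc = json.dumps(agreement_report(cohort).to_dict(), default=str)
        assert json.loads(doc)["n_eyes"] == 80

    def test_bias_recovery_small_cohort(self):
        spec = CohortSimSpec(n_eyes=2000, seed=10)
        rep = agreement_report(generate_cohort(spec))
        se = np.sqrt(2) * 0.30 / np.sqrt(spec.n_eyes)
        ba = rep.bland_altman[("manual", "rgb")]
        assert ba.mean_diff == pytest.approx(-spec.biases_mm["rgb"], abs=3 * se)
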