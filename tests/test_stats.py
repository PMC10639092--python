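import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from strokenet.cohort import CohortTable, SubjectRecord
from strokenet.exceptions import (
    DataAlignmentError,
    DegenerateInputError,
)
from strokenet.stats import (
    DomainZScores,
    ancova_global,
    apply_regional_exclusions,
    bh_fdr,
    chi_square_2x2,
    cognitive_z_scores,
    contralesional_nodes,
    impairment_table,
    predict_cognition,
    regional_mass_univariate,
)


def make_subject(i, group, side="none", age=50.0, sex="male", scores=None,
                 volume=None, aed=False):
    if volume is None:
        volume = 0.0 if side == "none" else 10.0
    return SubjectRecord(f"sub-{i:03d}", group, age, sex, side, volume, aed,
                         scores or {})


class TestZScores:
    def controls(self, mean=10.0, sd=2.0, n=20):
        # symmetric raw scores around `mean` with sample SD exactly `sd`
        offsets = np.linspace(-1, 1, n)
        offsets = offsets / np.std(offsets, ddof=1) * sd
        return [
            make_subject(i, "control", scores={"symbol_digit": mean + off})
            for i, off in enumerate(offsets)
        ]

    def test_control_mean_maps_to_zero(self):
        subjects = self.controls() + [
            make_subject(100, "stroke_pse", "left", scores={"symbol_digit": 10.0})
        ]
        dz = cognitive_z_scores(CohortTable(subjects))
        assert dz.z.loc["sub-100", "processing_speed"] == pytest.approx(0.0)
        assert not dz.impaired.loc["sub-100", "processing_speed"]

    def test_two_sd_below_is_impaired(self):
        subjects = self.controls() + [
            make_subject(100, "stroke_pse", "left", scores={"symbol_digit": 6.0})
        ]
        dz = cognitive_z_scores(CohortTable(subjects))
        assert dz.z.loc["sub-100", "processing_speed"] == pytest.approx(-2.0)
        assert bool(dz.impaired.loc["sub-100", "processing_speed"])

    def test_cutoff_arithmetic(self):
        """Raw 6.9 against control mean 10, SD 2 gives z = -1.55, which is
        below the -1.5 impairment cutoff."""
        subjects = self.controls() + [
            make_subject(100, "stroke_pse", "left", scores={"symbol_digit": 6.9})
        ]
        dz = cognitive_z_scores(CohortTable(subjects))
        assert dz.z.loc["sub-100", "processing_speed"] == pytest.approx(-1.55)
        assert bool(dz.impaired.loc["sub-100", "processing_speed"])

    def test_sign_alignment_for_time_scored_test(self):
        # stroop_time: higher raw = slower = worse; orientation -1
        controls = [
            make_subject(i, "control", scores={"stroop_time": v})
            for i, v in enumerate([8, 9, 10, 11, 12] * 4)
        ]
        slow = make_subject(100, "stroke_pse", "left", scores={"stroop_time": 20.0})
        dz = cognitive_z_scores(CohortTable(controls + [slow]))
        assert dz.z.loc["sub-100", "processing_speed"] < -1.5

    def test_zero_control_sd_raises(self):
        controls = [make_subject(i, "control", scores={"symbol_digit": 10.0})
                    for i in range(5)]
        with pytest.raises(DegenerateInputError):
            cognitive_z_scores(CohortTable(controls))

    def test_domain_averages_tests(self):
        controls = []
        for i, off in enumerate(np.linspace(-1, 1, 21)):
            controls.append(make_subject(i, "control", scores={
                "symbol_digit": 10 + off, "stroop_time": 30 - off}))
        target = make_subject(100, "stroke_pse", "left",
                              scores={"symbol_digit": 10.0, "stroop_time": 30.0})
        dz = cognitive_z_scores(CohortTable(controls + [target]))
        assert dz.z.loc["sub-100", "processing_speed"] == pytest.approx(0.0)


class TestImpairmentAndChiSquare:
    def test_counts_and_percentages_from_flags(self):
        z = pd.DataFrame(
            {"processing_speed": [-2.0] * 10 + [0.0] * 11 + [-2.0] * 35 + [0.0] * 103},
            index=[f"s{i}" for i in range(159)],
        )
        dz = DomainZScores(z=z, impaired=z < -1.5)
        subjects = [
            make_subject(i, "stroke_pse" if i < 21 else "stroke_nopse",
                         "left")
            for i in range(159)
        ]
        # re-key the z index to the subject ids
        ids = [s.subject_id for s in subjects]
        dz = DomainZScores(z=z.set_axis(ids), impaired=(z < -1.5).set_axis(ids))
        table = impairment_table(dz, CohortTable(subjects))
        pse = table[(table.group == "stroke_pse")].iloc[0]
        nopse = table[(table.group == "stroke_nopse")].iloc[0]
        assert (pse.impaired, pse.total) == (10, 21)
        assert pse.pct == pytest.approx(47.6, abs=0.05)
        assert nopse.pct == pytest.approx(25.4, abs=0.05)

    def test_all_zero_scores_no_impairment(self):
        z = pd.DataFrame({"attention": [0.0, 0.0]}, index=["sub-000", "sub-001"])
        dz = DomainZScores(z=z, impaired=z < -1.5)
        cohort = CohortTable([make_subject(0, "control"), make_subject(1, "control")])
        table = impairment_table(dz, cohort)
        assert table["impaired"].sum() == 0

    def test_chi_square_closed_form(self):
        a, b, c, d = 10, 11, 35, 103
        res = chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.p < 0.05

    def test_chi_square_matches_scipy(self):
        table = [[12, 18], [40, 95]]
        res = chi_square_2x2(table)
        stat, p, _, _ = sstats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(stat)
        assert res.p == pytest.approx(p)
        res_y = chi_square_2x2(table, yates=True)
        stat_y, p_y, _, _ = sstats.chi2_contingency(table, correction=True)
        assert res_y.statistic == pytest.approx(stat_y)

    def test_identical_rows_give_zero_statistic(self):
        res = chi_square_2x2([[5, 10], [5, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_marginal_raises(self):
        with pytest.raises(DegenerateInputError):
            chi_square_2x2([[0, 0], [5, 10]])


class TestBhFdr:
    def test_worked_step_up_example(self):
        adjusted, reject = bh_fdr([0.001, 0.008, 0.039, 0.041], q=0.05)
        assert reject.all()

    def test_all_ones(self):
        adjusted, reject = bh_fdr(np.ones(10))
        assert np.all(adjusted == 1.0)
        assert not reject.any()

    def test_single_p_unchanged(self):
        adjusted, _ = bh_fdr([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_step_up_definition(self, pvals):
        p = np.array(pvals)
        adjusted, reject = bh_fdr(p, q=0.05)
        m = p.size
        order = np.argsort(p, kind="stable")
        # brute-force the definition: adj_(i) = min_{j>=i} m p_(j) / j
        brute_sorted = [
            min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
            for i in range(m)
        ]
        brute = np.empty(m)
        brute[order] = brute_sorted
        assert np.allclose(adjusted, brute, atol=1e-12)
        assert np.array_equal(reject, brute <= 0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(40)
        adjusted, reject = bh_fdr(p, q=0.05)
        sm_reject, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adjusted, sm_adj, atol=1e-12)
        assert np.array_equal(reject, sm_reject)


class TestAncova:
    def make_cohort(self, n, rng, effect=0.0):
        subjects, values = [], {}
        for i in range(2 * n):
            group = "stroke_pse" if i < n else "stroke_nopse"
            s = make_subject(i, group, "left", age=float(rng.uniform(30, 65)),
                             sex="male" if rng.random() < 0.5 else "female")
            subjects.append(s)
            values[s.subject_id] = float(rng.normal()) + (effect if group == "stroke_pse" else 0.0)
        return CohortTable(subjects), values

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        cohort, values = self.make_cohort(20, rng, effect=0.5)
        res = ancova_global(values, cohort)
        shifted = {k: v + 100.0 for k, v in values.items()}
        res2 = ancova_global(shifted, cohort)
        assert res2.estimate == pytest.approx(res.estimate)
        assert res2.p == pytest.approx(res.p)

    def test_agrees_with_t_test_when_covariates_null(self):
        rng = np.random.default_rng(2)
        cohort, values = self.make_cohort(100, rng, effect=0.3)
        res = ancova_global(values, cohort)
        a = [values[s.subject_id] for s in cohort if s.group == "stroke_pse"]
        b = [values[s.subject_id] for s in cohort if s.group == "stroke_nopse"]
        _, p_t = sstats.ttest_ind(a, b)
        assert abs(res.p - p_t) < 0.02

    def test_too_few_subjects_raises(self):
        rng = np.random.default_rng(3)
        cohort, values = self.make_cohort(2, rng)
        with pytest.raises(DegenerateInputError):
            ancova_global(values, cohort)

    def test_missing_metric_raises(self):
        rng = np.random.default_rng(4)
        cohort, values = self.make_cohort(5, rng)
        values.pop(cohort.subject_ids[0])
        with pytest.raises(DataAlignmentError):
            ancova_global(values, cohort)


class TestContralesionalSelection:
    def test_left_lesion_selects_right_nodes(self, parcellation):
        s = make_subject(0, "stroke_pse", "left")
        nodes = contralesional_nodes(parcellation, s)
        assert len(nodes) == 41
        assert set(nodes) == set(parcellation.hemisphere_nodes("right"))

    def test_partition_of_all_nodes(self, parcellation):
        left = contralesional_nodes(parcellation, make_subject(0, "stroke_pse", "left"))
        right = contralesional_nodes(parcellation, make_subject(1, "stroke_pse", "right"))
        assert sorted(left + right) == list(range(82))

    def test_bilateral_raises(self, parcellation):
        with pytest.raises(DegenerateInputError):
            contralesional_nodes(parcellation, make_subject(0, "stroke_pse", "bilateral"))


class TestRegionalExclusions:
    def test_bookkeeping_reconciles(self):
        subjects = (
            [make_subject(i, "stroke_nopse", "left") for i in range(10)]
            + [make_subject(20 + i, "stroke_pse", "bilateral") for i in range(2)]
            + [make_subject(30, "stroke_pse", "none", volume=0.0)]
            + [make_subject(40 + i, "control") for i in range(5)]
        )
        retained, log = apply_regional_exclusions(CohortTable(subjects))
        assert log["input"] == 13  # stroke subjects only
        assert log["retained"] == len(retained) == 10
        assert log["excluded_bilateral"] == 2
        assert log["excluded_no_lesion"] == 1
        assert log["retained"] + len(log["excluded_ids"]) == log["input"]

    def test_identity_when_all_unilateral(self):
        subjects = [make_subject(i, "stroke_nopse", "right") for i in range(6)]
        retained, log = apply_regional_exclusions(CohortTable(subjects))
        assert len(retained) == 6 and not log["excluded_ids"]


class TestRegionalMassUnivariate:
    def make_regional(self, rng, n_per_group=20, regions=("a", "b", "c", "d"),
                      effect_regions=(), effect=1.0, volume_coupled=False):
        subjects, rows = [], []
        for i in range(2 * n_per_group):
            group = "stroke_pse" if i < n_per_group else "stroke_nopse"
            volume = float(rng.lognormal(2.5, 0.5))
            s = make_subject(i, group, "left", age=float(rng.uniform(30, 65)),
                             sex="male" if rng.random() < 0.5 else "female",
                             volume=volume)
            subjects.append(s)
            for region in regions:
                value = float(rng.normal())
                if volume_coupled:
                    value += 0.02 * volume
                if region in effect_regions and group == "stroke_pse":
                    value -= effect
                rows.append({"subject_id": s.subject_id, "region": region,
                             "metric": "clustering_coefficient", "value": value})
        return CohortTable(subjects), pd.DataFrame(rows)

    def test_planted_region_has_smaller_p(self):
        rng = np.random.default_rng(5)
        hub_ranks = []
        for _ in range(10):
            cohort, table = self.make_regional(rng, effect_regions=("a",), effect=1.2)
            res = regional_mass_univariate(table, cohort, model=1)
            res = res.sort_values("p").reset_index(drop=True)
            hub_ranks.append(res.index[res.region == "a"][0])
        assert np.mean(hub_ranks) < 1.0  # hub region usually ranks first

    def test_model2_close_to_model1_when_volume_independent(self):
        rng = np.random.default_rng(6)
        cohort, table = self.make_regional(rng, effect_regions=("a",), effect=1.0)
        m1 = regional_mass_univariate(table, cohort, model=1).set_index("region")
        m2 = regional_mass_univariate(table, cohort, model=2).set_index("region")
        delta = abs(m1.loc["a", "estimate"] - m2.loc["a", "estimate"])
        assert delta < 2 * m1.loc["a", "se"]

    def test_single_region_fdr_equals_raw(self):
        rng = np.random.default_rng(7)
        cohort, table = self.make_regional(rng, regions=("solo",))
        res = regional_mass_univariate(table, cohort, model=1)
        assert len(res) == 1
        assert res.iloc[0]["p_fdr"] == pytest.approx(res.iloc[0]["p"])

    def test_fdr_grouped_per_metric_family(self):
        rng = np.random.default_rng(8)
        cohort, table = self.make_regional(rng)
        other = table.copy()
        other["metric"] = "nodal_efficiency"
        res = regional_mass_univariate(pd.concat([table, other]), cohort, model=1)
        for _, fam in res.groupby("metric"):
            assert np.all(fam["p_fdr"] >= fam["p"] - 1e-12)


class TestPredictCognition:
    def make_inputs(self, rng, n=200, beta=0.5, controls=50):
        subjects, rows, zrows = [], [], {}
        for i in range(n + controls):
            group = "stroke_pse" if i < n else "control"
            s = make_subject(i, group, "left" if group != "control" else "none",
                             age=float(rng.uniform(30, 65)),
                             aed=bool(rng.random() < 0.5) if group != "control" else False)
            subjects.append(s)
            metric = float(rng.normal())
            rows.append({"subject_id": s.subject_id, "region": "precuneus",
                         "metric": "clustering_coefficient", "value": metric})
            zrows[s.subject_id] = {"processing_speed": beta * metric + float(rng.normal(0, 0.8))}
        z = pd.DataFrame.from_dict(zrows, orient="index")
        dz = DomainZScores(z=z, impaired=z < -1.5)
        return dz, pd.DataFrame(rows), CohortTable(subjects)

    def test_recovers_planted_coefficient(self):
        rng = np.random.default_rng(9)
        dz, table, cohort = self.make_inputs(rng, beta=0.5)
        res = predict_cognition(dz, table, cohort, "precuneus", "clustering_coefficient")
        assert abs(res.estimate - 0.5) < 3 * res.se
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_null_coverage(self):
        rng = np.random.default_rng(10)
        inside = 0
        for _ in range(100):
            dz, table, cohort = self.make_inputs(rng, n=60, beta=0.0, controls=5)
            res = predict_cognition(dz, table, cohort, "precuneus",
                                    "clustering_coefficient")
            inside += abs(res.estimate) < 2 * res.se
        assert inside >= 93

    def test_constant_metric_raises(self):
        rng = np.random.default_rng(11)
        dz, table, cohort = self.make_inputs(rng, n=20)
        table["value"] = 1.0
        with pytest.raises(DegenerateInputError):
            predict_cognition(dz, table, cohort, "precuneus", "clustering_coefficient")

    def test_small_sample_flagged(self):
        rng = np.random.default_rng(12)
        dz, table, cohort = self.make_inputs(rng, n=4, controls=0)
        res = predict_cognition(dz, table, cohort, "precuneus", "clustering_coefficient")
        assert res.warning is not None
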