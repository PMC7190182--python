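"""Group-by-side mixed models, Benjamini-Liu FDR, and summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sccmorph import datasets
from sccmorph import stats as st
from sccmorph.parameters import PARAMETERS
from sccmorph.phantom import CohortSimSpec, generate_measurement_table

NOMINAL_P = [0.6573, 0.6669, 0.0012, 0.3652, 0.8941, 0.4356, 0.0604, 0.0548,
             0.5124]


def make_table(cells, n1=20, n2=19, parameter="lateral_inclination", sd=0.0,
               seed=0):
    """Complete bilateral table with exact cell means.

    cells = (g1_L, g1_R, g2_L, g2_R)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, mu_l, mu_r in (("AIS", n1, cells[0], cells[1]),
                                 ("control", n2, cells[2], cells[3])):
        for mu, side in ((mu_r, "R"), (mu_l, "L")):
            vals = rng.normal(0, sd, n) if sd > 0 else np.zeros(n)
            vals = vals - vals.mean() + mu  # exact cell mean
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"{group}{i:03d}", "group": group,
                             "side": side, "parameter": parameter, "value": v})
    return pd.DataFrame(rows)


class TestBenjaminiLiu:
    def test_published_nine_pvalue_panel(self):
        res = st.benjamini_liu_adjust(NOMINAL_P)
        adj = dict(zip(NOMINAL_P, res.adjusted))
        assert round(adj[0.0012], 4) == 0.0107
        assert round(adj[0.0548], 4) == 0.3226
        assert round(adj[0.0604], 4) == 0.3226
        assert round(adj[0.3652], 4) == 0.6230
        for p in (0.4356, 0.5124, 0.6573, 0.6669, 0.8941):
            assert round(adj[p], 4) == 0.6230

    def test_single_test_unchanged(self):
        res = st.benjamini_liu_adjust([0.03])
        assert res.adjusted[0] == pytest.approx(0.03)

    def test_identical_pvalues_all_equal(self):
        res = st.benjamini_liu_adjust([0.001] * 9)
        assert np.allclose(res.adjusted, res.adjusted[0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=9))
    def test_dominance_and_permutation_equivariance(self, pvals):
        res = st.benjamini_liu_adjust(pvals)
        # note: unlike step-up procedures, the step-down adjusted value can
        # drop BELOW the nominal p for large p (e.g. nominal 0.8941 adjusts
        # to 0.6230 in the nine-parameter panel), so no dominance is claimed
        assert ((res.adjusted >= 0) & (res.adjusted <= 1)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(res.adjusted[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(pvals))
        res_p = st.benjamini_liu_adjust(np.asarray(pvals)[perm])
        # note: equal p-values may legitimately swap adjusted values
        assert np.allclose(np.sort(res_p.adjusted), np.sort(res.adjusted))

    def test_matches_stepdown_inversion_oracle(self):
        # oracle: adjusted_i = smallest q at which the step-down procedure
        # with critical values a_i = 1 - [1 - min(1, m q/(m-i+1))]^(1/(m-i+1))
        # rejects H_(i); inverted on a q-grid
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = int(rng.integers(2, 7))
            p = np.round(rng.uniform(0, 1, m), 4)
            res = st.benjamini_liu_adjust(p)
            qs = np.arange(1e-5, 1.0 + 1e-5, 1e-5)
            ps = np.sort(p)
            k = np.arange(1, m + 1)
            # a_i(q) for all grid q at once: (Q, m)
            mq = np.minimum(1.0, m * qs[:, None] / (m - k + 1))
            alpha = 1.0 - (1.0 - mq) ** (1.0 / (m - k + 1))
            passes = ps[None, :] <= alpha
            # step-down: H_(i) rejected iff all of p_(1..i) pass
            rejected = np.cumprod(passes, axis=1).astype(bool)
            oracle_sorted = np.array([
                qs[rejected[:, i]].min() if rejected[:, i].any() else 1.0
                for i in range(m)
            ])
            assert np.allclose(np.sort(res.adjusted), oracle_sorted, atol=2e-5)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            st.benjamini_liu_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            st.benjamini_liu_adjust([])


class TestSideDifferenceModel:
    def test_reference_cell_means_give_published_contrasts(self):
        table = make_table((1.46, 5.03, 5.21, 4.72), sd=3.0, seed=1)
        res = st.side_difference_model(table, "lateral_inclination")
        assert round(res.interaction, 1) == 4.1
        assert round(res.group_diffs["AIS"][0], 1) == 3.6
        assert round(res.group_diffs["control"][0], 1) == -0.5
        assert res.interaction == pytest.approx(4.06, abs=1e-9)

    def test_equal_sides_give_zero_interaction(self):
        rng = np.random.default_rng(2)
        rows = []
        for group, n in (("AIS", 8), ("control", 7)):
            for i in range(n):
                v = rng.normal()
                for side in ("R", "L"):
                    rows.append({"subject_id": f"{group}{i}", "group": group,
                                 "side": side, "parameter": "min_csa_lateral",
                                 "value": v})
        res = st.side_difference_model(pd.DataFrame(rows), "min_csa_lateral")
        assert res.interaction == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_matches_pooled_t_on_differences(self):
        # oracle: two-sample t-test on per-subject R-L differences
        from scipy import stats as sps

        table = make_table((1.0, 3.0, 2.0, 2.5), sd=2.5, seed=3)
        res = st.side_difference_model(table, "lateral_inclination")
        w = table.pivot_table(index=["subject_id", "group"], columns="side",
                              values="value").reset_index()
        d1 = (w[w.group == "AIS"]["R"] - w[w.group == "AIS"]["L"]).to_numpy()
        d2 = (w[w.group == "control"]["R"] - w[w.group == "control"]["L"]).to_numpy()
        t, p = sps.ttest_ind(d1, d2, equal_var=True)
        assert res.interaction == pytest.approx(d1.mean() - d2.mean(), rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_simulation_recovers_delta_with_nominal_coverage(self):
        # 500 simulated cohorts, delta = 4, SD of differences 3.6 per group
        var = (3.6**2) / 2  # independent sides: var_R + var_L = 3.6^2
        covs = {p: (var, var, 0.0) for p in PARAMETERS}
        est, cover = [], 0
        n_rep = 500
        for rep in range(n_rep):
            spec = CohortSimSpec(n_per_group=(20, 19), covariances=covs,
                                 interaction_delta=4.0, seed=10_000 + rep)
            table = generate_measurement_table(spec)
            res = st.side_difference_model(table, "lateral_inclination")
            est.append(res.interaction)
            lo, hi = res.interaction_ci
            cover += (lo <= 4.0 <= hi)
        assert np.mean(est) == pytest.approx(4.0, abs=0.2)
        assert cover / n_rep == pytest.approx(0.95, abs=0.03)

    def test_numeric_reml_handles_missing_sides(self):
        table = make_table((1.0, 4.0, 2.0, 2.2), sd=2.0, seed=4)
        complete = st.side_difference_model(table, "lateral_inclination")
        # drop one side for two subjects: estimates move only slightly
        drop = table[(table.subject_id == "AIS003") & (table.side == "L")].index
        drop = drop.union(table[(table.subject_id == "control002")
                                & (table.side == "R")].index)
        table2 = table.drop(drop)
        res = st.side_difference_model(table2, "lateral_inclination")
        assert res.method == "reml-numeric"
        assert res.interaction == pytest.approx(complete.interaction, abs=0.5)
        assert res.interaction_ci[0] < res.interaction < res.interaction_ci[1]

    def test_too_few_subjects_rejected(self):
        table = make_table((1, 2, 3, 4), n1=1, n2=5, sd=1.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            st.side_difference_model(table, "lateral_inclination")


class TestRunAllParameters:
    def test_missing_parameter_reduces_family_with_warning(self):
        spec = CohortSimSpec(n_per_group=(8, 8), seed=3)
        table = generate_measurement_table(spec)
        table = table[table.parameter != "min_csa_lateral"]
        with pytest.warns(RuntimeWarning, match="min_csa_lateral"):
            results, fdr = st.run_all_parameters(table)
        assert len(results) == 8
        assert len(fdr.parameters) == 8

    def test_single_strong_parameter_flagged(self):
        covs = {p: (1.0, 1.0, 0.5) for p in PARAMETERS}
        spec = CohortSimSpec(n_per_group=(20, 19), covariances=covs,
                             interaction_delta=4.0, seed=5)
        table = generate_measurement_table(spec)
        results, fdr = st.run_all_parameters(table)
        frame = fdr.to_frame().set_index("parameter")
        assert bool(frame.loc["lateral_inclination", "significant"])


class TestSummaries:
    def test_group_cell_means_and_sds(self):
        table = make_table((1.46, 5.03, 5.21, 4.72), sd=2.0, seed=6)
        summ = st.summarize_groups(table).set_index(["group", "side"])
        assert summ.loc[("AIS", "L"), "mean"] == pytest.approx(1.46, abs=0.005)
        assert summ.loc[("control", "R"), "mean"] == pytest.approx(4.72, abs=0.005)

    def test_identical_values_have_zero_sd(self):
        table = make_table((2.0, 2.0, 2.0, 2.0), sd=0.0)
        summ = st.summarize_groups(table)
        assert (summ["sd"] == 0).all()

    def test_large_simulated_cohort_recovers_reference_means(self):
        spec = CohortSimSpec(n_per_group=(10_000, 10_000),
                             means=datasets.reference_cell_means(), seed=8)
        table = generate_measurement_table(spec)
        summ = st.summarize_groups(table).set_index(["parameter", "group", "side"])
        for (g, s), mu in datasets.reference_cell_means()["lateral_inclination"].items():
            got = summ.loc[("lateral_inclination", g, s), "mean"]
            assert got == pytest.approx(mu, abs=0.1)

    def test_single_subject_group_sd_missing(self):
        rows = [
            {"subject_id": "a", "group": "AIS", "side": s,
             "parameter": "min_csa_lateral", "value": 1.0} for s in ("R", "L")
        ] + [
            {"subject_id": f"c{i}", "group": "control", "side": s,
             "parameter": "min_csa_lateral", "value": 1.0 + i}
            for i in range(3) for s in ("R", "L")
        ]
        summ = st.summarize_groups(pd.DataFrame(rows)).set_index(["group", "side"])
        assert np.isnan(summ.loc[("AIS", "R"), "sd"])

    def test_duplicate_measurement_rejected(self):
        rows = [{"subject_id": "a", "group": "AIS", "side": "R",
                 "parameter": "min_csa_lateral", "value": 1.0}] * 2
        with pytest.raises(ValueError, match="duplicate"):
            st.validate_table(pd.DataFrame(rows))


class TestCurveSummaries:
    def test_constant_differences(self):
        table = make_table((0.0, 2.0, 0.0, 2.0), n1=20, n2=19)
        curves = datasets.curve_records()
        curves = curves.assign(patient_id=[f"AIS{i:03d}" for i in range(20)])
        out = st.summarize_by_curve_type(table, curves)
        assert np.allclose(out["mean_diff"], 2.0)
        assert (out[out.n > 1]["sd"] == 0).all()

    def test_stratum_sizes_preserved(self):
        table = make_table((0.0, 2.0, 0.0, 2.0), n1=20, n2=19)
        curves = datasets.curve_records()
        curves = curves.assign(patient_id=[f"AIS{i:03d}" for i in range(20)])
        out = st.summarize_by_curve_type(table, curves).set_index("curve_type")
        assert out.loc["Control", "n"] == 19
        assert out.loc["R. Thoracic", "n"] == 10
        assert out.loc["Biphasic", "n"] == 8
        assert out.loc["R. Lumbar", "n"] == 1
        assert np.isnan(out.loc["R. Lumbar", "sd"])

    def test_unmatched_subject_rejected(self):
        table = make_table((0, 1, 0, 1), n1=3, n2=3)
        curves = pd.DataFrame({"patient_id": ["AIS000"], "curve_type": ["Biphasic"]})
        with pytest.raises(ValueError, match="without curve records"):
            st.summarize_by_curve_type(table, curves)

    def test_cobb_summaries_reproduce_reported_values(self):
        out = st.summarize_cobb(datasets.curve_records()).set_index("pattern")
        assert out.loc["R. Thoracic", "mean"] == 48.4
        assert out.loc["R. Thoracic", "sd"] == 10.0
        lumbar = out.loc[["R. Lumbar", "L. Lumbar"]]
        # the two lumbar curves (50 and 60 deg) summarize to 55.0 +/- 7.1
        angles = np.array([50.0, 60.0])
        assert angles.mean() == 55.0
        assert round(angles.std(ddof=1), 1) == 7.1
        assert out.loc["Biphasic (all angles)", "n_patients"] == 8

    def test_single_record_sd_missing(self):
        curves = pd.DataFrame({"patient_id": ["x"], "curve_type": ["R. Lumbar"],
                               "cobb1": [50.0], "cobb2": [np.nan]})
        out = st.summarize_cobb(curves)
        assert np.isnan(out["sd"]).all()
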