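"""Statistical layer: t-to-r, FDR, Fisher z, PTS split, GLM suite, group states."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dfncstates.association import (
    OcrAssociationModel,
    bh_fdr,
    classify_pts,
    compare_group_states,
    fisher_z_compare,
    fit_glm_association,
    run_association_suite,
    t_to_r,
)
from dfncstates.synthetic import (
    CohortDesign,
    MarkovDesign,
    effect_for_target_r,
    gen_cohort,
    simulated_ocr_sd,
)
from dfncstates.windows import DfncWindows, TaperSpec


class TestTtoR:
    def test_zero_t_gives_zero_r(self):
        assert t_to_r(0.0, 100) == 0.0

    def test_closed_form(self):
        assert np.isclose(t_to_r(2.0, 100), 2.0 / np.sqrt(104))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(min_value=-30, max_value=30),
           st.floats(min_value=-30, max_value=30),
           st.integers(min_value=1, max_value=500))
    def test_strictly_increasing_in_t(self, t1, t2, df):
        lo, hi = sorted([t1, t2])
        if hi - lo < 1e-6:
            return
        assert t_to_r(lo, df) < t_to_r(hi, df)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            t_to_r(1.0, 0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert np.allclose(bh_fdr([0.37]), [0.37])

    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFisher:
    def test_equal_correlations_give_null(self):
        cmp = fisher_z_compare(0.3, 50, 0.3, 80)
        assert cmp.z_stat == 0.0
        assert np.isclose(cmp.p_value, 0.5)

    def test_formula_oracle(self):
        z1, z2 = np.arctanh(0.5), np.arctanh(0.2)
        se = np.sqrt(2 / 97)
        cmp = fisher_z_compare(0.5, 100, 0.2, 100)
        assert np.isclose(cmp.z_stat, (z1 - z2) / se)
        assert np.isclose(cmp.z_stat, 2.4137, atol=1e-3)

    def test_antisymmetry(self):
        a = fisher_z_compare(0.4, 60, 0.1, 90)
        b = fisher_z_compare(0.1, 90, 0.4, 60)
        assert np.isclose(a.z_stat, -b.z_stat)
        assert np.isclose(a.p_value, b.p_value)

    def test_two_tailed_doubles_p(self):
        one = fisher_z_compare(0.4, 60, 0.1, 90, tails="one")
        two = fisher_z_compare(0.4, 60, 0.1, 90, tails="two")
        assert np.isclose(two.p_value, 2 * one.p_value)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(0.2, 3, 0.1, 50)


class TestPtsSplit:
    def test_boundary_rule(self):
        pheno = pd.DataFrame({"subject_id": ["a", "b", "c"],
                              "pcl5_wk2": [32.0, 30.0, 31.0]})
        out = classify_pts(pheno)
        assert dict(zip(out.subject_id, out.label)) == {
            "a": "PTS", "b": "non-PTS", "c": "non-PTS"}

    def test_missing_scores_excluded_with_warning(self):
        pheno = pd.DataFrame({"subject_id": ["a", "b"],
                              "pcl5_wk2": [40.0, np.nan]})
        with pytest.warns(UserWarning, match="missing"):
            out = classify_pts(pheno)
        assert list(out.subject_id) == ["a"]

    def test_group_sizes_match_counting_oracle(self, rng):
        scores = rng.uniform(0, 80, size=200)
        pheno = pd.DataFrame({"subject_id": [f"s{i}" for i in range(200)],
                              "pcl5_wk2": scores})
        out = classify_pts(pheno, cutoff=31)
        assert (out.label == "PTS").sum() == (scores > 31).sum()


class TestGlm:
    def test_no_covariates_reproduces_plain_pearson(self, rng):
        x = rng.normal(size=120)
        y = 0.4 * x + rng.normal(size=120)
        res = fit_glm_association(x, y)
        assert abs(res.r - np.corrcoef(x, y)[0, 1]) < 1e-10

    def test_result_invariants(self, rng):
        x = rng.uniform(0, 1, size=80)
        y = 20 + 5 * x + rng.normal(0, 3, size=80)
        cov = pd.DataFrame({"age": rng.normal(35, 10, 80),
                            "sex": rng.choice(["male", "female"], 80)})
        res = fit_glm_association(x, y, cov)
        assert res.ci_low <= res.beta <= res.ci_high
        assert np.isclose(res.r, np.sign(res.t) * np.sqrt(res.t**2 / (res.t**2 + res.df)))
        assert res.n_used == 80

    def test_listwise_deletion_counts(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y[:5] = np.nan
        res = fit_glm_association(x, y)
        assert res.n_used == 45

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_glm_association(np.ones(30), rng.normal(size=30))

    def test_collinear_covariate_dropped_with_warning(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        cov = pd.DataFrame({"age": rng.normal(35, 5, 60)})
        cov["age2"] = 2 * cov["age"]
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_glm_association(x, y, cov)
        assert res.n_used == 60


def _ocr_cohort(n, seed, effect=None, effect_timepoints=("M3",), noise_sd=16.0,
                missing=True):
    design = CohortDesign(
        n_subjects=n,
        effect=effect,
        effect_timepoints=effect_timepoints,
        outcome_noise_sd=noise_sd,
        **({} if missing else {"missingness": {tp: 0.0 for tp in
                                               ("WK2", "WK8", "M3", "M6", "M12")}}),
    )
    return gen_cohort(design, markov=MarkovDesign(K=3), seed=seed,
                      include_timecourses=False)


class TestSuite:
    def test_fifteen_models_per_stratum(self):
        cohort = _ocr_cohort(120, seed=5)
        table = run_association_suite(cohort.truth_ocr_table(), cohort.phenotypes)
        counts = table.groupby("stratum").size()
        assert counts["all"] == 15
        assert counts["female"] == 15
        assert counts["male"] == 15
        # FDR applied within each stratum: adjusted p's are monotone in raw p's
        for _, grp in table.groupby("stratum"):
            g = grp.sort_values("p")
            assert g["p_fdr"].is_monotonic_increasing

    def test_small_stratum_models_skipped(self):
        cohort = _ocr_cohort(14, seed=6)
        table = run_association_suite(cohort.truth_ocr_table(), cohort.phenotypes,
                                      strata=("male",))
        assert len(table) < 15  # the male stratum is far below the case minimum

    def test_effect_recovery_bias_below_20_percent(self):
        markov = MarkovDesign(K=3)
        sd1 = simulated_ocr_sd(markov, T=210, state=1, n_subjects=500, seed=0)
        beta = effect_for_target_r(0.2, sd1, 16.0)
        estimates = []
        for rep in range(20):
            cohort = _ocr_cohort(250, seed=300 + rep, effect=[beta, 0, 0],
                                 missing=False)
            table = run_association_suite(cohort.truth_ocr_table(),
                                          cohort.phenotypes, strata=("all",))
            row = table[(table.predictor == "state_1") & (table.timepoint == "M3")]
            estimates.append(float(row.beta.iloc[0]))
        bias = abs(np.mean(estimates) - beta)
        assert bias < 0.2 * beta

    def test_model_results_interface(self):
        cohort = _ocr_cohort(100, seed=7)
        res = OcrAssociationModel(cohort.truth_ocr_table(), cohort.phenotypes).fit(
            strata=("all",))
        assert len(res.table) == 15
        assert "association suite" in res.summary()
        assert (res.significant(alpha=1.0).shape[0] == 15)


class TestGroupStates:
    def _windows_from(self, mats):
        return [DfncWindows(subject_id=f"s{i}", matrix=m,
                            window_starts=np.arange(len(m)), n_components=5,
                            taper=TaperSpec())
                for i, m in enumerate(mats)]

    def test_identical_groups_match_perfectly(self, rng):
        base = [rng.normal(size=(40, 10)) for _ in range(4)]
        wins = self._windows_from(base + base)  # duplicate data across groups
        labels = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "label": ["non-PTS"] * 4 + ["PTS"] * 4,
        })
        cmp = compare_group_states(wins, labels, K=2, seed=0)
        assert np.allclose(cmp.matched_correlations, 1.0, atol=1e-6)

    def test_same_distribution_groups_highly_similar(self, small_partition,
                                                     small_archetypes):
        from dfncstates.presets import cohort_windows

        from dfncstates.presets import dwell_markov

        corr_means = []
        for rep in range(10):
            # dwell times well above the window length keep most windows pure
            design = CohortDesign(n_subjects=20, T=400)
            cohort = gen_cohort(design, small_partition, small_archetypes,
                                dwell_markov(mean_dwell=80.0), seed=800 + rep)
            wins = cohort_windows(cohort)
            labels = pd.DataFrame({
                "subject_id": [w.subject_id for w in wins],
                "label": ["non-PTS"] * 10 + ["PTS"] * 10,
            })
            cmp = compare_group_states(wins, labels, K=3, seed=rep)
            corr_means.append(cmp.matched_correlations.mean())
        assert np.mean(corr_means) > 0.95

    def test_state_one_is_most_occupied_in_both_groups(self, small_partition,
                                                       small_archetypes, rng):
        from dfncstates.presets import cohort_windows

        design = CohortDesign(n_subjects=8, T=220)
        cohort = gen_cohort(design, small_partition, small_archetypes,
                            MarkovDesign(K=3), seed=99)
        wins = cohort_windows(cohort)
        labels = pd.DataFrame({
            "subject_id": [w.subject_id for w in wins],
            "label": ["non-PTS"] * 4 + ["PTS"] * 4,
        })
        cmp = compare_group_states(wins, labels, K=3, seed=0)
        # group A's own relabeling guarantees state 1 has the top mean OCR
        row = cmp.ocr_means.loc["non-PTS"]
        assert row["state_1"] == row.max()

    def test_empty_group_rejected(self, rng):
        wins = self._windows_from([rng.normal(size=(20, 10))])
        labels = pd.DataFrame({"subject_id": ["s0"], "label": ["PTS"]})
        with pytest.raises(ValueError):
            compare_group_states(wins, labels, K=2)
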