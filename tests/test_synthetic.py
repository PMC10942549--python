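"""Generator correctness: partitions, state covariances, Markov dynamics,
Gaussian emissions, and whole-cohort structure."""

import numpy as np
import pandas as pd
import pytest

from dfncstates.synthetic import (
    CohortDesign,
    MarkovDesign,
    StateArchetype,
    default_archetypes,
    effect_for_target_r,
    gen_cohort,
    gen_network_partition,
    gen_state_covariances,
    gen_state_sequence,
    gen_timecourses,
    simulated_ocr_sd,
    state_correlation,
)


class TestNetworkPartition:
    def test_default_is_53_components_in_7_networks(self):
        p = gen_network_partition()
        assert p.n_components == 53
        assert p.n_networks == 7
        sizes = [len(p.indices(lab)) for lab in p.labels]
        assert sum(sizes) == 53
        # balanced as possible: sizes differ by at most one
        assert max(sizes) - min(sizes) <= 1

    def test_single_network_takes_all_components(self):
        p = gen_network_partition(5, 1)
        assert p.n_components == 5 and p.n_networks == 1
        assert set(p.assignment) == {p.labels[0]}

    def test_deterministic_given_seed(self):
        assert gen_network_partition(seed=7) == gen_network_partition(seed=7)

    def test_too_few_components_rejected(self):
        with pytest.raises(ValueError):
            gen_network_partition(3, 7)


class TestStateCovariances:
    def test_no_coupling_gives_identity(self, small_partition):
        arch = StateArchetype("null", intra_block_strength=0.0,
                              inter_block_strength=0.0, noise_sd=0.3)
        (cov,) = gen_state_covariances(small_partition, [arch])
        assert np.allclose(cov, np.eye(small_partition.n_components))

    def test_block_construction_by_definition(self, small_partition):
        arch = StateArchetype("blocks", intra_block_strength=0.6,
                              inter_block_strength=0.0, noise_sd=0.0)
        (cov,) = gen_state_covariances(small_partition, [arch])
        net = small_partition.network_index()
        same = net[:, None] == net[None, :]
        off = ~np.eye(len(net), dtype=bool)
        assert np.allclose(cov[same & off], 0.6)
        assert np.allclose(cov[~same], 0.0)
        assert np.allclose(np.diag(cov), 1.0)

    @pytest.mark.parametrize("noise_sd", [0.0, 0.1, 0.5])
    def test_always_positive_definite(self, small_partition, small_archetypes, noise_sd):
        covs = gen_state_covariances(
            small_partition,
            [StateArchetype(a.name, a.intra_block_strength, a.inter_block_strength,
                            noise_sd) for a in small_archetypes])
        for cov in covs:
            assert np.linalg.eigvalsh(cov)[0] > 0
            assert np.allclose(cov, cov.T)

    def test_repair_lifts_indefinite_block_matrix(self, small_partition):
        # strong negative coupling everywhere is not a valid correlation matrix
        arch = StateArchetype("bad", intra_block_strength=0.1,
                              inter_block_strength=-0.6, noise_sd=0.0)
        R = state_correlation(small_partition, arch)
        assert np.linalg.eigvalsh(R)[0] > 0
        assert np.allclose(np.diag(R), 1.0)

    def test_strength_out_of_range_rejected(self, small_partition):
        with pytest.raises(ValueError):
            state_correlation(small_partition,
                              StateArchetype("x", intra_block_strength=1.0))

    def test_default_archetypes_are_three_valid_states(self):
        p = gen_network_partition()
        covs = gen_state_covariances(p, default_archetypes())
        assert len(covs) == 3
        for cov in covs:
            assert np.linalg.eigvalsh(cov)[0] > 0


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        design = MarkovDesign(K=3, transition=np.eye(3),
                              initial=[0.0, 1.0, 0.0])
        seq = gen_state_sequence(50, design, seed=0)
        assert (seq == 2).all()

    def test_ergodic_frequencies_match_stationary(self):
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.25, 0.7]])
        design = MarkovDesign(K=3, transition=P)
        seq = gen_state_sequence(10000, design, seed=3)
        pi = design.stationary()
        freq = np.bincount(seq, minlength=4)[1:] / len(seq)
        assert np.abs(freq - pi).max() < 0.03

    def test_three_state_design_emits_three_values(self):
        seq = gen_state_sequence(5000, MarkovDesign(K=3), seed=1)
        assert set(np.unique(seq)) == {1, 2, 3}

    def test_non_stochastic_transition_rejected(self):
        with pytest.raises(ValueError):
            MarkovDesign(K=2, transition=np.array([[0.9, 0.2], [0.5, 0.5]]))

    def test_reproducible_given_seed(self):
        d = MarkovDesign(K=3)
        assert (gen_state_sequence(200, d, seed=5) == gen_state_sequence(200, d, seed=5)).all()


class TestTimecourses:
    def test_identity_covariance_yields_uncorrelated_columns(self):
        T, C = 2000, 6
        seq = np.ones(T, dtype=int)
        tc = gen_timecourses(seq, [np.eye(C)], seed=0)
        corr = np.corrcoef(tc.data, rowvar=False)
        off = corr[np.triu_indices(C, 1)]
        assert np.abs(off).mean() < 3 / np.sqrt(T)

    def test_sample_covariance_converges_to_state_covariance(self, small_covariances):
        T = 5000
        seq = np.full(T, 2, dtype=int)
        tc = gen_timecourses(seq, small_covariances, seed=1)
        S = np.cov(tc.data, rowvar=False)
        err = np.linalg.norm(S - small_covariances[1]) / np.linalg.norm(small_covariances[1])
        assert err < 0.1

    def test_default_dimension_is_53(self):
        p = gen_network_partition()
        covs = gen_state_covariances(p, default_archetypes())
        tc = gen_timecourses(np.ones(10, dtype=int), covs, seed=0)
        assert tc.n_components == 53

    def test_sequence_beyond_covariances_rejected(self):
        with pytest.raises(ValueError):
            gen_timecourses(np.array([1, 4]), [np.eye(2)] * 3, seed=0)


class TestCohort:
    def test_structure_and_ground_truth(self, tiny_cohort):
        n = len(tiny_cohort.timecourses)
        assert n == 6
        assert tiny_cohort.phenotypes.shape[0] == n
        ocr = tiny_cohort.truth["ocr"]
        assert ocr.shape == (n, 3)
        assert np.allclose(ocr.sum(axis=1), 1.0, atol=1e-12)
        for col in ("age", "sex", "education", "income_level", "marital",
                    "employment", "site", "adi_percentile", "pcl5_wk2", "pcl5_m3"):
            assert col in tiny_cohort.phenotypes.columns

    def test_bit_reproducible_given_seed(self, small_partition, small_archetypes):
        design = CohortDesign(n_subjects=3, T=60)
        mk = MarkovDesign(K=3)
        a = gen_cohort(design, small_partition, small_archetypes, mk, seed=9)
        b = gen_cohort(design, small_partition, small_archetypes, mk, seed=9)
        for ta, tb in zip(a.timecourses, b.timecourses):
            assert (ta.data == tb.data).all()
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_null_effect_gives_no_ocr_outcome_correlation(self):
        design = CohortDesign(n_subjects=300, effect=None, seed=0)
        cohort = gen_cohort(design, include_timecourses=False)
        ocr1 = cohort.truth["ocr"][:, 0]
        y = cohort.phenotypes["pcl5_wk2"].to_numpy()
        ok = ~np.isnan(y)
        r = np.corrcoef(ocr1[ok], y[ok])[0, 1]
        assert abs(r) < 0.12

    def test_missingness_reproduces_follow_up_attrition(self):
        design = CohortDesign(n_subjects=275, seed=1)
        cohort = gen_cohort(design, include_timecourses=False)
        n_m3 = cohort.phenotypes["pcl5_m3"].notna().sum()
        # target 226 of 275; allow binomial fluctuation (sd ~ 6.4)
        assert 200 <= n_m3 <= 250
        assert cohort.phenotypes["pcl5_wk2"].notna().all()

    def test_planted_effect_recovers_target_correlation(self):
        target, noise_sd, n = 0.2, 16.0, 250
        markov = MarkovDesign(K=3)
        sd1 = simulated_ocr_sd(markov, T=210, state=1, n_subjects=500, seed=0)
        beta = effect_for_target_r(target, sd1, noise_sd)
        rs = []
        for rep in range(20):
            design = CohortDesign(
                n_subjects=n, effect=[beta, 0.0, 0.0], effect_timepoints=("M3",),
                outcome_noise_sd=noise_sd,
                missingness={tp: 0.0 for tp in ("WK2", "WK8", "M3", "M6", "M12")},
            )
            cohort = gen_cohort(design, markov=markov, seed=1000 + rep,
                                include_timecourses=False)
            r = np.corrcoef(cohort.truth["ocr"][:, 0],
                            cohort.phenotypes["pcl5_m3"])[0, 1]
            rs.append(r)
        assert abs(np.mean(rs) - target) < 0.1
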