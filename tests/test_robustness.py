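"""Robustness battery and network summaries."""

import numpy as np
import pandas as pd
import pytest

import genconn as g
from genconn.robustness import _aligned_corr


@pytest.fixture(scope="module")
def inputs(cohort):
    genotypes, connectomes, covariates, _, _, _ = cohort
    conn_vec, idx = g.vectorize(connectomes)
    return genotypes.dosages, conn_vec, covariates, idx


class TestSplitHalf:
    def test_halves_are_disjoint_and_exhaustive(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        reports = g.split_half(dosages, conn_vec, cov, n_components=15,
                               seed=1)
        assert len(reports) == 2
        assert reports[0].n_subjects + reports[1].n_subjects == len(dosages)

    def test_strong_signal_reproduces_in_halves(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        reports = g.split_half(dosages, conn_vec, cov, n_components=15,
                               seed=1)
        for rep in reports:
            assert rep.conn_strength_r > 0.5
            assert rep.gen_strength_r > 0.5

    def test_pure_noise_does_not_reproduce_across_disjoint_halves(self,
                                                                  rng):
        # half-vs-full comparisons share subjects, which inflates the
        # null; two disjoint halves give the clean no-signal check
        n = 120
        dosages = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, 40)).astype(float),
            columns=[f"rs{i}" for i in range(40)])
        conn_vec = pd.DataFrame(rng.standard_normal((n, 60)))
        cov = pd.DataFrame({"age": rng.uniform(8, 18, n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        a = g.run_cca_pipeline(dosages.iloc[:60], conn_vec.iloc[:60],
                               cov.iloc[:60], n_components=10)
        b = g.run_cca_pipeline(dosages.iloc[60:], conn_vec.iloc[60:],
                               cov.iloc[60:], n_components=10)
        r = abs(np.corrcoef(a.conn_strengths, b.conn_strengths)[0, 1])
        assert r < 0.4

    def test_too_few_subjects_rejected(self, rng):
        d = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(ValueError, match="40"):
            g.split_half(d, d, d, seed=0)


class TestPcSensitivity:
    def test_baseline_k_reproduces_exactly(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        reports = g.pc_sensitivity(dosages, conn_vec, cov,
                                   k_list=(15,), baseline=15)
        assert reports[0].conn_strength_r == pytest.approx(1.0, abs=1e-9)
        assert reports[0].gen_strength_r == pytest.approx(1.0, abs=1e-9)

    def test_nearby_k_values_reproduce_mode(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        reports = g.pc_sensitivity(dosages, conn_vec, cov,
                                   k_list=(10, 25), baseline=15)
        for rep in reports:
            assert rep.conn_strength_r > 0.8

    def test_degenerate_k_degrades_and_invalid_k_skipped(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        reports = g.pc_sensitivity(dosages, conn_vec, cov,
                                   k_list=(1, 10_000), baseline=15)
        assert len(reports) == 1  # the huge K is skipped
        good = g.pc_sensitivity(dosages, conn_vec, cov, k_list=(10,),
                                baseline=15)
        assert reports[0].conn_strength_r < good[0].conn_strength_r


class TestSnpSubsetRerun:
    def test_full_subset_reproduces_exactly(self, inputs, cohort):
        dosages, conn_vec, cov, _ = inputs
        phenos = cohort[0].snp_meta["phenotype"]
        report, p = g.snp_subset_rerun(
            dosages, conn_vec, cov, phenos, set(phenos.unique()),
            n_components=15, B=99, seed=0)
        assert report.conn_strength_r == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(0.01)

    def test_causal_subset_reproduces_network(self, inputs, cohort):
        dosages, conn_vec, cov, _ = inputs
        geno, truth = cohort[0], cohort[5]
        phenos = geno.snp_meta["phenotype"]
        causal_phenos = set(phenos[truth.causal_snp_ids])
        report, p = g.snp_subset_rerun(dosages, conn_vec, cov, phenos,
                                       causal_phenos, n_components=15,
                                       B=99, seed=0)
        assert report.conn_strength_r > 0.8
        assert p <= 0.05

    def test_noncausal_subset_reproduces_far_less_than_causal(
            self, inputs, cohort):
        # the shared connectome block keeps some correlation even for a
        # signal-free genetic subset, so the check is comparative
        dosages, conn_vec, cov, _ = inputs
        geno, truth = cohort[0], cohort[5]
        phenos = geno.snp_meta["phenotype"]
        causal_phenos = set(phenos[truth.causal_snp_ids])
        null_phenos = set(phenos.unique()) - causal_phenos
        null_rep, _ = g.snp_subset_rerun(dosages, conn_vec, cov, phenos,
                                         null_phenos, n_components=15,
                                         B=99, seed=0)
        causal_rep, _ = g.snp_subset_rerun(dosages, conn_vec, cov, phenos,
                                           causal_phenos, n_components=15,
                                           B=99, seed=0)
        assert null_rep.conn_strength_r < 0.65
        assert null_rep.conn_strength_r < causal_rep.conn_strength_r - 0.2

    def test_empty_subset_rejected(self, inputs, cohort):
        dosages, conn_vec, cov, _ = inputs
        phenos = cohort[0].snp_meta["phenotype"]
        with pytest.raises(ValueError, match="fewer than 2"):
            g.snp_subset_rerun(dosages, conn_vec, cov, phenos,
                               {"no-such-phenotype"})


class TestExcludeSubjects:
    def test_exclude_none_reproduces_exactly(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        flags = np.zeros(len(dosages), dtype=bool)
        report = g.exclude_subjects_rerun(dosages, conn_vec, cov, flags,
                                          n_components=15)
        assert report.conn_strength_r == pytest.approx(1.0, abs=1e-9)

    def test_random_exclusion_is_stable(self, inputs, rng):
        dosages, conn_vec, cov, _ = inputs
        flags = np.zeros(len(dosages), dtype=bool)
        flags[rng.choice(len(flags), len(flags) // 10, replace=False)] = True
        report = g.exclude_subjects_rerun(dosages, conn_vec, cov, flags,
                                          n_components=15)
        assert report.conn_strength_r > 0.8

    def test_excluding_high_latent_subjects_degrades(self, inputs, cohort,
                                                     rng):
        dosages, conn_vec, cov, _ = inputs
        truth = cohort[5]
        top = truth.latent_g > np.median(truth.latent_g)
        targeted = g.exclude_subjects_rerun(dosages, conn_vec, cov, top,
                                            n_components=15)
        random_flags = np.zeros(len(dosages), dtype=bool)
        random_flags[rng.choice(len(dosages), int(top.sum()),
                                replace=False)] = True
        random_rep = g.exclude_subjects_rerun(dosages, conn_vec, cov,
                                              random_flags,
                                              n_components=15)
        assert targeted.conn_strength_r < random_rep.conn_strength_r

    def test_too_few_remaining_rejected(self, inputs):
        dosages, conn_vec, cov, _ = inputs
        flags = np.ones(len(dosages), dtype=bool)
        with pytest.raises(ValueError, match="30"):
            g.exclude_subjects_rerun(dosages, conn_vec, cov, flags)


class TestMeanConnectivity:
    def test_score_equal_to_subject_mean(self, rng):
        X = rng.random((50, 30))
        r, p = g.mean_connectivity_correlation(X, X.mean(axis=1), B=99,
                                               seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.01)

    def test_null_score_uncorrelated(self, rng):
        X = rng.random((200, 30))
        r, p = g.mean_connectivity_correlation(
            X, rng.standard_normal(200), B=199, seed=0)
        assert abs(r) < 0.2
        assert p > 0.01

    def test_planted_hypoconnectivity_negative(self, pipeline_result,
                                               cohort):
        _, connectomes, *_ = cohort
        conn_vec, _ = g.vectorize(connectomes)
        r, p = g.mean_connectivity_correlation(
            conn_vec.to_numpy(), pipeline_result.mode.y_scores,
            B=999, seed=0)
        assert r < 0
        assert p <= 0.01


class TestComputeHubs:
    def _strengths(self, strengths, qs):
        return pd.DataFrame({"feature_id": range(len(strengths)),
                             "strength": strengths, "p": qs, "q": qs,
                             "group": "connections"})

    def test_hand_classified_nodes(self):
        idx = g.edge_index(4)
        strengths = np.zeros(6)
        qs = np.ones(6)
        # node 0 gets significant -0.3 (edge 0-1) and -0.2 (edge 0-2)
        strengths[0], qs[0] = -0.3, 0.001
        strengths[1], qs[1] = -0.2, 0.001
        # node 3 gets +0.4 (edge 1-3) and -0.4 (edge 2-3): exact tie
        strengths[4], qs[4] = 0.4, 0.001
        strengths[5], qs[5] = -0.4, 0.001
        hubs = g.compute_hubs(self._strengths(strengths, qs), idx, 4)
        assert hubs.loc[0, "class"] == "hypo"
        assert hubs.loc[0, "summed_strength"] == pytest.approx(-0.5)
        assert hubs.loc[3, "class"] == "none"          # tie rule
        assert (hubs.loc[hubs["n_significant"] == 0, "class"]
                == "none").all()

    def test_planted_negative_hubs_rank_first(self, pipeline_result,
                                              cohort, small_cfg):
        truth = cohort[5]
        idx = g.edge_index(small_cfg.n_nodes)
        s = pipeline_result.conn_strengths
        q = np.where(np.abs(s) > 0.2, 0.01, 0.5)  # proxy significance
        table = self._strengths(s, q)
        hubs = g.compute_hubs(table, idx, small_cfg.n_nodes)
        # nodes touching many planted edges should carry negative sums
        edge_nodes = np.concatenate([
            idx.loc[truth.signal_connection_ids, "node_i"],
            idx.loc[truth.signal_connection_ids, "node_j"]])
        counts = np.bincount(edge_nodes, minlength=small_cfg.n_nodes)
        top = np.argsort(counts)[-3:]
        assert (hubs.loc[top, "summed_strength"] < 0).all()

    def test_average_variant(self):
        idx = g.edge_index(3)
        table = self._strengths([-0.4, -0.2, 0.0],
                                [0.001, 0.001, 0.9])
        hubs = g.compute_hubs(table, idx, 3, average=True)
        assert hubs.loc[0, "value"] == pytest.approx(-0.3)


class TestSignAlignment:
    def test_aligned_correlation_flips_negative(self, rng):
        a = rng.standard_normal(100)
        r, flipped = _aligned_corr(a, -a)
        assert r == pytest.approx(1.0)
        assert flipped
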