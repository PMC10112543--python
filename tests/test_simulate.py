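"""The synthetic-cohort generator: frequency model, admixed genotypes,
liability phenotypes, discovery statistics, onset channel, focal window
and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from admixprs.evaluate import roc_auc
from admixprs.haplotypes import enumerate_haplotypes, haplotype_sharing
from admixprs.io import read_cohort, read_summary_stats, read_vcf
from admixprs.simulate import (
    SimConfig,
    simulate_cohort,
    simulate_discovery_stats,
    simulate_focal_haplotypes,
    simulate_frequencies,
    simulate_genotypes,
    simulate_onset,
    simulate_phenotypes,
    write_bundle,
)


class TestFrequencies:
    def test_low_fst_limit_tracks_ancestral(self):
        cfg = SimConfig(seed=1, n_variants=2000, fst=(1e-4, 1e-4, 1e-4))
        rng = np.random.default_rng(cfg.seed)
        p_anc = np.random.default_rng(cfg.seed).uniform(0.05, 0.95, cfg.n_variants)
        freqs = simulate_frequencies(cfg, rng)
        assert np.abs(freqs - p_anc[None, :]).max() < 0.02

    def test_realized_fst_matches_configured(self):
        # Balding-Nichols: Var(p_k) = F p(1-p) around the ancestral p; with
        # many replicate populations the unbiased variance recovers F.
        cfg = SimConfig(seed=2, n_variants=5000, n_pops=20, fst=(0.1,) * 20,
                        dirichlet_alpha=(1.0,) * 20)
        freqs = simulate_frequencies(cfg)
        p_anc_mean = freqs.mean(axis=0)
        fst_hat = np.mean(
            freqs.var(axis=0, ddof=1) / (p_anc_mean * (1 - p_anc_mean))
        )
        assert abs(fst_hat - 0.1) < 0.02

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=3, n_variants=500)
        np.testing.assert_array_equal(simulate_frequencies(cfg), simulate_frequencies(cfg))


class TestGenotypes:
    def test_alpha_concentration_drives_mean_q(self):
        cfg = SimConfig(seed=4, n_samples=400, n_variants=50, n_causal=10,
                        dirichlet_alpha=(30.0, 1.0, 1.0))
        freqs = simulate_frequencies(cfg)
        _, q = simulate_genotypes(cfg, freqs)
        assert q[:, 0].mean() > 0.9

    def test_pure_ancestry_frequency_matches_reference(self):
        cfg = SimConfig(seed=5, n_samples=500, n_variants=300, n_pops=2,
                        fst=(0.2, 0.2), dirichlet_alpha=(1000.0, 0.001))
        freqs = simulate_frequencies(cfg)
        gs, q = simulate_genotypes(cfg, freqs)
        assert q[:, 0].min() > 0.99
        err = np.abs(gs.dosage.mean(axis=0) / 2 - freqs[0])
        assert np.mean(err) < 0.03

    def test_phased_pairs_sum_to_dosage(self):
        cfg = SimConfig(seed=6, n_samples=50, n_variants=100)
        freqs = simulate_frequencies(cfg)
        gs, _ = simulate_genotypes(cfg, freqs, phased=True)
        np.testing.assert_array_equal(gs.phased.sum(axis=2), gs.dosage)

    def test_ld_blocks_induce_correlation(self):
        from admixprs.prs import ld_r2

        cfg = SimConfig(seed=7, n_samples=400, n_variants=40, n_causal=10,
                        ld_block_size=10, dirichlet_alpha=(1.0, 1.0, 1.0))
        freqs = simulate_frequencies(cfg)
        gs, _ = simulate_genotypes(cfg, freqs)
        within = np.nanmean(
            [ld_r2(gs.dosage[:, j], gs.dosage[:, j + 1]) for j in (0, 1, 2, 11, 12, 13)]
        )
        between = np.nanmean(
            [ld_r2(gs.dosage[:, j], gs.dosage[:, k]) for j, k in ((0, 15), (5, 25), (12, 35))]
        )
        assert within > between + 0.05


class TestPhenotypes:
    def test_null_heritability_gives_null_auc(self):
        cfg = SimConfig(seed=8, n_samples=600, n_variants=300, n_causal=30, h2=0.0)
        bundle = simulate_cohort(cfg)
        auc = roc_auc(bundle.truth.true_score, bundle.cohort["status"].to_numpy())
        assert abs(auc - 0.5) < 0.05

    def test_heritable_liability_score_is_predictive(self):
        wins = 0
        for seed in range(5):
            cfg = SimConfig(seed=30 + seed, n_samples=800, n_variants=600, n_causal=60)
            bundle = simulate_cohort(cfg)
            auc = roc_auc(bundle.truth.true_score, bundle.cohort["status"].to_numpy())
            wins += auc > 0.65
        assert wins >= 4

    def test_pool_prevalence_near_configured(self):
        cfg = SimConfig(seed=9, n_samples=500, n_variants=200, n_causal=20)
        bundle = simulate_cohort(cfg)
        assert abs(bundle.truth.pool_prevalence - cfg.prevalence) < 0.01

    def test_case_control_ratio_honored(self):
        cfg = SimConfig(seed=10, n_samples=600, n_variants=200, n_causal=20,
                        case_control_ratio=0.5)
        counts = simulate_cohort(cfg).cohort["status"].value_counts()
        assert counts[1] == 200 and counts[0] == 400

    def test_onset_only_for_cases_and_adult(self):
        cfg = SimConfig(seed=11, n_samples=400, n_variants=200, n_causal=20)
        cohort = simulate_cohort(cfg).cohort
        onset = cohort["age_at_onset"]
        assert onset.notna().equals(cohort["status"] == 1)
        assert (onset.dropna() > 18).all()
        assert (onset.dropna() <= cohort.loc[onset.notna(), "age"]).all()


class TestStandalonePhenotypes:
    def test_ratio_and_truth_alignment(self):
        cfg = SimConfig(seed=50, n_samples=3000, n_variants=300, n_causal=30,
                        prevalence=0.3, case_control_ratio=1.0)
        freqs = simulate_frequencies(cfg)
        gs, _ = simulate_genotypes(cfg, freqs)
        cohort, score, beta = simulate_phenotypes(cfg, gs)
        assert len(score) == len(cohort)
        assert np.count_nonzero(beta) == 30
        counts = cohort["status"].value_counts()
        assert abs(counts[1] - counts[0]) <= 1
        # heritable score separates cases from controls
        assert roc_auc(score, cohort["status"].to_numpy()) > 0.6

    def test_no_cases_errors(self):
        cfg = SimConfig(seed=51, n_samples=20, n_variants=100, n_causal=10,
                        h2=0.0, prevalence=1e-6)
        freqs = simulate_frequencies(cfg)
        gs, _ = simulate_genotypes(cfg, freqs)
        with pytest.raises(ValueError, match="cases"):
            simulate_phenotypes(cfg, gs)


class TestDiscoveryStats:
    def test_infinite_sample_limit_recovers_beta(self):
        cfg = SimConfig(seed=12, n_samples=100, n_variants=300, n_causal=30,
                        discovery_n=int(1e9))
        rng = np.random.default_rng(cfg.seed)
        freqs = simulate_frequencies(cfg, rng)
        bundle = simulate_cohort(cfg)
        by_id = {r.variant_id: r.beta for r in bundle.sumstats}
        ids = bundle.genotypes.variants["variant_id"]
        est = np.array([by_id[v] for v in ids])
        err = np.abs(est - bundle.truth.beta_allele)
        # noise vanishes as 1/sqrt(discovery_n); only variants drifted to
        # extreme rarity in the discovery population retain visible error
        assert np.median(err) < 1e-4
        assert np.quantile(err, 0.95) < 1e-3

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(seed=13, n_samples=100, n_variants=1000, n_causal=0,
                        h2=0.0, discovery_n=20_000)
        freqs = simulate_frequencies(cfg)
        bundle = simulate_cohort(cfg)
        pvals = np.array([r.pvalue for r in bundle.sumstats])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_wald_pvalue_consistent_with_z(self):
        cfg = SimConfig(seed=14, n_samples=100, n_variants=100, n_causal=10)
        bundle = simulate_cohort(cfg)
        r = bundle.sumstats[0]
        z = r.beta / r.se
        assert r.pvalue == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-9)


class TestOnsetChannel:
    def test_all_latent_onsets_adult(self):
        cfg = SimConfig(seed=15, n_samples=500)
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame(
            {"sample_id": range(500), "status": 1, "sex": 0,
             "age": rng.uniform(45, 85, 500), "site": "site1"}
        )
        rec = simulate_onset(cfg, cohort, rng.normal(size=500))
        events = rec[rec["event"] == 1]
        assert (events["time"] > 18).all()

    def test_null_quintile_effect_logrank_uniform(self):
        from lifelines.statistics import multivariate_logrank_test

        cfg = SimConfig(seed=16, onset_top_log_hr=0.0)
        pvals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            cohort = pd.DataFrame(
                {"sample_id": range(400), "status": 1, "sex": 0,
                 "age": r.uniform(45, 85, 400), "site": "s"}
            )
            rec = simulate_onset(cfg, cohort, r.normal(size=400), rng=r)
            res = multivariate_logrank_test(rec["time"], rec["quintile"], rec["event"])
            pvals.append(res.p_value)
        assert (np.array(pvals) < 0.05).mean() <= 0.15
        assert sps.kstest(pvals, "uniform").pvalue > 0.005


class TestFocalWindow:
    def test_designed_haplotypes_recovered(self):
        cfg = SimConfig(seed=17, n_samples=1500)
        gs, cohort, truth = simulate_focal_haplotypes(cfg)
        table = enumerate_haplotypes(gs, truth.focal_variant_id, freq_min=0.01)
        strings = {h.alleles for h in table.haplotypes}
        assert {truth.hap_ancestral, truth.hap_g_discovery, truth.hap_g_target} <= strings

    def test_sharing_round_trip_within_one_point(self):
        cfg = SimConfig(seed=18, n_samples=800)
        _, _, truth = simulate_focal_haplotypes(cfg)
        share = haplotype_sharing(
            truth.hap_g_discovery, truth.hap_g_target, truth.hap_ancestral
        )
        assert abs(share - 100 * cfg.hap_share_target) <= 1.0

    def test_risk_flows_through_focal_allele(self):
        cfg = SimConfig(seed=19, n_samples=3000, focal_risk_or=2.0)
        gs, cohort, truth = simulate_focal_haplotypes(cfg)
        focal_col = gs.variant_index()[truth.focal_variant_id]
        g = gs.dosage[:, focal_col]
        y = cohort["status"].to_numpy()
        carrier_rate = y[g > 0].mean()
        noncarrier_rate = y[g == 0].mean()
        assert carrier_rate > noncarrier_rate + 0.05


class TestRoundTrip:
    def test_write_read_identical_genotypes(self, tmp_path):
        cfg = SimConfig(seed=20, n_samples=40, n_variants=60, n_causal=10)
        bundle = simulate_cohort(cfg)
        paths = write_bundle(bundle, tmp_path)
        gs = read_vcf(paths["vcf"])
        np.testing.assert_allclose(gs.dosage, bundle.genotypes.dosage, atol=1e-6)
        records, rejected = read_summary_stats(paths["sumstats"])
        assert rejected == 0 and len(records) == len(bundle.sumstats)
        cohort = read_cohort(paths["cohort"])
        assert len(cohort) == cfg.n_samples

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=21, n_samples=30, n_variants=40, n_causal=5)
        p1 = write_bundle(simulate_cohort(cfg), tmp_path / "a")
        p2 = write_bundle(simulate_cohort(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_truth_row_count(self, tmp_path):
        cfg = SimConfig(seed=22, n_samples=25, n_variants=30, n_causal=5)
        paths = write_bundle(simulate_cohort(cfg), tmp_path)
        truth = pd.read_csv(paths["truth"], sep="\t")
        assert len(truth) == cfg.n_samples
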