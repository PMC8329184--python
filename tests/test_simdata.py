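"""Generative model checks: determinism, HWE, LD structure, effect recovery
and the integrity of the simulated phenome."""

import numpy as np
import pytest
from scipy import stats

from kynscan.errors import ConfigError
from kynscan.phenome import map_events_to_phecodes
from kynscan.simdata import (
    SimConfig,
    simulate_demographics,
    simulate_diseases_and_icd,
    simulate_genotypes,
    simulate_metabolite,
    simulate_two_sample_sumstats,
    toy_phecode_map,
)


class TestConfig:
    def test_block_sizes_must_cover_variants(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, allele_freqs=(0.3, 0.4), ld_blocks=[(1, 0.0)])

    def test_frequency_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, allele_freqs=(0.001,), metabolite_effects=(0.1,))

    def test_rho_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, allele_freqs=(0.3,), metabolite_effects=(0.1,),
                      ld_blocks=[(1, 1.0)])


class TestGenotypes:
    def test_determinism(self):
        cfg = SimConfig(seed=42, n_individuals=500)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(SimConfig(seed=42, n_individuals=500))
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.person_ids == b.person_ids

    def test_different_seed_differs(self):
        a = simulate_genotypes(SimConfig(seed=1, n_individuals=500))
        b = simulate_genotypes(SimConfig(seed=2, n_individuals=500))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_hwe_at_half_frequency(self):
        cfg = SimConfig(seed=3, n_individuals=20_000, allele_freqs=(0.5,),
                        metabolite_effects=(0.0,))
        G = simulate_genotypes(cfg)
        counts = np.bincount(G.dosages[:, 0].astype(int), minlength=3) / 20_000
        np.testing.assert_allclose(counts, [0.25, 0.5, 0.25], atol=0.015)

    def test_unlinked_variants_near_zero_r2(self):
        cfg = SimConfig(seed=4, n_individuals=20_000,
                        allele_freqs=(0.3, 0.4), metabolite_effects=(0.0, 0.0))
        G = simulate_genotypes(cfg)
        r = np.corrcoef(G.dosages.T)[0, 1]
        assert r * r < 0.01

    def test_high_rho_block_high_r2(self):
        cfg = SimConfig(seed=5, n_individuals=5000,
                        allele_freqs=(0.4, 0.4), metabolite_effects=(0.0, 0.0),
                        ld_blocks=[(2, 0.99)])
        G = simulate_genotypes(cfg)
        r = np.corrcoef(G.dosages.T)[0, 1]
        # thresholding attenuates the latent correlation; rho=0.99 still
        # yields very strong dosage LD
        assert r * r > 0.8

    def test_ld_monotone_in_rho(self):
        r2 = []
        for rho in (0.2, 0.6, 0.95):
            cfg = SimConfig(seed=6, n_individuals=8000,
                            allele_freqs=(0.4, 0.4), metabolite_effects=(0.0, 0.0),
                            ld_blocks=[(2, rho)])
            G = simulate_genotypes(cfg)
            r2.append(np.corrcoef(G.dosages.T)[0, 1] ** 2)
        assert r2[0] < r2[1] < r2[2]


class TestMetabolite:
    def test_null_model_standard_normal(self):
        cfg = SimConfig(seed=7, n_individuals=10_000,
                        allele_freqs=(0.3,), metabolite_effects=(0.0,),
                        confounder_to_metabolite=0.0)
        G = simulate_genotypes(cfg)
        y, _ = simulate_metabolite(G, cfg)
        assert stats.kstest(y, "norm").pvalue > 0.01

    def test_effect_recovery(self):
        cfg = SimConfig(seed=8, n_individuals=10_000,
                        allele_freqs=(0.3,), metabolite_effects=(0.2,),
                        confounder_to_metabolite=0.0)
        G = simulate_genotypes(cfg)
        y, _ = simulate_metabolite(G, cfg)
        g = G.dosages[:, 0]
        slope, _, _, _, se = stats.linregress(g, y)
        assert abs(slope - 0.2) < 3 * se

    def test_variance_decomposition(self):
        freqs = (0.2, 0.4, 0.6)
        gammas = (0.1, 0.15, 0.2)
        cfg = SimConfig(seed=9, n_individuals=50_000, allele_freqs=freqs,
                        metabolite_effects=gammas, confounder_to_metabolite=0.0)
        G = simulate_genotypes(cfg)
        genetic = G.dosages @ np.asarray(gammas)
        expected = sum(2 * f * (1 - f) * g**2 for f, g in zip(freqs, gammas))
        assert genetic.var() == pytest.approx(expected, rel=0.05)
        y, _ = simulate_metabolite(G, cfg)
        assert y.var() == pytest.approx(1.0, rel=0.05)


class TestDiseasesAndIcd:
    def test_base_rate_honored(self):
        cfg = SimConfig(seed=10, n_individuals=10_000, n_phecodes=2,
                        disease_base_rates=0.05)
        G = simulate_genotypes(cfg)
        y, C = simulate_metabolite(G, cfg)
        disease, _ = simulate_diseases_and_icd(G, y, C, cfg)
        for col in disease.columns:
            n_cases = disease[col].sum()
            assert 400 <= n_cases <= 600  # binomial tolerance around 500

    def test_causal_effect_monotone_in_metabolite(self):
        cfg = SimConfig(seed=11, n_individuals=20_000, n_phecodes=1,
                        causal_effect=0.4, disease_base_rates=0.1)
        G = simulate_genotypes(cfg)
        y, C = simulate_metabolite(G, cfg)
        disease, _ = simulate_diseases_and_icd(G, y, C, cfg)
        quartile = np.digitize(y, np.quantile(y, [0.25, 0.5, 0.75]))
        prevalence = [disease.iloc[quartile == k, 0].mean() for k in range(4)]
        assert prevalence == sorted(prevalence)

    def test_cases_have_two_distinct_date_instances(self):
        cfg = SimConfig(seed=12, n_individuals=2000, n_phecodes=3,
                        disease_base_rates=0.1)
        G = simulate_genotypes(cfg)
        y, C = simulate_metabolite(G, cfg)
        disease, events = simulate_diseases_and_icd(G, y, C, cfg)
        pmap = toy_phecode_map(3)
        counts, unmapped = map_events_to_phecodes(events, pmap)
        counts = counts.set_index(["person_id", "phecode"])["n_instances"]
        for phecode in disease.columns:
            cases = disease.index[disease[phecode] == 1]
            for person in cases[:50]:
                assert counts.loc[(person, phecode)] >= 2
        # noise codes exist and are unmapped; they never touch the phenome
        assert (unmapped["code"] == "Z99.9").any()

    def test_controls_carry_no_disease_codes(self):
        cfg = SimConfig(seed=13, n_individuals=2000, n_phecodes=2,
                        disease_base_rates=0.1)
        G = simulate_genotypes(cfg)
        y, C = simulate_metabolite(G, cfg)
        disease, events = simulate_diseases_and_icd(G, y, C, cfg)
        pmap = toy_phecode_map(2)
        counts, _ = map_events_to_phecodes(events, pmap)
        for phecode in disease.columns:
            controls = set(disease.index[disease[phecode] == 0])
            coded = set(counts.loc[counts["phecode"] == phecode, "person_id"])
            assert not (controls & coded)

    def test_determinism_of_events(self):
        cfg = SimConfig(seed=14, n_individuals=1000, n_phecodes=2)
        G = simulate_genotypes(cfg)
        y, C = simulate_metabolite(G, cfg)
        _, ev_a = simulate_diseases_and_icd(G, y, C, cfg)
        _, ev_b = simulate_diseases_and_icd(G, y, C, cfg)
        assert ev_a.equals(ev_b)


class TestTwoSampleSumstats:
    def test_null_centering_over_replicates(self):
        from kynscan.mr import MRInput, ivw

        ests = []
        for seed in range(60):
            cfg = SimConfig(seed=200 + seed, n_sample_exposure=2000,
                            n_sample_outcome=2000)
            ts = simulate_two_sample_sumstats(cfg, theta=0.0)
            inp = MRInput(bx=[r.beta for r in ts.exposure],
                          sx=[r.se for r in ts.exposure],
                          by=[r.beta for r in ts.outcome],
                          sy=[r.se for r in ts.outcome])
            ests.append(ivw(inp).estimate)
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 4 * mc_se + 0.01

    def test_reported_se_matches_replicate_scatter(self):
        betas, ses = [], []
        for seed in range(60):
            cfg = SimConfig(seed=300 + seed, allele_freqs=(0.3,),
                            metabolite_effects=(0.1,), n_sample_exposure=2000)
            ts = simulate_two_sample_sumstats(cfg, theta=0.0)
            betas.append(ts.exposure[0].beta)
            ses.append(ts.exposure[0].se)
        assert np.mean(ses) == pytest.approx(np.std(betas, ddof=1), rel=0.25)

    def test_egger_intercept_sees_directional_pleiotropy(self):
        from kynscan.mr import MRInput, egger

        # strong, well-spread instruments: Egger's intercept is only clean
        # when errors-in-variables attenuation of the slope is negligible
        intercepts = []
        freqs = tuple(np.linspace(0.15, 0.7, 30))
        effects = tuple(np.linspace(0.06, 0.24, 30))
        for seed in range(30):
            cfg = SimConfig(seed=400 + seed, allele_freqs=freqs,
                            metabolite_effects=effects,
                            pleiotropy_mean=0.05, pleiotropy_sd=0.01,
                            pleiotropy_frac=1.0,
                            n_sample_exposure=12_000, n_sample_outcome=4000)
            ts = simulate_two_sample_sumstats(cfg, theta=0.2)
            inp = MRInput(bx=[r.beta for r in ts.exposure],
                          sx=[r.se for r in ts.exposure],
                          by=[r.beta for r in ts.outcome],
                          sy=[r.se for r in ts.outcome])
            intercepts.append(egger(inp).egger_intercept)
        mc_se = np.std(intercepts) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts) - 0.05) < 3 * mc_se + 0.005

    def test_determinism(self):
        a = simulate_two_sample_sumstats(SimConfig(seed=21), theta=0.2)
        b = simulate_two_sample_sumstats(SimConfig(seed=21), theta=0.2)
        assert a.exposure == b.exposure and a.outcome == b.outcome


def test_demographics_complete():
    cfg = SimConfig(seed=30, n_individuals=500)
    demo = simulate_demographics(cfg)
    assert len(demo) == 500
    assert set(demo["sex"].unique()) <= {"male", "female"}
    assert demo["age"].between(30, 79).all()
    assert {f"pc{k}" for k in range(1, 6)} <= set(demo.columns)
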