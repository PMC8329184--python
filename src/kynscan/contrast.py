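"""The pleiotropy-versus-causality contrast, end to end.

A central question for any biomarker PheWAS: when one of a metabolite's
instrument SNPs shows disease associations, is the metabolite causal for
those diseases, or does the SNP act through a separate (horizontally
pleiotropic) pathway? The discriminating pattern is a single-SNP scan that
lights up for the pleiotropic variant while the multi-SNP polygenic-score
scan — which dilutes any one variant's direct effects across the whole
instrument set — stays null.

This module wires the full pipeline (genotypes -> metabolite -> diseases ->
ICD events -> phecode cohort -> single-SNP and PRS scans -> FDR) over a
scenario with exactly that architecture: one instrument variant carries
direct log-odds effects on three diseases, the metabolite itself has no
causal disease effect, and the pleiotropic variant contributes a minority
of the score weight (the dilution that makes the contrast detectable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import compute_prs, phewas_scan, scan_to_frame
from .phenome import build_cohort, map_events_to_phecodes
from .simdata import (
    SimConfig,
    simulate_demographics,
    simulate_diseases_and_icd,
    simulate_genotypes,
    simulate_metabolite,
    toy_phecode_map,
)
from .synthesis import annotate_fdr

#: index of the pleiotropic instrument within the default six-variant set
PLEIOTROPIC_VARIANT = 2
#: diseases (phecode indices) the pleiotropic variant acts on directly
AFFECTED_DISEASES = (0, 1, 2)
#: direct log-odds effect per allele on each affected disease
DIRECT_EFFECT = 0.30

# Instrument effects on the metabolite (SD units per allele). The
# pleiotropic variant is given a small metabolite effect so it carries a
# minority of the polygenic-score weight; the contrast hinges on that.
SCENARIO_EFFECTS = (0.16, 0.32, 0.03, 0.14, 0.16, 0.22)


def contrast_config(seed: int, n_individuals: int = 20_000, n_phecodes: int = 12) -> SimConfig:
    """Study conditions for the contrast scenario: a biobank-scale cohort, a
    dozen common diagnoses (8% base rate), no metabolite->disease effect,
    and one pleiotropic instrument."""
    pi = np.zeros((len(SCENARIO_EFFECTS), n_phecodes))
    pi[PLEIOTROPIC_VARIANT, list(AFFECTED_DISEASES)] = DIRECT_EFFECT
    return SimConfig(
        seed=seed,
        n_individuals=n_individuals,
        metabolite_effects=SCENARIO_EFFECTS,
        causal_effect=0.0,
        snp_disease_effects=pi,
        disease_base_rates=0.08,
        n_phecodes=n_phecodes,
    )


@dataclass
class ContrastResult:
    single_snp: pd.DataFrame
    prs: pd.DataFrame
    pleiotropic_variant: str
    affected_phecodes: list[str]

    def snp_hits(self, q: float = 0.05) -> list[str]:
        t = self.single_snp
        return list(t.loc[t["q"] < q, "phenotype"])

    def prs_hits(self, q: float = 0.05) -> list[str]:
        t = self.prs
        return list(t.loc[t["q"] < q, "phenotype"])

    def detected_affected(self, q: float = 0.05) -> int:
        return len(set(self.snp_hits(q)) & set(self.affected_phecodes))


def run_contrast_replicate(seed: int, n_individuals: int = 20_000,
                           min_cases: int = 300) -> ContrastResult:
    """One full pipeline pass over the contrast scenario.

    Simulates the cohort, builds the phecode case/control sets, and runs the
    single-SNP PheWAS for the pleiotropic variant and the PRS PheWAS with
    the discovery (generative) weights, each with BH q-values.
    """
    cfg = contrast_config(seed, n_individuals=n_individuals)
    G = simulate_genotypes(cfg)
    y, C = simulate_metabolite(G, cfg)
    pmap = toy_phecode_map(cfg.n_phecodes)
    disease, events = simulate_diseases_and_icd(G, y, C, cfg, pmap)
    demo = simulate_demographics(cfg)

    counts, _ = map_events_to_phecodes(events, pmap)
    cohort = build_cohort(counts, pmap, demo, min_cases=min_cases)

    covars = np.column_stack([
        (demo["sex"] == "male").to_numpy(float),
        demo["age"].to_numpy(float),
        demo[[f"pc{k}" for k in range(1, 6)]].to_numpy(float),
    ])

    pleio_id = G.variants["variant_id"][PLEIOTROPIC_VARIANT]
    snp_results = phewas_scan(cohort, G.dosages[:, PLEIOTROPIC_VARIANT], covars,
                              predictor_name=pleio_id)
    snp_table = annotate_fdr(scan_to_frame(snp_results))

    weights = [(vid, alt, beta) for vid, alt, beta in zip(
        G.variants["variant_id"], G.variants["alt"], SCENARIO_EFFECTS)]
    prs = compute_prs(G, weights)
    prs_results = phewas_scan(cohort, prs.standardized, covars, predictor_name="PRS")
    prs_table = annotate_fdr(scan_to_frame(prs_results))

    affected = [disease.columns[d] for d in AFFECTED_DISEASES]
    return ContrastResult(single_snp=snp_table, prs=prs_table,
                          pleiotropic_variant=pleio_id, affected_phecodes=affected)
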