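"""Generate the synthetic study population.

Simulates the discovery conditions the rest of the analysis assumes: six
instrument SNPs at realistic frequencies, a unit-variance plasma metabolite
they regulate, a dozen common diagnoses with ICD-9/ICD-10 event streams, and
per-person demographics/PCs. Writes every standard input file the pipeline
reads under results/01_cohort/.
"""

from pathlib import Path

import pandas as pd

from kynscan.simdata import (
    SimConfig, simulate_demographics, simulate_diseases_and_icd,
    simulate_genotypes, simulate_metabolite, toy_phecode_map,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "01_cohort"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=2024, n_individuals=20_000, n_phecodes=12,
                disease_base_rates=0.08)
G = simulate_genotypes(cfg)
y, C = simulate_metabolite(G, cfg)
pmap = toy_phecode_map(cfg.n_phecodes)
disease, events = simulate_diseases_and_icd(G, y, C, cfg, pmap)
demo = simulate_demographics(cfg)

G.to_dosage_tsv(OUT / "dosages.tsv")
events.to_csv(OUT / "icd_events.csv", index=False)
pmap.table.to_csv(OUT / "phecode_map.csv", index=False)
demo.to_csv(OUT / "demographics.csv")
pd.DataFrame({"person_id": G.person_ids, "metabolite": y}).to_csv(
    OUT / "metabolite.csv", index=False)

print(f"persons: {G.n_persons}, variants: {G.n_variants}")
print(f"metabolite variance: {y.var():.3f} (target 1.0)")
print(f"disease prevalences: {disease.mean().round(3).to_dict()}")
print(f"ICD events written: {len(events)} -> {OUT}")
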