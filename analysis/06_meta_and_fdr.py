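"""Combine two simulated cohorts and control the false discovery rate.

Runs the single-SNP scan of the contrast scenario in two independently
seeded cohorts (standing in for two EHR studies), combines each phecode's
estimates with the sample-size-weighted z scheme (the METAL default), and
applies Benjamini–Hochberg across the phenome. The meta-analysis should
sharpen the three true signals without admitting new ones.
"""

from pathlib import Path

from kynscan.contrast import run_contrast_replicate
from kynscan.synthesis import MetaInput, meta_report

OUT = Path(__file__).resolve().parent.parent / "results" / "06_meta"
OUT.mkdir(parents=True, exist_ok=True)

study_a = run_contrast_replicate(seed=2024)
study_b = run_contrast_replicate(seed=2124)

phenos, inputs = [], []
for _, row_a in study_a.single_snp.iterrows():
    row_b = study_b.single_snp[study_b.single_snp.phenotype == row_a.phenotype]
    if row_a.failed or row_b.empty or bool(row_b.failed.iloc[0]):
        continue
    row_b = row_b.iloc[0]
    phenos.append(row_a.phenotype)
    inputs.append(MetaInput(
        [row_a.beta, row_b.beta], [row_a.se, row_b.se],
        [row_a.n_cases + row_a.n_controls, row_b.n_cases + row_b.n_controls]))

report = meta_report(phenos, inputs)
report.to_csv(OUT / "meta_single_snp.tsv", sep="\t", index=False)

sig = report[report.q < 0.05]
print(f"phecodes meta-analyzed: {len(report)}")
print(f"q<0.05 after meta-analysis: {list(sig.phenotype)}")
print(f"true direct-effect phecodes: {study_a.affected_phecodes}")
print(report.round(4).to_string(index=False))
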