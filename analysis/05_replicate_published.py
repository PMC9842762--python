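#!/usr/bin/env python
"""Replicate the deposited-study analysis when its source tables are supplied.

This driver is intentionally offline: it expects the study's MaxQuant
proteinGroups table and a sample sheet to be placed under
data/supplementary/ by the user (e.g. exported from the public deposit).
It then runs the full differential pipeline (50% valid filter, downshift
imputation, S0 = 0.1 moderated t at permutation FDR 0.05) and, per patient,
the dPPi monitor.  Without the files it exits with a clear message; nothing
is downloaded.
"""

from pathlib import Path

from dppi import pipeline

supp = Path("data/supplementary")
matrix = supp / "proteinGroups.txt"
sheet = supp / "samples.tsv"

if not matrix.exists() or not sheet.exists():
    raise SystemExit(
        f"supplementary tables not found under {supp}/ "
        "(expected proteinGroups.txt and samples.tsv); "
        "place the deposited study tables there to run the replication")

cfg = pipeline.PipelineConfig(
    matrix_path=str(matrix), sheet_path=str(sheet),
    dialect="maxquant_proteingroups",
    out_dir="results/replication", seed=1)
manifest = pipeline.run_diff(cfg)
print(f"filtered protein set: {manifest['counts']['n_proteins_filtered']}")
print(f"significant proteins: {manifest['n_significant']}")

patients = input("comma-separated patient ids to monitor (blank to skip): ").strip()
for patient in filter(None, (p.strip() for p in patients.split(","))):
    report = pipeline.run_monitor(cfg, patient)
    print(report.rows.to_string(index=False))
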