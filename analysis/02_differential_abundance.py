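#!/usr/bin/env python
"""Differential abundance on the simulated cohort (run 01 first).

Replicate-averages, log2-transforms, filters at 50% valid in at least one
group, imputes missing values by Gaussian downshift (width 0.5, downshift
1.8), then runs the S0-moderated t-test (S0 = 0.1) with permutation-based
FDR 0.05.  Outputs: differential table, volcano export, class counts and a
column dendrogram under results/differential/.
"""

from pathlib import Path

from dppi import pipeline

sim = Path("results/simulated")
if not sim.exists():
    raise SystemExit("run analysis/01_simulate_cohort.py first")

cfg = pipeline.PipelineConfig(
    matrix_path=str(sim / "sim_matrix.tsv"),
    sheet_path=str(sim / "sim_samples.tsv"),
    out_dir="results/differential",
    seed=1,
)
manifest = pipeline.run_diff(cfg)

print(f"kept {manifest['counts']['n_proteins_filtered']} of "
      f"{manifest['counts']['n_proteins_input']} proteins after the 50% rule")
print(f"significant at permutation FDR 0.05, S0 0.1: {manifest['n_significant']}")
print(f"class counts: {manifest['class_counts']}")
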