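"""End-to-end pipeline runners with deterministic seeding and run manifests.

Each runner chains the library stages (read -> replicate-average -> log2 ->
filter -> impute -> test / monitor), writes every intermediate matrix and the
final tables to an output directory, and records parameters, derived seeds
and per-stage row counts in a manifest JSON, which is sufficient to re-run
the analysis byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, io_formats, pathway_monitor, preprocess, synthetic_data
from .differential import DiffTestConfig
from .io_formats import ProteinQuantMatrix, SampleRecord
from .pathway_monitor import AlertConfig
from .preprocess import FilterConfig, ImputeConfig

log = logging.getLogger("dppi")

__all__ = ["PipelineConfig", "run_diff", "run_monitor", "run_simulate"]


@dataclass
class PipelineConfig:
    matrix_path: str | None = None
    sheet_path: str | None = None
    signature_path: str | None = None   # None = bundled panel
    dialect: str = "plain_wide"
    out_dir: str = "results"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    diff: DiffTestConfig = field(default_factory=DiffTestConfig)
    alert: AlertConfig = field(default_factory=AlertConfig)
    sim: synthetic_data.CohortSimConfig = field(
        default_factory=synthetic_data.CohortSimConfig)

    def derived_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _load_signature(cfg: PipelineConfig):
    if cfg.signature_path:
        return io_formats.read_gmt(cfg.signature_path)
    return io_formats.load_builtin_signature()


def _load_inputs(cfg: PipelineConfig) -> tuple[ProteinQuantMatrix, list[SampleRecord]]:
    if not cfg.matrix_path or not Path(cfg.matrix_path).exists():
        raise FileNotFoundError(f"quantification matrix not found: {cfg.matrix_path}")
    if not cfg.sheet_path or not Path(cfg.sheet_path).exists():
        raise FileNotFoundError(f"sample sheet not found: {cfg.sheet_path}")
    matrix = io_formats.read_quant_matrix(cfg.matrix_path, cfg.dialect)
    sheet = io_formats.read_sample_sheet(cfg.sheet_path)
    return matrix, sheet


def _write_manifest(out: Path, name: str, payload: dict) -> Path:
    path = out / f"{name}_manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")
    return path


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def preprocess_for_test(
    matrix: ProteinQuantMatrix,
    sheet: list[SampleRecord],
    cfg: PipelineConfig,
) -> tuple[ProteinQuantMatrix, list[SampleRecord], dict]:
    """raw -> replicate-averaged -> log2 -> filtered -> imputed, with counts.

    The averaged columns are named <patient>_t<timepoint>; a per-patient sheet
    (one pseudo-sample per patient/timepoint) is returned alongside.
    """
    averaged = preprocess.average_technical_replicates(matrix, sheet)
    seen = {}
    for r in sheet:
        seen.setdefault((r.patient_id, r.timepoint_index),
                        SampleRecord(f"{r.patient_id}_t{r.timepoint_index}",
                                     r.patient_id, r.timepoint_index,
                                     r.group, 1, r.month))
    avg_sheet = list(seen.values())
    logged = preprocess.log2_transform(averaged)
    filtered, report = preprocess.filter_min_valid(logged, avg_sheet, cfg.filter)
    imp_cfg = dataclasses.replace(cfg.impute, seed=cfg.derived_seed("impute"))
    imputed = preprocess.impute_gaussian_downshift(filtered, imp_cfg)
    counts = {
        "n_proteins_input": matrix.shape[0],
        "n_proteins_filtered": filtered.shape[0],
        "n_samples_input": matrix.shape[1],
        "n_columns_averaged": averaged.shape[1],
        "impute_seed": imp_cfg.seed,
    }
    return imputed, avg_sheet, counts


def run_diff(cfg: PipelineConfig) -> dict:
    """Differential-abundance pipeline: preprocess, test, volcano, cluster."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, sheet = _load_inputs(cfg)
    log.info("diff: %d proteins x %d samples", *matrix.shape)

    imputed, avg_sheet, counts = preprocess_for_test(matrix, sheet, cfg)
    io_formats.write_quant_matrix(imputed, out / "matrix_imputed.tsv")

    diff_cfg = dataclasses.replace(cfg.diff, seed=cfg.derived_seed("permute"))
    diff = differential.permutation_fdr(imputed, avg_sheet, diff_cfg)
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)
    volcano, class_counts = differential.volcano_table(diff)
    volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
    (out / "class_counts.json").write_text(json.dumps(class_counts) + "\n")

    clust = differential.hierarchical_cluster(imputed, z_score_rows=True)
    (out / "columns_dendrogram.nwk").write_text(clust.to_newick() + "\n")

    manifest = {
        "stage": "diff", "seed": cfg.seed, "counts": counts,
        "diff_seed": diff_cfg.seed,
        "s0": cfg.diff.s0, "fdr": cfg.diff.fdr,
        "n_significant": int(diff["significant"].sum()),
        "class_counts": class_counts,
        "outputs": {p.name: _hash_file(p) for p in sorted(out.glob("*"))
                    if p.is_file() and "manifest" not in p.name},
    }
    _write_manifest(out, "diff", manifest)
    return manifest


def run_monitor(cfg: PipelineConfig, patient: str) -> pathway_monitor.MonitoringReport:
    """Longitudinal monitoring for one patient: PPi, dPPi trajectory, alerts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, sheet = _load_inputs(cfg)
    sig = _load_signature(cfg)
    averaged = preprocess.average_technical_replicates(matrix, sheet)

    traj = pathway_monitor.dppi_trajectory(averaged, sheet, sig, patient, cfg.alert)
    rows = pd.DataFrame([{
        "patient": r.patient_id, "timepoint": r.timepoint_index,
        "dppi_total": r.dppi_total, "dppi_percent": r.dppi_percent,
        "alert": "Yes" if r.alert else "No",
    } for r in traj])
    rows.to_csv(out / f"dppi_trajectory_{patient}.tsv", sep="\t", index=False)

    long_rows = [
        {"patient": r.patient_id, "timepoint": r.timepoint_index,
         "pathway": pid, "dppi": v}
        for r in traj for pid, v in r.per_pathway_dppi.items()
    ]
    pd.DataFrame(long_rows).to_csv(
        out / f"dppi_per_pathway_{patient}.tsv", sep="\t", index=False)

    report = pathway_monitor.build_report(traj, cfg=cfg.alert)
    report.rows.to_csv(out / f"monitor_report_{patient}.tsv", sep="\t", index=False)
    _write_manifest(out, f"monitor_{patient}", {
        "stage": "monitor", "patient": patient, "seed": cfg.seed,
        "alert_threshold": cfg.alert.threshold,
        "n_timepoints": len(traj) + 1,
    })
    return report


def run_simulate(cfg: PipelineConfig) -> dict:
    """Emit a synthetic cohort (matrix, sheet, truth tables) to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.derived_seed("simulate"))
    if sim_cfg.n_proteins < 1:
        raise ValueError("n_proteins must be positive")
    matrix, sheet, truth = synthetic_data.simulate_cohort(sim_cfg)
    io_formats.write_quant_matrix(matrix, out / "sim_matrix.tsv")
    io_formats.write_sample_sheet(sheet, out / "sim_samples.tsv")
    pd.DataFrame({
        "row": truth.effect_rows,
        "gene": [matrix.gene_names[i] for i in truth.effect_rows],
        "log2fc": truth.effect_log2fc,
    }).to_csv(out / "sim_truth.tsv", sep="\t", index=False)
    manifest = {
        "stage": "simulate", "seed": cfg.seed, "sim_seed": sim_cfg.seed,
        "n_proteins": sim_cfg.n_proteins,
        "n_samples": matrix.shape[1],
        "missing_fraction": float(matrix.missing_mask().mean()),
        "outputs": {p.name: _hash_file(p) for p in sorted(out.glob("sim_*"))},
    }
    _write_manifest(out, "simulate", manifest)
    return manifest
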