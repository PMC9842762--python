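"""Personal Pathway index (PPi) and its longitudinal differential (dPPi).

The PPi for a patient at a timepoint is the sum of the raw LFQ intensities of
the signature proteins — overall (over the deduplicated union of the seven
pathways' members) and per pathway.  The dPPi at timepoint t_y is the relative
change of that sum against the disease-onset baseline t1:

    dPPi(t_y) = (PPi(t_y) - PPi(t1)) / PPi(t1)

reported as an integer percent (rounded half-away-from-zero).  Every
timepoint is referenced to t1, never chained to the previous timepoint.  A
signature protein not detected at a timepoint contributes 0 (below detection
limit); imputed values never enter the sums.

A more positive dPPi flags a potentially worsening clinical course; the
default alert threshold of -5 percent separates all follow-up decisions in
the bundled clinical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantMatrix, SampleRecord, SignatureSet

__all__ = [
    "PPiRecord",
    "DPPiRecord",
    "AlertConfig",
    "MonitoringReport",
    "match_signature",
    "compute_ppi",
    "compute_dppi",
    "dppi_trajectory",
    "alert_decision",
    "build_report",
    "load_followup_table",
]


@dataclass(frozen=True)
class PPiRecord:
    patient_id: str
    timepoint_index: int
    per_pathway_sum: dict[str, float]
    total_sum: float
    n_matched: int


@dataclass(frozen=True)
class DPPiRecord:
    patient_id: str
    timepoint_index: int
    dppi_total: float
    dppi_percent: int
    per_pathway_dppi: dict[str, float | None]
    alert: bool = False


@dataclass(frozen=True)
class AlertConfig:
    """Alert fires iff dppi_percent >= threshold (default -5)."""

    threshold: float = -5.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class MonitoringReport:
    rows: pd.DataFrame
    concordance: float | None = None


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def match_signature(
    matrix: ProteinQuantMatrix, sig: SignatureSet
) -> dict[str, list[int]]:
    """Map signature symbol -> matrix row indices carrying that symbol.

    Matching is case-insensitive and splits semicolon-joined gene-group
    entries; a protein group matches if ANY of its names matches.
    """
    rows_by_symbol: dict[str, list[int]] = {}
    wanted = {s.upper() for s in sig.union()}
    for i, names in enumerate(matrix.gene_names):
        for name in str(names).split(";"):
            u = name.strip().upper()
            if u in wanted:
                rows_by_symbol.setdefault(u, []).append(i)
    return rows_by_symbol


def _column_for(
    matrix: ProteinQuantMatrix,
    sheet: Iterable[SampleRecord] | None,
    patient: str,
    timepoint: int,
) -> str:
    if sheet is not None:
        hits = [r.sample_id for r in sheet
                if r.patient_id == patient and r.timepoint_index == timepoint
                and r.sample_id in matrix.values.columns]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise ValueError(
                f"{patient} t{timepoint}: {len(hits)} columns; average "
                "technical replicates first")
    col = f"{patient}_t{timepoint}"
    if col in matrix.values.columns:
        return col
    raise KeyError(f"no column for patient {patient!r} timepoint {timepoint}")


def compute_ppi(
    matrix: ProteinQuantMatrix,
    sig: SignatureSet,
    patient: str,
    timepoint: int,
    sheet: Iterable[SampleRecord] | None = None,
) -> PPiRecord:
    """Sum raw LFQ intensities of signature proteins at one timepoint.

    Per-pathway sums count a shared protein in every pathway that lists it;
    the total sums the deduplicated union once.  Missing intensities count
    as 0.  Works on raw or replicate-averaged matrices.
    """
    if matrix.stage not in ("raw", "replicate-averaged"):
        raise ValueError(
            f"PPi is defined on raw-scale intensities, not stage {matrix.stage!r}")
    sheet = list(sheet) if sheet is not None else None
    col = _column_for(matrix, sheet, patient, timepoint)
    values = matrix.values[col].fillna(0.0).to_numpy(dtype=float)
    rows_by_symbol = match_signature(matrix, sig)

    def symbol_sum(symbols: Iterable[str]) -> float:
        rows: set[int] = set()
        for s in symbols:
            rows.update(rows_by_symbol.get(s.upper(), ()))
        return float(values[sorted(rows)].sum()) if rows else 0.0

    per_pathway = {p.pathway_id: symbol_sum(p.members) for p in sig}
    union = sig.union()
    n_matched = sum(1 for s in union if s.upper() in rows_by_symbol)
    if n_matched == 0:
        raise ValueError("no signature protein matched the matrix gene names")
    return PPiRecord(patient, timepoint, per_pathway, symbol_sum(union), n_matched)


def compute_dppi(current: PPiRecord, baseline: PPiRecord) -> DPPiRecord:
    """Relative change of PPi against the t1 baseline (Table-2 convention)."""
    if baseline.timepoint_index != 1:
        raise ValueError("baseline must be timepoint 1")
    if current.patient_id != baseline.patient_id:
        raise ValueError("baseline and current belong to different patients")
    if baseline.total_sum <= 0:
        raise ZeroDivisionError(
            f"{baseline.patient_id}: baseline PPi is 0; dPPi undefined")
    d = (current.total_sum - baseline.total_sum) / baseline.total_sum
    per_pathway: dict[str, float | None] = {}
    for pid, cur in current.per_pathway_sum.items():
        base = baseline.per_pathway_sum.get(pid, 0.0)
        per_pathway[pid] = (cur - base) / base if base > 0 else None
    return DPPiRecord(current.patient_id, current.timepoint_index,
                      d, _round_half_away(100.0 * d), per_pathway)


def dppi_trajectory(
    matrix: ProteinQuantMatrix,
    sheet: Iterable[SampleRecord],
    sig: SignatureSet,
    patient: str,
    alert_cfg: AlertConfig = AlertConfig(),
) -> list[DPPiRecord]:
    """One dPPi record per timepoint >= 2, each referenced to timepoint 1."""
    sheet = list(sheet)
    tps = sorted({r.timepoint_index for r in sheet if r.patient_id == patient})
    if not tps:
        raise KeyError(f"unknown patient {patient!r}")
    if 1 not in tps:
        raise ValueError(f"patient {patient!r} has no timepoint-1 baseline")
    baseline = compute_ppi(matrix, sig, patient, 1, sheet)
    out = []
    for tp in tps:
        if tp == 1:
            continue
        rec = compute_dppi(compute_ppi(matrix, sig, patient, tp, sheet), baseline)
        out.append(DPPiRecord(
            rec.patient_id, rec.timepoint_index, rec.dppi_total,
            rec.dppi_percent, rec.per_pathway_dppi,
            alert=alert_decision(rec, alert_cfg)))
    return out


def alert_decision(rec: DPPiRecord, cfg: AlertConfig = AlertConfig()) -> bool:
    return rec.dppi_percent >= cfg.threshold


def load_followup_table() -> pd.DataFrame:
    """The bundled 16-row clinical follow-up table (six monitored patients).

    Columns: patient, timepoint, dppi_percent, recommended_intervention,
    procedure, outcome, intervention_true.  Note: the narrative for patient 1
    timepoint 2 quotes +35% while the table prints 20; the printed table
    value is bundled and the discrepancy documented, not reconciled.
    """
    with resources.as_file(
        resources.files("dppi.data").joinpath("followup_table.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t")


def build_report(
    records: Iterable[DPPiRecord] | pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    cfg: AlertConfig = AlertConfig(),
) -> MonitoringReport:
    """Follow-up-table-shaped report with recommendation concordance.

    ``records`` is either a list of DPPiRecord or a DataFrame with columns
    patient, timepoint, dppi_percent (e.g. the bundled clinical table).  When
    recorded recommendations (column recommended_intervention, Yes/No) are
    available, the concordance fraction between our alert and the recorded
    recommendation is computed.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([{
            "patient": r.patient_id, "timepoint": r.timepoint_index,
            "dppi_percent": r.dppi_percent,
        } for r in records])
    if df.empty:
        return MonitoringReport(df, None)
    df["alert"] = np.where(df["dppi_percent"] >= cfg.threshold, "Yes", "No")
    if clinical is not None:
        df = df.merge(clinical, on=["patient", "timepoint"], how="left")
    if "recommended_intervention" in df.columns:
        rec = df["recommended_intervention"].astype(str).str.strip().str.capitalize()
        df["concordant"] = np.where(df["alert"] == rec, "Yes", "No")
        concordance = float((df["concordant"] == "Yes").mean())
    else:
        concordance = None
    return MonitoringReport(df, concordance)
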