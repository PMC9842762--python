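"""Readers/writers for quantification matrices, sample sheets and gene sets.

The central container is :class:`ProteinQuantMatrix`, a thin dataclass around
a pandas DataFrame of label-free quantification (LFQ) intensities, proteins in
rows and samples in columns, with ``NaN`` as the single missing marker.  A raw
LFQ intensity of exactly 0 means "not detected" (MaxQuant's convention) and is
stored as missing on read, so that downstream left-censored imputation and
the raw-scale pathway sums both see a consistent picture.

The seven-pathway cancer-hallmark signature used for longitudinal monitoring
is bundled as a versioned GMT file so results cannot drift with ontology
releases; :func:`load_builtin_signature` returns it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ProteinQuantMatrix",
    "SampleRecord",
    "Pathway",
    "SignatureSet",
    "read_quant_matrix",
    "write_quant_matrix",
    "read_sample_sheet",
    "load_builtin_signature",
    "read_gmt",
    "write_gmt",
]

STAGES = ("raw", "log2", "imputed", "replicate-averaged")


class FormatError(ValueError):
    """A malformed input file (missing column, bad cell, short GMT line)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinQuantMatrix:
    """Proteins x samples intensity matrix with explicit missingness.

    Parameters
    ----------
    protein_ids
        Accession strings; semicolon-joined protein groups allowed.
    gene_names
        Gene symbols aligned with ``protein_ids``; may be semicolon-joined.
    values
        DataFrame (proteins x samples) of intensities, ``NaN`` = missing.
    stage
        Processing state: raw | log2 | imputed | replicate-averaged.
    """

    protein_ids: list[str]
    gene_names: list[str]
    values: pd.DataFrame
    stage: str = "raw"
    parse_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if len(self.gene_names) != n or self.values.shape[0] != n:
            raise ValueError(
                f"row mismatch: {n} protein ids, {len(self.gene_names)} gene "
                f"names, {self.values.shape[0]} value rows"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        sids = list(self.values.columns)
        if len(set(sids)) != len(sids):
            raise FormatError("duplicate sample columns")
        if self.stage == "raw":
            v = self.values.to_numpy(dtype=float)
            if np.nanmin(v, initial=np.inf) < 0:
                raise ValueError("raw intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, stage: str) -> "ProteinQuantMatrix":
        return replace(self, values=values, stage=stage)

    def missing_mask(self) -> np.ndarray:
        return self.values.isna().to_numpy()


@dataclass(frozen=True)
class SampleRecord:
    """One measured sample: who, when, which clinical group, which replicate."""

    sample_id: str
    patient_id: str
    timepoint_index: int
    group: str = "unknown"
    replicate_id: int = 1
    month: int | None = None

    def __post_init__(self) -> None:
        if self.timepoint_index < 1:
            raise FormatError(
                f"sample {self.sample_id}: timepoint must be >= 1 "
                f"(got {self.timepoint_index}); t1 is the baseline"
            )
        if self.replicate_id < 1:
            raise FormatError(f"sample {self.sample_id}: replicate must be >= 1")


GROUPS = ("recurrence", "no_recurrence", "unknown")


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    accession: str
    name: str
    source: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class SignatureSet:
    """An ordered collection of gene-symbol pathways (the monitoring panel)."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("pathway ids must be unique")
        for p in self.pathways:
            for m in p.members:
                if not m or m != m.upper():
                    raise ValueError(
                        f"{p.pathway_id}: member {m!r} must be non-empty upper-case"
                    )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def union(self) -> tuple[str, ...]:
        """Deduplicated union of member symbols, first-seen order."""
        seen: dict[str, None] = {}
        for p in self.pathways:
            for m in p.members:
                seen.setdefault(m, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# quantification matrices
# ---------------------------------------------------------------------------

def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        out[col] = coerced.astype(float)
    return out


def read_quant_matrix(path, dialect: str = "plain_wide") -> ProteinQuantMatrix:
    """Read a wide protein-quantification table into a raw-stage matrix.

    ``maxquant_proteingroups`` expects MaxQuant's proteinGroups.txt TSV with
    "Protein IDs", "Gene names" and "LFQ intensity <sample>" columns; rows
    flagged "+" in "Reverse" or "Potential contaminant" are dropped and
    counted in ``parse_summary``.  ``plain_wide`` expects protein and gene
    columns first, then one numeric column per sample.  Intensities of 0 and
    empty cells both become missing (NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    n_input = len(df)

    if dialect == "maxquant_proteingroups":
        for col in ("Protein IDs", "Gene names"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        lfq_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
        if not lfq_cols:
            raise FormatError(f"{path}: no 'LFQ intensity <sample>' columns")
        dropped = {"reverse": 0, "contaminant": 0}
        for flag, key in (("Reverse", "reverse"), ("Potential contaminant", "contaminant")):
            if flag in df.columns:
                hit = df[flag].fillna("") == "+"
                dropped[key] = int(hit.sum())
                df = df[~hit]
        protein_ids = df["Protein IDs"].fillna("").tolist()
        gene_names = df["Gene names"].fillna("").tolist()
        values = _check_numeric(df[lfq_cols], path)
        values.columns = [c[len("LFQ intensity "):] for c in lfq_cols]
        summary = {"n_input_rows": n_input, "n_kept_rows": len(df),
                   "n_dropped_reverse": dropped["reverse"],
                   "n_dropped_contaminant": dropped["contaminant"]}
    elif dialect == "plain_wide":
        if df.shape[1] < 3:
            raise FormatError(f"{path}: need protein, gene and >=1 sample column")
        protein_ids = df.iloc[:, 0].fillna("").tolist()
        gene_names = df.iloc[:, 1].fillna("").tolist()
        values = _check_numeric(df.iloc[:, 2:], path)
        summary = {"n_input_rows": n_input, "n_kept_rows": n_input,
                   "n_dropped_reverse": 0, "n_dropped_contaminant": 0}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(set(values.columns)) != len(values.columns):
        raise FormatError(f"{path}: duplicate sample columns")
    # 0 == not detected in LFQ output: store as missing
    values = values.mask(values == 0)
    values.index = pd.RangeIndex(len(values))
    return ProteinQuantMatrix(protein_ids, gene_names, values, "raw", summary)


def write_quant_matrix(matrix: ProteinQuantMatrix, path) -> None:
    """Write any stage as plain wide TSV (stage tagged in a header comment)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# stage={matrix.stage}\n")
        out = matrix.values.copy()
        out.insert(0, "gene", matrix.gene_names)
        out.insert(0, "protein", matrix.protein_ids)
        out.to_csv(fh, sep="\t", index=False, na_rep="")


def read_written_matrix(path) -> ProteinQuantMatrix:
    """Read back a matrix written by :func:`write_quant_matrix`."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        stage = "raw"
        if first.startswith("# stage="):
            stage = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", dtype={"protein": str, "gene": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"protein": str, "gene": str})
    values = df.iloc[:, 2:].astype(float)
    values.index = pd.RangeIndex(len(values))
    return ProteinQuantMatrix(
        df["protein"].fillna("").tolist(), df["gene"].fillna("").tolist(),
        values, stage)


def write_parse_summary(matrix: ProteinQuantMatrix, path) -> None:
    Path(path).write_text(json.dumps(matrix.parse_summary, indent=1) + "\n")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def _norm_group(raw: str) -> str:
    s = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
    if s in ("recurrence", "recurrent", "rec"):
        return "recurrence"
    if s in ("no_recurrence", "norecurrence", "nonrecurrence", "no_rec", "control"):
        return "no_recurrence"
    return "unknown"


def read_sample_sheet(path) -> list[SampleRecord]:
    """Read a sample sheet (TSV or CSV) mapping samples to patients/timepoints.

    Requires headers sample_id, patient_id, timepoint, group, replicate;
    month is optional.  Unknown group strings map to "unknown"; duplicate
    (patient, timepoint, replicate) triples are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ("sample_id", "patient_id", "timepoint", "group", "replicate")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records = []
    for _, row in df.iterrows():
        records.append(SampleRecord(
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            timepoint_index=int(row["timepoint"]),
            group=_norm_group(row["group"]),
            replicate_id=int(row["replicate"]),
            month=int(row["month"]) if "month" in df.columns and pd.notna(row.get("month")) else None,
        ))
    validate_sheet(records)
    return records


def validate_sheet(records: Iterable[SampleRecord]) -> None:
    seen: set[tuple] = set()
    for r in records:
        key = (r.patient_id, r.timepoint_index, r.replicate_id)
        if key in seen:
            raise FormatError(f"duplicate (patient, timepoint, replicate): {key}")
        seen.add(key)


def sheet_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "patient_id": r.patient_id,
        "timepoint": r.timepoint_index, "group": r.group,
        "replicate": r.replicate_id, "month": r.month,
    } for r in records])


def write_sample_sheet(records: Iterable[SampleRecord], path) -> None:
    sheet_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def _parse_description(desc: str) -> tuple[str, str, str]:
    parts = desc.split("|")
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    return "", desc, ""


def read_gmt(path) -> SignatureSet:
    """Read a GMT gene-set file (name, description, members per line)."""
    path = Path(path)
    pathways = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            accession, name, source = _parse_description(fields[1])
            members = tuple(m.strip().upper() for m in fields[2:] if m.strip())
            pathways.append(Pathway(fields[0], accession, name, source, members))
    return SignatureSet(tuple(pathways))


def write_gmt(sig: SignatureSet, path) -> None:
    with Path(path).open("w") as fh:
        for p in sig.pathways:
            desc = f"{p.accession}|{p.name}|{p.source}"
            fh.write("\t".join([p.pathway_id, desc, *p.members]) + "\n")


def load_builtin_signature() -> SignatureSet:
    """The bundled seven-pathway cancer-hallmark urine signature (P1-P7)."""
    with resources.as_file(
        resources.files("dppi.data").joinpath("hallmark_signature.gmt")
    ) as p:
        return read_gmt(p)
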