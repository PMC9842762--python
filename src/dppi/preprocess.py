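"""Matrix conditioning: replicate averaging, log2, valid-value filter, imputation.

Mirrors the standard Perseus workflow for label-free data: average technical
replicates on the raw intensity scale, log2-transform, keep proteins with at
least a minimum fraction of valid values in at least one clinical group, then
replace left-censored missing values with draws from a down-shifted, narrowed
per-column Gaussian (width 0.5, downshift 1.8 column-SD units by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantMatrix, SampleRecord

__all__ = [
    "FilterConfig",
    "ImputeConfig",
    "average_technical_replicates",
    "log2_transform",
    "filter_min_valid",
    "impute_gaussian_downshift",
]


@dataclass(frozen=True)
class FilterConfig:
    """Minimum fraction of valid (non-missing) values required in >=1 group."""

    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ImputeConfig:
    """Gaussian downshift imputation parameters (Perseus convention).

    width scales the column SD of the imputation distribution; downshift
    moves its mean below the observed column mean, in column-SD units.
    """

    width: float = 0.5
    downshift: float = 1.8
    per_column: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


def average_technical_replicates(
    matrix: ProteinQuantMatrix, sheet: Iterable[SampleRecord]
) -> ProteinQuantMatrix:
    """Collapse technical replicates to one column per (patient, timepoint).

    Averages on the raw intensity scale; a cell is the mean of the observed
    replicate values, or missing when all replicates are missing.
    """
    by_sample = {r.sample_id: r for r in sheet}
    missing = [s for s in matrix.sample_ids if s not in by_sample]
    if missing:
        raise ValueError(f"samples absent from sheet: {missing}")
    groups: dict[tuple, list[str]] = {}
    for s in matrix.sample_ids:
        r = by_sample[s]
        groups.setdefault((r.patient_id, r.timepoint_index), []).append(s)
    cols = {}
    for (pat, tp), samples in groups.items():
        cols[f"{pat}_t{tp}"] = matrix.values[samples].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols)
    return matrix.with_values(out, "replicate-averaged")


def log2_transform(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    if matrix.stage not in ("raw", "replicate-averaged"):
        raise ValueError(f"cannot log2-transform stage {matrix.stage!r}")
    v = matrix.values.to_numpy(dtype=float)
    if np.nanmin(v, initial=np.inf) <= 0:
        raise ValueError(
            "non-positive intensity present; zeros must be coded as missing")
    return matrix.with_values(np.log2(matrix.values), "log2")


def filter_min_valid(
    matrix: ProteinQuantMatrix,
    sheet: Iterable[SampleRecord],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[ProteinQuantMatrix, pd.DataFrame]:
    """Keep proteins with >= min_valid_fraction observed in at least one group.

    The boundary is inclusive: exactly 50% valid in a group keeps the row at
    the default threshold.  Returns the filtered matrix and a kept/dropped
    report with per-group valid fractions.
    """
    by_sample = {r.sample_id: r for r in sheet}
    group_cols: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        if s in by_sample:
            group_cols.setdefault(by_sample[s].group, []).append(s)
    group_cols = {g: c for g, c in group_cols.items() if g != "unknown"}
    if not group_cols:
        raise ValueError("no grouped columns to filter on")
    for g, c in group_cols.items():
        if not c:
            raise ValueError(f"empty group {g!r}")

    fractions = pd.DataFrame({
        g: matrix.values[c].notna().sum(axis=1) / len(c)
        for g, c in group_cols.items()
    })
    keep = (fractions >= cfg.min_valid_fraction).any(axis=1)
    report = fractions.copy()
    report.insert(0, "gene", matrix.gene_names)
    report.insert(0, "protein", matrix.protein_ids)
    report["kept"] = keep.to_numpy()

    idx = np.flatnonzero(keep.to_numpy())
    out = ProteinQuantMatrix(
        [matrix.protein_ids[i] for i in idx],
        [matrix.gene_names[i] for i in idx],
        matrix.values.iloc[idx].reset_index(drop=True),
        matrix.stage,
        dict(matrix.parse_summary, n_filtered_out=int((~keep).sum())),
    )
    return out, report


def impute_gaussian_downshift(
    matrix: ProteinQuantMatrix, cfg: ImputeConfig = ImputeConfig()
) -> ProteinQuantMatrix:
    """Replace missing log2 values with Normal(m - downshift*s, (width*s)^2).

    m and s are each column's observed mean and SD (whole-matrix when
    per_column=False).  Observed cells are untouched; the draw is
    deterministic given cfg.seed.
    """
    if matrix.stage != "log2":
        raise ValueError("impute on log2-transformed data")
    rng = np.random.default_rng(cfg.seed)
    v = matrix.values.to_numpy(dtype=float).copy()
    mask = np.isnan(v)

    if cfg.per_column:
        for j, col in enumerate(matrix.sample_ids):
            obs = v[~mask[:, j], j]
            n_miss = int(mask[:, j].sum())
            if n_miss == 0:
                continue
            if obs.size < 2:
                raise ValueError(
                    f"column {col!r}: need >=2 observed values to impute")
            m, s = obs.mean(), obs.std(ddof=1)
            v[mask[:, j], j] = rng.normal(m - cfg.downshift * s, cfg.width * s, n_miss)
    else:
        obs = v[~mask]
        if mask.any():
            if obs.size < 2:
                raise ValueError("need >=2 observed values to impute")
            m, s = obs.mean(), obs.std(ddof=1)
            v[mask] = rng.normal(m - cfg.downshift * s, cfg.width * s, int(mask.sum()))

    out = pd.DataFrame(v, columns=matrix.sample_ids)
    return matrix.with_values(out, "imputed")
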