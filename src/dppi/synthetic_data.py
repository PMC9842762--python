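"""Synthetic LFQ cohorts and longitudinal disease courses with known truth.

The generative model is the minimal one under which the downstream pipeline's
assumptions hold: protein log2 intensities are Gaussian around a per-protein
baseline (log-normal raw intensities), a group effect shifts the signature
proteins in the recurrence arm, technical replicates add independent noise,
and cells drop out missing-not-at-random via a logistic curve decreasing in
the underlying log2 value (low-abundance proteins vanish first, the regime
Gaussian-downshift imputation targets).

Longitudinal courses multiply the signature proteins' raw intensities by an
event-driven disease multiplier, so the true dPPi at each timepoint is
analytically multiplier - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantMatrix, SampleRecord, load_builtin_signature

__all__ = [
    "CohortSimConfig",
    "CourseEvent",
    "SimTruth",
    "simulate_cohort",
    "simulate_patient_course",
    "apply_mnar_missingness",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Two-arm cross-sectional design: 13 recurrence vs 17 no-recurrence
    patients, two technical replicates each, 400 proteins."""

    n_recurrence: int = 13
    n_no_recurrence: int = 17
    n_proteins: int = 400
    n_replicates: int = 2
    log2_mean_range: tuple[float, float] = (20.0, 32.0)
    protein_sd: float = 0.5
    tech_sd: float = 0.2
    effect_proteins: tuple[str, ...] | None = None  # None = signature union
    effect_log2fc: float = 1.0
    mnar_midpoint: float = 22.0
    mnar_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_recurrence, self.n_no_recurrence, self.n_proteins,
               self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if self.protein_sd < 0 or self.tech_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class CourseEvent:
    """A clinical event and the disease multiplier it imposes from its month
    onward (e.g. recurrence 2.0, post-resection 0.3)."""

    month: int
    kind: str  # onset | TURBT | recurrence | cystectomy | none
    disease_multiplier: float

    def __post_init__(self) -> None:
        if self.disease_multiplier <= 0:
            raise ValueError("disease multiplier must be > 0")


@dataclass
class SimTruth:
    effect_rows: np.ndarray                      # row indices of planted effects
    effect_log2fc: float
    true_dppi: dict[tuple[str, int], float] = field(default_factory=dict)
    missing_mask: np.ndarray | None = None
    multipliers: dict[int, float] = field(default_factory=dict)


def _gene_universe(n_proteins: int, effect_proteins: tuple[str, ...] | None):
    sig_union = list(load_builtin_signature().union())
    if effect_proteins is None:
        effect_proteins = tuple(sig_union)
    symbols = list(sig_union)
    i = 1
    while len(symbols) < n_proteins:
        s = f"GENE{i:04d}"
        if s not in symbols:
            symbols.append(s)
        i += 1
    symbols = symbols[:n_proteins]
    missing = set(effect_proteins) - set(symbols)
    if missing:
        raise ValueError(f"effect proteins not in generated universe: {sorted(missing)}")
    return symbols, effect_proteins


def apply_mnar_missingness(
    matrix: ProteinQuantMatrix, midpoint: float, slope: float, seed: int = 0
) -> tuple[ProteinQuantMatrix, np.ndarray]:
    """Censor cells MNAR: P(missing | log2 v) = 1 / (1 + exp(slope*(v - midpoint))).

    Monotone decreasing in v; slope 0 gives a flat 50% dropout.  Returns the
    censored matrix (NaN where dropped) and the boolean missingness mask.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    rng = np.random.default_rng(seed)
    raw = matrix.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        v = np.log2(np.where(raw > 0, raw, np.nan))
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(slope * (v - midpoint)))
    p_miss = np.where(np.isnan(p_miss), 1.0, p_miss)
    mask = rng.random(raw.shape) < p_miss
    out = matrix.values.mask(pd.DataFrame(mask, columns=matrix.sample_ids,
                                          index=matrix.values.index))
    return matrix.with_values(out, matrix.stage), mask


def simulate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(),
) -> tuple[ProteinQuantMatrix, list[SampleRecord], SimTruth]:
    """Simulate the two-group cross-sectional cohort with MNAR dropout."""
    rng = np.random.default_rng(cfg.seed)
    symbols, effect_proteins = _gene_universe(cfg.n_proteins, cfg.effect_proteins)
    effect_rows = np.array([i for i, s in enumerate(symbols) if s in set(effect_proteins)])

    lo, hi = cfg.log2_mean_range
    mu = rng.uniform(lo, hi, cfg.n_proteins)

    records: list[SampleRecord] = []
    cols: dict[str, np.ndarray] = {}
    for group, n_pat, prefix in (("recurrence", cfg.n_recurrence, "R"),
                                 ("no_recurrence", cfg.n_no_recurrence, "N")):
        for p in range(1, n_pat + 1):
            pid = f"{prefix}{p:02d}"
            bio = rng.normal(mu, cfg.protein_sd)
            if group == "recurrence":
                bio = bio.copy()
                bio[effect_rows] += cfg.effect_log2fc
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{pid}_t1_r{rep}"
                log2v = bio + rng.normal(0.0, cfg.tech_sd, cfg.n_proteins)
                cols[sid] = np.exp2(log2v)
                records.append(SampleRecord(sid, pid, 1, group, rep))

    values = pd.DataFrame(cols)
    matrix = ProteinQuantMatrix(list(symbols), list(symbols), values, "raw")
    matrix, mask = apply_mnar_missingness(
        matrix, cfg.mnar_midpoint, cfg.mnar_slope,
        seed=int(rng.integers(2**31)))
    truth = SimTruth(effect_rows, cfg.effect_log2fc, missing_mask=mask)
    return matrix, records, truth


def simulate_patient_course(
    cfg: CohortSimConfig,
    events: Sequence[CourseEvent],
    n_timepoints: int,
    patient_id: str = "PT1",
    mnar: bool = False,
) -> tuple[ProteinQuantMatrix, list[SampleRecord], SimTruth]:
    """Simulate one patient's longitudinal course.

    Timepoints are placed at the event months (the first event must be onset
    with multiplier 1); signature proteins' expected raw intensities scale
    with the multiplier in force at each timepoint, other proteins are
    stationary.  True dPPi at timepoint t is multiplier(t) - 1 in the
    no-noise, no-missingness limit.
    """
    if not events or events[0].kind != "onset" or events[0].disease_multiplier != 1.0:
        raise ValueError("first event must be onset with multiplier 1")
    months = [e.month for e in events]
    if any(b < a for a, b in zip(months, months[1:])):
        raise ValueError("event months must be non-decreasing")
    if n_timepoints > len(events):
        raise ValueError("need one event per timepoint")

    rng = np.random.default_rng(cfg.seed)
    symbols, effect_proteins = _gene_universe(cfg.n_proteins, cfg.effect_proteins)
    sig_rows = np.array([i for i, s in enumerate(symbols) if s in set(effect_proteins)])

    lo, hi = cfg.log2_mean_range
    mu = rng.uniform(lo, hi, cfg.n_proteins)
    bio = rng.normal(mu, cfg.protein_sd)     # the patient's personal baseline
    base_raw = np.exp2(bio)

    records: list[SampleRecord] = []
    cols: dict[str, np.ndarray] = {}
    truth = SimTruth(sig_rows, 0.0)
    for t in range(1, n_timepoints + 1):
        m = events[t - 1].disease_multiplier
        expected = base_raw.copy()
        expected[sig_rows] *= m
        truth.multipliers[t] = m
        truth.true_dppi[(patient_id, t)] = m - 1.0
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{patient_id}_t{t}_r{rep}"
            noise = rng.normal(0.0, cfg.tech_sd, cfg.n_proteins) if cfg.tech_sd > 0 \
                else np.zeros(cfg.n_proteins)
            cols[sid] = expected * np.exp2(noise)
            records.append(SampleRecord(sid, patient_id, t, "unknown", rep,
                                        month=events[t - 1].month))
    truth.true_dppi[(patient_id, 1)] = 0.0

    values = pd.DataFrame(cols)
    matrix = ProteinQuantMatrix(list(symbols), list(symbols), values, "raw")
    if mnar:
        matrix, mask = apply_mnar_missingness(
            matrix, cfg.mnar_midpoint, cfg.mnar_slope,
            seed=int(rng.integers(2**31)))
        truth.missing_mask = mask
    return matrix, records, truth
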