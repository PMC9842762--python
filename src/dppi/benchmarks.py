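"""Self-contained evaluation routines for the pipeline's headline claims.

Each function runs the relevant part of the pipeline from scratch on bundled
or simulated inputs and returns the measured quantity: clinical-table alert
concordance, closed-form dPPi identities on noise-free courses, null
calibration and planted-effect recovery of the permutation-FDR test, dPPi
recovery error under replicate noise, and the moments of the downshift
imputation distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import differential, pathway_monitor, pipeline, preprocess, synthetic_data
from .io_formats import load_builtin_signature
from .pathway_monitor import AlertConfig
from .preprocess import ImputeConfig
from .synthetic_data import CohortSimConfig, CourseEvent

__all__ = [
    "followup_concordance",
    "closed_form_course_check",
    "null_significant_fraction",
    "planted_recovery",
    "dppi_recovery_mae",
    "imputation_moments",
]


def followup_concordance(threshold: float = -5.0) -> tuple[float, int]:
    """Alert vs recorded recommendation over the bundled 16-row follow-up table.

    Returns (concordance fraction, number of rows)."""
    table = pathway_monitor.load_followup_table()
    report = pathway_monitor.build_report(table, cfg=AlertConfig(threshold))
    return float(report.concordance), len(table)


def closed_form_course_check(seed: int = 0) -> dict[str, float]:
    """Noise-free longitudinal identities of the dPPi definition.

    Multiplying every signature protein by m at time t must give
    dppi_total = m - 1 exactly; the baseline index is 0; rescaling all
    intensities globally changes nothing.  Returns the maximum absolute
    deviations observed.
    """
    sig = load_builtin_signature()
    multipliers = (1.0, 2.0, 0.3, 1.7)
    events = [CourseEvent(3 * i, "onset" if i == 0 else "none", m)
              for i, m in enumerate(multipliers)]
    cfg = CohortSimConfig(tech_sd=0.0, seed=seed)
    matrix, sheet, truth = synthetic_data.simulate_patient_course(
        cfg, events, len(multipliers))
    avg = preprocess.average_technical_replicates(matrix, sheet)
    traj = pathway_monitor.dppi_trajectory(avg, sheet, sig, "PT1")
    mult_err = max(abs(r.dppi_total - (truth.multipliers[r.timepoint_index] - 1.0))
                   for r in traj)

    base = pathway_monitor.compute_ppi(avg, sig, "PT1", 1)
    baseline_err = abs(pathway_monitor.compute_dppi(base, base).dppi_total)

    scaled = avg.with_values(avg.values * 7.3, "replicate-averaged")
    traj_s = pathway_monitor.dppi_trajectory(scaled, sheet, sig, "PT1")
    scale_err = max(abs(a.dppi_total - b.dppi_total)
                    for a, b in zip(traj, traj_s))
    return {"multiplier_identity_max_err": mult_err,
            "baseline_identity_err": baseline_err,
            "scale_invariance_max_err": scale_err}


def null_significant_fraction(
    n_repeats: int = 50, n_proteins: int = 400, n_a: int = 13, n_b: int = 17,
    seed: int = 0, n_permutations: int = 250,
) -> float:
    """Mean fraction of proteins called significant under the global null.

    Both groups are drawn from the same Normal per protein, so every call is
    a false positive; the permutation-FDR rule should keep the fraction near
    or below the 5% target.
    """
    import pandas as pd
    from .io_formats import ProteinQuantMatrix, SampleRecord
    rng = np.random.default_rng(seed)
    fracs = []
    for rep in range(n_repeats):
        X = rng.normal(25.0, 1.0, (n_proteins, n_a + n_b))
        ids = [f"S{j}" for j in range(n_a + n_b)]
        sheet = [SampleRecord(ids[j], f"P{j}", 1,
                              "recurrence" if j < n_a else "no_recurrence", 1)
                 for j in range(n_a + n_b)]
        mat = ProteinQuantMatrix(
            [f"P{i}" for i in range(n_proteins)],
            [f"G{i}" for i in range(n_proteins)],
            pd.DataFrame(X, columns=ids), "imputed")
        res = differential.permutation_fdr(
            mat, sheet,
            differential.DiffTestConfig(seed=int(rng.integers(2**31)),
                                        n_permutations=n_permutations))
        fracs.append(float(res["significant"].mean()))
    return float(np.mean(fracs))


def planted_recovery(
    n_seeds: int = 20, effect_log2fc: float = 2.0, base_seed: int = 0,
) -> tuple[float, float]:
    """Full-pipeline recovery of planted group effects.

    Simulates the two-arm cohort design (13 vs 17 patients, two technical
    replicates), runs replicate averaging, log2, 50% valid-value filtering,
    downshift imputation and the permutation-FDR test, and returns
    (mean sensitivity over planted proteins, mean observed FDR) over seeds.
    """
    sens, fdrs = [], []
    for k in range(n_seeds):
        sim_cfg = CohortSimConfig(effect_log2fc=effect_log2fc,
                                  seed=base_seed + 1000 + k)
        matrix, sheet, truth = synthetic_data.simulate_cohort(sim_cfg)
        planted_genes = {matrix.gene_names[i] for i in truth.effect_rows}
        cfg = pipeline.PipelineConfig(seed=base_seed + 2000 + k)
        imputed, avg_sheet, _ = pipeline.preprocess_for_test(matrix, sheet, cfg)
        res = differential.permutation_fdr(
            imputed, avg_sheet,
            differential.DiffTestConfig(seed=base_seed + 3000 + k))
        called = res.loc[res["significant"], "gene"]
        tp = called.isin(planted_genes).sum()
        fp = len(called) - tp
        sens.append(tp / len(planted_genes))
        fdrs.append(fp / max(1, len(called)))
    return float(np.mean(sens)), float(np.mean(fdrs))


def dppi_recovery_mae(
    n_patients: int = 200, tech_sd: float = 0.2, base_seed: int = 0,
) -> float:
    """Mean absolute error of recovered dppi_total vs simulated truth."""
    sig = load_builtin_signature()
    events = [CourseEvent(0, "onset", 1.0), CourseEvent(2, "recurrence", 2.0),
              CourseEvent(18, "cystectomy", 0.3)]
    errs = []
    for k in range(n_patients):
        cfg = CohortSimConfig(tech_sd=tech_sd, seed=base_seed + 5000 + k)
        matrix, sheet, truth = synthetic_data.simulate_patient_course(cfg, events, 3)
        avg = preprocess.average_technical_replicates(matrix, sheet)
        for r in pathway_monitor.dppi_trajectory(avg, sheet, sig, "PT1"):
            errs.append(abs(r.dppi_total - truth.true_dppi[("PT1", r.timepoint_index)]))
    return float(np.mean(errs))


def imputation_moments(
    n_missing: int = 10_000, m: float = 25.0, s: float = 2.0, seed: int = 0,
) -> dict[str, float]:
    """Moments of imputed draws for a column with observed mean m and SD s.

    Returns the imputed mean and SD and their deviation from the nominal
    Normal(m - 1.8 s, (0.5 s)^2), plus whether observed cells were altered.
    """
    import pandas as pd
    from .io_formats import ProteinQuantMatrix
    rng = np.random.default_rng(seed)
    n_obs = 2000
    obs = rng.normal(m, s, n_obs)
    obs = (obs - obs.mean()) / obs.std(ddof=1) * s + m   # exact sample moments
    col = np.concatenate([obs, np.full(n_missing, np.nan)])
    mat = ProteinQuantMatrix(
        [f"P{i}" for i in range(col.size)], [f"G{i}" for i in range(col.size)],
        pd.DataFrame({"S1": col}), "log2")
    out = preprocess.impute_gaussian_downshift(mat, ImputeConfig(seed=seed + 1))
    imputed = out.values.to_numpy()[n_obs:, 0]
    observed_changed = not np.array_equal(obs, out.values.to_numpy()[:n_obs, 0])
    return {
        "imputed_mean": float(imputed.mean()),
        "imputed_sd": float(imputed.std(ddof=1)),
        "mean_abs_err": float(abs(imputed.mean() - (m - 1.8 * s))),
        "sd_abs_err": float(abs(imputed.std(ddof=1) - 0.5 * s)),
        "observed_changed": float(observed_changed),
    }
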