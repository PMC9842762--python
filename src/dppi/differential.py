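"""S0-moderated two-sample testing with permutation FDR, plus clustering.

The test statistic is the SAM-style moderated t: the difference of group
means divided by the pooled-variance standard error inflated by an additive
fudge constant S0, which damps the significance of proteins whose variance
is accidentally tiny.  Significance is declared by a permutation estimate of
the false discovery rate: group labels are permuted, the null distribution
of |d| is accumulated, and the smallest cutoff on observed |d| with
estimated FDR below the target marks the significant set (pi0 is fixed at 1,
conservative).

Column clustering (average linkage, Euclidean) is delegated to scipy and
exported as Newick.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_formats import ProteinQuantMatrix, SampleRecord

__all__ = [
    "DiffTestConfig",
    "moderated_t",
    "moderated_t_matrix",
    "permutation_fdr",
    "volcano_table",
    "hierarchical_cluster",
    "ClusterResult",
]

EXHAUSTIVE_AUTO_LIMIT = 10_000


@dataclass(frozen=True)
class DiffTestConfig:
    s0: float = 0.1
    fdr: float = 0.05
    n_permutations: int = 250
    seed: int = 0
    exhaustive: bool | None = None  # None = auto when feasible

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def moderated_t_matrix(
    a: np.ndarray, b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised moderated t over protein rows.

    a, b: (proteins x n_a), (proteins x n_b) arrays of log2 intensities.
    Returns (d_moderated, t_classic, p_value); p is the two-tailed classic-t
    p-value with n_a + n_b - 2 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    den = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, diff / np.where(den > 0, den, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = np.where(np.isinf(t), 0.0,
                 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2))
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return d, t, p


def moderated_t(
    values_a: Iterable[float], values_b: Iterable[float], s0: float = 0.1
) -> tuple[float, float, float]:
    """Moderated t for one protein; see :func:`moderated_t_matrix`."""
    a = np.atleast_2d(np.asarray(list(values_a), dtype=float))
    b = np.atleast_2d(np.asarray(list(values_b), dtype=float))
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    d, t, p = moderated_t_matrix(a, b, s0)
    return float(d[0]), float(t[0]), float(p[0])


def _group_columns(
    matrix: ProteinQuantMatrix, sheet: Iterable[SampleRecord]
) -> tuple[list[str], list[str], tuple[str, str]]:
    by_sample = {r.sample_id: r for r in sheet}
    grouped: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        if s in by_sample and by_sample[s].group != "unknown":
            grouped.setdefault(by_sample[s].group, []).append(s)
    if len(grouped) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(grouped)}")
    # case group first: log2_fc is recurrence minus no_recurrence
    if "recurrence" in grouped:
        ga = "recurrence"
        gb = next(g for g in grouped if g != ga)
    else:
        ga, gb = sorted(grouped)
    return grouped[ga], grouped[gb], (ga, gb)


def _fdr_curve(abs_d: np.ndarray, perm_abs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ratio-of-counts FDR estimate at each observed |d| as cutoff.

    FDR(c) = mean over permutations of #{|d*| >= c} / max(1, #{|d| >= c}).
    """
    cutoffs = np.sort(np.unique(abs_d))
    obs_sorted = np.sort(abs_d)
    n_obs = abs_d.size - np.searchsorted(obs_sorted, cutoffs, side="left")
    flat = np.sort(perm_abs.ravel())
    n_null = (flat.size - np.searchsorted(flat, cutoffs, side="left")) / perm_abs.shape[0]
    fdr = n_null / np.maximum(1, n_obs)
    return cutoffs, fdr


def permutation_fdr(
    matrix: ProteinQuantMatrix,
    sheet: Iterable[SampleRecord],
    cfg: DiffTestConfig = DiffTestConfig(),
) -> pd.DataFrame:
    """Two-group moderated-t test with permutation-based FDR control.

    Returns one row per protein: means, log2_fc, d_moderated, t_classic,
    p_value, significant, direction.  With exhaustive=True (or auto when the
    number of distinct relabelings is <= 10,000) all label assignments are
    enumerated and the result is seed-independent.
    """
    if matrix.missing_mask().any():
        raise ValueError("matrix has missing values; impute first")
    sheet = list(sheet)
    cols_a, cols_b, _ = _group_columns(matrix, sheet)
    na, nb = len(cols_a), len(cols_b)
    X = matrix.values[cols_a + cols_b].to_numpy(dtype=float)
    n = na + nb

    d, t, p = moderated_t_matrix(X[:, :na], X[:, na:], cfg.s0)
    abs_d = np.abs(d)

    n_distinct = math.comb(n, na)
    exhaustive = cfg.exhaustive
    if exhaustive is None:
        exhaustive = n_distinct <= EXHAUSTIVE_AUTO_LIMIT
    if not exhaustive and n_distinct < 10:
        warnings.warn(
            f"only {n_distinct} distinct relabelings; exhaustive mode recommended",
            stacklevel=2,
        )

    if exhaustive:
        assignments = [np.array(c) for c in itertools.combinations(range(n), na)]
    else:
        rng = np.random.default_rng(cfg.seed)
        assignments = [rng.permutation(n)[:na] for _ in range(cfg.n_permutations)]

    perm_abs = np.empty((len(assignments), X.shape[0]))
    all_idx = np.arange(n)
    for k, ia in enumerate(assignments):
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        dk, _, _ = moderated_t_matrix(X[:, ia], X[:, ib], cfg.s0)
        perm_abs[k] = np.abs(dk)

    cutoffs, fdr_hat = _fdr_curve(abs_d, perm_abs)
    ok = cutoffs[fdr_hat <= cfg.fdr]
    if ok.size:
        c_star = ok.min()
        significant = abs_d >= c_star
    else:
        significant = np.zeros_like(abs_d, dtype=bool)

    mean_a = X[:, :na].mean(axis=1)
    mean_b = X[:, na:].mean(axis=1)
    log2_fc = mean_a - mean_b
    direction = np.where(~significant, "ns", np.where(log2_fc > 0, "up", "down"))
    return pd.DataFrame({
        "protein": matrix.protein_ids,
        "gene": matrix.gene_names,
        "mean_a": mean_a, "mean_b": mean_b, "log2_fc": log2_fc,
        "t_classic": t, "d_moderated": d, "p_value": p,
        "significant": significant, "direction": direction,
    })


def volcano_table(diff: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Volcano export: gene, log2_fc, -log10 p, class; plus class counts."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(diff["p_value"].to_numpy())
    table = pd.DataFrame({
        "gene": diff["gene"],
        "log2_fc": diff["log2_fc"],
        "neg_log10_p": neglog,
        "class": diff["direction"],
    })
    counts = {c: int((table["class"] == c).sum()) for c in ("up", "down", "ns")}
    return table, counts


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix over columns
    labels: list[str]            # column ids in input order
    leaf_order: list[str]        # dendrogram leaf order

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            bl = node.dist / 2.0
            return f"({left}:{bl:g},{right}:{bl:g})"

        return walk(tree) + ";"

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def hierarchical_cluster(
    matrix: ProteinQuantMatrix,
    z_score_rows: bool = False,
    kmeans_preprocess: bool = False,
    n_kmeans_clusters: int = 300,
    seed: int = 0,
) -> ClusterResult:
    """Average-linkage Euclidean clustering of sample columns.

    Rows may be z-scored first.  kmeans_preprocess optionally collapses rows
    to k-means centroids before clustering columns (a speed heuristic; off by
    default, it does not change results at this data scale).
    """
    if matrix.missing_mask().any():
        raise ValueError("matrix has missing values; impute before clustering")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    X = matrix.values.to_numpy(dtype=float)
    if z_score_rows:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if kmeans_preprocess and X.shape[0] > n_kmeans_clusters:
        from scipy.cluster.vq import kmeans2
        centroids, _ = kmeans2(X, n_kmeans_clusters, seed=seed, minit="++")
        X = centroids
    Z = hierarchy.linkage(X.T, method="average", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    labels = matrix.sample_ids
    return ClusterResult(Z, labels, [labels[i] for i in order])
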