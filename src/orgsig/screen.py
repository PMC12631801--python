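"""The organelle-signature statistical screen.

Per-metric two-sided Mann-Whitney U tests between two cell groups, with
multiplicity handled by the two-stage ("adaptive") linear step-up procedure
of Benjamini, Krieger & Yekutieli at a false discovery rate of 10%;
significance tiers follow q ≤ 0.1 (*), ≤ 0.05 (**), ≤ 0.01 (***),
≤ 0.001 (****).  Also provides log2 fold changes of group means,
standardized PCA with parallel-analysis component retention, Ward
hierarchical clustering (ward.D on Euclidean distances, as in R's hclust),
and Spearman correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core import ValidationError

_TIERS = ((0.001, "****"), (0.01, "***"), (0.05, "**"), (0.1, "*"))


# ---------------------------------------------------------------------------
# multiple testing: BKY two-stage linear step-up


def _step_up_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the BH linear step-up at `level` (denominator m)."""
    m = len(p_sorted)
    crit = np.arange(1, m + 1) * level / m
    below = np.nonzero(p_sorted <= crit)[0]
    return 0 if len(below) == 0 else int(below[-1]) + 1


def bky_reject(pvalues: np.ndarray, q: float = 0.10) -> np.ndarray:
    """Rejection decisions of the two-stage BKY procedure at FDR level ``q``.

    Stage 1 runs the linear step-up at q′ = q/(1+q), giving r₁ rejections.
    If r₁ is 0 or m the procedure stops with that decision; otherwise stage 2
    reruns the step-up at level q′·m/(m−r₁) (equivalently, BH at q′ with the
    estimate m₀ = m−r₁ of true nulls).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q1 = q / (1.0 + q)
    r1 = _step_up_count(ps, q1)
    if r1 == 0:
        k = 0
    elif r1 == m:
        k = m
    else:
        k = _step_up_count(ps, q1 * m / (m - r1))
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def bky_adjust(pvalues: np.ndarray, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Decisions at FDR ``q`` plus per-metric q-values.

    The q-value of a metric is the smallest FDR level at which the two-stage
    procedure rejects it (found by bisection; the rejection set grows with
    the level), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    reject = bky_reject(p, q)
    qvals = np.ones(len(p))
    reject_at_one = bky_reject(p, 1.0 - 1e-12)
    for i in range(len(p)):
        if not reject_at_one[i]:
            continue
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if bky_reject(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        qvals[i] = hi
    return reject, qvals


def significance_tier(qvalue: float) -> str:
    """Star notation for a q-value: ns, *, **, ***, or ****."""
    for level, stars in _TIERS:
        if qvalue <= level:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Mann-Whitney U screen


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided MWU; exact for small tie-free groups, tie-corrected normal otherwise."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mwu_screen(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = "group",
    fdr: float = 0.10,
    metric_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-metric Mann-Whitney U screen between two groups with BKY FDR control.

    Missing values are dropped pairwise per metric; metrics where either
    group then has one or fewer data points are excluded from the screen.
    Returns one row per tested metric with columns ``metric, n_A, n_B, U, p,
    q, significant, stars, mean_rank_diff, log2_fc``; the mean rank
    difference is (mean rank of A) − (mean rank of B) under joint ranking.
    """
    if not 0 < fdr < 1:
        raise ValidationError(f"FDR must be in (0, 1), got {fdr}")
    sub_a = table[table[group_col] == group_a]
    sub_b = table[table[group_col] == group_b]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValidationError(f"empty group: {group_a if len(sub_a) == 0 else group_b}")
    if metric_cols is None:
        metric_cols = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for col in metric_cols:
        a = sub_a[col].dropna().to_numpy(dtype=float)
        b = sub_b[col].dropna().to_numpy(dtype=float)
        if len(a) <= 1 or len(b) <= 1:
            continue  # insufficient data points in one comparison group
        u, p = _mwu(a, b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        mrd = float(ranks[: len(a)].mean() - ranks[len(a):].mean())
        fc = log2_fc(a, b)
        rows.append((col, len(a), len(b), u, p, mrd, fc))
    if not rows:
        raise ValidationError("no metric had at least two data points per group")
    out = pd.DataFrame(
        rows, columns=["metric", "n_A", "n_B", "U", "p", "mean_rank_diff", "log2_fc"]
    )
    reject, qvals = bky_adjust(out["p"].to_numpy(), q=fdr)
    out["q"] = qvals
    out["significant"] = reject
    out["stars"] = [significance_tier(qv) if rej else "ns"
                    for qv, rej in zip(qvals, reject)]
    return out[["metric", "n_A", "n_B", "U", "p", "q", "significant", "stars",
                "mean_rank_diff", "log2_fc"]]


def log2_fc(treated: np.ndarray, control: np.ndarray) -> float:
    """log2 of the ratio of group means; NaN unless both means are positive."""
    mt = float(np.mean(treated)) if len(treated) else float("nan")
    mc = float(np.mean(control)) if len(control) else float("nan")
    if not (mt > 0 and mc > 0):
        return float("nan")
    return float(np.log2(mt / mc))


def log2_fc_frame(
    treated: pd.DataFrame, control: pd.DataFrame, metric_cols: list[str] | None = None
) -> pd.Series:
    """Per-metric log2 fold change of group means (treated over control)."""
    if len(treated) == 0 or len(control) == 0:
        raise ValidationError("both groups need at least one row")
    if metric_cols is None:
        metric_cols = [c for c in treated.columns
                       if pd.api.types.is_numeric_dtype(treated[c])]
    return pd.Series(
        {c: log2_fc(treated[c].dropna().to_numpy(), control[c].dropna().to_numpy())
         for c in metric_cols},
        name="log2_fc",
    )


# ---------------------------------------------------------------------------
# PCA with parallel analysis


@dataclass(frozen=True)
class PCAResult:
    """Standardized PCA with parallel-analysis component retention."""

    n_retained: int
    scores: np.ndarray  # (n_cells, n_components)
    loadings: np.ndarray  # (n_components, n_kept_columns)
    explained_variance: np.ndarray  # eigenvalues
    explained_pct: np.ndarray  # percentage of variance per component
    null_thresholds: np.ndarray  # per-component percentile of null eigenvalues
    kept_columns: tuple[str, ...]
    dropped_columns: tuple[str, ...]
    seed: int


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def pca_parallel(
    table: pd.DataFrame,
    n_sim: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    metric_cols: list[str] | None = None,
) -> PCAResult:
    """Standardized PCA with parallel-analysis retention.

    Zero-variance columns are dropped and the rest z-scored to mean 0 / SD 1.
    Components are retained while the observed eigenvalue exceeds the
    ``percentile``-th percentile of the matching eigenvalue from ``n_sim``
    standard-normal matrices of identical shape (processed identically).
    """
    if metric_cols is None:
        metric_cols = [c for c in table.columns
                       if pd.api.types.is_numeric_dtype(table[c])]
    x = table[metric_cols].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 rows")
    sd = x.std(axis=0, ddof=1)
    keep = np.isfinite(sd) & (sd > 0) & np.isfinite(x).all(axis=0)
    kept = [c for c, k in zip(metric_cols, keep) if k]
    dropped = [c for c, k in zip(metric_cols, keep) if not k]
    xz = _zscore(x[:, keep])

    n, p = xz.shape
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(xz)
    eig = pca.explained_variance_

    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_sim, len(eig)))
    for i in range(n_sim):
        sim = _zscore(rng.standard_normal((n, p)))
        s = np.linalg.svd(sim, compute_uv=False)
        null_eigs[i] = (s ** 2 / (n - 1))[: len(eig)]
    thresholds = np.percentile(null_eigs, percentile, axis=0)

    n_retained = 0
    for obs, thr in zip(eig, thresholds):
        if obs > thr:
            n_retained += 1
        else:
            break
    return PCAResult(
        n_retained=n_retained,
        scores=scores,
        loadings=pca.components_,
        explained_variance=eig,
        explained_pct=100.0 * pca.explained_variance_ratio_,
        null_thresholds=thresholds,
        kept_columns=tuple(kept),
        dropped_columns=tuple(dropped),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering and correlation


def hier_cluster(
    table: pd.DataFrame, metric_cols: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of cells on the standardized metric matrix.

    Reproduces R's ``hclust(d, "ward.D")`` on Euclidean distances: the
    Lance-Williams Ward update applied to unsquared distances.  SciPy's
    ``ward`` applies the update to squared input distances, so the Euclidean
    distances are passed through a square root and the merge heights squared
    back.  Returns ``(linkage_matrix, leaf_order)``.
    """
    if metric_cols is None:
        metric_cols = [c for c in table.columns
                       if pd.api.types.is_numeric_dtype(table[c])]
    x = table[metric_cols].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    sd = x.std(axis=0, ddof=1)
    keep = np.isfinite(sd) & (sd > 0) & np.isfinite(x).all(axis=0)
    xz = _zscore(x[:, keep])
    d = pdist(xz, metric="euclidean")
    z = hierarchy.linkage(np.sqrt(d), method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2  # back to ward.D heights on unsquared distances
    return z, hierarchy.leaves_list(z)


def spearman_matrix(
    table_x: pd.DataFrame, table_y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation (and two-sided p) for every column pair."""
    if len(table_x) != len(table_y):
        raise ValidationError("tables must have the same number of rows")
    cols_x = list(table_x.columns)
    cols_y = list(table_y.columns)
    r = pd.DataFrame(index=cols_x, columns=cols_y, dtype=float)
    p = pd.DataFrame(index=cols_x, columns=cols_y, dtype=float)
    for cx in cols_x:
        for cy in cols_y:
            res = stats.spearmanr(table_x[cx], table_y[cy], nan_policy="omit")
            r.loc[cx, cy] = float(res.statistic)
            p.loc[cx, cy] = float(res.pvalue)
    return r, p


__all__ = [
    "bky_reject",
    "bky_adjust",
    "significance_tier",
    "mwu_screen",
    "log2_fc",
    "log2_fc_frame",
    "PCAResult",
    "pca_parallel",
    "hier_cluster",
    "spearman_matrix",
]
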