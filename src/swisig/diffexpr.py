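"""Count preprocessing and the empirical-Bayes differential-expression engine.

Normalization follows the weighted trimmed mean of M-values (TMM) algorithm:
per-sample scale factors from a doubly trimmed, inverse-variance-weighted mean
of gene-wise log ratios against a reference sample, rescaled to geometric mean
one.  Expression is summarised as log2 counts-per-million with a pseudo-count
of 1, and genes with log2-CPM below 1 in more than three samples are removed
before testing.

The test engine is a moderated t: per-feature linear model (group plus an
optional batch factor), residual variances shrunk toward a pooled prior via
moment matching of log variances (digamma/trigamma inversion), t on the
augmented degrees of freedom.  The same engine serves RNA log2-CPM and co-IP
protein log2 intensities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

__all__ = [
    "filter_low_expression",
    "tmm_factors",
    "log2_cpm",
    "moderated_t_test",
    "bh_fdr",
    "cluster_samples",
]


def _trigamma(x):
    return polygamma(1, x)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log2_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, pseudo: float = 1.0
) -> pd.DataFrame:
    """log2(CPM + pseudo) with TMM-effective library sizes.

    Effective library size is raw depth times the TMM factor (all ones when
    ``factors`` is None).  A zero count maps to ``log2(pseudo)``.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"degenerate sample(s) with zero library size: {bad}")
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + pseudo)


def filter_low_expression(
    counts: pd.DataFrame, min_logcpm: float = 1.0, max_fail_samples: int = 3
) -> pd.DataFrame:
    """Remove genes with log2-CPM below ``min_logcpm`` in more than
    ``max_fail_samples`` samples (raw library sizes, pseudo-count 1)."""
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    lcpm = log2_cpm(counts)
    n_fail = (lcpm < min_logcpm).sum(axis=1)
    return counts.loc[n_fail <= max_fail_samples]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        raise ValueError("no gene positive in both test and reference sample")
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial (delta-method) variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.abs(m).max() < 1e-6:  # samples identical up to depth
        return 0.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    # ordinal ranks (ties broken by gene order): keeps the trim well defined
    # even when many genes share an identical log ratio
    rank_m = np.empty(n)
    rank_m[np.argsort(m, kind="stable")] = np.arange(1, n + 1)
    rank_a = np.empty(n)
    rank_a[np.argsort(a, kind="stable")] = np.arange(1, n + 1)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean one.

    The reference is the sample whose upper quartile of count fractions is
    closest to the mean upper quartile.  Each factor is 2 to the weighted
    trimmed mean of M-values against the reference, with two-sided trims
    ``trim_m`` on M and ``trim_a`` on A and inverse-binomial-variance
    weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"degenerate sample(s) with all-zero counts: {bad}")
    frac = counts.div(lib, axis=1)
    uq = frac.quantile(0.75, axis=0)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    n_ref = lib[ref_sample]

    log_f = {}
    for s in counts.columns:
        if s == ref_sample:
            log_f[s] = 0.0
        else:
            log_f[s] = _tmm_pair(
                counts[s].to_numpy(), ref, lib[s], n_ref, trim_m, trim_a
            )
    factors = pd.Series({s: 2.0 ** v for s, v in log_f.items()})[counts.columns]
    factors /= np.exp(np.mean(np.log(factors)))
    factors.name = "tmm_factor"
    return factors


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances.

    Returns ``(d0, s0_sq)``: prior degrees of freedom (may be inf) and prior
    variance.  With a single informative feature there is nothing to shrink
    toward and ``d0 = 0`` is returned (ordinary t).
    """
    ok = np.isfinite(s2) & (df > 0) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return 0.0, float(s2[0]) if s2.size else np.nan
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(_trigamma(df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def _design_matrix(
    group_labels: Sequence, batch_labels: Sequence | None
) -> tuple[np.ndarray, list]:
    groups = pd.unique(np.asarray(group_labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    g = np.asarray([1.0 if x == groups[1] else 0.0 for x in group_labels])
    cols = [np.ones(len(g)), g]
    if batch_labels is not None:
        batches = pd.unique(np.asarray(batch_labels))
        for b in batches[1:]:
            cols.append(np.asarray([1.0 if x == b else 0.0 for x in batch_labels]))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix (group confounded with batch?)")
    return x, list(groups)


def moderated_t_test(
    matrix: pd.DataFrame,
    group_labels: Sequence,
    batch_labels: Sequence | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group test per feature.

    ``matrix`` is features × samples on a log scale; ``group_labels`` gives
    one of two labels per sample.  The reported ``log2fc`` is group2 minus
    group1 in order of first appearance.  Features with missing values are
    fit on their observed samples; a feature whose observed samples do not
    cover both groups at least twice gets NA statistics.  ``prior_df``
    forces the prior degrees of freedom (``inf`` gives the fully shrunk
    limit); by default it is estimated from the data.
    """
    x_full, groups = _design_matrix(group_labels, batch_labels)
    y = matrix.to_numpy(dtype=float)
    n_feat, n_samp = y.shape
    if x_full.shape[0] != n_samp:
        raise ValueError("label length does not match number of samples")

    coef = np.full(n_feat, np.nan)
    stdev_unscaled = np.full(n_feat, np.nan)
    s2 = np.full(n_feat, np.nan)
    df_resid = np.zeros(n_feat)
    grp = np.asarray([0 if g == groups[0] else 1 for g in group_labels])

    finite = np.isfinite(y)
    complete = finite.all(axis=1)

    def fit_rows(rows: np.ndarray, x: np.ndarray, yy: np.ndarray) -> None:
        # shared-design OLS for a block of features
        pinv = np.linalg.pinv(x)
        beta = yy @ pinv.T
        resid = yy - beta @ x.T
        dof = x.shape[0] - np.linalg.matrix_rank(x)
        xtx_inv = np.linalg.inv(x.T @ x)
        coef[rows] = beta[:, 1]
        stdev_unscaled[rows] = np.sqrt(xtx_inv[1, 1])
        if dof > 0:
            s2[rows] = (resid ** 2).sum(axis=1) / dof
        df_resid[rows] = dof

    if complete.any():
        fit_rows(np.where(complete)[0], x_full, y[complete])
    for i in np.where(~complete)[0]:
        obs = finite[i]
        if min((grp[obs] == 0).sum(), (grp[obs] == 1).sum()) < 2:
            continue  # NA statistics
        xi = x_full[obs]
        keep_cols = [j for j in range(xi.shape[1]) if j < 2 or np.ptp(xi[:, j]) > 0]
        xi = xi[:, keep_cols]
        if np.linalg.matrix_rank(xi) < xi.shape[1]:
            continue
        fit_rows(np.array([i]), xi, y[i][obs][None, :])

    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / (np.sqrt(s2_post) * stdev_unscaled)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[df_resid == 0] = np.nan
    t[df_resid == 0] = np.nan

    result = pd.DataFrame(
        {
            "log2fc": coef,
            "mean_expr": np.nanmean(y, axis=1),
            "t_stat": t,
            "p": p,
            "fdr": bh_fdr(p),
            "df": df_total,
        },
        index=matrix.index,
    )
    result.attrs["prior_df"] = d0
    result.attrs["prior_var"] = s0_sq
    result.attrs["groups"] = groups
    return result


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving).

    NaN inputs stay NaN and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_samples(
    matrix: pd.DataFrame, n_top_variable: int = 500, n_clusters: int | None = None
):
    """Ward clustering of samples on the top variable genes.

    Genes are ranked by variance across samples (ties broken by gene id,
    lexicographic) and the top ``n_top_variable`` kept; samples are clustered
    with Ward linkage on Euclidean distances.  Returns ``(linkage, labels)``
    where ``labels`` is a Series of flat cluster ids when ``n_clusters`` is
    given, else None.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    top = order[: min(n_top_variable, len(order))]
    sub = matrix.loc[top]
    link = hierarchy.ward(sub.to_numpy().T)
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
        labels = pd.Series(flat, index=matrix.columns, name="cluster")
    return link, labels
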