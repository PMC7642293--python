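"""Co-IP mass-spectrometry enrichment analysis.

Label-free branch: Top3 protein roll-up (sum of the three most intense
peptides), peptide normalization (log2 + cyclic median alignment),
Gaussian-downshift imputation of left-censored missing values (peptide level:
width 0.3, downshift 1.8 sample SDs; protein level: 0.2 and 2.5), a moderated
t of IP vs IgG with BH correction, and a hyperbolic significance curve
(maximum adjusted p of 0.05 at large fold change, tightening to zero as
|log2FC| approaches 1).

Dimethyl-label branch: per-protein log2 ratio of total experimental to
control signal-to-noise, after dropping PSMs with heavy+light S/N below 10
and proteins with fewer than 8 surviving PSMs; a zero control total is
replaced by 1 (the theoretical ideal of a control-absent partner).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import bh_fdr, moderated_t_test

__all__ = [
    "top3_quantify",
    "normalize_peptides",
    "impute_missing",
    "enrichment_test",
    "significance_curve",
    "dimethyl_ratios",
    "IMPUTE_DEFAULTS",
]

# (width, downshift) in units of the per-sample SD of observed values
IMPUTE_DEFAULTS = {"peptide": (0.3, 1.8), "protein": (0.2, 2.5)}


# ---------------------------------------------------------------------------
# protein roll-up
# ---------------------------------------------------------------------------

def top3_quantify(peptides: pd.DataFrame, value_col: str = "intensity") -> pd.DataFrame:
    """Top3 roll-up: per (protein, condition, replicate), the sum of the three
    largest observed peptide intensities.

    With fewer than three observed peptides, sums what exists; the
    ``evidence`` column records how many peptides contributed.  A protein is
    missing in a replicate iff no peptide was observed there.
    """
    if peptides.empty:
        raise ValueError("empty peptide table")
    if (peptides[value_col].dropna() < 0).any():
        raise ValueError("negative peptide intensity")
    obs = peptides.dropna(subset=[value_col])

    def _top3(v: pd.Series) -> float:
        return v.nlargest(3).sum()

    grouped = obs.groupby(["protein", "condition", "replicate"])[value_col]
    out = grouped.agg(top3=_top3, evidence="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# peptide normalization
# ---------------------------------------------------------------------------

def normalize_peptides(
    peptides: pd.DataFrame,
    value_col: str = "intensity",
    mode: str = "log2-median",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Variance-stabilizing peptide normalization across replicates.

    ``mode='log2-median'`` (default) log2-transforms intensities and cyclically
    aligns per-replicate medians of observed values to the grand median until
    they agree to ``tol``.  ``mode='arcsinh'`` applies the inverse hyperbolic
    sine before the same median alignment.  Missing values are untouched.
    Returns a copy with a ``log_intensity`` column.
    """
    if peptides["replicate"].nunique() < 2 and peptides["condition"].nunique() < 2:
        raise ValueError("need at least two replicates to normalize")
    out = peptides.copy()
    vals = out[value_col].to_numpy(dtype=float)
    if mode == "log2-median":
        log_vals = np.log2(vals)
    elif mode == "arcsinh":
        log_vals = np.arcsinh(vals)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out["log_intensity"] = log_vals
    key = out["condition"].astype(str) + "/" + out["replicate"].astype(str)
    for _ in range(max_iter):
        medians = out.groupby(key)["log_intensity"].median()
        target = medians.median()
        shift = (medians - target).reindex(key).to_numpy()
        if np.nanmax(np.abs(shift)) <= tol:
            break
        out["log_intensity"] = out["log_intensity"] - shift
    out.attrs["normalization"] = mode
    return out


# ---------------------------------------------------------------------------
# downshifted imputation
# ---------------------------------------------------------------------------

def impute_missing(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    level: str = "protein",
    width: float | None = None,
    downshift: float | None = None,
    min_evidence: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian-downshift imputation of left-censored missing values.

    ``matrix`` is features × samples on the log scale; ``groups`` maps sample
    id to its replicate group.  A feature is eligible iff at least one group
    has ``min_evidence`` observed values; ineligible features are dropped.
    Each eligible missing cell in sample ``s`` is drawn from
    ``Normal(mean_s - downshift * sd_s, (width * sd_s)^2)`` with mean/sd over
    that sample's observed values.  Defaults: (0.3, 1.8) at peptide level,
    (0.2, 2.5) at protein level.
    """
    if level not in IMPUTE_DEFAULTS:
        raise ValueError(f"unknown imputation level {level!r}")
    d_width, d_shift = IMPUTE_DEFAULTS[level]
    width = d_width if width is None else width
    downshift = d_shift if downshift is None else downshift
    unknown = set(matrix.columns) - set(groups)
    if unknown:
        raise ValueError(f"samples without group assignment: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    obs = matrix.notna()
    group_labels = pd.Series({s: groups[s] for s in matrix.columns})
    eligible = pd.Series(False, index=matrix.index)
    for g in group_labels.unique():
        cols = group_labels.index[group_labels == g]
        eligible |= obs[cols].sum(axis=1) >= min_evidence
    out = matrix.loc[eligible].copy()

    for s in out.columns:
        col = out[s]
        n_miss = int(col.isna().sum())
        if not n_miss:
            continue
        observed = col.dropna()
        if observed.size < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 observed values; sd undefined")
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_miss)
        out.loc[col.isna(), s] = draws
    out.attrs["imputation"] = {
        "level": level, "width": width, "downshift": downshift,
        "min_evidence": min_evidence, "seed": seed,
        "n_dropped": int((~eligible).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# enrichment testing and significance curve
# ---------------------------------------------------------------------------

def enrichment_test(
    quant: pd.DataFrame, design: Mapping[str, str], test_group: str = "IP"
) -> pd.DataFrame:
    """Moderated-t enrichment of IP over IgG on log2 protein intensities.

    ``quant`` is proteins × samples (log2, post-imputation); ``design`` maps
    sample to condition.  log2fc is mean(IP) minus mean(IgG); p-values are
    BH-adjusted into ``p_adj``.
    """
    labels = [design[s] for s in quant.columns]
    conditions = pd.unique(np.asarray(labels))
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {list(conditions)}")
    # order groups so that log2fc is test_group minus the other
    other = [c for c in conditions if c != test_group][0]
    ordered_cols = [s for s in quant.columns if design[s] == other] + [
        s for s in quant.columns if design[s] == test_group
    ]
    quant = quant[ordered_cols]
    labels = [design[s] for s in ordered_cols]
    res = moderated_t_test(quant, labels)
    res = res.rename(columns={"fdr": "p_adj", "t_stat": "t"})
    return res[["log2fc", "mean_expr", "t", "p", "p_adj", "df"]]


def significance_curve(
    results: pd.DataFrame,
    p0: float = 0.05,
    fc0: float = 1.0,
    s0_mult: float = 1.0,
    s0: float | None = None,
) -> pd.DataFrame:
    """Flag significant enrichment with a hyperbolic fold-change/p curve.

    A protein is significant iff ``|log2fc| > fc0`` and
    ``-log10(p_adj) >= -log10(p0) + c / (|log2fc| - fc0)`` where ``c`` is
    ``s0_mult`` times the overall SD of log2fc across proteins (or ``s0``
    directly, when given).  At ``|log2fc| = fc0`` the threshold diverges
    (never significant); for large fold changes it relaxes to
    ``p_adj <= p0``.  ``curve_margin`` is the left-hand side minus the
    threshold (positive where significant).
    """
    out = results.copy()
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        out["curve_margin"] = pd.Series(dtype=float)
        return out
    lfc = out["log2fc"].to_numpy(dtype=float)
    padj = out["p_adj"].to_numpy(dtype=float)
    c = s0 if s0 is not None else s0_mult * np.nanstd(lfc, ddof=1)
    abs_lfc = np.abs(lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        neglog_p = -np.log10(np.maximum(padj, 1e-300))
        threshold = np.where(
            abs_lfc > fc0, -np.log10(p0) + c / (abs_lfc - fc0), np.inf
        )
        margin = neglog_p - threshold
    out["significant"] = (abs_lfc > fc0) & (margin >= 0)
    out["curve_margin"] = margin
    out.attrs["curve"] = {"p0": p0, "fc0": fc0, "s0": float(c)}
    return out


# ---------------------------------------------------------------------------
# dimethyl-label ratios
# ---------------------------------------------------------------------------

def dimethyl_ratios(
    psms: pd.DataFrame,
    experimental_channel: str = "heavy",
    min_psms: int = 8,
    min_sn_sum: float = 10.0,
) -> pd.DataFrame:
    """Per-protein log2 ratio of total experimental over control S/N.

    PSMs with heavy+light S/N below ``min_sn_sum`` are dropped, then proteins
    with fewer than ``min_psms`` surviving PSMs.  The ratio is
    ``log2(sum experimental S/N / sum control S/N)``; a zero control total is
    replaced by 1 before the ratio (control-absent partners).
    """
    if experimental_channel not in ("heavy", "light"):
        raise ValueError(f"unassigned channel: {experimental_channel!r}")
    if (psms[["heavy_sn", "light_sn"]] < 0).any().any():
        raise ValueError("signal-to-noise must be non-negative")
    ctl_channel = "light" if experimental_channel == "heavy" else "heavy"

    keep = psms[(psms["heavy_sn"] + psms["light_sn"]) >= min_sn_sum]
    counts = keep.groupby("protein").size()
    good = counts[counts >= min_psms].index
    keep = keep[keep["protein"].isin(good)]

    totals = keep.groupby("protein").agg(
        experimental_sn=(f"{experimental_channel}_sn", "sum"),
        control_sn=(f"{ctl_channel}_sn", "sum"),
        n_psms=("psm", "count"),
    )
    denom = totals["control_sn"].where(totals["control_sn"] > 0, 1.0)
    totals["control_imputed"] = totals["control_sn"] == 0
    totals["log2_ratio"] = np.log2(totals["experimental_sn"] / denom)
    return totals.reset_index()
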