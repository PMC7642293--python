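"""Knock-down signature derivation, cohort scoring and quartile classification.

A signature is the top-N genes differentially expressed on target depletion
(|log2FC| >= 1.5, FDR < 0.01, default top 419), each with a direction and a
weight.  A cohort sample's raw score is the weighted sum of within-cohort
z-scores of the signature genes; raw scores are rescaled so the empirical
2.5% and 97.5% quantiles map to -1 and +1, and samples split into the bottom
quartile (low), top quartile (high) and the remainder (mid).  A low score
marks a transcriptome resembling active SMARCA4 loss-of-function — the
aggressive, CRPC-NE-like phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("swisig")

__all__ = [
    "SignatureModel",
    "derive_signature",
    "score_samples",
    "rescale_scores",
    "classify_quartiles",
]


@dataclass
class SignatureModel:
    """Ordered gene list with per-gene weight/direction and derivation metadata."""

    genes: list
    weights: dict
    directions: dict
    derivation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        for g in self.genes:
            w = self.weights[g]
            if w != 0 and np.sign(w) != self.directions[g]:
                raise ValueError(f"direction of {g!r} must equal sign(weight)")

    def downregulated(self) -> list:
        return [g for g in self.genes if self.directions[g] < 0]

    def upregulated(self) -> list:
        return [g for g in self.genes if self.directions[g] > 0]


def derive_signature(
    de: pd.DataFrame,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
    top_n: int = 419,
    weight_mode: str = "sign",
) -> SignatureModel:
    """Select signature genes from a differential-expression table.

    Keeps genes with ``|log2fc| >= lfc_threshold`` and ``fdr < fdr_threshold``,
    ranks by FDR ascending then |log2fc| descending then gene id, truncates to
    ``top_n``.  ``weight_mode='sign'`` gives unit weights carrying only the
    direction of change; ``'log2fc'`` uses the fold change itself.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    if weight_mode not in ("sign", "log2fc"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    ok = de.dropna(subset=["log2fc", "fdr"])
    passing = ok[(ok["log2fc"].abs() >= lfc_threshold) & (ok["fdr"] < fdr_threshold)]
    if passing.empty:
        raise ValueError(
            f"no gene passes |log2fc| >= {lfc_threshold} and fdr < {fdr_threshold} "
            f"({len(de)} genes tested)"
        )
    ranked = passing.assign(_abs=passing["log2fc"].abs()).sort_values(
        by=["fdr", "_abs"],
        ascending=[True, False],
        kind="mergesort",
    )
    # tie-break on gene id for fully tied (fdr, |lfc|)
    ranked = ranked.assign(_gene=ranked.index).sort_values(
        by=["fdr", "_abs", "_gene"], ascending=[True, False, True], kind="mergesort"
    )
    ranked = ranked.head(top_n)
    genes = ranked.index.tolist()
    if weight_mode == "sign":
        weights = {g: float(np.sign(ranked.loc[g, "log2fc"])) for g in genes}
    else:
        weights = {g: float(ranked.loc[g, "log2fc"]) for g in genes}
    directions = {g: int(np.sign(ranked.loc[g, "log2fc"])) for g in genes}
    meta = {
        "lfc_threshold": lfc_threshold,
        "fdr_threshold": fdr_threshold,
        "top_n": top_n,
        "weight_mode": weight_mode,
        "n_passing": int(len(passing)),
        "engine": "moderated-t on TMM log2-CPM",
    }
    return SignatureModel(genes=genes, weights=weights, directions=directions, derivation=meta)


def score_samples(expr: pd.DataFrame, sig: SignatureModel) -> pd.Series:
    """Raw signature scores: weighted sum of within-cohort z-scores.

    z-scores are computed per gene across the cohort being scored.  Signature
    genes absent from the matrix, or with zero variance across samples, are
    skipped (and logged).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples to z-score a cohort")
    present = [g for g in sig.genes if g in expr.index]
    absent = set(sig.genes) - set(present)
    if absent:
        logger.warning("score_samples: %d signature gene(s) absent, skipped", len(absent))
    if not present:
        raise ValueError("no signature gene present in expression matrix")
    sub = expr.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.all():
        logger.warning(
            "score_samples: %d zero-variance gene(s) skipped", int((~usable).sum())
        )
    sub = sub.loc[usable]
    z = sub.sub(mu[usable], axis=0).div(sd[usable], axis=0)
    w = pd.Series({g: sig.weights[g] for g in sub.index})
    raw = z.mul(w, axis=0).sum(axis=0)
    raw.name = "raw_score"
    return raw


def rescale_scores(
    raw: pd.Series, q_low: float = 0.025, q_high: float = 0.975
) -> pd.Series:
    """Affine rescaling so empirical quantiles ``q_low``/``q_high`` map to -1/+1.

    Quantiles use linear (type-7) interpolation.  Raises on degenerate input
    where both quantiles coincide.
    """
    lo = float(np.quantile(raw.to_numpy(dtype=float), q_low, method="linear"))
    hi = float(np.quantile(raw.to_numpy(dtype=float), q_high, method="linear"))
    if hi == lo:
        raise ValueError(f"degenerate scores: Q({q_low}) == Q({q_high}) == {lo}")
    rescaled = 2.0 * (raw - lo) / (hi - lo) - 1.0
    rescaled.name = "rescaled_score"
    return rescaled


def classify_quartiles(rescaled: pd.Series) -> pd.Series:
    """Label the bottom quartile 'low', the top quartile 'high', rest 'mid'.

    Exactly ``floor(n/4)`` samples each in low and high; boundary ties broken
    by sample id (lexicographic, stable).
    """
    n = len(rescaled)
    if n < 4:
        raise ValueError(f"need at least 4 samples to classify quartiles, got {n}")
    k = n // 4
    order = rescaled.to_frame("s").assign(_id=rescaled.index.astype(str))
    order = order.sort_values(by=["s", "_id"], kind="mergesort")
    classes = pd.Series("mid", index=rescaled.index, name="class")
    classes[order.index[:k]] = "low"
    classes[order.index[-k:]] = "high"
    return classes
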