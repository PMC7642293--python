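"""Association statistics, implemented from first principles.

Exact 2x2 Fisher test (log-gamma hypergeometric enumeration over the fixed
margins), Mann-Whitney U with an exact small-sample path, the Mann-Kendall
trend test with tie-corrected variance, the pooled two-proportion score test,
per-state loss-of-heterozygosity comparisons, and Kaplan-Meier estimation
with the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_exact_2x2",
    "mann_whitney_u",
    "mann_kendall",
    "two_proportion_test",
    "loh_state_compare",
    "km_logrank",
    "KaplanMeierCurve",
]


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = a) for the 2x2 table with margins (r1, r2) x (c1, c2)."""
    n = r1 + r2
    return (
        lgamma(r1 + 1) - lgamma(a + 1) - lgamma(r1 - a + 1)
        + lgamma(r2 + 1) - lgamma(c1 - a + 1) - lgamma(r2 - c1 + a + 1)
        - (lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1))
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table ``[[a, b], [c, d]]``.

    The two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table (with 1e-7 relative slack against roundoff).  Returns
    ``(odds_ratio, p)`` with the sample odds ratio ad/bc (inf when bc = 0).
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        raise ValueError("zero margin in 2x2 table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    cutoff = log_obs + np.log1p(1e-7)
    p = sum(
        np.exp(lp)
        for x in range(lo, hi + 1)
        if (lp := _log_hypergeom_pmf(x, r1, r2, c1)) <= cutoff
    )
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_exact_p(u: float, nx: int, ny: int) -> float:
    """Exact two-sided p by enumeration of all C(nx+ny, nx) labelings."""
    n = nx + ny
    ranks = np.arange(1, n + 1)
    base = nx * (nx + 1) / 2.0
    us = [sum(cmb) - base for cmb in combinations(ranks, nx)]
    us = np.asarray(us)
    mean_u = nx * ny / 2.0
    dev = abs(u - mean_u)
    p = np.mean(np.abs(us - mean_u) >= dev - 1e-12)
    return float(min(1.0, p))


def mann_whitney_u(x: Sequence, y: Sequence) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    U counts, over all (x, y) pairs, the x values exceeding y (midranks for
    ties).  Exact p by enumeration when n_x + n_y <= 12 and there are no
    ties; otherwise normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if nx + ny <= 12 and not has_ties:
        return float(u), _mwu_exact_p(u, nx, ny)

    mean_u = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return float(u), 1.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(u), float(min(1.0, p))


# ---------------------------------------------------------------------------
# Mann-Kendall trend test
# ---------------------------------------------------------------------------

def _mk_exact_p(s: int, n: int) -> float:
    """Exact two-sided P(|S| >= |s|) under the permutation null (no ties).

    For distinct values, S = C(n,2) - 2 * (number of inversions); the
    inversion-count distribution over all n! orderings follows the classic
    dynamic programme, evaluated in exact integer arithmetic.
    """
    counts = [1]
    for m in range(2, n + 1):
        prev = counts
        counts = [0] * (len(prev) + m - 1)
        run = 0
        for k in range(len(counts)):
            run += prev[k] if k < len(prev) else 0
            if k - m >= 0:
                run -= prev[k - m]
            counts[k] = run
    total = sum(counts)
    c = n * (n - 1) // 2
    hit = sum(counts[k] for k in range(len(counts)) if abs(c - 2 * k) >= abs(s))
    return hit / total


def mann_kendall(series: Sequence) -> tuple[int, float, float]:
    """Mann-Kendall monotone-trend test on an ordered series.

    S sums sign(x_j - x_i) over i < j.  For tie-free series of up to 50
    points the two-sided p is exact (full permutation-null enumeration via
    the inversion-count recursion); otherwise it comes from the normal
    approximation with tie-corrected variance
    [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 and a +/-1 continuity
    correction.  Returns ``(S, z, p_two_sided)``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:
        return s, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    no_ties = np.unique(x).size == n
    if no_ties and n <= 50:
        p = _mk_exact_p(s, n)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(min(1.0, p))


# ---------------------------------------------------------------------------
# two-proportion score test
# ---------------------------------------------------------------------------

def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Pooled two-proportion score test, two-tailed.

    Without continuity correction, z squared equals the Pearson chi-square of
    the corresponding 2x2 table; with ``continuity=True`` a Yates-style
    correction of ``0.5 * (1/n1 + 1/n2)`` shrinks the difference toward zero.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = np.sign(diff) * max(abs(diff) - cc, 0.0)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


# ---------------------------------------------------------------------------
# LOH comparisons
# ---------------------------------------------------------------------------

LOH_CATEGORIES = ("hemizygous_deletion", "CNNL")


def loh_state_compare(
    loh: pd.DataFrame,
    annotation: pd.DataFrame,
    gene: str,
    alpha: float = 0.05,
    continuity: bool = False,
) -> dict:
    """Per-state LOH fractions for one gene and pairwise proportion tests.

    A sample counts as LOH if its call is hemizygous deletion or copy-number
    neutral LOH.  Returns ``{"fractions": {state: (k, n, frac)},
    "tests": {(s1, s2): (z, p, significant)}}``; state pairs where either
    state has zero LOH calls in both states combined are still tested unless
    no LOH exists at all, in which case tests are skipped with a message.
    """
    if gene not in loh.index:
        raise ValueError(f"gene {gene!r} not in LOH matrix")
    calls = loh.loc[gene]
    states = annotation.loc[calls.index, "state"]
    fractions: dict[str, tuple[int, int, float]] = {}
    for state in pd.unique(states):
        mask = states == state
        n = int(mask.sum())
        k = int(calls[mask].isin(LOH_CATEGORIES).sum())
        fractions[state] = (k, n, k / n if n else np.nan)
    tests: dict[tuple[str, str], tuple[float, float, bool]] = {}
    skipped = []
    for s1, s2 in combinations(fractions, 2):
        k1, n1, _ = fractions[s1]
        k2, n2, _ = fractions[s2]
        if k1 + k2 == 0 or (k1 == n1 and k2 == n2):
            skipped.append((s1, s2))
            continue
        z, p = two_proportion_test(k1, n1, k2, n2, continuity=continuity)
        tests[(s1, s2)] = (z, p, p < alpha)
    out = {"gene": gene, "fractions": fractions, "tests": tests}
    if skipped:
        out["skipped"] = [f"{s1} vs {s2}: no variation in LOH calls" for s1, s2 in skipped]
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate: step function S(t)."""

    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _km_curve(time: np.ndarray, event: np.ndarray) -> KaplanMeierCurve:
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in ev_times:
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KaplanMeierCurve(
        times=ev_times, survival=np.asarray(surv),
        n_at_risk=np.asarray(at_risk), n_events=np.asarray(n_ev),
    )


def km_logrank(
    time: Sequence, event: Sequence, group: Sequence
) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    :class:`KaplanMeierCurve`.  The log-rank chi-square compares observed and
    expected events in group 1 over the pooled risk sets, with the
    hypergeometric variance, on 1 degree of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if (time < 0).any():
        raise ValueError("negative survival time")
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {list(labels)}")
    for lab in labels:
        if (group == lab).sum() == 0:
            raise ValueError(f"group {lab!r} has zero subjects")

    curves = {
        lab: _km_curve(time[group == lab], event[group == lab]) for lab in labels
    }

    g1 = group == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return curves, 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return curves, float(chi2), p
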