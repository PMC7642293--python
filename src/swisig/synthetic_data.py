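"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one input the real study measured: negative-binomial
knock-down vs control RNA-seq counts with a batch factor, a multi-state
prostate-cancer cohort in which CRPC-NE samples carry a planted shift on the
signature genes, log-normal bait/IgG co-IP peptide intensities with
intensity-dependent (missing-not-at-random) dropout, gamma-distributed
heavy/light PSM signal-to-noise, and Bernoulli loss-of-heterozygosity calls.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded from
the config, so a fixed seed yields byte-identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_core import VALID_STATES, log_stage

__all__ = [
    "KDSimConfig",
    "CohortSimConfig",
    "CoipSimConfig",
    "DimethylSimConfig",
    "GroundTruth",
    "gen_kd_counts",
    "gen_cohort",
    "gen_coip_peptides",
    "gen_dimethyl_psms",
    "gen_loh_calls",
]


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated dataset."""

    true_de_genes: dict = field(default_factory=dict)  # gene -> signed log2FC
    true_partner_proteins: list = field(default_factory=list)
    true_state_of_sample: dict = field(default_factory=dict)
    loh_fractions: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config field {field_name!r}: {msg}")


# ---------------------------------------------------------------------------
# knock-down vs control counts
# ---------------------------------------------------------------------------

@dataclass
class KDSimConfig:
    """Negative-binomial knock-down vs scrambled-control experiment.

    Variance follows the mean-dispersion form var = mu + dispersion * mu^2.
    Replicates are split over two batches with a multiplicative per-gene
    batch effect of log-scale SD ``batch_effect_sd``.
    """

    n_genes: int = 2000
    n_replicates_per_arm: int = 4
    n_true_de: int = 400
    log2fc_magnitude: float = 2.0
    dispersion: float = 0.05
    baseline_log_mean: float = 5.0
    batch_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(self.n_true_de <= self.n_genes, "n_true_de", "must be <= n_genes")
        _require(self.n_true_de >= 0, "n_true_de", "must be >= 0")
        _require(self.dispersion > 0, "dispersion", "must be > 0")
        _require(
            self.n_replicates_per_arm >= 2, "n_replicates_per_arm", "must be >= 2"
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with var = mu + phi mu^2  <=>  n = 1/phi, p = n/(n+mu)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_kd_counts(config: KDSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a counts matrix for knock-down vs control.

    Returns ``(counts, annotation, truth)``: a genes × (2 * replicates)
    integer matrix, a per-sample table with ``group`` and ``batch`` columns,
    and the ground truth listing the planted differential genes with their
    signed log2 fold changes (applied in the knock-down arm).
    """
    log_stage("gen_kd_counts", asdict(config))
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    r = config.n_replicates_per_arm

    genes = [f"g{i:05d}" for i in range(g)]
    base_mean = np.exp(rng.normal(config.baseline_log_mean, 1.0, size=g))

    signs = np.where(np.arange(config.n_true_de) % 2 == 0, 1.0, -1.0)
    lfc = np.zeros(g)
    lfc[: config.n_true_de] = signs * config.log2fc_magnitude

    samples, groups, batches = [], [], []
    for arm in ("ctrl", "kd"):
        for i in range(r):
            samples.append(f"{arm}_{i + 1}")
            groups.append(arm)
            batches.append("A" if i % 2 == 0 else "B")

    batch_fx = {
        b: np.exp(rng.normal(0.0, config.batch_effect_sd, size=g)) for b in ("A", "B")
    }
    cols = {}
    for s, grp, b in zip(samples, groups, batches):
        mu = base_mean * batch_fx[b]
        if grp == "kd":
            mu = mu * np.exp2(lfc)
        cols[s] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"), dtype=np.int64)
    annotation = pd.DataFrame(
        {"group": groups, "batch": batches}, index=pd.Index(samples, name="sample")
    )
    truth = GroundTruth(
        true_de_genes={genes[i]: float(lfc[i]) for i in range(config.n_true_de)}
    )
    return counts, annotation, truth


# ---------------------------------------------------------------------------
# multi-state cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Multi-state cohort with a planted signature shift in CRPC-NE samples.

    ``signature_genes`` maps gene id to direction (+1/-1).  CRPC-NE samples
    are shifted on each signature gene by ``effect_size_sd * direction`` in
    units of the within-cohort noise SD, so a sign-weighted score separates
    CRPC-NE from the remaining states by design.  The ordinal Gleason group
    is drawn from a proportional-odds model on the planted aggressiveness
    score and the continuous risk score is that latent score plus noise.
    """

    n_samples_per_state: Mapping[str, int] = field(
        default_factory=lambda: {"benign": 20, "PCa": 60, "CRPC-Adeno": 120, "CRPC-NE": 60}
    )
    signature_genes: Mapping[str, int] = field(
        default_factory=lambda: {f"sig{i:03d}": (1 if i % 2 == 0 else -1) for i in range(100)}
    )
    effect_size_sd: float = 1.5
    noise_sd: float = 1.0
    n_background_genes: int = 900
    survival: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_samples_per_state) - set(VALID_STATES)
        _require(not unknown, "n_samples_per_state", f"unknown state(s) {sorted(unknown)}")
        _require(
            all(n >= 0 for n in self.n_samples_per_state.values()),
            "n_samples_per_state",
            "counts must be >= 0",
        )
        _require(self.effect_size_sd >= 0, "effect_size_sd", "must be >= 0")
        _require(self.noise_sd > 0, "noise_sd", "must be > 0")
        _require(
            all(d in (-1, 1) for d in self.signature_genes.values()),
            "signature_genes",
            "directions must be +1 or -1",
        )


# latent aggressiveness per state; CRPC-NE most aggressive
_STATE_AGGR = {"benign": 0.0, "PCa": 1.0, "CRPC-Adeno": 2.0, "CRPC-NE": 3.0}


def gen_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate ``(expression, annotation, truth)`` for a multi-state cohort.

    Expression is log-scale (arbitrary log2 units) with per-gene baselines;
    only CRPC-NE samples carry the signature shift.
    """
    log_stage("gen_cohort", {**asdict(config), "signature_genes": len(config.signature_genes)})
    rng = np.random.default_rng(config.seed)

    samples, states = [], []
    for state in VALID_STATES:  # fixed order for determinism
        n = int(config.n_samples_per_state.get(state, 0))
        for i in range(n):
            samples.append(f"{state.replace('-', '')}_{i + 1:03d}")
            states.append(state)
    n_samp = len(samples)
    _require(n_samp > 0, "n_samples_per_state", "no samples configured")

    sig_genes = list(config.signature_genes)
    genes = sig_genes + [f"bg{i:05d}" for i in range(config.n_background_genes)]
    n_genes = len(genes)

    baseline = rng.normal(6.0, 2.0, size=n_genes)
    expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samp))

    is_ne = np.array([s == "CRPC-NE" for s in states])
    directions = np.array([config.signature_genes[g] for g in sig_genes], dtype=float)
    shift = config.effect_size_sd * config.noise_sd * directions
    expr[: len(sig_genes), :][:, is_ne] += shift[:, None]

    matrix = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"), columns=samples
    )

    # latent aggressiveness drives Gleason (proportional odds) and risk score
    latent = np.array([_STATE_AGGR[s] for s in states]) + rng.normal(0, 0.5, n_samp)
    cuts = np.array([0.5, 1.25, 2.0, 2.75])  # 4 cutpoints -> 5 ordinal groups
    u = rng.uniform(size=n_samp)
    # P(G <= k) = expit(cut_k - latent); invert the CDF by comparison
    cdf = expit(cuts[None, :] - latent[:, None])
    gleason = 1 + (u[:, None] > cdf).sum(axis=1)
    risk = latent + rng.normal(0, 0.5, n_samp)

    annotation = pd.DataFrame(
        {
            "state": states,
            "gleason_group": gleason.astype(int),
            "risk_score": risk,
        },
        index=pd.Index(samples, name="sample"),
    )
    if config.survival:
        # exponential survival, hazard increasing with latent aggressiveness
        hazard = 0.1 * np.exp(0.5 * latent)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0, 30, n_samp)
        annotation["time"] = np.minimum(t_event, t_cens)
        annotation["event"] = (t_event <= t_cens).astype(int)

    truth = GroundTruth(
        true_state_of_sample=dict(zip(samples, states)),
        extra={
            "signature_genes": dict(config.signature_genes),
            "effect_size_sd": config.effect_size_sd,
            "latent_aggressiveness": dict(zip(samples, latent.tolist())),
        },
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# co-IP peptide intensities
# ---------------------------------------------------------------------------

@dataclass
class CoipSimConfig:
    """Log-normal bait/IgG co-IP pulldown with MNAR dropout.

    Partner proteins are enriched by ``enrichment_log2`` (log2 units) in the
    IP condition.  Each intensity is set missing independently with
    probability ``expit(-missingness_steepness * (log2 I - midpoint))`` — a
    logistic left-censoring model, strictly decreasing in intensity for
    positive steepness.  ``missingness_midpoint = -inf`` disables dropout.
    """

    n_proteins: int = 800
    n_bait_partners: int = 20
    enrichment_log2: float = 3.0
    n_replicates: int = 3
    missingness_steepness: float = 0.8
    missingness_midpoint: float = 17.0
    peptides_per_protein: tuple[int, int] = (3, 8)
    peptide_sd: float = 1.0
    replicate_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        _require(
            self.n_bait_partners <= self.n_proteins,
            "n_bait_partners",
            "must be <= n_proteins",
        )
        _require(self.n_replicates >= 2, "n_replicates", "must be >= 2")
        _require(
            self.missingness_steepness >= 0, "missingness_steepness", "must be >= 0"
        )
        lo, hi = self.peptides_per_protein
        _require(1 <= lo <= hi, "peptides_per_protein", "need 1 <= lo <= hi")


def gen_coip_peptides(config: CoipSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format peptide table for an IP vs IgG pulldown.

    Columns: protein, peptide, condition (IP/IgG), replicate, intensity
    (linear scale; ``NaN`` where the logistic dropout removed the value).
    """
    log_stage("gen_coip_peptides", asdict(config))
    rng = np.random.default_rng(config.seed)
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    partners = proteins[: config.n_bait_partners]

    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=config.n_proteins)
    prot_base = rng.normal(20.0, 1.5, size=config.n_proteins)  # log2 units

    rows = []
    for pi, prot in enumerate(proteins):
        pep_offsets = rng.normal(0.0, config.peptide_sd, size=n_pep[pi])
        for pj in range(n_pep[pi]):
            base = prot_base[pi] + pep_offsets[pj]
            for cond in ("IP", "IgG"):
                mu = base + (
                    config.enrichment_log2 if (cond == "IP" and pi < config.n_bait_partners) else 0.0
                )
                for rep in range(1, config.n_replicates + 1):
                    log_i = mu + rng.normal(0.0, config.replicate_sd)
                    rows.append((prot, f"{prot}_pep{pj + 1}", cond, rep, log_i))
    table = pd.DataFrame(
        rows, columns=["protein", "peptide", "condition", "replicate", "log2_intensity"]
    )
    # MNAR dropout, logistic in log-intensity
    if np.isneginf(config.missingness_midpoint):
        p_miss = np.zeros(len(table))
    else:
        p_miss = expit(
            -config.missingness_steepness
            * (table["log2_intensity"].to_numpy() - config.missingness_midpoint)
        )
    miss = rng.uniform(size=len(table)) < p_miss
    intensity = np.exp2(table["log2_intensity"].to_numpy())
    intensity[miss] = np.nan
    out = table.drop(columns="log2_intensity").assign(intensity=intensity)
    truth = GroundTruth(true_partner_proteins=partners)
    return out, truth


# ---------------------------------------------------------------------------
# dimethyl-label PSM tables
# ---------------------------------------------------------------------------

@dataclass
class DimethylSimConfig:
    """Heavy/light dimethyl-label PSM signal-to-noise table.

    S/N values are gamma distributed.  ``heavy_is_experimental`` assigns the
    heavy channel to the experimental (bait) pulldown.  A configurable
    fraction of proteins receives fewer than ``min_psms`` PSMs and a fraction
    of PSMs a heavy+light S/N sum below the filter, to exercise the filter
    rules; ``n_control_absent`` partner proteins have control S/N forced to 0.
    """

    n_proteins: int = 100
    n_partners: int = 10
    psms_per_protein: tuple[int, int] = (8, 20)
    gamma_shape: float = 2.0
    gamma_scale: float = 20.0
    enrichment_log2: float = 3.0
    frac_low_psm_proteins: float = 0.1
    frac_low_sn_psms: float = 0.1
    n_control_absent: int = 2
    heavy_is_experimental: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_partners <= self.n_proteins, "n_partners", "<= n_proteins")
        _require(self.gamma_shape > 0, "gamma_shape", "must be > 0")
        _require(self.gamma_scale > 0, "gamma_scale", "must be > 0")
        _require(0 <= self.frac_low_psm_proteins <= 1, "frac_low_psm_proteins", "in [0,1]")
        _require(0 <= self.frac_low_sn_psms <= 1, "frac_low_sn_psms", "in [0,1]")
        _require(
            self.n_control_absent <= self.n_partners, "n_control_absent", "<= n_partners"
        )
        lo, hi = self.psms_per_protein
        _require(1 <= lo <= hi, "psms_per_protein", "need 1 <= lo <= hi")


def gen_dimethyl_psms(config: DimethylSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a PSM table with heavy/light S/N per record.

    Columns: protein, psm, heavy_sn, light_sn.  Ground truth lists partner
    proteins, the control-absent proteins, and which channel is experimental.
    """
    log_stage("gen_dimethyl_psms", asdict(config))
    rng = np.random.default_rng(config.seed)
    proteins = [f"D{i:04d}" for i in range(config.n_proteins)]
    partners = set(proteins[: config.n_partners])
    control_absent = set(proteins[: config.n_control_absent])

    n_low_psm = int(round(config.frac_low_psm_proteins * config.n_proteins))
    low_psm = set(proteins[config.n_proteins - n_low_psm :]) - partners

    lo, hi = config.psms_per_protein
    rows = []
    for prot in proteins:
        n = int(rng.integers(lo, hi + 1))
        if prot in low_psm:
            n = int(rng.integers(1, 8))
        for k in range(n):
            exp_sn = rng.gamma(config.gamma_shape, config.gamma_scale)
            ctl_sn = rng.gamma(config.gamma_shape, config.gamma_scale)
            if prot in partners:
                exp_sn *= 2.0 ** config.enrichment_log2
            if prot in control_absent:
                ctl_sn = 0.0
            if rng.uniform() < config.frac_low_sn_psms:
                total = exp_sn + ctl_sn
                if total > 0:  # squash the pair below the S/N-sum filter
                    scale = rng.uniform(1.0, 9.0) / total
                    exp_sn, ctl_sn = exp_sn * scale, ctl_sn * scale
            heavy, light = (exp_sn, ctl_sn) if config.heavy_is_experimental else (ctl_sn, exp_sn)
            rows.append((prot, f"{prot}_psm{k + 1}", heavy, light))
    table = pd.DataFrame(rows, columns=["protein", "psm", "heavy_sn", "light_sn"])
    truth = GroundTruth(
        true_partner_proteins=sorted(partners),
        extra={
            "control_absent": sorted(control_absent),
            "experimental_channel": "heavy" if config.heavy_is_experimental else "light",
            "low_psm_proteins": sorted(low_psm),
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# LOH call matrices
# ---------------------------------------------------------------------------

def gen_loh_calls(
    states: Sequence[str],
    per_state_fractions: Mapping[str, float],
    n_genes: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate categorical LOH calls per gene and sample.

    Each (gene, sample) is LOH with the planted per-state probability; LOH
    calls split evenly between hemizygous deletion and copy-number-neutral
    LOH.  Returns ``(calls, annotation, truth)``.
    """
    for s in states:
        if s not in VALID_STATES:
            raise ValueError(f"unknown state label: {s!r}")
    for s, f in per_state_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"invalid config field 'per_state_fractions': {s}={f} outside [0,1]")
    rng = np.random.default_rng(seed)
    samples = [f"s{i:04d}" for i in range(len(states))]
    genes = [f"loh_g{i:03d}" for i in range(n_genes)]
    frac = np.array([per_state_fractions.get(s, 0.0) for s in states])
    is_loh = rng.uniform(size=(n_genes, len(states))) < frac[None, :]
    kind = rng.uniform(size=(n_genes, len(states))) < 0.5
    calls = np.where(
        is_loh, np.where(kind, "hemizygous_deletion", "CNNL"), "none"
    )
    matrix = pd.DataFrame(calls, index=pd.Index(genes, name="gene"), columns=samples)
    annotation = pd.DataFrame(
        {"state": list(states)}, index=pd.Index(samples, name="sample")
    )
    truth = GroundTruth(
        true_state_of_sample=dict(zip(samples, states)),
        loh_fractions=dict(per_state_fractions),
    )
    return matrix, annotation, truth
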