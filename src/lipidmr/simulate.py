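"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator realizes an exposure -> mediator -> outcome causal graph on
summary-statistic scale.  Each candidate SNP belongs to one of three panels:

* exposure instruments: true exposure effect ``gamma`` drawn from a
  half-normal with scale ``effect_sd`` left-truncated at ``effect_floor``
  (the panel models loci that already reached discovery significance, so
  effects sit clear of the detection boundary; the effect allele is coded
  as the trait-increasing allele, the orientation under which directional
  pleiotropy is defined);
* mediator instruments (``mediator_snp_fraction``): zero exposure effect,
  direct mediator effect ``delta`` from the same truncated half-normal;
* null SNPs (``null_fraction``): no effect on anything.

True per-SNP associations follow the graph: mediator beta
``a_true * gamma + delta``; outcome beta (log-odds scale)
``theta_total * gamma + b_true * delta + alpha`` where ``alpha`` is an
optional horizontal-pleiotropy effect ``N(pleiotropy_mean, pleiotropy_sd^2)``
added to the outcome only (InSIDE holds).  Estimated betas add independent
Gaussian noise with standard error ``1 / sqrt(2 * eaf * (1 - eaf) * n)``
per trait — the standard variance approximation for an SD-standardized
trait — and the reported SE equals that noise SD, so exposure, mediator and
outcome samples are non-overlapping by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import SummaryStats, swap_alleles, flip_strand

_TINY_P = 5e-324  # smallest subnormal double; keeps p-values in (0, 1]

#: Ordered allele pairs that are neither identical nor strand-palindromic.
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic exposure/mediator/outcome triplet.

    Defaults model a GWAS panel of published genome-wide-significant lipid
    loci: strong instruments (per-allele effects of a few tenths of an SD)
    measured in biobank-scale samples.
    """

    n_snps: int = 50
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.3
    effect_floor: float = 0.025
    theta_total: float = 0.2
    a_true: float = 0.5
    b_true: float = 0.4
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    null_fraction: float = 0.0
    mediator_snp_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            n = getattr(self, name)
            if not np.isfinite(n) or n < 2:
                raise ValueError(f"{name} must be a finite sample size >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if not (np.isfinite(self.effect_sd) and self.effect_sd > 0):
            raise ValueError("effect_sd must be positive and finite")
        if not (np.isfinite(self.effect_floor) and self.effect_floor >= 0):
            raise ValueError("effect_floor must be >= 0 and finite")
        for name in ("theta_total", "a_true", "b_true", "pleiotropy_mean", "pleiotropy_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not 0 <= self.null_fraction <= 1:
            raise ValueError("null_fraction must lie in [0, 1]")
        if not 0 <= self.mediator_snp_fraction <= 1:
            raise ValueError("mediator_snp_fraction must lie in [0, 1]")
        if self.null_fraction + self.mediator_snp_fraction > 1:
            raise ValueError("null_fraction + mediator_snp_fraction must be <= 1")


def _noisy_stats(true_beta, eaf, n, rng) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    beta = true_beta + rng.normal(0.0, se)
    pval = np.maximum(2.0 * sps.norm.sf(np.abs(beta / se)), _TINY_P)
    return beta, se, pval


def simulate_triplet(
    config: SimConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, pd.DataFrame]:
    """Generate (exposure, mediator, outcome) summary statistics plus truth.

    Returns the three :class:`~lipidmr.gwas_io.SummaryStats` tables (the
    outcome on log-odds scale, ``trait_type="binary"``) and a truth
    DataFrame with one row per SNP: columns ``snp``, ``gamma`` (true
    exposure effect), ``delta`` (direct mediator effect), ``pleiotropy``,
    ``beta_exposure_true``, ``beta_mediator_true``, ``beta_outcome_true``,
    ``wald_true`` (implied outcome/exposure ratio, NaN for SNPs with zero
    exposure effect), ``is_null`` and ``is_mediator_instrument``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps

    n_null = int(round(cfg.null_fraction * n))
    n_med = int(round(cfg.mediator_snp_fraction * n))
    if n_null + n_med > n:
        n_med = n - n_null
    is_null = np.zeros(n, dtype=bool)
    is_med = np.zeros(n, dtype=bool)
    is_null[:n_null] = True
    is_med[n_null : n_null + n_med] = True

    def draw_effects(size):
        # half-normal(effect_sd) left-truncated at effect_floor via inverse CDF
        lo = sps.halfnorm.cdf(cfg.effect_floor, scale=cfg.effect_sd)
        u = rng.uniform(lo, 1.0, size)
        return sps.halfnorm.ppf(u, scale=cfg.effect_sd)

    gamma = draw_effects(n)
    gamma[is_null | is_med] = 0.0
    delta = draw_effects(n)
    delta[~is_med] = 0.0
    if cfg.pleiotropy_mean != 0.0 or cfg.pleiotropy_sd > 0.0:
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n)
    else:
        alpha = np.zeros(n)

    bx_true = gamma
    bm_true = cfg.a_true * gamma + delta
    by_true = cfg.theta_total * gamma + cfg.b_true * delta + alpha

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n)
    minor_is_effect = rng.random(n) < 0.5
    eaf = np.where(minor_is_effect, maf, 1.0 - maf)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    snp = np.array([f"rs{i + 1:06d}" for i in range(n)])
    chrom = (np.arange(n) % 22) + 1
    # 50 Mb spacing: far beyond any clumping window, so LD-free panels clump
    # to themselves.
    pos = 1_000_000 + (np.arange(n) // 22) * 50_000_000

    def build(trait_id, trait_type, true_beta, n_sample):
        beta, se, pval = _noisy_stats(true_beta, eaf, n_sample, rng)
        df = pd.DataFrame(
            {
                "snp": snp, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
                "eaf": eaf, "beta": beta, "se": se, "pval": pval,
                "n": n_sample,
            }
        )
        return SummaryStats(trait_id=trait_id, trait_type=trait_type, data=df)

    exposure = build("exposure", "continuous", bx_true, cfg.n_exposure)
    mediator = build("mediator", "continuous", bm_true, cfg.n_mediator)
    outcome = build("outcome", "binary", by_true, cfg.n_outcome)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald_true = np.where(gamma != 0, by_true / np.where(gamma == 0, np.nan, gamma), np.nan)
    truth = pd.DataFrame(
        {
            "snp": snp,
            "gamma": gamma,
            "delta": delta,
            "pleiotropy": alpha,
            "beta_exposure_true": bx_true,
            "beta_mediator_true": bm_true,
            "beta_outcome_true": by_true,
            "wald_true": wald_true,
            "is_null": is_null,
            "is_mediator_instrument": is_med,
        }
    )
    return exposure, mediator, outcome, truth


def simulate_study(
    lipid_thetas: dict[str, float],
    n_cohorts: int,
    config: SimConfig | None = None,
    between_cohort_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, SummaryStats], dict[str, SummaryStats], pd.DataFrame]:
    """Generate a multi-lipid, multi-cohort screening study on one SNP panel.

    Each lipid receives its own disjoint block of ``config.n_snps``
    instruments (lipids are genetically independent here); every trait is
    reported over the union panel so any pair can be harmonized.  Cohort
    ``c``'s outcome betas sum the lipid effects with per-cohort causal
    effects ``theta_l + N(0, between_cohort_sd^2)`` plus sampling noise, so
    ``between_cohort_sd`` induces genuine cross-cohort heterogeneity.  The
    perturbation only applies to lipids with nonzero ``theta_l``: a null
    lipid is null in every cohort.

    Returns ``(lipids, cohorts, truth)`` where the dicts map trait name to
    :class:`~lipidmr.gwas_io.SummaryStats` and ``truth`` records per-SNP
    block membership, true effects, and the per-cohort realized thetas.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    lipid_names = list(lipid_thetas)
    n_lip = len(lipid_names)
    n = cfg.n_snps * n_lip

    lo = sps.halfnorm.cdf(cfg.effect_floor, scale=cfg.effect_sd)
    gamma = sps.halfnorm.ppf(rng.uniform(lo, 1.0, n), scale=cfg.effect_sd)
    block = np.repeat(np.arange(n_lip), cfg.n_snps)

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n)
    eaf = np.where(rng.random(n) < 0.5, maf, 1.0 - maf)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snp = np.array([f"rs{i + 1:06d}" for i in range(n)])
    chrom = (np.arange(n) % 22) + 1
    pos = 1_000_000 + (np.arange(n) // 22) * 50_000_000

    def build(trait_id, trait_type, true_beta, n_sample):
        beta, se, pval = _noisy_stats(true_beta, eaf, n_sample, rng)
        df = pd.DataFrame(
            {
                "snp": snp, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
                "eaf": eaf, "beta": beta, "se": se, "pval": pval, "n": n_sample,
            }
        )
        return SummaryStats(trait_id=trait_id, trait_type=trait_type, data=df)

    lipids = {}
    for li, name in enumerate(lipid_names):
        true_beta = np.where(block == li, gamma, 0.0)
        lipids[name] = build(name, "continuous", true_beta, cfg.n_exposure)

    theta_matrix = np.empty((n_cohorts, n_lip))
    cohorts = {}
    for c in range(n_cohorts):
        base_thetas = np.array([lipid_thetas[nm] for nm in lipid_names])
        thetas_c = base_thetas
        if between_cohort_sd > 0:
            thetas_c = base_thetas + rng.normal(0.0, between_cohort_sd, n_lip) * (
                base_thetas != 0
            )
        theta_matrix[c] = thetas_c
        by_true = thetas_c[block] * gamma
        cohorts[f"cohort_{c + 1}"] = build(f"cohort_{c + 1}", "binary", by_true, cfg.n_outcome)

    truth = pd.DataFrame(
        {
            "snp": snp,
            "lipid": np.array(lipid_names)[block],
            "gamma": gamma,
        }
    )
    for c in range(n_cohorts):
        truth[f"theta_cohort_{c + 1}"] = theta_matrix[c][block]
    return lipids, cohorts, truth


def inject_harmonization_noise(
    stats: SummaryStats,
    flip_fraction: float,
    palindrome_fraction: float,
    seed: int = 0,
) -> SummaryStats:
    """Stress-test input for the harmonizer.

    A ``flip_fraction`` subset of records is rewritten by an allele swap, a
    strand complement, or both — each an exactly invertible re-encoding of
    the same association (swaps negate beta and reflect eaf).  A disjoint
    ``palindrome_fraction`` subset has its allele pair replaced by a
    strand-palindromic one (A/T or C/G), keeping the statistics; those
    records can only be oriented by frequency downstream.
    """
    if not 0 <= flip_fraction <= 1 or not 0 <= palindrome_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if flip_fraction + palindrome_fraction > 1:
        raise ValueError("flip_fraction + palindrome_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    n = len(stats)
    perm = rng.permutation(n)
    n_flip = int(round(flip_fraction * n))
    n_pal = int(round(palindrome_fraction * n))
    flip_idx = perm[:n_flip]
    pal_idx = perm[n_flip : n_flip + n_pal]

    df = stats.data.copy()
    ops = rng.integers(0, 3, n_flip)  # 0: swap, 1: strand, 2: both
    swap_mask = np.zeros(n, dtype=bool)
    strand_mask = np.zeros(n, dtype=bool)
    swap_mask[flip_idx[ops != 1]] = True
    strand_mask[flip_idx[ops != 0]] = True
    df = swap_alleles(df, swap_mask)
    df = flip_strand(df, strand_mask)

    if n_pal:
        pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), n_pal)
        df.iloc[pal_idx, df.columns.get_loc("ea")] = [
            _PALINDROMIC_PAIRS[i][0] for i in pal_choice
        ]
        df.iloc[pal_idx, df.columns.get_loc("oa")] = [
            _PALINDROMIC_PAIRS[i][1] for i in pal_choice
        ]
    return replace(stats, data=df)
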