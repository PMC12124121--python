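"""End-to-end orchestration: forward screen, multi-cohort selection,
meta-analysis, reverse MR and the two-step mediation stage.

Every exposure x outcome pair runs the same instrument pipeline —
p-threshold, LD clumping, harmonization, outcome-association filter,
Steiger directionality filter, one round of MR-PRESSO outlier removal —
followed by the estimator suite and the primary-estimate selection rule.
Results are tidy DataFrames (one row per pair) ready to write as TSV;
per-pair diagnostics (provenance flags, leave-one-out tables) are kept
alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import estimators as est
from .gwas_io import HarmonizedSet, SummaryStats, harmonize
from .instruments import (
    LDMatrix,
    clump,
    f_statistic,
    filter_outcome_associated,
    steiger_filter,
    threshold_instruments,
)
from .mediation import two_step_mediation
from .meta import pool_random_effects

log = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient_instruments"


@dataclass
class MRParams:
    """Pipeline thresholds and settings.

    Defaults are the study conventions: forward instrument threshold
    p < 5e-6, reverse p < 5e-8, clumping at r^2 < 0.001 within a 10,000 kb
    window, removal of SNPs associated with the outcome at p < 5e-5, and a
    0.05 significance level throughout.
    """

    p_exposure: float = 5e-6
    p_reverse: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    p_outcome_filter: float = 5e-5
    palindrome_maf_limit: float = 0.42
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    presso_min_snps: int = 4
    n_boot: int = 1000
    alpha: float = 0.05
    min_instruments: int = 2
    include_median_mode: bool = True

    def __post_init__(self) -> None:
        for name in ("p_exposure", "p_reverse", "p_outcome_filter", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class PairResult:
    """One exposure x outcome MR analysis: summary row plus diagnostics."""

    row: dict
    provenance: pd.DataFrame | None = None
    loo: pd.DataFrame | None = None
    hset: HarmonizedSet | None = None
    fits: dict = field(default_factory=dict)

    @property
    def status(self) -> str:
        return self.row["status"]


@dataclass
class ScreenResult:
    """Forward-screen output: tidy table plus per-pair diagnostics."""

    table: pd.DataFrame
    diagnostics: dict[tuple[str, str], PairResult]


def _empty_row(exposure_id, outcome_id, reason, counts=None) -> dict:
    row = {
        "exposure": exposure_id,
        "outcome": outcome_id,
        "status": reason,
        "method": None,
        "n_snps": 0,
        "beta": np.nan,
        "se": np.nan,
        "or": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "pval": np.nan,
        "q": np.nan,
        "q_pval": np.nan,
        "egger_intercept": np.nan,
        "intercept_p": np.nan,
        "presso_global_p": np.nan,
        "ivw_beta": np.nan,
        "ivw_se": np.nan,
        "mean_f": np.nan,
    }
    row.update(counts or {})
    return row


def analyze_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    params: MRParams | None = None,
    ld: LDMatrix | None = None,
    p_threshold: float | None = None,
    outcome_p_filter: float | None | str = "default",
    exclude_associated: SummaryStats | None = None,
    seed: int = 0,
    keep_diagnostics: bool = True,
) -> PairResult:
    """Run the full instrument pipeline and estimator suite on one pair.

    ``outcome_p_filter`` defaults to the params value; pass ``None`` to skip
    the outcome-association filter (needed when the "outcome" is a
    downstream mediator whose instruments would otherwise all be removed).
    ``exclude_associated`` drops instruments associated (p < outcome filter
    threshold) with a third trait — used for the mediator -> outcome leg of
    the mediation stage so the mediator's effect is not contaminated by the
    upstream exposure's instruments.
    """
    params = params or MRParams()
    p_thr = params.p_exposure if p_threshold is None else p_threshold
    out_p = params.p_outcome_filter if outcome_p_filter == "default" else outcome_p_filter

    candidates = threshold_instruments(exposure, p_thr)
    counts = {"n_candidates": len(exposure), "n_after_p": len(candidates)}
    if len(candidates) == 0:
        log.info("%s -> %s: no SNPs pass p < %g", exposure.trait_id, outcome.trait_id, p_thr)
        return PairResult(row=_empty_row(exposure.trait_id, outcome.trait_id, STATUS_INSUFFICIENT, counts))

    clumped = clump(candidates, ld, params.clump_r2, params.clump_kb)
    counts["n_after_clump"] = len(clumped)

    try:
        hset = harmonize(clumped, outcome, params.palindrome_maf_limit)
    except ValueError:
        log.info("%s -> %s: no overlapping SNPs", exposure.trait_id, outcome.trait_id)
        return PairResult(row=_empty_row(exposure.trait_id, outcome.trait_id, STATUS_INSUFFICIENT, counts))
    counts["n_harmonized"] = len(hset)

    excluded_assoc: list[str] = []
    if exclude_associated is not None:
        thr = params.p_outcome_filter
        assoc = exclude_associated.data.loc[
            exclude_associated.data["pval"] < thr, "snp"
        ]
        mask = ~hset.data["snp"].isin(set(assoc))
        excluded_assoc = hset.data.loc[~mask, "snp"].tolist()
        hset = hset.subset(mask)
    counts["n_after_exposure_exclusion"] = len(hset)

    outcome_dropped: list[str] = []
    if out_p is not None:
        hset, outcome_dropped = filter_outcome_associated(hset, out_p)
    counts["n_after_outcome_filter"] = len(hset)

    steiger_dropped: list[str] = []
    if len(hset) > 0:
        hset, steiger_dropped = steiger_filter(hset)
    counts["n_after_steiger"] = len(hset)

    presso = None
    presso_dropped: list[str] = []
    if len(hset) >= params.presso_min_snps:
        presso = est.presso_global(
            hset,
            n_sim=params.presso_n_sim,
            outlier_alpha=params.presso_outlier_alpha,
            seed=np.random.default_rng([seed, 1]),
        )
        if presso.outliers:
            hset = hset.subset(~hset.data["snp"].isin(set(presso.outliers)))
            presso_dropped = presso.outliers
    counts["n_after_presso"] = len(hset)

    provenance = None
    if keep_diagnostics:
        prov = clumped.data[["snp"]].copy()
        prov["passed_p"] = True
        prov["clump_index"] = True
        prov["harmonize_action"] = prov["snp"].map(
            dict(zip(hset.actions["snp"], hset.actions["action"]))
            if len(hset.actions)
            else {}
        )
        prov["exposure_excluded"] = prov["snp"].isin(excluded_assoc)
        prov["outcome_filtered"] = prov["snp"].isin(outcome_dropped)
        prov["steiger_dropped"] = prov["snp"].isin(steiger_dropped)
        prov["presso_dropped"] = prov["snp"].isin(presso_dropped)
        prov["retained"] = prov["snp"].isin(set(hset.data["snp"]))
        provenance = prov

    if len(hset) < max(1, params.min_instruments):
        row = _empty_row(exposure.trait_id, outcome.trait_id, STATUS_INSUFFICIENT, counts)
        if presso is not None:
            row["presso_global_p"] = presso.global_p
        return PairResult(row=row, provenance=provenance)

    fits = est.fit_suite(
        hset,
        n_boot=params.n_boot,
        seed=np.random.default_rng([seed, 2]),
        include_median_mode=params.include_median_mode and len(hset) >= 3,
    )
    sel = fits["selected"]
    mean_f = float(np.mean(f_statistic(hset.data["beta_exp"], hset.data["se_exp"])))

    row = _empty_row(exposure.trait_id, outcome.trait_id, STATUS_OK, counts)
    row.update(
        {
            "method": sel.method,
            "n_snps": sel.n_snps,
            "beta": sel.beta,
            "se": sel.se,
            "or": sel.odds_ratio,
            "ci_low": sel.or_ci[0],
            "ci_high": sel.or_ci[1],
            "pval": sel.pval,
            "mean_f": mean_f,
        }
    )
    if "q" in fits:
        row["q"] = fits["q"].q
        row["q_pval"] = fits["q"].pval
    if "egger" in fits:
        row["egger_intercept"] = fits["egger"].extra["intercept"]
        row["intercept_p"] = fits["egger"].extra["intercept_p"]
    if presso is not None:
        row["presso_global_p"] = presso.global_p
    if "ivw_fe" in fits:
        # IVW under the heterogeneity rule: the estimate meta-analysis pools
        ivw_rule = fits["ivw_mre"] if fits["q"].pval < params.alpha else fits["ivw_fe"]
        row["ivw_beta"] = ivw_rule.beta
        row["ivw_se"] = ivw_rule.se

    loo = None
    if keep_diagnostics and len(hset) >= 3:
        loo = est.leave_one_out(hset)
    return PairResult(row=row, provenance=provenance, loo=loo, hset=hset, fits=fits)


def run_forward_screen(
    exposures: Mapping[str, SummaryStats],
    outcomes: Mapping[str, SummaryStats],
    params: MRParams | None = None,
    ld: LDMatrix | None = None,
    seed: int = 0,
    keep_diagnostics: bool = True,
) -> ScreenResult:
    """MR of every exposure against every outcome cohort.

    Returns a tidy table with one row per exposure x cohort, a per-pair
    significance flag (primary p < alpha) and, per exposure, the number of
    cohorts in which it is significant.  Pairs with too few instruments are
    recorded, not fatal.  An empty exposure list yields an empty result with
    a warning.
    """
    params = params or MRParams()
    if not exposures:
        log.warning("forward screen: empty exposure list")
        return ScreenResult(table=pd.DataFrame(), diagnostics={})
    rows = []
    diagnostics: dict[tuple[str, str], PairResult] = {}
    for i, (exp_name, exp_stats) in enumerate(exposures.items()):
        for j, (coh_name, coh_stats) in enumerate(outcomes.items()):
            pr = analyze_pair(
                exp_stats,
                coh_stats,
                params=params,
                ld=ld,
                seed=int(np.random.default_rng([seed, i, j]).integers(2**31 - 1)),
                keep_diagnostics=keep_diagnostics,
            )
            row = dict(pr.row)
            row["exposure"] = exp_name
            row["outcome"] = coh_name
            rows.append(row)
            diagnostics[(exp_name, coh_name)] = pr
    table = pd.DataFrame(rows)
    table["significant"] = (table["status"] == STATUS_OK) & (table["pval"] < params.alpha)
    n_sig = table.groupby("exposure")["significant"].sum().astype(int)
    table["n_cohorts_significant"] = table["exposure"].map(n_sig)
    return ScreenResult(table=table, diagnostics=diagnostics)


def select_multi_cohort(screen: ScreenResult | pd.DataFrame, min_cohorts: int = 2) -> list[str]:
    """Exposures significant in at least ``min_cohorts`` cohorts."""
    if min_cohorts < 2:
        raise ValueError("min_cohorts must be >= 2")
    table = screen.table if isinstance(screen, ScreenResult) else screen
    if table.empty:
        return []
    n_sig = table.groupby("exposure")["significant"].sum()
    return sorted(n_sig.index[n_sig >= min_cohorts])


def run_meta(
    screen: ScreenResult | pd.DataFrame,
    exposures: list[str] | None = None,
    min_cohorts: int = 2,
) -> pd.DataFrame:
    """Random-effects meta-analysis of per-cohort IVW estimates.

    Pools, per exposure, the IVW estimate (MRE under heterogeneity) across
    cohorts with an OK status.  ``exposures`` defaults to the multi-cohort
    selection.
    """
    table = screen.table if isinstance(screen, ScreenResult) else screen
    if exposures is None:
        exposures = select_multi_cohort(table, min_cohorts)
    rows = []
    for exp in exposures:
        sub = table[(table["exposure"] == exp) & (table["status"] == STATUS_OK)]
        sub = sub.dropna(subset=["ivw_beta", "ivw_se"])
        if len(sub) < 2:
            log.warning("meta: %s has < 2 poolable cohorts, skipped", exp)
            continue
        res = pool_random_effects(
            sub["ivw_beta"].to_numpy(), sub["ivw_se"].to_numpy(), sub["outcome"].tolist()
        )
        rows.append(
            {
                "exposure": exp,
                "k_cohorts": res.k,
                "beta": res.beta,
                "se": res.se,
                "or": float(np.exp(res.beta)),
                "ci_low": float(np.exp(res.ci_low)),
                "ci_high": float(np.exp(res.ci_high)),
                "pval": res.pval,
                "tau2": res.tau2,
                "q": res.q,
                "q_pval": res.q_pval,
                "i2": res.i2,
            }
        )
    return pd.DataFrame(rows)


def run_reverse(
    cohorts: Mapping[str, SummaryStats],
    lipids: Mapping[str, SummaryStats],
    params: MRParams | None = None,
    ld: LDMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Reverse MR: each outcome cohort as exposure against each lipid.

    Uses the stricter reverse instrument threshold; otherwise the same
    pipeline stages as the forward screen.
    """
    params = params or MRParams()
    rows = []
    for i, (coh_name, coh_stats) in enumerate(cohorts.items()):
        for j, (lip_name, lip_stats) in enumerate(lipids.items()):
            pr = analyze_pair(
                coh_stats,
                lip_stats,
                params=params,
                ld=ld,
                p_threshold=params.p_reverse,
                seed=int(np.random.default_rng([seed, 7, i, j]).integers(2**31 - 1)),
                keep_diagnostics=False,
            )
            row = dict(pr.row)
            row["exposure"] = coh_name
            row["outcome"] = lip_name
            rows.append(row)
    return pd.DataFrame(rows)


def run_mediation_stage(
    cholesterol: Mapping[str, SummaryStats],
    mediators: Mapping[str, SummaryStats],
    outcomes: Mapping[str, SummaryStats],
    params: MRParams | None = None,
    ld: LDMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-step MR mediation for every (cholesterol exposure, mediator,
    outcome cohort) combination.

    Per combination: ``c`` is the total exposure -> outcome effect, ``a``
    the exposure -> mediator effect and ``b`` the mediator -> outcome effect
    with exposure-associated mediator instruments excluded; the
    product-method decomposition and delta-method z test follow.  Undefined
    proportions (|c| ~ 0) or legs with too few instruments yield NA rows
    with a reason.

    The outcome-association filter is not applied on any mediation leg: it
    exists to purge pleiotropic variants when screening mostly-null
    exposures, and for an exposure with a genuine downstream effect it would
    preferentially discard the valid instruments (every instrument of a
    causal exposure is associated with the outcome).  Clumping, Steiger
    filtering and MR-PRESSO still run.
    """
    params = params or MRParams()
    rows = []
    for ei, (exp_name, exp_stats) in enumerate(cholesterol.items()):
        for mi, (med_name, med_stats) in enumerate(mediators.items()):
            for oi, (out_name, out_stats) in enumerate(outcomes.items()):
                base = {
                    "mediator": med_name,
                    "exposure": exp_name,
                    "outcome": out_name,
                }
                seeds = [
                    int(np.random.default_rng([seed, 11, ei, mi, oi, t]).integers(2**31 - 1))
                    for t in range(3)
                ]
                c_fit = analyze_pair(exp_stats, out_stats, params=params, ld=ld,
                                     outcome_p_filter=None, seed=seeds[0],
                                     keep_diagnostics=False)
                a_fit = analyze_pair(exp_stats, med_stats, params=params, ld=ld,
                                     outcome_p_filter=None, seed=seeds[1],
                                     keep_diagnostics=False)
                b_fit = analyze_pair(med_stats, out_stats, params=params, ld=ld,
                                     outcome_p_filter=None,
                                     exclude_associated=exp_stats, seed=seeds[2],
                                     keep_diagnostics=False)
                if any(f.status != STATUS_OK for f in (c_fit, a_fit, b_fit)):
                    log.warning("mediation %s/%s/%s: insufficient instruments on a leg",
                                exp_name, med_name, out_name)
                    rows.append({**base, "status": STATUS_INSUFFICIENT})
                    continue
                try:
                    med = two_step_mediation(
                        a_fit.row["beta"], a_fit.row["se"],
                        b_fit.row["beta"], b_fit.row["se"],
                        c_fit.row["beta"], c_fit.row["se"],
                    )
                except ValueError as exc:
                    rows.append({**base, "status": f"undefined: {exc}"})
                    continue
                rows.append(
                    {
                        **base,
                        "status": STATUS_OK,
                        "a": med.a, "se_a": med.se_a,
                        "b": med.b, "se_b": med.se_b,
                        "c": med.c, "se_c": med.se_c,
                        "indirect": med.indirect,
                        "direct": med.direct,
                        "proportion_pct": 100 * med.proportion,
                        "ci_low_pct": 100 * med.ci_low,
                        "ci_high_pct": 100 * med.ci_high,
                        "z": med.z,
                        "pval": med.pval,
                    }
                )
    return pd.DataFrame(rows)
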