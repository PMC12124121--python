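"""Two-sample MR estimators, heterogeneity and pleiotropy diagnostics.

All estimators consume a :class:`~lipidmr.gwas_io.HarmonizedSet` and return
:class:`MREstimate` records on the estimation scale (log-odds per exposure
unit for a binary outcome; odds ratios are a reporting concern).

The suite: per-SNP Wald ratio, inverse-variance-weighted (fixed and
multiplicative-random-effects), MR-Egger with its intercept test, weighted
median, weighted mode, Cochran's Q, the MR-PRESSO global/outlier test,
leave-one-out, and the estimator-selection rule (Egger under directional
pleiotropy, MRE-IVW under heterogeneity, otherwise FE-IVW).

Wald-ratio standard errors are first-order (exposure-side noise ignored),
matching the conventional IVW weighting; a second-order option is exposed
where it matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import HarmonizedSet

Z95 = float(sps.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One method's causal-effect estimate.

    ``beta`` is on the estimation scale (log-odds per exposure unit when the
    outcome is binary); the 95% CI is normal and symmetric about ``beta``;
    ``pval`` is the two-sided normal test of ``beta / se``.  Method-specific
    extras (Egger intercept and its test, Q statistics, bootstrap settings)
    live in ``extra``.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class QTestResult:
    """Cochran's Q heterogeneity test."""

    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global test and per-SNP outlier assessment."""

    rss_obs: float
    global_p: float
    outlier_pvals: pd.Series  # indexed by snp id
    outliers: list[str]
    n_simulations: int
    seed: int


def _make_estimate(method, beta, se, n_snps, extra=None) -> MREstimate:
    beta = float(beta)
    se = float(se)
    if se > 0:
        pval = float(2 * sps.norm.sf(abs(beta) / se))
    else:
        pval = 1.0 if beta == 0 else 0.0
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        n_snps=int(n_snps),
        extra=extra or {},
    )


def _arrays(hset: HarmonizedSet):
    d = hset.data
    return (
        d["beta_exp"].to_numpy(float),
        d["se_exp"].to_numpy(float),
        d["beta_out"].to_numpy(float),
        d["se_out"].to_numpy(float),
    )


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``.

    The default SE is first-order, ``|se_out / beta_exp|``; with
    ``second_order=True`` the exposure-side variance term is added.
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    if second_order:
        se = np.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    else:
        se = abs(se_out / beta_exp)
    return _make_estimate("wald", beta, se, 1)


def ivw(hset: HarmonizedSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights ``1 / se_out^2``; equivalently the inverse-variance
    weighted mean of per-SNP Wald ratios.  ``model="fixed"`` uses the
    closed-form SE; ``model="mre"`` (multiplicative random effects) inflates
    it by ``sqrt(max(1, Q / (k - 1)))``.
    """
    if model not in ("fixed", "mre"):
        raise ValueError("model must be 'fixed' or 'mre'")
    bx, _, by, sy = _arrays(hset)
    k = len(bx)
    if k < 2:
        raise ValueError("ivw requires >= 2 SNPs; use wald_ratio for a single SNP")
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / sxx
    se = 1.0 / np.sqrt(sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_pval = float(sps.chi2.sf(q, k - 1))
    if model == "mre":
        se = se * np.sqrt(max(1.0, q / (k - 1)))
    return _make_estimate(
        f"ivw_{'fe' if model == 'fixed' else 'mre'}",
        beta,
        se,
        k,
        extra={"q": q, "q_df": k - 1, "q_pval": q_pval},
    )


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of outcome on exposure betas with a
    free intercept after orienting all exposure betas non-negative.

    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy and its two-sided normal test is stored in
    ``extra`` (``intercept``, ``intercept_se``, ``intercept_p``).  Both SEs
    carry the multiplicative random-effects scaling
    ``sqrt(max(1, Q_egger / (k - 2)))``.
    """
    bx, _, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("egger requires >= 3 SNPs")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    sw = np.sum(w)
    sx = np.sum(w * x)
    sy_ = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    det = sw * sxx - sx**2
    if det <= 0:
        raise ValueError("degenerate design: exposure betas carry no variation")
    slope = (sw * sxy - sx * sy_) / det
    intercept = (sxx * sy_ - sx * sxy) / det
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    scale = np.sqrt(max(1.0, q / (k - 2)))
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(sxx / det) * scale
    int_p = float(2 * sps.norm.sf(abs(intercept) / se_int)) if se_int > 0 else 1.0
    return _make_estimate(
        "egger",
        slope,
        se_slope,
        k,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": int_p,
            "q": q,
            "q_df": k - 2,
            "q_pval": float(sps.chi2.sf(q, k - 2)),
        },
    )


def _ratio_weights(hset: HarmonizedSet):
    bx, _, by, sy = _arrays(hset)
    ratios = by / bx
    w = bx**2 / sy**2  # inverse first-order variance of each ratio
    return ratios, w


def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    ww = w[order]
    p = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Consistent when SNPs contributing at least half the weight are valid
    instruments.  The estimate interpolates the ratio at cumulative
    normalized weight 0.5; the SE comes from a parametric bootstrap that
    redraws exposure and outcome betas from their reported sampling
    distributions.
    """
    bx, sx, by, sy = _arrays(hset)
    if len(bx) < 3:
        raise ValueError("weighted_median requires >= 3 SNPs")
    ratios, w = _ratio_weights(hset)
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        boots[b] = _weighted_median(byb / bxb, bxb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _make_estimate(
        "weighted_median", est, se, len(bx), extra={"n_boot": n_boot}
    )


def _weighted_mode(ratios: np.ndarray, w: np.ndarray, phi: float) -> float:
    wn = w / np.sum(w)
    sd = np.std(ratios, ddof=1)
    mad = sps.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad) * len(ratios) ** (-1 / 5)
    if s <= 0:  # all ratios identical (or MAD zero with tiny spread)
        s = max(sd, 1e-12)
    h = phi * s
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(wn[:, None] * sps.norm.pdf((grid[None, :] - ratios[:, None]) / h), axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MREstimate:
    """Weighted mode of per-SNP Wald ratios (normal-kernel density argmax).

    Bandwidth is ``bandwidth_phi`` times the modified Silverman rule
    ``0.9 * min(sd, mad) * k^(-1/5)`` over the ratios; weights are the
    normalized inverse ratio variances.  SE by parametric bootstrap as in
    :func:`weighted_median`.
    """
    bx, sx, by, sy = _arrays(hset)
    if len(bx) < 3:
        raise ValueError("weighted_mode requires >= 3 SNPs")
    ratios, w = _ratio_weights(hset)
    if np.allclose(ratios, ratios[0]):
        est = float(ratios[0])
    else:
        est = _weighted_mode(ratios, w, bandwidth_phi)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        rb = byb / bxb
        boots[b] = _weighted_mode(rb, bxb**2 / sy**2, bandwidth_phi)
    se = float(np.std(boots, ddof=1))
    return _make_estimate(
        "weighted_mode",
        est,
        se,
        len(bx),
        extra={"bandwidth_phi": bandwidth_phi, "n_boot": n_boot},
    )


def cochran_q(hset: HarmonizedSet, reference_beta: float | None = None, df: int | None = None) -> QTestResult:
    """Cochran's Q over per-SNP Wald ratios.

    ``Q = sum_i w_i (ratio_i - reference)^2`` with first-order ratio weights
    ``w_i = beta_exp_i^2 / se_out_i^2``.  The reference defaults to the
    fixed-effect IVW estimate (df = k - 1); pass ``df=k-2`` for an
    Egger-based reference.
    """
    ratios, w = _ratio_weights(hset)
    k = len(ratios)
    if k < 2:
        raise ValueError("cochran_q requires >= 2 SNPs")
    if reference_beta is None:
        reference_beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - reference_beta) ** 2))
    if df is None:
        df = k - 1
    return QTestResult(q=q, df=df, pval=float(sps.chi2.sf(q, df)))


def _loo_predictions(bx, by, w):
    """Per-SNP IVW predictions with that SNP left out (closed form)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    beta_loo = (sxy - w * bx * by) / (sxx - w * bx**2)
    return beta_loo * bx


def presso_global(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> PressoResult:
    """MR-PRESSO global heterogeneity test with per-SNP outlier detection.

    The observed statistic is the weighted residual sum of squares of
    outcome betas around leave-one-out IVW predictions.  Its null
    distribution is simulated by redrawing each outcome beta from a normal
    centred on its leave-one-out prediction with the reported SE and
    recomputing the statistic; the global p is ``(1 + #{sim >= obs}) /
    (n_sim + 1)``.  Per-SNP outlier p-values compare each observed weighted
    residual with its simulated counterparts and are flagged at the
    Bonferroni-adjusted ``outlier_alpha``.
    """
    bx, _, by, sy = _arrays(hset)
    k = len(bx)
    if k < 4:
        raise ValueError("presso_global requires >= 4 SNPs")
    if n_sim < 100:
        import warnings

        warnings.warn("presso_global: n_sim < 100 gives a very coarse p-value")
    w = 1.0 / sy**2
    pred = _loo_predictions(bx, by, w)
    e_obs = w * (by - pred) ** 2
    rss_obs = float(np.sum(e_obs))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(pred, sy, size=(n_sim, k))
    sxy_sim = by_sim @ (w * bx)
    sxx = np.sum(w * bx**2)
    beta_loo_sim = (sxy_sim[:, None] - (w * bx) * by_sim) / (sxx - w * bx**2)
    pred_sim = beta_loo_sim * bx
    e_sim = w * (by_sim - pred_sim) ** 2
    rss_sim = e_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(e_sim >= e_obs, axis=0)) / (n_sim + 1)
    snp_ids = hset.data["snp"].tolist()
    outlier_pvals = pd.Series(p_snp, index=snp_ids)
    cutoff = outlier_alpha / k
    outliers = [s for s, p in outlier_pvals.items() if p < cutoff]
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        n_simulations=n_sim,
        seed=int(seed_val),
    )


def leave_one_out(hset: HarmonizedSet, model: str | None = None) -> pd.DataFrame:
    """IVW estimates with each SNP omitted in turn.

    ``model`` (``"fixed"`` / ``"mre"``) defaults to the full fit's own
    selection: MRE when the full-fit Q is significant at 0.05, FE otherwise.
    Returns a DataFrame with one row per omitted SNP.
    """
    if len(hset) < 3:
        raise ValueError("leave_one_out requires >= 3 SNPs")
    if model is None:
        full = ivw(hset, model="fixed")
        model = "mre" if full.extra["q_pval"] < 0.05 else "fixed"
    rows = []
    for i in range(len(hset)):
        mask = np.ones(len(hset), dtype=bool)
        mask[i] = False
        est = ivw(hset.subset(mask), model=model)
        rows.append(
            {
                "snp_omitted": hset.data.at[i, "snp"],
                "method": est.method,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "n_snps": est.n_snps,
            }
        )
    return pd.DataFrame(rows)


def select_primary(
    ivw_fe: MREstimate,
    ivw_mre: MREstimate,
    egger_est: MREstimate,
    q: QTestResult,
    intercept_p: float | None = None,
    alpha: float = 0.05,
    intercept_magnitude: float = 0.01,
) -> MREstimate:
    """Pick the primary estimate by the pleiotropy/heterogeneity rule.

    MR-Egger is preferred when directional pleiotropy is declared — the
    intercept test is significant at ``alpha`` AND the intercept magnitude
    reaches ``intercept_magnitude`` (the compound reading of the
    "intercept < 0.01, p > 0.05" no-pleiotropy criterion).  Otherwise
    MRE-IVW under heterogeneity (Q p < ``alpha``), else FE-IVW.  The chosen
    estimate is returned with the reason recorded in ``extra``.
    """
    if intercept_p is None:
        intercept_p = egger_est.extra["intercept_p"]
    intercept = abs(egger_est.extra.get("intercept", np.inf))
    if intercept_p < alpha and intercept >= intercept_magnitude:
        chosen, reason = egger_est, "directional_pleiotropy"
    elif q.pval < alpha:
        chosen, reason = ivw_mre, "heterogeneity"
    else:
        chosen, reason = ivw_fe, "homogeneous"
    chosen = MREstimate(
        method=chosen.method,
        beta=chosen.beta,
        se=chosen.se,
        ci_low=chosen.ci_low,
        ci_high=chosen.ci_high,
        pval=chosen.pval,
        n_snps=chosen.n_snps,
        extra={**chosen.extra, "selection_reason": reason},
    )
    return chosen


def fit_suite(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    include_median_mode: bool = True,
) -> dict:
    """Run the full estimator suite and the selection rule on one set.

    Returns a dict with keys ``ivw_fe``, ``ivw_mre``, ``egger``, ``q``,
    ``selected`` and (when requested and k >= 3) ``weighted_median`` and
    ``weighted_mode``.  For a single SNP, returns the Wald ratio as
    ``selected`` with no diagnostics.
    """
    k = len(hset)
    if k == 0:
        raise ValueError("empty harmonized set")
    if k == 1:
        row = hset.data.iloc[0]
        est = wald_ratio(row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"])
        return {"selected": est}
    rng = np.random.default_rng(seed)
    fe = ivw(hset, model="fixed")
    mre = ivw(hset, model="mre")
    q = cochran_q(hset, reference_beta=fe.beta)
    out = {"ivw_fe": fe, "ivw_mre": mre, "q": q}
    if k >= 3:
        eg = egger(hset)
        out["egger"] = eg
        out["selected"] = select_primary(fe, mre, eg, q)
        if include_median_mode:
            out["weighted_median"] = weighted_median(hset, n_boot=n_boot, seed=rng)
            out["weighted_mode"] = weighted_mode(hset, n_boot=n_boot, seed=rng)
    else:
        # too few SNPs for Egger: fall back on the heterogeneity rule alone
        chosen = mre if q.pval < 0.05 else fe
        out["selected"] = chosen
    return out
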