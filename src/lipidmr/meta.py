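"""Random-effects meta-analysis of per-cohort MR estimates.

Pooling is DerSimonian–Laird on the log-odds scale: the closed-form moment
estimator of the between-cohort variance tau^2 with inverse-variance
weights.  Odds ratios are a reporting boundary only (see
:func:`forest_table`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate, Z95


@dataclass
class MetaResult:
    """Pooled cross-cohort estimate with heterogeneity statistics.

    ``beta``/``se`` are the random-effects pooled log-OR and its SE; ``q``
    and ``q_pval`` test heterogeneity against the fixed-effect pooled value;
    ``i2`` is the fraction of variation attributed to heterogeneity; the
    per-cohort inputs are echoed in ``table`` with their random-effects
    weights.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    tau2: float
    q: float
    q_df: int
    q_pval: float
    i2: float
    beta_fixed: float
    se_fixed: float
    k: int
    table: pd.DataFrame


def pool_random_effects(
    betas: Sequence[float] | Sequence[MREstimate],
    ses: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of >= 2 estimates.

    Accepts either parallel ``betas``/``ses`` sequences or a list of
    :class:`~lipidmr.estimators.MREstimate`.  All inputs must share scale
    (log-odds).  tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))
    with fixed-effect weights w = 1/se^2; random-effects weights are
    1/(se^2 + tau^2).
    """
    if ses is None:
        estimates = list(betas)
        betas = [e.beta for e in estimates]
        ses = [e.se for e in estimates]
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    k = len(b)
    if k < 2:
        raise ValueError("meta-analysis requires >= 2 estimates")
    if (s <= 0).any():
        raise ValueError("all standard errors must be positive")
    if labels is None:
        labels = [f"cohort_{i + 1}" for i in range(k)]

    w = 1.0 / s**2
    beta_fixed = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta_fixed) ** 2))
    q_df = k - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = float(max(0.0, (q - q_df) / c)) if c > 0 else 0.0
    i2 = float(max(0.0, (q - q_df) / q)) if q > 0 else 0.0

    w_re = 1.0 / (s**2 + tau2)
    beta_re = float(np.sum(w_re * b) / np.sum(w_re))
    se_re = float(1.0 / np.sqrt(np.sum(w_re)))
    pval = float(2 * sps.norm.sf(abs(beta_re) / se_re))

    table = pd.DataFrame(
        {
            "cohort": list(labels),
            "beta": b,
            "se": s,
            "weight_fe_pct": 100 * w / np.sum(w),
            "weight_re_pct": 100 * w_re / np.sum(w_re),
        }
    )
    return MetaResult(
        beta=beta_re,
        se=se_re,
        ci_low=beta_re - Z95 * se_re,
        ci_high=beta_re + Z95 * se_re,
        pval=pval,
        tau2=tau2,
        q=q,
        q_df=q_df,
        q_pval=float(sps.chi2.sf(q, q_df)),
        i2=i2,
        beta_fixed=beta_fixed,
        se_fixed=se_fixed,
        k=k,
        table=table,
    )


def forest_table(result: MetaResult) -> pd.DataFrame:
    """Forest-plot content as data: per-cohort OR rows plus a pooled row."""
    rows = []
    for _, r in result.table.iterrows():
        rows.append(
            {
                "cohort": r["cohort"],
                "or": np.exp(r["beta"]),
                "ci_low": np.exp(r["beta"] - Z95 * r["se"]),
                "ci_high": np.exp(r["beta"] + Z95 * r["se"]),
                "weight_pct": r["weight_re_pct"],
            }
        )
    rows.append(
        {
            "cohort": "pooled (random effects)",
            "or": np.exp(result.beta),
            "ci_low": np.exp(result.ci_low),
            "ci_high": np.exp(result.ci_high),
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
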