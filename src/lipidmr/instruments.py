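"""Instrument selection and filtering for two-sample MR.

Selection follows the conventional screen: a p-value threshold on the
exposure GWAS, greedy LD clumping (r-squared + distance window), removal of
variants directly associated with the outcome, and Steiger directionality
filtering.  MR-PRESSO outlier removal lives in :mod:`lipidmr.estimators`
and is invoked from the pipeline; its flags are recorded alongside these.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import HarmonizedSet, SummaryStats

log = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise r-squared between named SNPs (symmetric, unit diagonal)."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if (self.r2 < 0).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r-squared values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        ids = list(snp_ids)
        return cls(ids, np.eye(len(ids)))

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )

    def lookup(self, a: str, b: str) -> float:
        """r-squared between two SNPs; unknown SNPs are treated as unlinked."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


def threshold_instruments(stats: SummaryStats, p_threshold: float) -> SummaryStats:
    """Keep SNPs with exposure p-value strictly below ``p_threshold``."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    keep = stats.data["pval"] < p_threshold
    return replace(stats, data=stats.data.loc[keep].reset_index(drop=True))


def clump(
    stats: SummaryStats,
    ld: LDMatrix | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryStats:
    """Greedy LD clumping: keep index SNPs in ascending p-value order.

    The best remaining SNP becomes an index; every remaining SNP on the same
    chromosome within ``window_kb`` of it with r-squared >= ``r2_threshold``
    is removed.  Ties on p-value break by snp id (lexicographic) so output
    is deterministic.  SNPs absent from ``ld`` are treated as unlinked.
    """
    df = stats.data
    if df.empty:
        return replace(stats, data=df.copy())
    if ld is not None:
        unknown = [s for s in df["snp"] if s not in ld._index]
        if unknown:
            log.warning("clump: %d SNP(s) missing from LD matrix, treated as unlinked", len(unknown))
    order = df.sort_values(["pval", "snp"], kind="mergesort").index.to_list()
    window_bp = window_kb * 1_000
    removed: set[int] = set()
    index_rows: list[int] = []
    for i in order:
        if i in removed:
            continue
        index_rows.append(i)
        for j in order:
            if j == i or j in removed:
                continue
            same_chr = df.at[i, "chr"] == df.at[j, "chr"]
            near = abs(df.at[i, "pos"] - df.at[j, "pos"]) <= window_bp
            r2 = ld.lookup(df.at[i, "snp"], df.at[j, "snp"]) if ld is not None else 0.0
            if same_chr and near and r2 >= r2_threshold:
                removed.add(j)
    keep = df.loc[sorted(index_rows)]
    return replace(stats, data=keep.reset_index(drop=True))


def filter_outcome_associated(
    hset: HarmonizedSet, outcome_p_threshold: float = 5e-5
) -> tuple[HarmonizedSet, list[str]]:
    """Remove variants directly associated with the outcome.

    The outcome p-value is recomputed as a two-sided normal test of
    ``beta_out / se_out``; rows with p strictly below the threshold are
    dropped.  Returns the filtered set and the dropped snp ids.
    """
    z = np.abs(hset.data["beta_out"] / hset.data["se_out"])
    p = 2 * sps.norm.sf(z)
    drop = p < outcome_p_threshold
    dropped = hset.data.loc[drop, "snp"].tolist()
    return hset.subset(~drop), dropped


def steiger_filter(
    hset: HarmonizedSet,
    n_exp: float | None = None,
    n_out: float | None = None,
) -> tuple[HarmonizedSet, list[str]]:
    """Drop variants explaining more outcome than exposure variance.

    Variance explained is approximated per trait as ``t^2 / (t^2 + n - 2)``
    with ``t = beta / se`` (log-odds treated as continuous).  Rows with
    strictly greater outcome r-squared are removed.  Sample sizes default to
    the per-row ``n_exp`` / ``n_out`` columns.
    """
    d = hset.data
    ne = d["n_exp"] if n_exp is None else n_exp
    no = d["n_out"] if n_out is None else n_out
    if np.any(np.asarray(ne) <= 2) or np.any(np.asarray(no) <= 2):
        raise ValueError("Steiger filtering requires sample sizes > 2")
    t_exp = (d["beta_exp"] / d["se_exp"]) ** 2
    t_out = (d["beta_out"] / d["se_out"]) ** 2
    r2_exp = t_exp / (t_exp + ne - 2)
    r2_out = t_out / (t_out + no - 2)
    drop = r2_out > r2_exp
    dropped = d.loc[drop, "snp"].tolist()
    return hset.subset(~drop), dropped


def f_statistic(beta_exp, se_exp):
    """Per-SNP instrument-strength F statistic, ``(beta / se)^2``.

    Reported as a diagnostic only; no F cutoff is applied in selection.
    """
    return (np.asarray(beta_exp, dtype=float) / np.asarray(se_exp, dtype=float)) ** 2


@dataclass
class InstrumentSet:
    """A filtered harmonized set plus per-SNP selection provenance.

    ``provenance`` has one row per candidate SNP that entered selection with
    boolean stage flags (``passed_p``, ``clump_index``, ``outcome_filtered``,
    ``steiger_dropped``, ``presso_dropped``) and the per-SNP F statistic, so
    retained + dropped counts reconstruct the candidate total exactly.
    """

    hset: HarmonizedSet
    provenance: pd.DataFrame
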