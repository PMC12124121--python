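"""Reading, writing and harmonizing GWAS summary statistics.

Summary statistics are carried as a :class:`SummaryStats` record: one row
per SNP with the canonical columns ``snp, chr, pos, ea, oa, eaf, beta, se,
pval, n``.  Files are tab-separated UTF-8 with ``.`` decimals (gzip is
transparent); other headers are supported through a column map.

Harmonization aligns an exposure/outcome pair of summary-statistics tables
to a common effect allele, resolving allele swaps and strand flips and
orienting or dropping palindromic (A/T, C/G) variants by allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

#: Canonical column order of the summary-statistics dialect.
COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonization outcomes for one SNP.
ACTION_NONE = "none"
ACTION_FLIPPED = "flipped"            # strand complement only
ACTION_SWAPPED = "swapped"            # effect/other alleles exchanged (maybe + strand)
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_MISMATCH = "dropped_mismatch"


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(COMPLEMENT)


@dataclass
class SummaryStats:
    """Per-SNP GWAS association records for one trait on one scale.

    Parameters
    ----------
    trait_id
        Trait label (e.g. ``"sterol_ester_27:1/14:0"``).
    trait_type
        ``"continuous"`` (linear betas) or ``"binary"`` (log-odds betas).
    data
        DataFrame with the canonical columns; one row per SNP.
    n_rejected
        Number of malformed rows discarded while reading.
    """

    trait_id: str
    trait_type: str
    data: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        df = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate snp ids: {dups[:5]}")
        if (df["se"] <= 0).any():
            raise ValueError("all standard errors must be strictly positive")
        if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
            raise ValueError("effect-allele frequencies must lie in (0, 1)")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def subset(self, snp_ids) -> "SummaryStats":
        """Return a new SummaryStats restricted to ``snp_ids`` (order preserved)."""
        keep = self.data["snp"].isin(set(snp_ids))
        return replace(self, data=self.data.loc[keep].reset_index(drop=True))


@dataclass
class HarmonizedSet:
    """Exposure/outcome SNP pairs aligned to a common effect allele.

    ``data`` holds retained rows only; ``actions`` records the harmonization
    action for every SNP in the intersection, including dropped ones, so the
    action counts partition the intersection exactly.
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    actions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp", "action"]))
    exposure_type: str = "continuous"
    outcome_type: str = "binary"

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "HarmonizedSet":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))


def read_summary_stats(
    path,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    column_map: Mapping[str, str] | None = None,
) -> SummaryStats:
    """Read a summary-statistics TSV into a validated :class:`SummaryStats`.

    ``column_map`` maps canonical names to the file's header names (e.g.
    ``{"snp": "rsid", "pval": "p"}``) for non-default dialects.  Rows with
    non-finite or non-positive standard errors, non-finite betas, or
    out-of-range frequencies/p-values are rejected with a logged warning;
    a missing mandatory column is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "ea": str, "oa": str})
    if column_map:
        rename = {file_col: canon for canon, file_col in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = df.loc[:, list(COLUMNS)]

    numeric = ["eaf", "beta", "se", "pval", "n"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = (
        ~np.isfinite(df["beta"])
        | ~np.isfinite(df["se"])
        | (df["se"] <= 0)
        | (df["eaf"] <= 0)
        | (df["eaf"] >= 1)
        | (df["pval"] <= 0)
        | (df["pval"] > 1)
        | df[numeric].isna().any(axis=1)
    )
    n_rejected = int(bad.sum())
    if n_rejected:
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        log.warning("%s: rejected %d malformed row(s) at line(s) %s", path, n_rejected, lines[:10])
        df = df.loc[~bad]
    return SummaryStats(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        data=df.reset_index(drop=True),
        n_rejected=n_rejected,
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write ``stats`` in the canonical TSV dialect (gzip if path ends .gz)."""
    stats.data.to_csv(path, sep="\t", index=False)


def swap_alleles(data: pd.DataFrame, mask) -> pd.DataFrame:
    """Exchange effect/other alleles on ``mask`` rows, negating beta and
    reflecting eaf so the record describes the same association."""
    out = data.copy()
    ea = out.loc[mask, "ea"].copy()
    out.loc[mask, "ea"] = out.loc[mask, "oa"]
    out.loc[mask, "oa"] = ea
    out.loc[mask, "beta"] = -out.loc[mask, "beta"]
    out.loc[mask, "eaf"] = 1.0 - out.loc[mask, "eaf"]
    return out


def flip_strand(data: pd.DataFrame, mask) -> pd.DataFrame:
    """Complement both alleles on ``mask`` rows (statistics unchanged)."""
    out = data.copy()
    out.loc[mask, "ea"] = out.loc[mask, "ea"].map(COMPLEMENT)
    out.loc[mask, "oa"] = out.loc[mask, "oa"].map(COMPLEMENT)
    return out


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_maf_limit: float = 0.42,
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect alleles.

    SNPs are intersected on id.  Outcome records whose alleles are swapped
    relative to the exposure have their beta sign and frequency inverted;
    strand-complement matches are complemented; palindromic variants are kept
    with frequency-based orientation only when both traits' minor-allele
    frequencies are below ``palindrome_maf_limit``, otherwise dropped.  Allele
    pairs that cannot be reconciled are dropped as mismatches.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize requires non-empty exposure and outcome sets")
    m = exposure.data.merge(outcome.data, on="snp", suffixes=("_exp", "_out"))
    if m.empty:
        raise ValueError(
            f"no overlapping SNPs between exposure {exposure.trait_id!r} "
            f"and outcome {outcome.trait_id!r}"
        )

    ea_e, oa_e = m["ea_exp"], m["oa_exp"]
    ea_o, oa_o = m["ea_out"], m["oa_out"]
    cea_o, coa_o = _complement(ea_o), _complement(oa_o)

    palindromic = ea_e == oa_e.map(COMPLEMENT)

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    strand = (cea_o == ea_e) & (coa_o == oa_e)
    strand_swapped = (cea_o == oa_e) & (coa_o == ea_e)

    action = pd.Series(ACTION_DROPPED_MISMATCH, index=m.index)
    need_swap = pd.Series(False, index=m.index)

    np_mask = ~palindromic
    action[np_mask & same] = ACTION_NONE
    action[np_mask & swapped] = ACTION_SWAPPED
    need_swap[np_mask & swapped] = True
    action[np_mask & strand & ~same & ~swapped] = ACTION_FLIPPED
    action[np_mask & strand_swapped & ~same & ~swapped] = ACTION_SWAPPED
    need_swap[np_mask & strand_swapped & ~same & ~swapped] = True

    # Palindromic: alleles are strand-ambiguous; orient by allele frequency
    # when both frequencies are clearly away from 0.5.
    pal_same_set = palindromic & (same | swapped | strand | strand_swapped)
    informative = (
        np.minimum(m["eaf_exp"], 1 - m["eaf_exp"]) < palindrome_maf_limit
    ) & (np.minimum(m["eaf_out"], 1 - m["eaf_out"]) < palindrome_maf_limit)
    aligned = (m["eaf_exp"] < 0.5) == (m["eaf_out"] < 0.5)
    action[pal_same_set & informative & aligned] = ACTION_NONE
    action[pal_same_set & informative & ~aligned] = ACTION_SWAPPED
    need_swap[pal_same_set & informative & ~aligned] = True
    action[pal_same_set & ~informative] = ACTION_DROPPED_PALINDROMIC

    beta_out = m["beta_out"].where(~need_swap, -m["beta_out"])
    eaf_out = m["eaf_out"].where(~need_swap, 1 - m["eaf_out"])

    keep = ~action.isin([ACTION_DROPPED_PALINDROMIC, ACTION_DROPPED_MISMATCH])
    data = pd.DataFrame(
        {
            "snp": m["snp"],
            "chr": m["chr_exp"],
            "pos": m["pos_exp"],
            "ea": ea_e,
            "oa": oa_e,
            "eaf": m["eaf_exp"],
            "eaf_out": eaf_out,
            "beta_exp": m["beta_exp"],
            "se_exp": m["se_exp"],
            "pval_exp": m["pval_exp"],
            "n_exp": m["n_exp"],
            "beta_out": beta_out,
            "se_out": m["se_out"],
            "pval_out": m["pval_out"],
            "n_out": m["n_out"],
            "action": action,
        }
    ).loc[keep].reset_index(drop=True)

    actions = pd.DataFrame({"snp": m["snp"], "action": action})
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        data=data,
        actions=actions,
        exposure_type=exposure.trait_type,
        outcome_type=outcome.trait_type,
    )
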