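"""Shared construction helpers for the test suite."""

import numpy as np
import pandas as pd

from lipidmr import HarmonizedSet, SummaryStats


def make_hset(beta_exp, se_exp, beta_out, se_out, n_exp=100_000, n_out=100_000):
    """Build a HarmonizedSet directly from effect arrays."""
    k = len(beta_exp)
    data = pd.DataFrame(
        {
            "snp": [f"rs{i:04d}" for i in range(k)],
            "chr": 1,
            "pos": np.arange(k) * 1_000_000 + 1,
            "ea": "A",
            "oa": "G",
            "eaf": 0.3,
            "eaf_out": 0.3,
            "beta_exp": np.asarray(beta_exp, float),
            "se_exp": np.asarray(se_exp, float),
            "pval_exp": 1e-8,
            "n_exp": n_exp,
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
            "pval_out": 0.5,
            "n_out": n_out,
            "action": "none",
        }
    )
    return HarmonizedSet(exposure_id="x", outcome_id="y", data=data)


def make_stats(trait_id="trait", trait_type="continuous", **columns):
    """Build SummaryStats from column overrides on a simple default frame."""
    k = len(next(iter(columns.values())))
    base = {
        "snp": [f"rs{i:04d}" for i in range(k)],
        "chr": [1] * k,
        "pos": [1_000_000 * (i + 1) for i in range(k)],
        "ea": ["A"] * k,
        "oa": ["G"] * k,
        "eaf": [0.3] * k,
        "beta": [0.1] * k,
        "se": [0.01] * k,
        "pval": [1e-8] * k,
        "n": [100_000] * k,
    }
    base.update(columns)
    return SummaryStats(trait_id=trait_id, trait_type=trait_type, data=pd.DataFrame(base))
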