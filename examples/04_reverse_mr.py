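"""Reverse MR: does the outcome causally move the lipids?

Uses each outcome cohort as the exposure (stricter instrument threshold,
p < 5e-8) against each lipid.  In this study the outcome has no causal
effect on any lipid, so reverse estimates should be null — and cohorts
usually lack enough genuine instruments, which is itself the expected
answer and is recorded rather than raised.
"""

from lipidmr import MRParams, SimConfig, run_reverse
from lipidmr.simulate import simulate_study

lipids, cohorts, _ = simulate_study(
    {"se_27_1_14_0": 0.25, "se_27_1_16_0": 0.2}, n_cohorts=2,
    config=SimConfig(n_snps=25), seed=19,
)

table = run_reverse(cohorts, lipids, MRParams(include_median_mode=False), seed=2)
cols = ["exposure", "outcome", "status", "method", "n_snps", "or", "pval"]
print(table[cols].round(3).to_string(index=False))
# "insufficient_instruments" rows mean the cohort had no independent
# genome-wide-significant SNPs left after filtering (Steiger removes SNPs
# whose association is really with the lipid); any fitted rows should have
# p > 0.05 since no reverse effect was simulated.
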