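"""Generate a synthetic GWAS triplet and inspect the ground truth.

The generator emits exposure, mediator and outcome summary statistics for a
shared SNP panel under a known causal graph (exposure -> mediator ->
outcome), so every downstream method can be checked by parameter recovery.
"""

from lipidmr import SimConfig, simulate_triplet

cfg = SimConfig(
    n_snps=50,
    theta_total=0.2,   # total causal effect, log-odds per exposure SD
    a_true=0.5,        # exposure -> mediator
    b_true=0.4,        # mediator -> outcome
    seed=1,
)
exposure, mediator, outcome, truth = simulate_triplet(cfg)

print(exposure.data.head().to_string(index=False))
print(f"\npanel: {cfg.n_snps} SNPs, exposure GWAS n={cfg.n_exposure:,}")
print(f"median per-SNP exposure z: {abs(exposure.data.beta / exposure.data.se).median():.1f}")
ratios = outcome.data["beta"] / exposure.data["beta"]
print(f"mean raw Wald ratio: {ratios.mean():.3f}  (true total effect {cfg.theta_total})")
# Each Wald ratio estimates theta_total; sampling noise in both GWAS spreads
# them around 0.2, which is what the IVW estimator then averages away.
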