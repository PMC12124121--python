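"""One exposure-outcome MR analysis: harmonize, fit the estimator suite,
read the diagnostics.

Prints the IVW (fixed and multiplicative random effects), MR-Egger,
weighted-median and weighted-mode estimates with the heterogeneity Q test,
the Egger intercept test and the MR-PRESSO global p — then the primary
estimate chosen by the selection rule (Egger under directional pleiotropy,
MRE-IVW under heterogeneity, FE-IVW otherwise).
"""

import numpy as np

from lipidmr import SimConfig, fit_suite, harmonize, presso_global, simulate_triplet

exposure, _, outcome, _ = simulate_triplet(SimConfig(n_snps=50, theta_total=0.2, seed=7))
hset = harmonize(exposure, outcome)
print(f"harmonized {len(hset)} SNPs "
      f"(actions: {hset.actions['action'].value_counts().to_dict()})\n")

fits = fit_suite(hset, n_boot=1000, seed=3)
for key in ("ivw_fe", "ivw_mre", "egger", "weighted_median", "weighted_mode"):
    e = fits[key]
    print(f"{e.method:16s} beta={e.beta:+.4f}  se={e.se:.4f}  "
          f"OR={e.odds_ratio:.3f} ({e.or_ci[0]:.3f}-{e.or_ci[1]:.3f})  p={e.pval:.2e}")

q = fits["q"]
eg = fits["egger"].extra
presso = presso_global(hset, n_sim=1000, seed=5)
print(f"\nCochran Q = {q.q:.1f} (df {q.df}, p = {q.pval:.3f})")
print(f"Egger intercept = {eg['intercept']:+.5f} (p = {eg['intercept_p']:.3f})")
print(f"MR-PRESSO global p = {presso.global_p:.3f}, outliers: {presso.outliers or 'none'}")
sel = fits["selected"]
print(f"\nselected primary: {sel.method} ({sel.extra['selection_reason']}), "
      f"OR = {sel.odds_ratio:.3f}, true OR = {np.exp(0.2):.3f}")
# With clean homogeneous instruments the rule keeps fixed-effect IVW and the
# estimate sits on the simulated truth.
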