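"""Parameter-recovery and calibration experiments on synthetic GWAS panels.

Each function runs a replicated simulation under the generator's study
conditions and summarizes estimator behaviour: type-I error and diagnostic
calibration under the null, recovery of causal effects and of directional
pleiotropy, MR-PRESSO outlier detection, mediation-proportion recovery and
cross-cohort meta-analysis recovery.  These drive the validation suite and
the reproduction script; they are also the quickest way to study how the
estimators behave as the generative settings move.

Seeds: every experiment takes one integer seed and derives per-replicate
seeds from it deterministically, so results are reproducible and replicates
are independent.
"""

from __future__ import annotations

import numpy as np

from .estimators import cochran_q, egger, ivw, presso_global, select_primary
from .gwas_io import harmonize
from .instruments import threshold_instruments
from .mediation import two_step_mediation
from .meta import pool_random_effects
from .simulate import SimConfig, simulate_triplet


def _child_seeds(seed: int, n: int) -> np.ndarray:
    # keep derived seeds in int32 range
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _core_fits(cfg: SimConfig):
    exposure, _, outcome, _ = simulate_triplet(cfg)
    hset = harmonize(exposure, outcome)
    fe = ivw(hset, "fixed")
    mre = ivw(hset, "mre")
    eg = egger(hset)
    q = cochran_q(hset, reference_beta=fe.beta)
    selected = select_primary(fe, mre, eg, q)
    return hset, fe, mre, eg, q, selected


def null_calibration(
    n_reps: int = 1000, seed: int = 0, n_snps: int = 50, n_samples: int = 100_000
) -> dict:
    """Type-I error of the selected primary estimate and rejection rates of
    the Cochran-Q and Egger-intercept diagnostics under a global null
    (no causal effect, no pleiotropy).  All three should sit near 0.05."""
    seeds = _child_seeds(seed, n_reps)
    rej = q_rej = int_rej = 0
    for s in seeds:
        cfg = SimConfig(
            n_snps=n_snps, n_exposure=n_samples, n_mediator=n_samples,
            n_outcome=n_samples, theta_total=0.0, seed=int(s),
        )
        _, fe, mre, eg, q, selected = _core_fits(cfg)
        rej += selected.pval < 0.05
        q_rej += q.pval < 0.05
        int_rej += eg.extra["intercept_p"] < 0.05
    return {
        "n_reps": n_reps,
        "type1_error": rej / n_reps,
        "q_rejection": q_rej / n_reps,
        "egger_intercept_rejection": int_rej / n_reps,
    }


def effect_recovery(
    n_reps: int = 1000, seed: int = 0, theta: float = 0.2,
    n_snps: int = 50, n_samples: int = 100_000,
) -> dict:
    """Bias and 95% CI coverage of fixed-effect IVW under a homogeneous
    causal effect with strong instruments."""
    seeds = _child_seeds(seed + 1, n_reps)
    betas = np.empty(n_reps)
    covered = 0
    for i, s in enumerate(seeds):
        cfg = SimConfig(
            n_snps=n_snps, n_exposure=n_samples, n_mediator=n_samples,
            n_outcome=n_samples, theta_total=theta, seed=int(s),
        )
        _, fe, *_ = _core_fits(cfg)
        betas[i] = fe.beta
        covered += fe.ci_low <= theta <= fe.ci_high
    return {
        "n_reps": n_reps,
        "theta_true": theta,
        "mean_estimate": float(betas.mean()),
        "mcse": float(betas.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
    }


def pleiotropy_recovery(
    n_reps: int = 500, seed: int = 0, theta: float = 0.2,
    pleiotropy_mean: float = 0.05, pleiotropy_sd: float = 0.02,
    n_snps: int = 50, n_samples: int = 100_000,
) -> dict:
    """Recovery of a directional-pleiotropy intercept by MR-Egger, alongside
    the bias it induces in IVW."""
    seeds = _child_seeds(seed + 2, n_reps)
    intercepts = np.empty(n_reps)
    ivw_betas = np.empty(n_reps)
    for i, s in enumerate(seeds):
        cfg = SimConfig(
            n_snps=n_snps, n_exposure=n_samples, n_mediator=n_samples,
            n_outcome=n_samples, theta_total=theta,
            pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=pleiotropy_sd,
            seed=int(s),
        )
        _, fe, _, eg, _, _ = _core_fits(cfg)
        intercepts[i] = eg.extra["intercept"]
        ivw_betas[i] = fe.beta
    return {
        "n_reps": n_reps,
        "pleiotropy_true": pleiotropy_mean,
        "mean_intercept": float(intercepts.mean()),
        "intercept_mcse": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "mean_ivw": float(ivw_betas.mean()),
        "ivw_mcse": float(ivw_betas.std(ddof=1) / np.sqrt(n_reps)),
        "theta_true": theta,
    }


def presso_spike_in(
    n_reps: int = 100, seed: int = 0, offset_se: float = 10.0,
    n_snps: int = 50, n_sim: int = 1000, n_samples: int = 100_000,
) -> dict:
    """One pleiotropic outlier (outcome beta shifted by ``offset_se`` times
    its SE) among otherwise clean instruments: how often MR-PRESSO ranks it
    as the top outlier and rejects globally at p <= 0.01."""
    seeds = _child_seeds(seed + 3, n_reps)
    top = glob = 0
    for s in seeds:
        cfg = SimConfig(
            n_snps=n_snps, n_exposure=n_samples, n_mediator=n_samples,
            n_outcome=n_samples, theta_total=0.2, seed=int(s),
        )
        exposure, _, outcome, _ = simulate_triplet(cfg)
        hset = harmonize(exposure, outcome)
        spike = int(s) % n_snps
        hset.data.loc[spike, "beta_out"] += offset_se * hset.data.loc[spike, "se_out"]
        res = presso_global(hset, n_sim=n_sim, outlier_alpha=0.05, seed=int(s) + 1)
        top += res.outlier_pvals.idxmin() == hset.data.loc[spike, "snp"]
        glob += res.global_p <= 0.01
    return {
        "n_reps": n_reps,
        "top_outlier_rate": top / n_reps,
        "global_p_le_0.01_rate": glob / n_reps,
    }


def mediation_recovery(
    n_reps: int = 500, seed: int = 0, a_true: float = 0.5, b_true: float = 0.4,
    theta_total: float = 0.25, n_snps: int = 60, n_samples: int = 100_000,
    p_instrument: float = 5e-6, p_exclude: float = 5e-5,
) -> dict:
    """Recovery of the mediated proportion by two-step MR.

    Half the panel instruments the exposure, half the mediator.  Per
    replicate: instruments are selected by significance in the respective
    GWAS; exposure-associated SNPs are excluded from the mediator's
    instruments; a, b and c come from fixed-effect IVW and feed the
    product-method decomposition.  True proportion is
    ``a_true * b_true / theta_total``.
    """
    true_prop = a_true * b_true / theta_total
    seeds = _child_seeds(seed + 4, n_reps)
    props = np.empty(n_reps)
    covered = 0
    identity_err = 0.0
    for i, s in enumerate(seeds):
        cfg = SimConfig(
            n_snps=n_snps, mediator_snp_fraction=0.5,
            n_exposure=n_samples, n_mediator=n_samples, n_outcome=n_samples,
            a_true=a_true, b_true=b_true, theta_total=theta_total, seed=int(s),
        )
        exposure, mediator, outcome, _ = simulate_triplet(cfg)
        exp_iv = threshold_instruments(exposure, p_instrument)
        c = ivw(harmonize(exp_iv, outcome), "fixed")
        a = ivw(harmonize(exp_iv, mediator), "fixed")
        med_iv = threshold_instruments(mediator, p_instrument)
        assoc = set(exposure.data.loc[exposure.data["pval"] < p_exclude, "snp"])
        med_iv = med_iv.subset([x for x in med_iv.data["snp"] if x not in assoc])
        b = ivw(harmonize(med_iv, outcome), "fixed")
        m = two_step_mediation(a.beta, a.se, b.beta, b.se, c.beta, c.se)
        props[i] = m.proportion
        covered += m.ci_low <= true_prop <= m.ci_high
        identity_err = max(identity_err, abs(m.indirect + m.direct - m.c))
    return {
        "n_reps": n_reps,
        "proportion_true": true_prop,
        "mean_proportion": float(props.mean()),
        "mcse": float(props.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
        "identity_max_abs_error": float(identity_err),
    }


def meta_recovery(
    n_reps: int = 500, seed: int = 0, theta: float = 0.15,
    between_cohort_sd: float = 0.05, n_cohorts: int = 4,
    n_snps: int = 50, n_samples: int = 100_000,
) -> dict:
    """Recovery of the pooled effect and of tau^2 by DerSimonian-Laird
    pooling of per-cohort IVW estimates under genuine between-cohort
    heterogeneity (per-cohort effects ``N(theta, between_cohort_sd^2)``)."""
    rng = np.random.default_rng(seed + 5)
    seeds = _child_seeds(seed + 6, n_reps * n_cohorts).reshape(n_reps, n_cohorts)
    pooled = np.empty(n_reps)
    tau2s = np.empty(n_reps)
    for i in range(n_reps):
        thetas = rng.normal(theta, between_cohort_sd, n_cohorts)
        ests = []
        for j in range(n_cohorts):
            cfg = SimConfig(
                n_snps=n_snps, n_exposure=n_samples, n_mediator=n_samples,
                n_outcome=n_samples, theta_total=float(thetas[j]),
                seed=int(seeds[i, j]),
            )
            exposure, _, outcome, _ = simulate_triplet(cfg)
            ests.append(ivw(harmonize(exposure, outcome), "fixed"))
        res = pool_random_effects(ests)
        pooled[i] = res.beta
        tau2s[i] = res.tau2
    return {
        "n_reps": n_reps,
        "theta_true": theta,
        "tau2_true": between_cohort_sd**2,
        "pooled_mean": float(pooled.mean()),
        "pooled_mcse": float(pooled.std(ddof=1) / np.sqrt(n_reps)),
        "tau2_mean": float(tau2s.mean()),
        "tau2_mcse": float(tau2s.std(ddof=1) / np.sqrt(n_reps)),
    }
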