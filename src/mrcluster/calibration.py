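"""Monte-Carlo calibration studies over the synthetic generator.

These are the repeated-simulation harnesses behind the package's own
validation: null type-I error of each estimator, MR-PRESSO null rejection
rate, Egger-versus-IVW bias under directional pleiotropy, weighted-median
robustness under invalid-instrument contamination, planted-subset recovery
for MR-BMA, and end-to-end mediated-proportion recovery. Every study reads
its truth from the generator's record, never from constants, and streams
all randomness from one root seed.

Bootstrap SEs inside the repeated studies use 200 replicates (the single-fit
default is 1000): across hundreds of repetitions the bootstrap noise
averages out, and this keeps each full study in the tens of seconds.
"""

from __future__ import annotations

import numpy as np

from .estimators import egger, ivw_mre, weighted_median, weighted_mode
from .instruments import HarmonizedInstrument
from .mediation import two_step
from .mrbma import BMAConfig, JointInstrumentMatrix, mip_and_mace, model_posteriors
from .sensitivity import presso
from .synthdata import ScenarioConfig, simulate_mediation, simulate_multivariable, simulate_tsmr_pair

CAL_N_BOOT = 200


def harmonized_from_truth(
    exposure, outcome, drop_quirks: bool = True
) -> list[HarmonizedInstrument]:
    """Pair simulated panels sharing variant ids directly (no allele quirks)."""
    out = outcome.lookup()
    hs = []
    for v in exposure.variants:
        o = out[v.variant_id]
        hs.append(HarmonizedInstrument(v.variant_id, v.beta, v.se, o.beta, o.se, "aligned"))
    return hs


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def null_type1_error(
    n_reps: int = 500,
    J: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    n_boot: int = CAL_N_BOOT,
) -> dict[str, float]:
    """Empirical rejection rate of each estimator on θ=0, no-pleiotropy data."""
    rejections = {m: 0 for m in ("ivw_mre", "egger", "weighted_median", "weighted_mode")}
    for rep_seed in _seeds(seed, n_reps):
        cfg = ScenarioConfig(seed=int(rep_seed), J=J, theta=0.0, pleiotropy="none")
        exposure, outcome, _ = simulate_tsmr_pair(cfg)
        hs = harmonized_from_truth(exposure, outcome)
        fits = {
            "ivw_mre": ivw_mre(hs),
            "egger": egger(hs),
            "weighted_median": weighted_median(hs, n_boot=n_boot, seed=int(rep_seed) + 1),
            "weighted_mode": weighted_mode(hs, n_boot=n_boot, seed=int(rep_seed) + 2),
        }
        for m, f in fits.items():
            rejections[m] += f.pval < alpha
    return {m: r / n_reps for m, r in rejections.items()}


def presso_null_rate(
    n_reps: int = 200,
    J: int = 20,
    theta: float = 0.3,
    n_sim: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of null datasets where the PRESSO global test rejects."""
    hits = 0
    for rep_seed in _seeds(seed, n_reps):
        cfg = ScenarioConfig(seed=int(rep_seed), J=J, theta=theta, pleiotropy="none")
        exposure, outcome, _ = simulate_tsmr_pair(cfg)
        hs = harmonized_from_truth(exposure, outcome)
        rec = presso(hs, n_sim=n_sim, seed=int(rep_seed) + 1)
        hits += rec.global_pval < alpha
    return hits / n_reps


def directional_pleiotropy_bias(
    n_reps: int = 500,
    J: int = 50,
    theta: float = 0.2,
    seed: int = 0,
) -> dict[str, float]:
    """Mean IVW and Egger estimates under directional pleiotropy with InSIDE."""
    ivw_est, egger_est = [], []
    theta_true = None
    for rep_seed in _seeds(seed, n_reps):
        cfg = ScenarioConfig(seed=int(rep_seed), J=J, theta=theta, pleiotropy="directional")
        exposure, outcome, truth = simulate_tsmr_pair(cfg)
        theta_true = truth["theta"]
        hs = harmonized_from_truth(exposure, outcome)
        ivw_est.append(ivw_mre(hs).estimate)
        egger_est.append(egger(hs).estimate)
    return {
        "theta": theta_true,
        "ivw_mean": float(np.mean(ivw_est)),
        "egger_mean": float(np.mean(egger_est)),
        "ivw_bias": float(np.mean(ivw_est) - theta_true),
        "egger_bias": float(np.mean(egger_est) - theta_true),
        "egger_mc_se": float(np.std(egger_est, ddof=1) / np.sqrt(n_reps)),
    }


def contaminated_median_recovery(
    n_reps: int = 500,
    J: int = 50,
    theta: float = 0.2,
    invalid_fraction: float = 0.4,
    pleiotropy_effect: float = 0.15,
    seed: int = 0,
) -> dict[str, float]:
    """Weighted-median mean estimate with a minority of pleiotropic instruments.

    The invalid minority carries balanced (mean-zero, alternating-sign)
    pleiotropic shifts several outcome-SEs wide: each contaminated
    instrument is individually invalid, while more than half the weight
    stays on valid instruments — the weighted median's consistency regime.
    """
    estimates = []
    n_invalid = int(round(invalid_fraction * J))
    for rep_seed in _seeds(seed, n_reps):
        cfg = ScenarioConfig(seed=int(rep_seed), J=J, theta=theta, pleiotropy="none")
        exposure, outcome, truth = simulate_tsmr_pair(cfg)
        hs = harmonized_from_truth(exposure, outcome)
        contaminated = []
        for i, h in enumerate(hs):
            if i < n_invalid:
                shift = pleiotropy_effect * (1 if i % 2 else -1)
                h = HarmonizedInstrument(
                    h.variant_id, h.beta_exp, h.se_exp,
                    h.beta_out + shift, h.se_out, h.action,
                )
            contaminated.append(h)
        estimates.append(
            weighted_median(contaminated, n_boot=CAL_N_BOOT, seed=int(rep_seed)).estimate
        )
    return {
        "theta": theta,
        "median_mean": float(np.mean(estimates)),
        "mc_se": float(np.std(estimates, ddof=1) / np.sqrt(n_reps)),
    }


def bma_planted_recovery(
    n_reps: int = 100,
    d: int = 8,
    J: int = 60,
    exposure_corr: float = 0.5,
    true_subset: tuple[int, ...] = (0, 1),
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of reps where the causal exposures occupy the top MIP ranks."""
    hits = 0
    bma_cfg = BMAConfig()
    for rep_seed in _seeds(seed, n_reps):
        cfg = ScenarioConfig(
            seed=int(rep_seed), J=J, n_exposures=d,
            true_subset=true_subset, exposure_corr=exposure_corr,
        )
        panels, outcome, truth = simulate_multivariable(cfg)
        matrix = _matrix_from_panels(panels, outcome)
        posteriors, estimates = model_posteriors(matrix, bma_cfg)
        mip, _ = mip_and_mace(posteriors, estimates, d)
        top = set(np.argsort(-mip)[: len(true_subset)])
        hits += top == set(truth["true_subset"])
    return {"recovery_rate": hits / n_reps, "n_reps": n_reps}


def _matrix_from_panels(panels, outcome) -> JointInstrumentMatrix:
    """Assemble the joint matrix directly for panels sharing all variant ids."""
    out = outcome.lookup()
    ids = [v.variant_id for v in panels[0].variants]
    beta_x = np.array([[p.lookup()[i].beta for p in panels] for i in ids])
    se_x = np.array([[p.lookup()[i].se for p in panels] for i in ids])
    beta_y = np.array([out[i].beta for i in ids])
    se_y = np.array([out[i].se for i in ids])
    return JointInstrumentMatrix(ids, [p.trait_id for p in panels],
                                 beta_x, se_x, beta_y, se_y)


def mediation_recovery(
    beta1: float = 0.3,
    beta2: float = 0.5,
    direct: float = 0.1,
    J: int = 60,
    se_x: float = 0.01,
    se_y: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Recovered mediated proportion on one small-SE mediation chain."""
    cfg = ScenarioConfig(
        seed=seed, J=J, J_mediator=40, mediation=(beta1, beta2, direct),
        se_x=se_x, se_y=se_y,
    )
    exposure, mediator, outcome, truth = simulate_mediation(cfg)
    from .synthdata import default_study_ld

    res = two_step(exposure, mediator, outcome, default_study_ld([]),
                   seed=seed + 1, n_boot=CAL_N_BOOT)
    return {
        "proportion": res.proportion,
        "truth": truth["proportion"],
        "beta1": res.beta1, "beta2": res.beta2, "beta3": res.beta3,
    }
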