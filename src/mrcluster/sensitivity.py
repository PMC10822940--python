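"""Sensitivity battery for two-sample MR and the robustness verdict.

Covers Cochran's Q heterogeneity, leave-one-out influence, the Steiger
directionality test with per-variant filtering, an MR-PRESSO-style
residual-sum-of-squares outlier procedure, and the rule that combines
them (with the secondary-estimator sign pattern) into a verdict of
``robust``, ``caution`` or ``rejected`` that gates downstream
multivariable and mediation analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MRFit, ivw_mre
from .instruments import HarmonizedInstrument


@dataclass
class SteigerRecord:
    direction: str  # forward | reverse
    pval: float
    r2_exp: dict[str, float]
    r2_out: dict[str, float]
    removed_ids: list[str]


@dataclass
class PressoRecord:
    global_rss: float
    global_pval: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    corrected_estimate: float | None
    distortion_pval: float | None


@dataclass
class SensitivityReport:
    cochran_q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: dict | None = None
    loo: "LooResult | None" = None
    steiger: SteigerRecord | None = None
    presso: PressoRecord | None = None
    verdict: str = ""
    verdict_reason: str = ""
    flags: list[str] = field(default_factory=list)


@dataclass
class LooResult:
    estimates: dict[str, float]  # omitted id -> re-fit estimate
    pvals: dict[str, float]
    unstable: bool
    reason: str = ""


def _ratio_arrays(hs: list[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in hs], float)
    by = np.array([h.beta_out for h in hs], float)
    sy = np.array([h.se_out for h in hs], float)
    return bx, by, sy


def cochran_q(hs: list[HarmonizedInstrument], theta_hat: float) -> tuple[float, int, float]:
    """Q = Σ wᵢ (rᵢ − θ̂)² over Wald ratios, wᵢ = bxᵢ²/se_outᵢ²; χ²(J−1) p."""
    if len(hs) < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    bx, by, sy = _ratio_arrays(hs)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; ratio undefined")
    w = bx**2 / sy**2
    q = float(np.sum(w * (by / bx - theta_hat) ** 2))
    df = len(hs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(hs: list[HarmonizedInstrument]) -> LooResult:
    """Re-fit IVW omitting each instrument; flag sign flips and p-crossings at 0.05."""
    if len(hs) < 3:
        return LooResult({}, {}, False, "not applicable (J < 3)")
    full = ivw_mre(hs)
    estimates, pvals = {}, {}
    unstable = False
    for i, h in enumerate(hs):
        sub = ivw_mre(hs[:i] + hs[i + 1 :])
        estimates[h.variant_id] = sub.estimate
        pvals[h.variant_id] = sub.pval
        if np.sign(sub.estimate) != np.sign(full.estimate):
            unstable = True
        if (sub.pval < 0.05) != (full.pval < 0.05):
            unstable = True
    return LooResult(estimates, pvals, unstable)


def _r2_from_t(beta: float, se: float, n: int) -> float:
    """Variance explained from summary stats: t²/(t² + n − 2)."""
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(
    hs: list[HarmonizedInstrument],
    n_exp: int,
    n_out: int,
) -> tuple[SteigerRecord, list[HarmonizedInstrument]]:
    """Directionality test: per-variant variance explained on each side.

    Variants explaining more outcome than exposure variance are removed.
    The aggregate direction is forward iff Σ r²_exp > Σ r²_out; the
    aggregate p compares the two aggregate correlations with a Fisher-z
    test across the two (independent) samples.
    """
    r2_exp, r2_out = {}, {}
    removed = []
    kept = []
    for h in hs:
        re_ = _r2_from_t(h.beta_exp, h.se_exp, n_exp)
        ro = _r2_from_t(h.beta_out, h.se_out, n_out)
        r2_exp[h.variant_id] = re_
        r2_out[h.variant_id] = ro
        if ro > re_:
            removed.append(h.variant_id)
        else:
            kept.append(h)
    sum_exp, sum_out = sum(r2_exp.values()), sum(r2_out.values())
    direction = "forward" if sum_exp > sum_out else "reverse"
    r_exp = math.sqrt(min(sum_exp, 1 - 1e-12))
    r_out = math.sqrt(min(sum_out, 1 - 1e-12))
    z = (math.atanh(r_exp) - math.atanh(r_out)) / math.sqrt(
        1 / (n_exp - 3) + 1 / (n_out - 3)
    )
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerRecord(direction, pval, r2_exp, r2_out, removed), kept


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates in O(J) via sufficient statistics."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def presso(
    hs: list[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoRecord:
    """Residual-sum-of-squares pleiotropy test with outlier and distortion steps.

    Global: observed RSS = Σ wᵢ (byᵢ − θ̂₋ᵢ bxᵢ)² with θ̂₋ᵢ the leave-one-out
    IVW and wᵢ = 1/se_outᵢ²; the null distribution comes from n_sim
    parametric draws by*ᵢ ~ N(θ̂₋ᵢ bxᵢ, se_outᵢ), each re-fitted leave-one-out.
    Outliers: per-variant simulated-contribution p, Bonferroni-corrected by J.
    Distortion: the change in IVW estimate after removing the outliers is
    compared with removals of random subsets of the same size.
    """
    J = len(hs)
    if J < 4:
        raise ValueError("presso needs >= 4 instruments")
    bx, by, sy = _ratio_arrays(hs)
    w = 1.0 / sy**2
    theta_loo = _loo_thetas(bx, by, w)
    contrib_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(contrib_obs))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    # vectorized leave-one-out over simulations
    s_xy = np.sum(w * bx * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx**2)
    theta_loo_sim = (s_xy - w * bx * by_sim) / (s_xx - w * bx**2)
    contrib_sim = w * (by_sim - theta_loo_sim * bx) ** 2
    rss_sim = contrib_sim.sum(axis=1)
    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    per_variant_p = (np.sum(contrib_sim >= contrib_obs, axis=0) + 1) / (n_sim + 1)
    corrected_p = np.minimum(per_variant_p * J, 1.0)
    outlier_mask = corrected_p < outlier_alpha
    outlier_ids = [hs[i].variant_id for i in np.flatnonzero(outlier_mask)]
    outlier_pvals = {hs[i].variant_id: float(corrected_p[i]) for i in range(J)}

    corrected_estimate = None
    distortion_pval = None
    k = int(outlier_mask.sum())
    if 0 < k <= J - 2:
        keep = ~outlier_mask
        theta_full = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        theta_corr = float(
            np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(w[keep] * bx[keep] ** 2)
        )
        corrected_estimate = theta_corr
        d_obs = theta_corr - theta_full
        d_sim = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(J, size=k, replace=False)
            m = np.ones(J, bool)
            m[drop] = False
            d_sim[s] = (
                np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] ** 2) - theta_full
            )
        distortion_pval = float((np.sum(np.abs(d_sim) >= abs(d_obs)) + 1) / (n_sim + 1))
    return PressoRecord(rss_obs, global_pval, outlier_ids, outlier_pvals,
                        corrected_estimate, distortion_pval)


def robustness_verdict(
    fits: dict[str, MRFit],
    report: SensitivityReport,
    tier: str,
) -> tuple[str, str]:
    """Combine estimator sign patterns and sensitivity flags into a verdict.

    Rejected when a potential-tier association has any secondary estimator
    (Egger / weighted median / weighted mode) disagreeing in sign with the
    primary fit, when leave-one-out is unstable, when outlier removal flips
    the estimate's sign, or when the Steiger direction is reverse.
    Significant-tier sign disagreement downgrades to caution instead of
    rejection. An Egger intercept p < 0.05 adds a caution flag only.
    """
    primary = fits.get("ivw_mre") or fits.get("wald_ratio")
    if primary is None:
        raise ValueError("primary fit (IVW or Wald ratio) required")
    p_sign = np.sign(primary.estimate)
    secondary = [fits[m] for m in ("egger", "weighted_median", "weighted_mode") if m in fits]
    sign_inconsistent = any(np.sign(f.estimate) != p_sign for f in secondary)

    flags = list(report.flags)
    if (
        report.egger_intercept is not None
        and report.egger_intercept.get("pval", 1.0) < 0.05
    ):
        flags.append("egger intercept p < 0.05")

    if tier == "potential" and sign_inconsistent:
        return "rejected", "secondary estimator sign inconsistent with primary (potential tier)"
    if report.loo is not None and report.loo.unstable:
        return "rejected", "leave-one-out unstable"
    if (
        report.presso is not None
        and report.presso.outlier_ids
        and report.presso.corrected_estimate is not None
        and np.sign(report.presso.corrected_estimate) != p_sign
    ):
        return "rejected", "outlier-corrected estimate changes sign"
    if report.steiger is not None and report.steiger.direction == "reverse":
        return "rejected", "Steiger direction reverse"
    if tier == "significant" and sign_inconsistent:
        return "caution", "secondary estimator sign inconsistent with primary (significant tier)"
    if flags:
        return "caution", "; ".join(flags)
    return "robust", ""


def run_sensitivity(
    hs: list[HarmonizedInstrument],
    fits: dict[str, MRFit],
    tier: str,
    n_exp: int | None = None,
    n_out: int | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> SensitivityReport:
    """Assemble the full battery (skipping tests J does not permit) and verdict."""
    report = SensitivityReport()
    primary = fits.get("ivw_mre") or fits.get("wald_ratio")
    J = len(hs)
    if J >= 2 and primary is not None:
        report.cochran_q, report.q_df, report.q_pval = cochran_q(hs, primary.estimate)
    if "egger" in fits:
        e = fits["egger"].extra
        report.egger_intercept = {
            "estimate": e["intercept"],
            "se": e["intercept_se"],
            "pval": e["intercept_pval"],
        }
    report.loo = leave_one_out(hs)
    if n_exp is not None and n_out is not None:
        report.steiger, _ = steiger_filter(hs, n_exp, n_out)
    if J >= 4:
        report.presso = presso(hs, n_sim=n_sim, seed=seed)
    report.verdict, report.verdict_reason = robustness_verdict(fits, report, tier)
    return report
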