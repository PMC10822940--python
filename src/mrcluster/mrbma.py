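"""Bayesian model-averaging multivariable MR over correlated exposures.

Instruments and outcome effects are standardized by the outcome SE
(ỹᵢ = βyᵢ/se_yᵢ, X̃ᵢⱼ = βxᵢⱼ/se_yᵢ) and each exposure column is scaled to
unit Euclidean norm, so one prior effect variance σ² applies across
exposures regardless of units. For an exposure subset S the marginal
likelihood is the Gaussian closed form with unit residual variance and
independent N(0, σ²) priors on the included effects:

    log ML(S) = −½ log det(I + σ² X̃_S X̃_Sᵀ) − ½ ỹᵀ (I + σ² X̃_S X̃_Sᵀ)⁻¹ ỹ

and the posterior model probability combines it with the independent
Bernoulli(p) inclusion prior. Per-exposure summaries are the marginal
inclusion probability (MIP: summed posterior probability of models
containing the exposure) and the model-averaged causal effect (MACE:
posterior-probability-weighted model-specific effect, zero when excluded).
Heterogeneity (q) contributions and Cook's distances on the top models
flag outlying and influential instruments, which are removed for a single
re-run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import LDReference, SummaryPanel
from .instruments import clump, select_instruments, InstrumentRecord

logger = logging.getLogger(__name__)

Model = frozenset[int]


@dataclass
class BMAConfig:
    prior_p: float = 0.1
    prior_sigma2: float = 0.5
    max_model_size: int | None = None
    search: str = "exhaustive"  # or "stochastic"
    n_iter: int = 20_000
    seed: int = 0
    top_models: int = 10
    top_model_min_pp: float = 0.02  # diagnostics ignore models below this mass
    q_outlier_threshold: float = 10.0
    mace_conditional: bool = False  # True: average θ over including models only
    exhaustive_d_limit: int = 18

    def __post_init__(self) -> None:
        if not (0 < self.prior_p < 1):
            raise ValueError("prior_p must lie in (0, 1)")
        if self.prior_sigma2 <= 0:
            raise ValueError("prior_sigma2 must be positive")


@dataclass
class JointInstrumentMatrix:
    variant_ids: list[str]
    exposure_ids: list[str]
    beta_x: np.ndarray  # (J, d)
    se_x: np.ndarray  # (J, d)
    beta_y: np.ndarray  # (J,)
    se_y: np.ndarray  # (J,)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variant, reason)

    @property
    def J(self) -> int:
        return len(self.variant_ids)

    @property
    def d(self) -> int:
        return len(self.exposure_ids)

    def subset(self, keep_rows: np.ndarray) -> "JointInstrumentMatrix":
        ids = [v for v, k in zip(self.variant_ids, keep_rows) if k]
        return JointInstrumentMatrix(
            ids, self.exposure_ids,
            self.beta_x[keep_rows], self.se_x[keep_rows],
            self.beta_y[keep_rows], self.se_y[keep_rows],
        )


@dataclass
class BMAResult:
    exposure_ids: list[str]
    mip: np.ndarray  # (d,)
    mace: np.ndarray  # (d,)
    posteriors: dict[Model, float]
    model_estimates: dict[Model, np.ndarray]  # original-scale effects, len |S|
    diagnostics: dict | None = None
    removed_variants: list[str] = field(default_factory=list)
    rerun: "BMAResult | None" = None

    def ranking(self) -> list[tuple[str, float, float]]:
        order = np.argsort(-self.mip)
        return [(self.exposure_ids[i], float(self.mip[i]), float(self.mace[i])) for i in order]


class InsufficientJointInstrumentsError(ValueError):
    pass


def build_joint_matrix(
    exposure_panels: list[SummaryPanel],
    outcome: SummaryPanel,
    ld: LDReference,
    p_thresholds: dict[str, float] | float = 1e-5,
    f_min: float = 10.0,
    maf_min: float = 0.01,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> JointInstrumentMatrix:
    """Union of per-exposure instruments, jointly clumped, harmonized, filled.

    The union contains every variant passing its own panel's selection for
    at least one exposure; joint clumping ranks by the best p across
    exposures. Each variant's effect on every exposure is then filled from
    that panel at any p; variants missing from some exposure panel or lost
    in harmonization are dropped and logged.
    """
    if len(exposure_panels) < 2:
        raise ValueError("multivariable MR needs >= 2 exposure panels")

    def thr(panel: SummaryPanel) -> float:
        if isinstance(p_thresholds, dict):
            return p_thresholds.get(panel.trait_id, p_thresholds.get("default", 1e-5))
        return p_thresholds

    # union of selected variants with their best (variant record, p) for clumping
    best: dict[str, InstrumentRecord] = {}
    for panel in exposure_panels:
        for rec in select_instruments(panel, thr(panel), f_min, maf_min):
            if not rec.selected:
                continue
            vid = rec.variant.variant_id
            if vid not in best or rec.variant.pval < best[vid].variant.pval:
                best[vid] = rec
    if not best:
        raise InsufficientJointInstrumentsError("no variant passes selection in any panel")
    kept_ids = clump(list(best.values()), ld, r2_max, window_kb)

    lookups = [p.lookup() for p in exposure_panels]
    out_lookup = outcome.lookup()
    variant_ids, rows_bx, rows_sx, beta_y, se_y = [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for vid in kept_ids:
        if any(vid not in lk for lk in lookups):
            dropped.append((vid, "missing from an exposure panel"))
            continue
        if vid not in out_lookup:
            dropped.append((vid, "missing from outcome panel"))
            continue
        # harmonize each exposure to the outcome's effect allele
        out = out_lookup[vid]
        if out.is_palindromic:
            dropped.append((vid, "palindromic"))
            continue
        bx_row, sx_row = [], []
        ok = True
        for lk in lookups:
            v = lk[vid]
            if (v.effect_allele, v.other_allele) == (out.effect_allele, out.other_allele):
                bx_row.append(v.beta)
            elif (v.other_allele, v.effect_allele) == (out.effect_allele, out.other_allele):
                bx_row.append(-v.beta)
            else:
                ok = False
                break
            sx_row.append(v.se)
        if not ok:
            dropped.append((vid, "incompatible alleles"))
            continue
        variant_ids.append(vid)
        rows_bx.append(bx_row)
        rows_sx.append(sx_row)
        beta_y.append(out.beta)
        se_y.append(out.se)

    d = len(exposure_panels)
    if len(variant_ids) < d + 2:
        raise InsufficientJointInstrumentsError(
            f"J={len(variant_ids)} < d+2={d + 2} after assembly"
        )
    for vid, reason in dropped:
        logger.info("joint matrix: dropped %s (%s)", vid, reason)
    return JointInstrumentMatrix(
        variant_ids,
        [p.trait_id for p in exposure_panels],
        np.array(rows_bx, float),
        np.array(rows_sx, float),
        np.array(beta_y, float),
        np.array(se_y, float),
        dropped,
    )


def _standardize(m: JointInstrumentMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (y_tilde, X_tilde column-normalized, column norms)."""
    y = m.beta_y / m.se_y
    X = m.beta_x / m.se_y[:, None]
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("an exposure has all-zero standardized effects")
    return y, X / norms, norms


def _log_ml(y: np.ndarray, Xs: np.ndarray, sigma2: float) -> float:
    """Gaussian marginal likelihood via the Woodbury/determinant identities."""
    k = Xs.shape[1]
    A = np.eye(k) + sigma2 * (Xs.T @ Xs)
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive-definite model Gram matrix")
    Xty = Xs.T @ y
    quad = y @ y - sigma2 * (Xty @ np.linalg.solve(A, Xty))
    return -0.5 * logdet - 0.5 * quad


def _model_estimate(y: np.ndarray, Xs: np.ndarray, sigma2: float) -> np.ndarray:
    """Posterior-mean ridge fit on the standardized scale."""
    k = Xs.shape[1]
    return np.linalg.solve(Xs.T @ Xs + np.eye(k) / sigma2, Xs.T @ y)


def _log_prior(size: int, d: int, p: float) -> float:
    return size * np.log(p) + (d - size) * np.log1p(-p)


def _enumerate_models(d: int, max_size: int) -> list[Model]:
    return [
        frozenset(c)
        for k in range(1, max_size + 1)
        for c in itertools.combinations(range(d), k)
    ]


def model_posteriors(
    m: JointInstrumentMatrix, cfg: BMAConfig
) -> tuple[dict[Model, float], dict[Model, np.ndarray]]:
    """Posterior probability and original-scale effect estimate per model.

    Exhaustive enumeration of all non-empty subsets up to ``max_model_size``
    when the exposure count permits; otherwise (or on request) shotgun
    stochastic search with add/delete/swap proposals, normalizing over the
    set of visited models.
    """
    y, X, norms = _standardize(m)
    d = m.d
    max_size = min(cfg.max_model_size or d, d)
    sigma2 = cfg.prior_sigma2

    def score(model: Model) -> float:
        idx = sorted(model)
        try:
            return _log_ml(y, X[:, idx], sigma2) + _log_prior(len(model), d, cfg.prior_p)
        except np.linalg.LinAlgError:
            logger.warning("model %s numerically singular; skipped", idx)
            return -np.inf

    if cfg.search == "exhaustive" and d <= cfg.exhaustive_d_limit:
        models = _enumerate_models(d, max_size)
        log_scores = {s: score(s) for s in models}
    else:
        log_scores = _stochastic_search(score, d, max_size, cfg)

    finite = {s: v for s, v in log_scores.items() if np.isfinite(v)}
    mx = max(finite.values())
    unnorm = {s: np.exp(v - mx) for s, v in finite.items()}
    total = sum(unnorm.values())
    posteriors = {s: v / total for s, v in unnorm.items()}
    estimates = {
        s: _model_estimate(y, X[:, sorted(s)], sigma2) / norms[sorted(s)]
        for s in posteriors
    }
    return posteriors, estimates


def _stochastic_search(score, d: int, max_size: int, cfg: BMAConfig) -> dict[Model, float]:
    """Shotgun stochastic search: Metropolis walk, keep every visited model's score."""
    rng = np.random.default_rng(cfg.seed)
    current: Model = frozenset({int(rng.integers(d))})
    visited: dict[Model, float] = {current: score(current)}
    for _ in range(cfg.n_iter):
        members = sorted(current)
        outside = [j for j in range(d) if j not in current]
        proposals = []
        if outside and len(current) < max_size:
            proposals.append(frozenset(current | {int(rng.choice(outside))}))
        if len(current) > 1:
            proposals.append(frozenset(current - {int(rng.choice(members))}))
        if outside and members:
            proposals.append(
                frozenset((current - {int(rng.choice(members))}) | {int(rng.choice(outside))})
            )
        if not proposals:
            continue
        prop = proposals[int(rng.integers(len(proposals)))]
        if prop not in visited:
            visited[prop] = score(prop)
        if np.log(rng.random()) < visited[prop] - visited[current]:
            current = prop
    return visited


def mip_and_mace(
    posteriors: dict[Model, float],
    model_estimates: dict[Model, np.ndarray],
    d: int,
    conditional: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal inclusion probabilities and model-averaged causal effects.

    MACE averages the model-specific effect over all models with θ = 0 when
    the exposure is excluded (the average direct effect); ``conditional``
    instead averages only over including models.
    """
    mip = np.zeros(d)
    mace = np.zeros(d)
    for model, pp in posteriors.items():
        est = model_estimates[model]
        for pos, j in enumerate(sorted(model)):
            mip[j] += pp
            mace[j] += pp * est[pos]
    if conditional:
        with np.errstate(invalid="ignore", divide="ignore"):
            mace = np.where(mip > 0, mace / mip, 0.0)
    return mip, mace


def diagnose(
    m: JointInstrumentMatrix,
    posteriors: dict[Model, float],
    cfg: BMAConfig,
) -> dict:
    """Per-variant q contributions and Cook's distances on the top models.

    Residuals and leverages come from each top model's weighted
    least-squares fit (the regression the inverse-SE standardization
    implies), so a model that fits a variant exactly contributes q = 0
    there. A variant is an outlier if its squared standardized residual
    exceeds ``q_outlier_threshold`` in any top model, influential if its
    Cook's distance exceeds the median of an F(d_S, J − d_S) reference.
    """
    y, X, _ = _standardize(m)
    ranked = sorted(posteriors, key=posteriors.get, reverse=True)[: cfg.top_models]
    top = [s for s in ranked if posteriors[s] >= cfg.top_model_min_pp] or ranked[:1]
    q_table: dict[Model, np.ndarray] = {}
    cook_table: dict[Model, np.ndarray] = {}
    flagged: set[int] = set()
    J = m.J
    for model in top:
        idx = sorted(model)
        Xs = X[:, idx]
        k = len(idx)
        G = Xs.T @ Xs
        theta = np.linalg.solve(G, Xs.T @ y)
        resid = y - Xs @ theta
        q = resid**2
        h = np.einsum("ij,jk,ik->i", Xs, np.linalg.inv(G), Xs)
        s2 = float(np.sum(q)) / max(J - k, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cook = np.where(s2 > 0, q * h / (k * s2 * (1 - h) ** 2), 0.0)
        q_table[model] = q
        cook_table[model] = cook
        f_ref = stats.f.median(k, max(J - k, 1))
        flagged |= set(np.flatnonzero(q > cfg.q_outlier_threshold))
        flagged |= set(np.flatnonzero(cook > f_ref))
    return {
        "top_models": top,
        "q": q_table,
        "cooks": cook_table,
        "flagged_rows": sorted(flagged),
        "flagged_ids": [m.variant_ids[i] for i in sorted(flagged)],
    }


def run_bma(m: JointInstrumentMatrix, cfg: BMAConfig) -> BMAResult:
    """Full pass: posteriors, MIP/MACE, diagnostics, and a single outlier re-run."""
    posteriors, estimates = model_posteriors(m, cfg)
    mip, mace = mip_and_mace(posteriors, estimates, m.d, cfg.mace_conditional)
    result = BMAResult(m.exposure_ids, mip, mace, posteriors, estimates)
    result.diagnostics = diagnose(m, posteriors, cfg)
    flagged = result.diagnostics["flagged_rows"]
    result.removed_variants = result.diagnostics["flagged_ids"]
    if flagged:
        keep = np.ones(m.J, bool)
        keep[flagged] = False
        if keep.sum() >= m.d + 2:
            sub = m.subset(keep)
            p2, e2 = model_posteriors(sub, cfg)
            mip2, mace2 = mip_and_mace(p2, e2, sub.d, cfg.mace_conditional)
            result.rerun = BMAResult(sub.exposure_ids, mip2, mace2, p2, e2)
        else:
            logger.warning("outlier removal leaves J < d + 2; re-run skipped")
    return result
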