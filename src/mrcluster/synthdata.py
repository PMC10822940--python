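"""Synthetic GWAS summary-statistics generator with known ground truth.

Summary statistics are simulated directly — no individual-level genotypes —
since two-sample MR consumes only per-variant betas and SEs. For a
single exposure-outcome pair, true instrument effects γⱼ are drawn from a
uniform magnitude range chosen so per-variant F spans roughly 10-300
(mirroring mixed-strength microbiota instruments selected at p < 1e-5);
observed effects add sampling noise β̂xⱼ ~ N(γⱼ, se_x) and
β̂yⱼ ~ N(θ·γⱼ + αⱼ, se_y), with the pleiotropy term αⱼ per regime:

* ``none`` — αⱼ = 0 (all instruments valid);
* ``balanced`` — αⱼ mean-zero (InSIDE holds, no directional bias);
* ``directional`` — αⱼ with positive mean, independent of γⱼ (InSIDE
  holds; IVW biased, Egger consistent);
* ``inside_violating`` — αⱼ correlated with γⱼ.

Panels carry rsID-like identifiers, chromosome/position layouts, allele
pairs (with configurable palindromic and strand-flip fractions to
exercise harmonization), effect-allele frequencies, and two-sided normal
p-values. Binary outcomes are emitted on the log-OR scale with SEs set by
the case/control split. A single root seed streams per-panel sub-seeds so
adding panels never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import LDReference, SummaryPanel, VariantAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class ScenarioConfig:
    """Ground-truth scenario for one synthetic study."""

    seed: int
    J: int = 50
    theta: float = 0.0
    gamma_range: tuple[float, float] = (0.07, 0.35)  # F ≈ 12-306 at se_x=0.02
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_scale: float = 0.05
    pleiotropy_mean: float = 0.1  # directional regime
    se_x: float = 0.02
    se_y: float = 0.05
    outcome_type: str = "continuous"
    n_cases: int = 20_000
    n_controls: int = 100_000
    n_exp: int = 20_000
    n_out: int = 100_000
    # multivariable
    n_exposures: int = 1
    true_subset: tuple[int, ...] = ()
    theta_subset: float = 0.3
    exposure_corr: float = 0.0
    # mediation (beta1, beta2, direct) — None disables
    mediation: tuple[float, float, float] | None = None
    J_mediator: int = 30
    # allele quirks
    frac_palindromic: float = 0.0
    frac_strand_flipped: float = 0.0
    # LD layout: list of (block_size, r2); blocks laid out within the clump window
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.se_x, self.se_y) <= 0:
            raise ValueError("SE scales must be positive")
        if any(i >= self.n_exposures for i in self.true_subset):
            raise ValueError("true_subset index outside exposures")


def _sub_rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    """Per-panel sub-stream off the root seed; stable as panels are added."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream])


def _variant_frame(cfg: ScenarioConfig, J: int, rng: np.random.Generator, offset: int = 0):
    """Shared variant layout: ids, chrom/pos, allele pairs, EAFs."""
    ids = [f"rs{offset + i + 1}" for i in range(J)]
    chroms = [str(1 + (offset + i) % 22) for i in range(J)]
    # one variant per 20 Mb keeps default variants outside each other's clump window
    pos = [1_000_000 + 20_000_000 * ((offset + i) // 22) for i in range(J)]
    alleles = [NON_PALINDROMIC_PAIRS[rng.integers(len(NON_PALINDROMIC_PAIRS))] for _ in range(J)]
    n_pal = int(round(cfg.frac_palindromic * J))
    for i in range(n_pal):
        alleles[i] = PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))]
    eaf = rng.uniform(0.05, 0.95, size=J)
    return ids, chroms, pos, alleles, eaf


def _pvals(beta: np.ndarray, se: float | np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)


def _binary_se(cfg: ScenarioConfig, eaf: np.ndarray) -> np.ndarray:
    """Log-OR SE from the case/control split: 1/sqrt(2 f(1−f) n_eff)."""
    n_eff = 4.0 / (1.0 / cfg.n_cases + 1.0 / cfg.n_controls)
    return 1.0 / np.sqrt(2 * eaf * (1 - eaf) * n_eff)


def _panel(
    trait_id: str,
    ids, chroms, pos, alleles, eaf,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    trait_type: str = "continuous",
    strand_flip_mask: np.ndarray | None = None,
) -> SummaryPanel:
    pv = _pvals(beta, se)
    variants = []
    for i, vid in enumerate(ids):
        ea, oa = alleles[i]
        if strand_flip_mask is not None and strand_flip_mask[i]:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        variants.append(
            VariantAssociation(
                variant_id=vid, chrom=chroms[i], pos=pos[i],
                effect_allele=ea, other_allele=oa,
                eaf=float(eaf[i]), beta=float(beta[i]), se=float(se[i]),
                pval=float(pv[i]), n=n,
            )
        )
    return SummaryPanel(trait_id, variants, trait_type=trait_type)


def _draw_gamma(cfg: ScenarioConfig, J: int, rng: np.random.Generator) -> np.ndarray:
    # effect alleles are coded exposure-increasing (γ ≥ 0), the convention of
    # instrument selection; a directional pleiotropy mean then cannot cancel
    # across oppositely-signed instruments
    lo, hi = cfg.gamma_range
    return rng.uniform(lo, hi, size=J)


def _draw_alpha(cfg: ScenarioConfig, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    J = len(gamma)
    if cfg.pleiotropy == "none":
        return np.zeros(J)
    if cfg.pleiotropy == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_scale, J)
    if cfg.pleiotropy == "directional":
        return rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_scale, J)
    if cfg.pleiotropy == "inside_violating":
        return 0.5 * np.abs(gamma) + rng.normal(0.0, cfg.pleiotropy_scale, J)
    raise ValueError(f"unknown pleiotropy regime {cfg.pleiotropy}")


def simulate_tsmr_pair(cfg: ScenarioConfig) -> tuple[SummaryPanel, SummaryPanel, dict]:
    """One exposure panel, one outcome panel (shared variants), and the truth record."""
    rng = _sub_rng(cfg, 0)
    ids, chroms, pos, alleles, eaf = _variant_frame(cfg, cfg.J, rng)
    gamma = _draw_gamma(cfg, cfg.J, rng)
    alpha = _draw_alpha(cfg, gamma, rng)
    bx = rng.normal(gamma, cfg.se_x)
    binary = cfg.outcome_type == "binary"
    se_y = _binary_se(cfg, eaf) if binary else np.full(cfg.J, cfg.se_y)
    by = rng.normal(cfg.theta * gamma + alpha, se_y)
    flips = rng.random(cfg.J) < cfg.frac_strand_flipped
    exposure = _panel("exposure", ids, chroms, pos, alleles, eaf,
                      bx, np.full(cfg.J, cfg.se_x), cfg.n_exp)
    outcome = _panel(
        "outcome", ids, chroms, pos, alleles, eaf, by, se_y, cfg.n_out,
        trait_type=cfg.outcome_type, strand_flip_mask=flips,
    )
    truth = {"theta": cfg.theta, "gamma": gamma, "alpha": alpha,
             "strand_flipped": flips}
    return exposure, outcome, truth


def simulate_multivariable(
    cfg: ScenarioConfig,
) -> tuple[list[SummaryPanel], SummaryPanel, dict]:
    """d exposure panels with correlated true effects, shared variant ids.

    True effect matrix G (J×d) has pairwise column correlation
    ``exposure_corr``; outcome effects sum θ over the causal subset.
    """
    d = cfg.n_exposures
    if d < 2:
        raise ValueError("simulate_multivariable needs n_exposures >= 2")
    rng = _sub_rng(cfg, 0)
    ids, chroms, pos, alleles, eaf = _variant_frame(cfg, cfg.J, rng)
    corr = np.full((d, d), cfg.exposure_corr) + (1 - cfg.exposure_corr) * np.eye(d)
    L = np.linalg.cholesky(corr)
    scale = np.mean(np.abs(cfg.gamma_range))
    G = rng.standard_normal((cfg.J, d)) @ L.T * scale
    theta_vec = np.zeros(d)
    theta_vec[list(cfg.true_subset)] = cfg.theta_subset
    by = rng.normal(G @ theta_vec, cfg.se_y)
    panels = []
    for j in range(d):
        bx_j = rng.normal(G[:, j], cfg.se_x)
        panels.append(
            _panel(f"exposure_{j}", ids, chroms, pos, alleles, eaf,
                   bx_j, np.full(cfg.J, cfg.se_x), cfg.n_exp)
        )
    outcome = _panel("outcome", ids, chroms, pos, alleles, eaf,
                     by, np.full(cfg.J, cfg.se_y), cfg.n_out,
                     trait_type=cfg.outcome_type)
    truth = {"theta": theta_vec, "true_subset": sorted(cfg.true_subset), "G": G}
    return panels, outcome, truth


def simulate_mediation(
    cfg: ScenarioConfig,
) -> tuple[SummaryPanel, SummaryPanel, SummaryPanel, dict]:
    """Exposure, mediator and outcome panels realizing a mediation chain.

    Exposure instruments act on the mediator through β1 and on the outcome
    through direct + β1·β2; the mediator has its own genome-wide-significant
    instruments (scaled stronger, as metabolite instruments are) acting on
    the outcome through β2.
    """
    if cfg.mediation is None:
        raise ValueError("cfg.mediation must be set")
    beta1, beta2, direct = cfg.mediation
    rng = _sub_rng(cfg, 0)
    J_e, J_m = cfg.J, cfg.J_mediator
    ids, chroms, pos, alleles, eaf = _variant_frame(cfg, J_e + J_m, rng)

    gamma_e = _draw_gamma(cfg, J_e, rng)  # exposure instrument effects
    delta_m = 3.0 * _draw_gamma(cfg, J_m, rng)  # mediator's own, stronger

    # exposure panel: its own instruments only
    bx = rng.normal(gamma_e, cfg.se_x)
    exposure = _panel("exposure", ids[:J_e], chroms[:J_e], pos[:J_e],
                      alleles[:J_e], eaf[:J_e], bx,
                      np.full(J_e, cfg.se_x), cfg.n_exp)

    # mediator panel: β1-chained effects on exposure IVs + own instruments
    true_med = np.concatenate([beta1 * gamma_e, delta_m])
    bm = rng.normal(true_med, cfg.se_x)
    mediator = _panel("mediator", ids, chroms, pos, alleles, eaf,
                      bm, np.full(J_e + J_m, cfg.se_x), cfg.n_exp)

    # outcome panel: total effect on exposure IVs, β2 on mediator IVs
    total = direct + beta1 * beta2
    true_out = np.concatenate([total * gamma_e, beta2 * delta_m])
    by = rng.normal(true_out, cfg.se_y)
    outcome = _panel("outcome", ids, chroms, pos, alleles, eaf,
                     by, np.full(J_e + J_m, cfg.se_y), cfg.n_out,
                     trait_type=cfg.outcome_type)
    truth = {
        "beta1": beta1, "beta2": beta2, "direct": direct,
        "total": total, "proportion": beta1 * beta2 / total if total else None,
    }
    return exposure, mediator, outcome, truth


def simulate_ld_reference(
    cfg: ScenarioConfig,
) -> tuple[LDReference, list[VariantAssociation]]:
    """LD blocks with configured within-block r²; cross-block pairs are 0.

    Variants within a block are placed 100 kb apart (inside the ±10,000 kb
    clump window); consecutive blocks are 50 Mb apart, outside it.
    """
    if not cfg.ld_blocks:
        raise ValueError("cfg.ld_blocks must be set")
    rng = _sub_rng(cfg, 1)
    ld = LDReference()
    variants: list[VariantAssociation] = []
    vid_counter = 0
    base = 1_000_000
    for block_size, r2 in cfg.ld_blocks:
        block_ids = []
        for i in range(block_size):
            vid = f"rs{vid_counter + 1}"
            vid_counter += 1
            block_ids.append(vid)
            beta = float(rng.uniform(0.1, 0.3))
            variants.append(
                VariantAssociation(
                    variant_id=vid, chrom="1", pos=base + 100_000 * i,
                    effect_allele="A", other_allele="G",
                    eaf=0.3, beta=beta, se=0.02,
                    pval=float(_pvals(np.array([beta]), 0.02)[0]), n=cfg.n_exp,
                )
            )
        for a in range(block_size):
            for b in range(a + 1, block_size):
                ld.add(block_ids[a], block_ids[b], r2)
        base += 50_000_000
    return ld, variants


def default_study_ld(panels: list[SummaryPanel]) -> LDReference:
    """Empty LD table for simulated panels whose variants are laid out independent."""
    return LDReference()
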