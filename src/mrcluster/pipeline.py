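"""End-to-end workflow orchestration.

Stages, in order: per-exposure instrument selection (p-threshold, MAF, F,
LD clumping); two-sample MR per exposure-outcome pair (Wald ratio for one
instrument, IVW with multiplicative random effects otherwise, plus Egger /
weighted median / weighted mode when at least three instruments survive);
per-category Bonferroni tiering with n counted from the run itself
(exposures with at least one valid instrument); the sensitivity battery
with robustness verdicts; Bayesian model-averaging multivariable MR per
eligible (category, outcome, tier) group; and two-step mediation of each
robust non-mediator exposure through each robust mediator. Only
associations that pass the sensitivity verdict feed the multivariable and
mediation stages. All randomness streams from the single run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .estimators import fit_all, primary_fit
from .gwas_io import Dialect, LDReference, SummaryPanel, read_ld_reference, read_panel, write_results
from .instruments import clump, harmonize, select_instruments, usable
from .mediation import two_step
from .mrbma import BMAConfig, InsufficientJointInstrumentsError, build_joint_matrix, run_bma
from .screen import ClassifiedAssociation, bma_eligibility, bonferroni_threshold, classify, rounded_threshold
from .sensitivity import run_sensitivity

logger = logging.getLogger(__name__)


@dataclass
class ExposureGroup:
    category: str
    p_threshold: float
    panels: list[SummaryPanel]
    is_mediator: bool = False


@dataclass
class StudyConfig:
    exposure_groups: list[ExposureGroup]
    outcomes: list[SummaryPanel]
    ld: LDReference
    seed: int = 0
    f_min: float = 10.0
    maf_min: float = 0.01
    r2_max: float = 0.001
    window_kb: int = 10_000
    n_boot: int = 1000
    presso_n_sim: int = 1000
    bma: BMAConfig = field(default_factory=BMAConfig)
    run_mediation: bool = True
    alpha: float = 0.05


@dataclass
class StudyResult:
    tables: dict[str, pd.DataFrame]
    classified: list[ClassifiedAssociation]
    sensitivity: dict[tuple[str, str], object]  # (exposure, outcome) -> report
    bma: dict[tuple[str, str, str], object]
    mediation: list
    log: dict
    manifest: dict | None = None


def _fit_row(exposure: SummaryPanel, group: ExposureGroup, outcome: SummaryPanel,
             fit, threshold: float, tier: str) -> dict:
    row = {
        "exposure": exposure.trait_id,
        "category": group.category,
        "outcome": outcome.trait_id,
        "method": fit.method,
        "estimate": fit.estimate,
        "se": fit.se,
        "ci_low": fit.ci_low,
        "ci_high": fit.ci_high,
        "pval": fit.pval,
        "n_snps": fit.n_snps,
        "threshold": threshold,
        "tier": tier,
    }
    if fit.or_scale:
        row.update({f"or_{k}": v for k, v in fit.or_scale.items()})
    return row


def run_pipeline(cfg: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full screening workflow; optionally write tables + manifest."""
    log: dict = {"stages": {}}

    # --- stage 1: instrument selection per exposure ----------------------
    instruments: dict[str, list] = {}
    for group in cfg.exposure_groups:
        for panel in group.panels:
            records = select_instruments(panel, group.p_threshold, cfg.f_min, cfg.maf_min)
            kept = set(clump([r for r in records if r.selected], cfg.ld,
                             cfg.r2_max, cfg.window_kb))
            instruments[panel.trait_id] = [r for r in records if r.variant.variant_id in kept]
    # n per category: exposures with >= 1 valid instrument after clumping
    n_by_category = {
        g.category: sum(1 for p in g.panels if instruments[p.trait_id])
        for g in cfg.exposure_groups
    }
    log["stages"]["selection"] = {
        "exposures": len(instruments),
        "valid_by_category": n_by_category,
    }

    # --- stage 2+3: TSMR and tiering --------------------------------------
    tsmr_rows, tier_rows = [], []
    classified: list[ClassifiedAssociation] = []
    fits_by_pair: dict[tuple[str, str], dict] = {}
    hs_by_pair: dict[tuple[str, str], list] = {}
    pair_meta: dict[tuple[str, str], tuple[ExposureGroup, SummaryPanel, SummaryPanel]] = {}
    seed_counter = cfg.seed
    for group in cfg.exposure_groups:
        n_cat = n_by_category[group.category]
        threshold = bonferroni_threshold(n_cat, cfg.alpha) if n_cat else None
        for panel in group.panels:
            ivs = instruments[panel.trait_id]
            if not ivs:
                continue
            for outcome in cfg.outcomes:
                hs = usable(harmonize(ivs, outcome))
                if not hs:
                    logger.info("%s -> %s: no usable instruments after harmonization",
                                panel.trait_id, outcome.trait_id)
                    continue
                seed_counter += 1
                fits = fit_all(hs, n_boot=cfg.n_boot, seed=seed_counter,
                               binary_outcome=outcome.trait_type == "binary")
                fit = primary_fit(fits)
                tier = classify(fit.pval, threshold)
                key = (panel.trait_id, outcome.trait_id)
                fits_by_pair[key] = fits
                hs_by_pair[key] = hs
                pair_meta[key] = (group, panel, outcome)
                classified.append(ClassifiedAssociation(
                    panel.trait_id, group.category, outcome.trait_id,
                    fit, threshold, tier))
                for f in fits.values():
                    tsmr_rows.append(_fit_row(panel, group, outcome, f, threshold, tier))
                tier_rows.append({
                    "exposure": panel.trait_id, "category": group.category,
                    "outcome": outcome.trait_id, "pval": fit.pval,
                    "threshold": threshold,
                    "threshold_printed": rounded_threshold(n_cat, cfg.alpha),
                    "n_tests": n_cat, "tier": tier,
                })
    log["stages"]["tsmr"] = {"pairs": len(classified)}
    log["stages"]["tiering"] = {
        t: sum(1 for c in classified if c.tier == t)
        for t in ("significant", "potential", "null")
    }

    # --- stage 4: sensitivity battery -------------------------------------
    sens_rows = []
    sensitivity: dict[tuple[str, str], object] = {}
    for c in classified:
        if c.tier == "null":
            continue
        key = (c.exposure_id, c.outcome_id)
        group, panel, outcome = pair_meta[key]
        hs = hs_by_pair[key]
        n_exp = next((v.n for v in panel.variants if v.n), None)
        n_out = next((v.n for v in outcome.variants if v.n), None)
        seed_counter += 1
        report = run_sensitivity(hs, fits_by_pair[key], c.tier,
                                 n_exp=n_exp, n_out=n_out,
                                 n_sim=cfg.presso_n_sim, seed=seed_counter)
        c.verdict = report.verdict
        sensitivity[key] = report
        sens_rows.append({
            "exposure": c.exposure_id, "outcome": c.outcome_id, "tier": c.tier,
            "cochran_q": report.cochran_q, "q_pval": report.q_pval,
            "egger_intercept_pval": (report.egger_intercept or {}).get("pval"),
            "loo_unstable": report.loo.unstable if report.loo else None,
            "steiger_direction": report.steiger.direction if report.steiger else None,
            "presso_global_pval": report.presso.global_pval if report.presso else None,
            "presso_outliers": len(report.presso.outlier_ids) if report.presso else None,
            "verdict": report.verdict, "reason": report.verdict_reason,
        })
    log["stages"]["sensitivity"] = {
        "tested": len(sens_rows),
        "verdicts": {v: sum(1 for r in sens_rows if r["verdict"] == v)
                     for v in ("robust", "caution", "rejected")},
    }

    # --- stage 5: MR-BMA per eligible group --------------------------------
    eligible = bma_eligibility(classified)
    bma_results: dict[tuple[str, str, str], object] = {}
    bma_rows = []
    panels_by_id = {p.trait_id: p for g in cfg.exposure_groups for p in g.panels}
    outcomes_by_id = {o.trait_id: o for o in cfg.outcomes}
    groups_by_cat = {g.category: g for g in cfg.exposure_groups}
    skipped = []
    # log groups that had exactly one robust member (the TSMR >= 2 gate)
    singles: dict[tuple[str, str, str], int] = {}
    for c in classified:
        if c.tier in ("significant", "potential") and c.verdict in ("robust", "caution"):
            k = (c.exposure_category, c.outcome_id, c.tier)
            singles[k] = singles.get(k, 0) + 1
    for k, count in singles.items():
        if count < 2:
            skipped.append({"group": k, "reason": "TSMR<2"})
            logger.info("bma group %s skipped: TSMR<2", k)
    for (category, outcome_id, tier), exposure_ids in eligible.items():
        group = groups_by_cat[category]
        seed_counter += 1
        bma_cfg = BMAConfig(**{**cfg.bma.__dict__, "seed": seed_counter})
        try:
            matrix = build_joint_matrix(
                [panels_by_id[e] for e in exposure_ids],
                outcomes_by_id[outcome_id], cfg.ld,
                p_thresholds=group.p_threshold,
                f_min=cfg.f_min, maf_min=cfg.maf_min,
                r2_max=cfg.r2_max, window_kb=cfg.window_kb,
            )
        except InsufficientJointInstrumentsError as exc:
            skipped.append({"group": (category, outcome_id, tier), "reason": str(exc)})
            continue
        result = run_bma(matrix, bma_cfg)
        bma_results[(category, outcome_id, tier)] = result
        for rank, (exp_id, mip, mace) in enumerate(result.ranking(), 1):
            bma_rows.append({
                "category": category, "outcome": outcome_id, "tier": tier,
                "rank": rank, "exposure": exp_id, "mip": mip, "mace": mace,
                "n_snps": matrix.J,
                "removed_variants": ",".join(result.removed_variants),
            })
    log["stages"]["bma"] = {
        "eligible_groups": len(eligible),
        "run": len(bma_results),
        "skipped": skipped,
    }

    # --- stage 6: mediation -------------------------------------------------
    mediation_results = []
    med_rows = []
    if cfg.run_mediation:
        robust = [c for c in classified
                  if c.tier in ("significant", "potential")
                  and c.verdict in ("robust", "caution")]
        mediator_cats = {g.category for g in cfg.exposure_groups if g.is_mediator}
        exposures_r = [c for c in robust if c.exposure_category not in mediator_cats]
        mediators_r = [c for c in robust if c.exposure_category in mediator_cats]
        for ce in exposures_r:
            for cm in mediators_r:
                if cm.outcome_id != ce.outcome_id:
                    continue
                group_e = groups_by_cat[ce.exposure_category]
                group_m = groups_by_cat[cm.exposure_category]
                seed_counter += 3
                try:
                    res = two_step(
                        panels_by_id[ce.exposure_id],
                        panels_by_id[cm.exposure_id],
                        outcomes_by_id[ce.outcome_id],
                        cfg.ld,
                        exposure_p_threshold=group_e.p_threshold,
                        mediator_p_threshold=group_m.p_threshold,
                        seed=seed_counter, n_boot=cfg.n_boot,
                    )
                except ValueError as exc:
                    logger.info("mediation %s/%s skipped: %s",
                                ce.exposure_id, cm.exposure_id, exc)
                    continue
                mediation_results.append(res)
                med_rows.append({
                    "exposure": res.exposure_id, "mediator": res.mediator_id,
                    "outcome": res.outcome_id, "beta1": res.beta1,
                    "beta2": res.beta2, "beta3": res.beta3,
                    "indirect": res.indirect, "proportion": res.proportion,
                    "se_proportion": res.se_proportion,
                    "consistent": res.consistent,
                    "overlap_instruments": res.overlap_instruments,
                })
    log["stages"]["mediation"] = {"pairs": len(mediation_results)}

    tables = {
        "tsmr": pd.DataFrame(tsmr_rows),
        "tiering": pd.DataFrame(tier_rows),
        "sensitivity": pd.DataFrame(sens_rows),
        "bma": pd.DataFrame(bma_rows),
        "mediation": pd.DataFrame(med_rows),
    }
    result = StudyResult(tables, classified, sensitivity, bma_results,
                         mediation_results, log)
    if out_dir is not None:
        result.manifest = write_results(tables, out_dir, config=_config_summary(cfg),
                                        seed=cfg.seed)
        result.manifest["log"] = log
        import json

        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
    return result


def _config_summary(cfg: StudyConfig) -> dict:
    return {
        "seed": cfg.seed,
        "groups": [
            {"category": g.category, "p_threshold": g.p_threshold,
             "panels": [p.trait_id for p in g.panels], "is_mediator": g.is_mediator}
            for g in cfg.exposure_groups
        ],
        "outcomes": [o.trait_id for o in cfg.outcomes],
        "f_min": cfg.f_min, "maf_min": cfg.maf_min,
        "r2_max": cfg.r2_max, "window_kb": cfg.window_kb,
        "n_boot": cfg.n_boot, "presso_n_sim": cfg.presso_n_sim,
    }


def load_study_config(path: str | Path) -> tuple[StudyConfig, Path]:
    """Build a StudyConfig from a YAML run configuration.

    Schema::

        seed: 7
        out_dir: results/run1
        ld_reference: ld.tsv
        exposure_groups:
          - category: genus
            p_threshold: 1.0e-5
            is_mediator: false
            panels: [exp1.tsv, exp2.tsv]
        outcomes:
          - {path: outcome.tsv, trait_type: binary}
        dialect: {variant_id: SNP, ...}      # optional
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    dialect = Dialect(**raw.get("dialect", {}))

    def resolve(p: str) -> Path:
        q = Path(p)
        full = q if q.is_absolute() else base / q
        if not full.exists():
            raise FileNotFoundError(f"configured path does not exist: {full}")
        return full

    groups = []
    for g in raw["exposure_groups"]:
        thr = float(g["p_threshold"])
        if not (0 < thr < 1):
            raise ValueError(f"p_threshold {thr} outside (0, 1)")
        panels = [
            read_panel(resolve(p), dialect, trait_category=g["category"])[0]
            for p in g["panels"]
        ]
        groups.append(ExposureGroup(g["category"], thr, panels,
                                    bool(g.get("is_mediator", False))))
    outcomes = []
    for o in raw["outcomes"]:
        entry = {"path": o} if isinstance(o, str) else o
        outcomes.append(read_panel(resolve(entry["path"]), dialect,
                                   trait_type=entry.get("trait_type", "continuous"))[0])
    ld = read_ld_reference(resolve(raw["ld_reference"])) if raw.get("ld_reference") else LDReference()
    bma = BMAConfig(**raw.get("bma", {}))
    cfg = StudyConfig(
        exposure_groups=groups, outcomes=outcomes, ld=ld,
        seed=int(raw.get("seed", 0)),
        n_boot=int(raw.get("n_boot", 1000)),
        presso_n_sim=int(raw.get("presso_n_sim", 1000)),
        bma=bma,
        run_mediation=bool(raw.get("run_mediation", True)),
    )
    out_dir = Path(raw.get("out_dir", "results"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return cfg, out_dir
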