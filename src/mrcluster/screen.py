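"""Per-category multiple-testing thresholds, tiering, and multivariable eligibility.

Each trait category (a microbiota taxonomic level, a metabolite class) gets
a Bonferroni threshold 0.05/n, where n counts the category's exposures that
yielded at least one valid instrument in this run. Associations below the
threshold are tier ``significant``; below 0.05 but not the threshold,
``potential``; otherwise ``null``. Groups of at least two robust
associations per (category, outcome, tier) are eligible for Bayesian
model-averaging multivariable MR.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .estimators import MRFit


@dataclass
class ClassifiedAssociation:
    exposure_id: str
    exposure_category: str
    outcome_id: str
    primary_fit: MRFit
    threshold: float
    tier: str  # significant | potential | null
    verdict: str = ""  # filled after the sensitivity battery


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests at full precision (reporting rounds separately)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def rounded_threshold(n_tests: int, alpha: float = 0.05, decimals: int = 4) -> float:
    """Half-up rounding to 4 decimals, matching conventional reporting."""
    t = Decimal(alpha) / Decimal(n_tests)
    return float(t.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def classify(assoc_pval: float, threshold: float) -> str:
    if not (0 < threshold <= 0.05):
        raise ValueError("threshold must lie in (0, 0.05]")
    if assoc_pval < threshold:
        return "significant"
    if assoc_pval < 0.05:
        return "potential"
    return "null"


def bma_eligibility(
    classified: list[ClassifiedAssociation],
) -> dict[tuple[str, str, str], list[str]]:
    """Group robust (or caution) associations by (category, outcome, tier).

    A group is eligible iff it contains >= 2 exposures whose sensitivity
    verdict is robust or caution; significant and potential tiers are
    emitted as separate groups.
    """
    groups: dict[tuple[str, str, str], list[str]] = {}
    for c in classified:
        if c.tier not in ("significant", "potential"):
            continue
        if c.verdict not in ("robust", "caution"):
            continue
        groups.setdefault((c.exposure_category, c.outcome_id, c.tier), []).append(c.exposure_id)
    return {k: v for k, v in groups.items() if len(v) >= 2}
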