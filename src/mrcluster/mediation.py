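"""Two-step MR mediation: exposure -> mediator -> outcome.

The three effects are each estimated by univariable two-sample MR
(IVW with multiplicative random effects, or the Wald ratio when a single
instrument survives selection): β1 exposure→mediator, β2 mediator→outcome,
β3 exposure→outcome (total). The mediated proportion is the product of
coefficients over the total effect, β1·β2/β3. An optional first-order
delta-method SE treats the three steps as independent, which the
two-sample design justifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .estimators import InsufficientInstrumentsError, MRFit, fit_all, primary_fit
from .gwas_io import LDReference, SummaryPanel
from .instruments import clump, harmonize, select_instruments, usable


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    beta2: float
    beta3: float
    indirect: float
    proportion: float | None
    se_proportion: float | None
    consistent: bool
    overlap_instruments: int = 0  # exposure IVs also used as mediator IVs (logged)


def proportion_se(
    beta1: float, se1: float, beta2: float, se2: float, beta3: float, se3: float
) -> float:
    """First-order delta-method SE of β1·β2/β3 with diagonal covariance."""
    if beta3 == 0:
        raise ValueError("beta3 is zero; proportion undefined")
    g1 = beta2 / beta3
    g2 = beta1 / beta3
    g3 = -beta1 * beta2 / beta3**2
    return math.sqrt((g1 * se1) ** 2 + (g2 * se2) ** 2 + (g3 * se3) ** 2)


def _univariable_fit(
    exposure: SummaryPanel,
    outcome: SummaryPanel,
    ld: LDReference,
    p_threshold: float,
    seed: int,
    n_boot: int = 1000,
) -> tuple[MRFit, list[str]]:
    """Select, clump, harmonize, fit; return the primary fit and the IV ids used."""
    records = select_instruments(exposure, p_threshold)
    kept_ids = set(clump([r for r in records if r.selected], ld))
    kept = [r for r in records if r.variant.variant_id in kept_ids]
    hs = usable(harmonize(kept, outcome))
    if not hs:
        raise InsufficientInstrumentsError(
            f"{exposure.trait_id} -> {outcome.trait_id}: no usable instruments"
        )
    fits = fit_all(hs, n_boot=n_boot, seed=seed)
    return primary_fit(fits), [h.variant_id for h in hs]


def two_step(
    exposure_panel: SummaryPanel,
    mediator_panel: SummaryPanel,
    outcome_panel: SummaryPanel,
    ld: LDReference,
    exposure_p_threshold: float = 1e-5,
    mediator_p_threshold: float = 5e-8,
    seed: int = 0,
    n_boot: int = 1000,
) -> MediationResult:
    """Estimate β1, β2, β3 by univariable TSMR and assemble the mediated proportion.

    ``proportion`` is None when the total effect β3 is zero to tolerance;
    proportions outside [0, 1] or with sign-inconsistent indirect and total
    effects are reported with ``consistent=False`` rather than clipped.
    """
    fit1, ivs1 = _univariable_fit(
        exposure_panel, mediator_panel, ld, exposure_p_threshold, seed
    )
    fit2, ivs2 = _univariable_fit(
        mediator_panel, outcome_panel, ld, mediator_p_threshold, seed + 1
    )
    fit3, _ = _univariable_fit(
        exposure_panel, outcome_panel, ld, exposure_p_threshold, seed + 2
    )
    b1, b2, b3 = fit1.estimate, fit2.estimate, fit3.estimate
    indirect = b1 * b2
    if abs(b3) < 1e-12:
        proportion, se_prop = None, None
    else:
        proportion = indirect / b3
        se_prop = proportion_se(b1, fit1.se, b2, fit2.se, b3, fit3.se)
    consistent = (
        proportion is not None and 0 <= proportion <= 1 and indirect * b3 >= 0
    )
    return MediationResult(
        exposure_id=exposure_panel.trait_id,
        mediator_id=mediator_panel.trait_id,
        outcome_id=outcome_panel.trait_id,
        beta1=b1,
        beta2=b2,
        beta3=b3,
        indirect=indirect,
        proportion=proportion,
        se_proportion=se_prop,
        consistent=consistent,
        overlap_instruments=len(set(ivs1) & set(ivs2)),
    )
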