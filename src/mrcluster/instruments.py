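"""Instrument selection, LD clumping and exposure-outcome harmonization.

Selection applies, in order: the association p-value threshold, the minor
allele frequency floor (MAF > 0.01 by default), and the instrument-strength
F statistic (F > 10 by default), recording the first failing criterion so
load reports are deterministic. Clumping is the standard greedy prune by
p-value (r² < 0.001 within ±10,000 kb by default). Harmonization aligns
each instrument's outcome association to the exposure's effect allele and
excludes palindromic variants unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gwas_io import LDReference, SummaryPanel, VariantAssociation


@dataclass(frozen=True)
class InstrumentRecord:
    variant: VariantAssociation
    f_stat: float
    selected: bool
    rejection_reason: str | None = None


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure-outcome-aligned instrument.

    ``action`` records how the alleles were reconciled; records whose action
    starts with ``dropped`` carry no usable outcome effect and must be
    excluded before estimation (see :func:`usable`).
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str  # aligned | flipped | dropped_palindromic | dropped_missing | dropped_incompatible
    eaf_out: float | None = None

    @property
    def dropped(self) -> bool:
        return self.action.startswith("dropped")


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F for one variant: (beta/se)**2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def select_instruments(
    panel: SummaryPanel,
    p_threshold: float,
    f_min: float = 10.0,
    maf_min: float = 0.01,
) -> list[InstrumentRecord]:
    """Mark each variant selected/rejected, criteria in order p, MAF, F."""
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1)")
    records = []
    for v in panel.variants:
        f = f_statistic(v.beta, v.se)
        reason = None
        if v.pval >= p_threshold:
            reason = "p-threshold"
        elif v.eaf is not None and min(v.eaf, 1 - v.eaf) <= maf_min:
            reason = "MAF"
        elif f <= f_min:
            reason = "weak instrument (F)"
        records.append(InstrumentRecord(v, f, reason is None, reason))
    return records


def clump(
    records: list[InstrumentRecord],
    ld: LDReference,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> list[str]:
    """Greedy LD clump of selected records; returns retained ids in retention order.

    Repeatedly keeps the remaining variant with the smallest p (ties broken
    by ascending variant id) and discards every remaining variant on the
    same chromosome within ±window_kb whose r² with it is >= r2_max.
    """
    pool = sorted(
        (r.variant for r in records if r.selected),
        key=lambda v: (v.pval, v.variant_id),
    )
    window_bp = window_kb * 1000
    retained: list[str] = []
    while pool:
        index = pool.pop(0)
        retained.append(index.variant_id)
        pool = [
            v
            for v in pool
            if v.chrom != index.chrom
            or abs(v.pos - index.pos) > window_bp
            or ld.r2(index.variant_id, v.variant_id) < r2_max
        ]
    return retained


def harmonize(
    instruments: list[InstrumentRecord],
    outcome: SummaryPanel,
) -> list[HarmonizedInstrument]:
    """Align outcome associations to each exposure instrument's effect allele.

    Per variant: absent from the outcome panel -> dropped_missing;
    palindromic (A/T or C/G) in either panel -> dropped_palindromic;
    outcome alleles equal to the exposure's (effect, other) -> aligned;
    equal to (other, effect) -> flipped, negating beta_out (and reflecting
    eaf_out); any other allele pair -> dropped_incompatible.
    """
    out_lookup = outcome.lookup()
    result = []
    for rec in instruments:
        exp = rec.variant
        out = out_lookup.get(exp.variant_id)
        if out is None:
            action, beta_out, se_out, eaf_out = "dropped_missing", 0.0, 1.0, None
        elif exp.is_palindromic or out.is_palindromic:
            action, beta_out, se_out, eaf_out = "dropped_palindromic", 0.0, 1.0, None
        elif (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
            action, beta_out, se_out, eaf_out = "aligned", out.beta, out.se, out.eaf
        elif (out.other_allele, out.effect_allele) == (exp.effect_allele, exp.other_allele):
            action = "flipped"
            beta_out, se_out = -out.beta, out.se
            eaf_out = None if out.eaf is None else 1 - out.eaf
        else:
            action, beta_out, se_out, eaf_out = "dropped_incompatible", 0.0, 1.0, None
        result.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=se_out,
                action=action,
                eaf_out=eaf_out,
            )
        )
    return result


def usable(harmonized: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The non-dropped subset that estimators may consume."""
    return [h for h in harmonized if not h.dropped]
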