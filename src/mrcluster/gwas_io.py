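"""Reading and writing GWAS summary panels, LD references and result tables.

All external formats are delimited text: summary panels are TSV with a
header (column names mapped through a :class:`Dialect`), the LD reference
is a three-column TSV (``variant_a variant_b r2``), results are TSV, and
the run manifest is JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` (log-OR for binary
    traits). ``eaf`` (effect-allele frequency) and ``n`` may be missing, as
    some consortia omit them.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: invalid allele")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: nonpositive SE")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: p-value outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: EAF outside (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pairs: strand unresolvable from alleles alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryPanel:
    """A panel of per-variant summary associations for one trait."""

    trait_id: str
    variants: list[VariantAssociation]
    trait_category: str = ""
    trait_type: str = "continuous"  # or "binary"

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"panel {self.trait_id}: empty")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"panel {self.trait_id}: duplicate variant {dup}")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"panel {self.trait_id}: unknown trait_type {self.trait_type}")

    def lookup(self) -> dict[str, VariantAssociation]:
        return {v.variant_id: v for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)


class LDReference:
    """Symmetric pairwise r-squared lookup.

    Absent pairs are treated as r² = 0; a variant with itself is 1.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[frozenset[str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise FormatError(f"r2({a},{b})={r2} outside [0, 1]")
        if a != b:
            self._pairs[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for heterogeneous consortium files.

    Defaults follow the GCTA-COJO ``.ma`` convention
    (SNP A1 A2 freq b se p N) plus chromosome/position columns.
    """

    variant_id: str = "SNP"
    effect_allele: str = "A1"
    other_allele: str = "A2"
    eaf: str | None = "freq"
    beta: str = "b"
    se: str = "se"
    pval: str = "p"
    n: str | None = "N"
    chrom: str | None = "chr"
    pos: str | None = "pos"
    delimiter: str = "\t"


@dataclass
class LoadReport:
    """Per-row rejection log from :func:`read_panel`."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, reason)


def read_panel(
    path: str | Path,
    dialect: Dialect = Dialect(),
    trait_id: str | None = None,
    trait_category: str = "",
    trait_type: str = "continuous",
) -> tuple[SummaryPanel, LoadReport]:
    """Read a summary panel, rejecting rows that violate the type invariants.

    Rows failing validation (nonpositive SE, p outside (0,1], bad alleles)
    are dropped and listed in the returned :class:`LoadReport` with a
    per-row reason; mandatory columns that cannot be resolved raise
    :class:`FormatError` naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    mandatory = {
        "variant_id": dialect.variant_id,
        "effect_allele": dialect.effect_allele,
        "other_allele": dialect.other_allele,
        "beta": dialect.beta,
        "se": dialect.se,
        "pval": dialect.pval,
    }
    for role, col in mandatory.items():
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' (for {role})")

    report = LoadReport(n_rows=len(df))
    variants: list[VariantAssociation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        vid = str(row[dialect.variant_id])
        if vid in seen:
            raise FormatError(f"duplicate variant_id {vid}")
        seen.add(vid)
        kwargs: dict = {}
        if dialect.eaf and dialect.eaf in df.columns and pd.notna(row[dialect.eaf]):
            kwargs["eaf"] = float(row[dialect.eaf])
        if dialect.n and dialect.n in df.columns and pd.notna(row[dialect.n]):
            kwargs["n"] = int(row[dialect.n])
        if dialect.chrom and dialect.chrom in df.columns and pd.notna(row[dialect.chrom]):
            kwargs["chrom"] = str(row[dialect.chrom])
        if dialect.pos and dialect.pos in df.columns and pd.notna(row[dialect.pos]):
            kwargs["pos"] = int(row[dialect.pos])
        try:
            variants.append(
                VariantAssociation(
                    variant_id=vid,
                    effect_allele=str(row[dialect.effect_allele]),
                    other_allele=str(row[dialect.other_allele]),
                    beta=float(row[dialect.beta]),
                    se=float(row[dialect.se]),
                    pval=float(row[dialect.pval]),
                    **kwargs,
                )
            )
        except ValueError as exc:
            reason = str(exc).split(": ", 1)[-1]
            report.rejected.append((vid, reason))
    report.n_accepted = len(variants)
    if not variants:
        raise FormatError(f"{path}: no valid rows")
    panel = SummaryPanel(
        trait_id=trait_id or path.stem,
        variants=variants,
        trait_category=trait_category,
        trait_type=trait_type,
    )
    return panel, report


def write_panel(panel: SummaryPanel, path: str | Path, dialect: Dialect = Dialect()) -> None:
    """Write a panel in the dialect's column layout (full float precision)."""
    rows = []
    for v in panel.variants:
        row = {
            dialect.variant_id: v.variant_id,
            dialect.effect_allele: v.effect_allele,
            dialect.other_allele: v.other_allele,
            dialect.beta: repr(v.beta),
            dialect.se: repr(v.se),
            dialect.pval: repr(v.pval),
        }
        if dialect.eaf:
            row[dialect.eaf] = "" if v.eaf is None else repr(v.eaf)
        if dialect.n:
            row[dialect.n] = "" if v.n is None else v.n
        if dialect.chrom:
            row[dialect.chrom] = v.chrom
        if dialect.pos:
            row[dialect.pos] = v.pos
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def read_ld_reference(path: str | Path) -> LDReference:
    """Read a three-column (variant_a, variant_b, r2) TSV into a symmetric lookup."""
    df = pd.read_csv(path, sep="\t")
    expected = ["variant_a", "variant_b", "r2"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"LD reference needs columns {expected}, got {list(df.columns)}")
    ld = LDReference()
    for a, b, r2 in df.itertuples(index=False):
        ld.add(str(a), str(b), float(r2))
    return ld


def write_ld_reference(ld: LDReference, path: str | Path) -> None:
    rows = sorted((tuple(sorted(k)), v) for k, v in ld._pairs.items())
    df = pd.DataFrame(
        [(a, b, r2) for (a, b), r2 in rows], columns=["variant_a", "variant_b", "r2"]
    )
    df.to_csv(path, sep="\t", index=False)


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write each named table as a TSV plus a JSON run manifest; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {
        "tables": {},
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "version": __version__,
    }
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.10g")
        manifest["tables"][name] = {"file": fname, "rows": int(len(table))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
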