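"""Domain types for panel-sequenced tumor cohorts.

The unit of analysis is a gene-level alteration profile per tumor: somatic
variant calls restricted to a capture panel, gene-level copy-number fold
changes, viral read fractions (EBV, HPV-16, HPV-18), an indel count over a
microsatellite locus catalog, and basic clinicopathological fields.
Coordinates are never interpreted; everything downstream works on gene
symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VAR_CLASSES = frozenset({"SNV", "insertion", "deletion"})
IMPACTS = frozenset({"high", "moderate", "low", "silent"})
LAUREN_TYPES = frozenset({"intestinal", "diffuse", "mixed", "unknown"})

#: case-insensitive impact synonyms (VEP/SnpEff style); MODIFIER maps to silent
IMPACT_SYNONYMS = {
    "high": "high",
    "moderate": "moderate",
    "low": "low",
    "silent": "silent",
    "modifier": "silent",
}


def normalize_impact(raw: str) -> str:
    """Map a raw impact string onto the closed vocabulary.

    Raises ValueError for strings outside the synonym table.
    """
    key = str(raw).strip().lower()
    try:
        return IMPACT_SYNONYMS[key]
    except KeyError:
        raise ValueError(
            f"unknown impact {raw!r}; expected one of {sorted(IMPACT_SYNONYMS)}"
        ) from None


@dataclass(frozen=True)
class GenePanel:
    """A capture panel: gene symbols, the actionable subset, and ROI size.

    ``roi_size_mb`` is the captured region in megabases — the denominator of
    the tumor mutation burden. The panel this package models has 435 genes of
    which 69 are actionable (paired with an FDA-approved targeted therapy),
    but any sizes are accepted.
    """

    genes: frozenset[str]
    actionable_genes: frozenset[str]
    roi_size_mb: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "actionable_genes", frozenset(self.actionable_genes))
        if not self.genes:
            raise ValueError("panel must contain at least one gene")
        if not self.actionable_genes <= self.genes:
            extra = sorted(self.actionable_genes - self.genes)
            raise ValueError(f"actionable genes not in panel: {extra}")
        if not self.roi_size_mb > 0:
            raise ValueError("roi_size_mb must be positive")


@dataclass(frozen=True)
class VariantCall:
    """One somatic small variant (SNV or indel) in one tumor."""

    gene: str
    var_class: str
    allele_fraction: float
    impact: str
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise ValueError(
                f"var_class must be one of {sorted(VAR_CLASSES)}, got {self.var_class!r}"
            )
        if self.impact not in IMPACTS:
            raise ValueError(
                f"impact must be one of {sorted(IMPACTS)}, got {self.impact!r}"
            )
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(
                f"allele_fraction must lie in [0, 1], got {self.allele_fraction}"
            )


@dataclass(frozen=True)
class CopyNumberCall:
    """Gene-level copy-number fold change; ``call`` is derived by thresholding.

    ``call`` is None until classified (see :func:`panelclass.biomarkers.call_scna`).
    """

    gene: str
    fold_change: float
    call: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change}")
        if self.call is not None and self.call not in {"gain", "loss", "neutral"}:
            raise ValueError(f"invalid copy-number call {self.call!r}")


@dataclass(frozen=True)
class ViralReadFractions:
    """Percentage of total reads mapping to each viral genome."""

    ebv_pct: float = 0.0
    hpv16_pct: float = 0.0
    hpv18_pct: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ebv_pct", "hpv16_pct", "hpv18_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class ClinicalRecord:
    age: Optional[float] = None
    sex: Optional[str] = None
    lauren_type: str = "unknown"
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lauren_type not in LAUREN_TYPES:
            raise ValueError(
                f"lauren_type must be one of {sorted(LAUREN_TYPES)}, got {self.lauren_type!r}"
            )


@dataclass
class TumorProfile:
    """All per-tumor inputs the classification consumes."""

    tumor_id: str
    variants: list[VariantCall] = field(default_factory=list)
    cnvs: list[CopyNumberCall] = field(default_factory=list)
    viral: ViralReadFractions = field(default_factory=ViralReadFractions)
    msi_indel_count: int = 0
    clinical: ClinicalRecord = field(default_factory=ClinicalRecord)

    def __post_init__(self) -> None:
        if self.msi_indel_count < 0:
            raise ValueError("msi_indel_count must be non-negative")


@dataclass
class Cohort:
    """An ordered collection of tumor profiles sharing one panel."""

    panel: GenePanel
    tumors: list[TumorProfile]

    def __post_init__(self) -> None:
        if not self.tumors:
            raise ValueError("cohort must contain at least one tumor")
        ids = [t.tumor_id for t in self.tumors]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate tumor_ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.tumors)

    def tumor_ids(self) -> list[str]:
        return [t.tumor_id for t in self.tumors]

    def get(self, tumor_id: str) -> TumorProfile:
        for t in self.tumors:
            if t.tumor_id == tumor_id:
                return t
        raise KeyError(tumor_id)
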