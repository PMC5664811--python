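"""TCGA-style molecular subtyping and hypermutation cutoff derivation.

Tumors are assigned to one of four subtypes by a sequential decision tree
with precedence EBV > MSI > CIN/GS:

1. EBV-positive tumors -> **EBV** subtype;
2. remaining MSI-H tumors -> **MSI** subtype;
3. remaining tumors with >= 4 SCNA loci -> **CIN** (chromosomal instability),
   else **GS** (genomically stable).

The hypermutation cutoff is data-derived as the minimum TMB among MSI-H
tumors; a tumor is hypermutated when its TMB reaches that cutoff
(inclusive, so the defining MSI-H tumor is itself hypermutated and the
hypermutated set always contains every MSI-H tumor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .biomarkers import MSI_HIGH, BiomarkerResult

SUBTYPES = ("EBV", "MSI", "CIN", "GS")
DEFAULT_SCNA_CUTOFF = 4


@dataclass(frozen=True)
class SubtypeCall:
    tumor_id: str
    subtype: str
    hypermutated: bool
    scna_locus_count: int
    tmb: float = 0.0

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}, got {self.subtype!r}")


def classify_tcga(biomarkers: BiomarkerResult, scna_cutoff: int = DEFAULT_SCNA_CUTOFF) -> str:
    """Subtype of one tumor under the EBV > MSI > CIN/GS precedence."""
    if biomarkers.ebv_positive:
        return "EBV"
    if biomarkers.msi_status == MSI_HIGH:
        return "MSI"
    if biomarkers.scna_locus_count >= scna_cutoff:
        return "CIN"
    return "GS"


def derive_hypermutation_cutoff(biomarkers: Iterable[BiomarkerResult]) -> float:
    """Minimum TMB over MSI-H tumors, in counts/Mb.

    Raises if the cohort contains no MSI-H tumor; pass an explicit cutoff to
    :func:`flag_hypermutated` in that case.
    """
    msih = [b.tmb for b in biomarkers if b.msi_status == MSI_HIGH]
    if not msih:
        raise ValueError(
            "no MSI-H tumor in cohort; the hypermutation cutoff cannot be derived "
            "— supply an explicit cutoff instead"
        )
    return min(msih)


def flag_hypermutated(tmb: float, cutoff: float) -> bool:
    """True iff tmb >= cutoff (inclusive)."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    return tmb >= cutoff


def classify_cohort(
    biomarkers: Sequence[BiomarkerResult],
    scna_cutoff: int = DEFAULT_SCNA_CUTOFF,
    hypermutation_cutoff: float | None = None,
) -> list[SubtypeCall]:
    """Subtype and hypermutation flag for every tumor.

    When ``hypermutation_cutoff`` is None it is derived as the MSI-H minimum.
    """
    cutoff = (
        derive_hypermutation_cutoff(biomarkers)
        if hypermutation_cutoff is None
        else hypermutation_cutoff
    )
    return [
        SubtypeCall(
            tumor_id=b.tumor_id,
            subtype=classify_tcga(b, scna_cutoff),
            hypermutated=flag_hypermutated(b.tmb, cutoff),
            scna_locus_count=b.scna_locus_count,
            tmb=b.tmb,
        )
        for b in biomarkers
    ]


def derive_scna_cutoff(
    biomarkers: Sequence[BiomarkerResult],
    tp53_mutant: Mapping[str, bool],
    lauren_type: Mapping[str, str],
    candidate_range: Iterable[int] = range(1, 11),
) -> int:
    """Data-driven SCNA-high cutoff from TP53 status and histology.

    For each candidate k, SCNA-high (>= k loci) should capture TP53-mutant
    tumors (the CIN phenotype) while SCNA-low (< k) captures diffuse-type
    tumors (the GS phenotype). Both associations are scored by two-tailed
    Fisher tests and the k minimizing the product of the two p-values wins;
    ties break toward smaller k. Only non-EBV, MSS tumors enter the scan,
    mirroring the decision tree where the SCNA split applies after the EBV
    and MSI branches.
    """
    eligible = [b for b in biomarkers if not b.ebv_positive and b.msi_status != MSI_HIGH]
    if not eligible:
        raise ValueError("no eligible (EBV-negative, MSS) tumors for cutoff derivation")
    candidates = sorted(set(candidate_range))
    if not candidates:
        raise ValueError("empty candidate range")

    best_k: int | None = None
    best_score = float("inf")
    for k in candidates:
        high = [b.scna_locus_count >= k for b in eligible]
        if all(high) or not any(high):
            continue  # degenerate split carries no information
        tp53 = [bool(tp53_mutant.get(b.tumor_id, False)) for b in eligible]
        diffuse = [lauren_type.get(b.tumor_id, "unknown") == "diffuse" for b in eligible]
        p_tp53 = fisher_exact(_crosstab(high, tp53))[1]
        p_diffuse = fisher_exact(_crosstab([not h for h in high], diffuse))[1]
        score = p_tp53 * p_diffuse
        if score < best_score:
            best_score = score
            best_k = k
    if best_k is None:
        raise ValueError(
            "degenerate cohort: every candidate cutoff puts all tumors on one side"
        )
    return best_k


def _crosstab(a: Sequence[bool], b: Sequence[bool]) -> list[list[int]]:
    t = [[0, 0], [0, 0]]
    for x, y in zip(a, b):
        t[0 if x else 1][0 if y else 1] += 1
    return t
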