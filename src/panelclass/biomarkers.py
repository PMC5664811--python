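"""Biomarker calling from gene-level tumor profiles.

Implements the post-alignment biomarker logic of a 435-gene tumor panel:

* **TMB** — tumor mutation burden, the rate of peptide-changing SNVs per
  megabase of captured region. Only SNVs with allele fraction >= 10% and
  high or moderate putative impact count; indels and silent/low-impact
  variants are excluded.
* **MSI** — microsatellite instability, called MSI-H when the indel count
  over the tandem-repeat locus catalog reaches a configurable threshold.
* **Viral status** — EBV / HPV-16 / HPV-18 positivity from the percentage of
  reads mapped to each viral genome, against empirical cutoffs of 0.0005%,
  0.02% and 0.01% respectively.
* **SCNA** — gene-level gain (> 2.5-fold) and loss (< 0.75-fold) calls, and
  the count of distinct altered loci used for CIN/GS subtyping.

Boundary comparisons for MSI, viral and hypermutation calls are inclusive
(>=); the SCNA thresholds are strict as stated (> 2.5, < 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import Cohort, CopyNumberCall, TumorProfile, VariantCall, ViralReadFractions

GAIN_THRESHOLD = 2.5
LOSS_THRESHOLD = 0.75

#: empirical viral positivity cutoffs, % of total reads
DEFAULT_VIRAL_CUTOFFS = {"hpv16": 0.02, "hpv18": 0.01, "ebv": 0.0005}

DEFAULT_AF_MIN = 0.10
DEFAULT_MSI_THRESHOLD = 20

MSI_HIGH = "MSI-H"
MSS = "MSS"


@dataclass(frozen=True)
class BiomarkerResult:
    """All biomarker calls for one tumor."""

    tumor_id: str
    tmb: float
    msi_status: str
    ebv_positive: bool
    hpv16_positive: bool
    hpv18_positive: bool
    scna_locus_count: int

    def __post_init__(self) -> None:
        if self.tmb < 0:
            raise ValueError("tmb must be non-negative")
        if self.msi_status not in (MSI_HIGH, MSS):
            raise ValueError(f"msi_status must be {MSI_HIGH!r} or {MSS!r}")
        if self.scna_locus_count < 0:
            raise ValueError("scna_locus_count must be non-negative")


def compute_tmb(
    variants: Iterable[VariantCall],
    roi_size_mb: float,
    af_min: float = DEFAULT_AF_MIN,
) -> float:
    """Tumor mutation burden in counts/Mb.

    Counts SNVs with ``impact`` in {high, moderate} and
    ``allele_fraction >= af_min``, divided by the captured region size in Mb.
    """
    if not roi_size_mb > 0:
        raise ValueError(f"roi_size_mb must be positive, got {roi_size_mb}")
    if not 0.0 <= af_min <= 1.0:
        raise ValueError(f"af_min must lie in [0, 1], got {af_min}")
    n = sum(
        1
        for v in variants
        if v.var_class == "SNV"
        and v.impact in ("high", "moderate")
        and v.allele_fraction >= af_min
    )
    return n / roi_size_mb


def call_msi(msi_indel_count: int, msi_threshold: int = DEFAULT_MSI_THRESHOLD) -> str:
    """MSI-H iff the repeat-locus indel count reaches the threshold (inclusive)."""
    if msi_indel_count < 0:
        raise ValueError("msi_indel_count must be non-negative")
    if msi_threshold < 1:
        raise ValueError("msi_threshold must be >= 1")
    return MSI_HIGH if msi_indel_count >= msi_threshold else MSS


def call_viral(
    viral: ViralReadFractions,
    cutoffs: dict[str, float] | None = None,
) -> tuple[bool, bool, bool]:
    """(ebv_positive, hpv16_positive, hpv18_positive), inclusive at the cutoff."""
    c = dict(DEFAULT_VIRAL_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    return (
        viral.ebv_pct >= c["ebv"],
        viral.hpv16_pct >= c["hpv16"],
        viral.hpv18_pct >= c["hpv18"],
    )


def call_scna(
    fold_change: float,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> str:
    """'gain' iff fold change > gain_threshold, 'loss' iff < loss_threshold."""
    if not fold_change > 0:
        raise ValueError(f"fold_change must be positive, got {fold_change}")
    if fold_change > gain_threshold:
        return "gain"
    if fold_change < loss_threshold:
        return "loss"
    return "neutral"


def classify_cnvs(cnvs: Iterable[CopyNumberCall]) -> list[CopyNumberCall]:
    """Return copies of the calls with ``call`` filled from the thresholds."""
    return [
        CopyNumberCall(gene=c.gene, fold_change=c.fold_change, call=call_scna(c.fold_change))
        for c in cnvs
    ]


def count_scna_loci(cnvs: Iterable[CopyNumberCall]) -> int:
    """Number of distinct genes carrying a gain or loss."""
    altered = set()
    for c in cnvs:
        call = c.call if c.call is not None else call_scna(c.fold_change)
        if call in ("gain", "loss"):
            altered.add(c.gene)
    return len(altered)


def compute_biomarkers(
    tumor: TumorProfile,
    roi_size_mb: float,
    af_min: float = DEFAULT_AF_MIN,
    msi_threshold: int = DEFAULT_MSI_THRESHOLD,
    viral_cutoffs: dict[str, float] | None = None,
) -> BiomarkerResult:
    """All biomarker calls for one tumor profile."""
    ebv, hpv16, hpv18 = call_viral(tumor.viral, viral_cutoffs)
    return BiomarkerResult(
        tumor_id=tumor.tumor_id,
        tmb=compute_tmb(tumor.variants, roi_size_mb, af_min),
        msi_status=call_msi(tumor.msi_indel_count, msi_threshold),
        ebv_positive=ebv,
        hpv16_positive=hpv16,
        hpv18_positive=hpv18,
        scna_locus_count=count_scna_loci(tumor.cnvs),
    )


def compute_cohort_biomarkers(
    cohort: Cohort,
    af_min: float = DEFAULT_AF_MIN,
    msi_threshold: int = DEFAULT_MSI_THRESHOLD,
    viral_cutoffs: dict[str, float] | None = None,
    roi_size_mb: float | None = None,
) -> list[BiomarkerResult]:
    """Biomarkers for every tumor; ROI size defaults to the cohort panel's."""
    roi = roi_size_mb if roi_size_mb is not None else cohort.panel.roi_size_mb
    return [
        compute_biomarkers(t, roi, af_min, msi_threshold, viral_cutoffs)
        for t in cohort.tumors
    ]


def altered_genes(
    tumor: TumorProfile,
    gene_set: Sequence[str] | set[str] | frozenset[str] | None = None,
) -> set[str]:
    """Genes carrying any small variant or an SCNA gain/loss in this tumor.

    This is the default "altered" predicate of the co-mutation clustering:
    the clusters of interest are defined by amplifications and deletions
    (e.g. ERBB2 gain, CDKN2A/B loss) as much as by mutations.
    """
    genes = {v.gene for v in tumor.variants}
    for c in tumor.cnvs:
        call = c.call if c.call is not None else call_scna(c.fold_change)
        if call in ("gain", "loss"):
            genes.add(c.gene)
    if gene_set is not None:
        genes &= set(gene_set)
    return genes
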