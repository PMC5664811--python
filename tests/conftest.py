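import pytest

from panelclass.models import (
    ClinicalRecord,
    Cohort,
    CopyNumberCall,
    GenePanel,
    TumorProfile,
    VariantCall,
    ViralReadFractions,
)


@pytest.fixture
def small_panel() -> GenePanel:
    genes = {"TP53", "ERBB2", "KRAS", "CDKN2A", "CDKN2B", "BRCA2", "ATM", "CDH1", "APC", "MYC"}
    actionable = {"ERBB2", "KRAS", "CDKN2A", "CDKN2B", "BRCA2", "ATM"}
    return GenePanel(genes=frozenset(genes), actionable_genes=frozenset(actionable), roi_size_mb=1.0)


def make_tumor(
    tumor_id: str,
    mutated: list[str] | None = None,
    gained: list[str] | None = None,
    lost: list[str] | None = None,
    ebv_pct: float = 0.0,
    msi_indel_count: int = 0,
    lauren: str = "unknown",
    af: float = 0.5,
    impact: str = "moderate",
) -> TumorProfile:
    variants = [
        VariantCall(gene=g, var_class="SNV", allele_fraction=af, impact=impact)
        for g in (mutated or [])
    ]
    cnvs = [CopyNumberCall(gene=g, fold_change=4.0, call="gain") for g in (gained or [])]
    cnvs += [CopyNumberCall(gene=g, fold_change=0.4, call="loss") for g in (lost or [])]
    return TumorProfile(
        tumor_id=tumor_id,
        variants=variants,
        cnvs=cnvs,
        viral=ViralReadFractions(ebv_pct=ebv_pct),
        msi_indel_count=msi_indel_count,
        clinical=ClinicalRecord(lauren_type=lauren),
    )


@pytest.fixture
def small_cohort(small_panel) -> Cohort:
    tumors = [
        make_tumor("T1", mutated=["TP53", "BRCA2"], gained=["ERBB2"]),
        make_tumor("T2", mutated=["TP53"], lost=["CDKN2A", "CDKN2B"]),
        make_tumor("T3", mutated=["KRAS", "ATM"], msi_indel_count=30),
        make_tumor("T4", ebv_pct=0.01),
    ]
    return Cohort(panel=small_panel, tumors=tumors)
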