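"""Readers and writers for the cohort's tabular dialects.

Canonical inputs are tab-separated UTF-8 files with a header row:

* variants: ``tumor_id  gene  var_class  allele_fraction  impact  [protein_change]``
* copy number: ``tumor_id  gene  fold_change``
* viral: ``tumor_id  ebv_pct  hpv16_pct  hpv18_pct``
* MSI: ``tumor_id  indel_count``
* clinical: ``tumor_id  age  sex  lauren_type  stage``
* panel: ``gene  actionable`` (0/1)

A VCF (v4.2, one sample per file) may replace the variant TSV; the allele
fraction is taken from FORMAT/AF when present, computed from FORMAT/AD
otherwise, and the putative impact comes from a configurable INFO key.

Genes outside the panel are dropped with a logged warning — calling is
restricted to the captured region, so out-of-panel symbols are treated as
annotation noise rather than errors.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .biomarkers import call_scna
from .models import (
    ClinicalRecord,
    Cohort,
    CopyNumberCall,
    GenePanel,
    TumorProfile,
    VariantCall,
    ViralReadFractions,
    normalize_impact,
)

logger = logging.getLogger(__name__)

DEFAULT_ROI_SIZE_MB = 1.7

_VARIANT_COLUMNS = ("tumor_id", "gene", "var_class", "allele_fraction", "impact")

_VAR_CLASS_SYNONYMS = {
    "snv": "SNV",
    "snp": "SNV",
    "snvs": "SNV",
    "insertion": "insertion",
    "ins": "insertion",
    "deletion": "deletion",
    "del": "deletion",
}


class FormatError(ValueError):
    """A structural problem in an input file (missing column, bad record)."""


def _read_tsv(path: str | os.PathLike, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tumor_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_panel(path: str | os.PathLike, roi_size_mb: float = DEFAULT_ROI_SIZE_MB) -> GenePanel:
    """Panel TSV (gene, actionable 0/1) -> GenePanel."""
    df = _read_tsv(path, ("gene", "actionable"))
    genes = frozenset(df["gene"].astype(str))
    if len(genes) != len(df):
        raise FormatError(f"{path}: duplicate gene symbols in panel")
    actionable = frozenset(df.loc[df["actionable"].astype(int) == 1, "gene"].astype(str))
    return GenePanel(genes=genes, actionable_genes=actionable, roi_size_mb=roi_size_mb)


def _parse_variant_row(row: Mapping, line_no: int, path) -> VariantCall:
    raw_class = str(row["var_class"]).strip().lower()
    var_class = _VAR_CLASS_SYNONYMS.get(raw_class)
    if var_class is None:
        raise FormatError(f"{path}: line {line_no}: unknown var_class {row['var_class']!r}")
    try:
        af = float(row["allele_fraction"])
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}: line {line_no}: unparseable allele_fraction {row['allele_fraction']!r}"
        ) from None
    protein_change = row.get("protein_change")
    if protein_change is not None and (pd.isna(protein_change) or protein_change == ""):
        protein_change = None
    return VariantCall(
        gene=str(row["gene"]),
        var_class=var_class,
        allele_fraction=af,
        impact=normalize_impact(row["impact"]),
        protein_change=protein_change,
    )


def read_variants(
    path: str | os.PathLike,
    panel: GenePanel,
    tumor_id: str | None = None,
    vcf_impact_key: str = "IMPACT",
    vcf_gene_key: str = "GENE",
) -> dict[str, list[VariantCall]]:
    """Parse variant calls grouped by tumor_id from a MAF-like TSV or a VCF.

    A ``.vcf`` extension selects the VCF route (one sample per file; the
    tumor id defaults to the VCF sample name). Genes outside the panel are
    dropped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.lower().endswith(".vcf.gz"):
        return _read_variants_vcf(path, panel, tumor_id, vcf_impact_key, vcf_gene_key)
    df = _read_tsv(path, _VARIANT_COLUMNS)
    out: dict[str, list[VariantCall]] = {}
    dropped = 0
    for idx, row in df.iterrows():
        call = _parse_variant_row(row, idx + 2, path)  # +2: header + 1-based
        if call.gene not in panel.genes:
            dropped += 1
            continue
        out.setdefault(str(row["tumor_id"]), []).append(call)
    if dropped:
        logger.warning("%s: dropped %d variant(s) in genes outside the panel", path, dropped)
    return out


def _read_variants_vcf(path, panel, tumor_id, impact_key, gene_key):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if tumor_id is None:
        tumor_id = vcf.samples[0] if vcf.samples else path.stem
    calls: list[VariantCall] = []
    dropped = 0
    for rec in vcf:
        gene = rec.INFO.get(gene_key)
        if gene is None:
            continue
        ref, alt = rec.REF, rec.ALT[0] if rec.ALT else rec.REF
        if len(ref) == len(alt) == 1:
            var_class = "SNV"
        elif len(alt) > len(ref):
            var_class = "insertion"
        else:
            var_class = "deletion"
        af = _vcf_allele_fraction(rec)
        if af is None:
            raise FormatError(f"{path}: {rec.CHROM}:{rec.POS}: no AF or AD available")
        impact = rec.INFO.get(impact_key, "silent")
        call = VariantCall(
            gene=str(gene),
            var_class=var_class,
            allele_fraction=float(af),
            impact=normalize_impact(impact),
        )
        if call.gene not in panel.genes:
            dropped += 1
            continue
        calls.append(call)
    if dropped:
        logger.warning("%s: dropped %d variant(s) in genes outside the panel", path, dropped)
    return {tumor_id: calls}


def _vcf_allele_fraction(rec):
    try:
        af = rec.format("AF")
        if af is not None:
            return float(af[0][0])
    except (KeyError, TypeError):
        pass
    info_af = rec.INFO.get("AF")
    if info_af is not None:
        return float(info_af if not isinstance(info_af, tuple) else info_af[0])
    try:
        ad = rec.format("AD")
    except (KeyError, TypeError):
        ad = None
    if ad is not None:
        ref_d, alt_d = float(ad[0][0]), float(ad[0][1])
        total = ref_d + alt_d
        return alt_d / total if total > 0 else None
    return None


def read_cnv(path: str | os.PathLike, panel: GenePanel) -> dict[str, list[CopyNumberCall]]:
    df = _read_tsv(path, ("tumor_id", "gene", "fold_change"))
    out: dict[str, list[CopyNumberCall]] = {}
    dropped = 0
    for idx, row in df.iterrows():
        gene = str(row["gene"])
        if gene not in panel.genes:
            dropped += 1
            continue
        try:
            fc = float(row["fold_change"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {idx + 2}: unparseable fold_change {row['fold_change']!r}"
            ) from None
        out.setdefault(str(row["tumor_id"]), []).append(
            CopyNumberCall(gene=gene, fold_change=fc, call=call_scna(fc))
        )
    if dropped:
        logger.warning("%s: dropped %d CNV call(s) in genes outside the panel", path, dropped)
    return out


def read_viral(path: str | os.PathLike) -> dict[str, ViralReadFractions]:
    df = _read_tsv(path, ("tumor_id", "ebv_pct", "hpv16_pct", "hpv18_pct"))
    return {
        str(r["tumor_id"]): ViralReadFractions(
            ebv_pct=float(r["ebv_pct"]),
            hpv16_pct=float(r["hpv16_pct"]),
            hpv18_pct=float(r["hpv18_pct"]),
        )
        for _, r in df.iterrows()
    }


def read_msi(path: str | os.PathLike) -> dict[str, int]:
    df = _read_tsv(path, ("tumor_id", "indel_count"))
    return {str(r["tumor_id"]): int(r["indel_count"]) for _, r in df.iterrows()}


def read_clinical(path: str | os.PathLike) -> dict[str, ClinicalRecord]:
    df = _read_tsv(path, ("tumor_id",))
    if df["tumor_id"].duplicated().any():
        dupes = sorted(df.loc[df["tumor_id"].duplicated(), "tumor_id"].unique())
        raise FormatError(f"{path}: duplicate tumor_id in clinical table: {dupes}")
    out = {}
    for _, r in df.iterrows():
        out[str(r["tumor_id"])] = ClinicalRecord(
            age=float(r["age"]) if "age" in df.columns and pd.notna(r.get("age")) else None,
            sex=str(r["sex"]) if "sex" in df.columns and pd.notna(r.get("sex")) else None,
            lauren_type=str(r["lauren_type"]) if "lauren_type" in df.columns and pd.notna(r.get("lauren_type")) else "unknown",
            stage=str(r["stage"]) if "stage" in df.columns and pd.notna(r.get("stage")) else None,
        )
    return out


def read_cohort(
    variants_path: str | os.PathLike,
    cnv_path: str | os.PathLike,
    viral_path: str | os.PathLike,
    msi_path: str | os.PathLike,
    clinical_path: str | os.PathLike,
    panel_path: str | os.PathLike,
    roi_size_mb: float = DEFAULT_ROI_SIZE_MB,
) -> Cohort:
    """Assemble one TumorProfile per clinical-table tumor.

    The clinical table defines the tumor universe; tumors missing from an
    auxiliary table get empty/zero defaults with a logged warning.
    """
    panel = read_panel(panel_path, roi_size_mb)
    clinical = read_clinical(clinical_path)
    variants = read_variants(variants_path, panel)
    cnvs = read_cnv(cnv_path, panel)
    viral = read_viral(viral_path)
    msi = read_msi(msi_path)
    tumors = []
    for tid in clinical:
        for name, table in (("variants", variants), ("cnv", cnvs), ("viral", viral), ("msi", msi)):
            if tid not in table:
                logger.warning("tumor %s missing from %s table; using empty/zero default", tid, name)
        tumors.append(
            TumorProfile(
                tumor_id=tid,
                variants=variants.get(tid, []),
                cnvs=cnvs.get(tid, []),
                viral=viral.get(tid, ViralReadFractions()),
                msi_indel_count=msi.get(tid, 0),
                clinical=clinical[tid],
            )
        )
    return Cohort(panel=panel, tumors=tumors)


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write a cohort back to the canonical TSV dialects (round-trippable).

    Numeric fields are printed to 6 significant digits. Returns the paths
    written, keyed by table name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in ("variants", "cnv", "viral", "msi", "clinical", "panel")}

    with open(paths["panel"], "w") as fh:
        fh.write("gene\tactionable\n")
        for g in sorted(cohort.panel.genes):
            fh.write(f"{g}\t{int(g in cohort.panel.actionable_genes)}\n")

    with open(paths["variants"], "w") as fh:
        fh.write("tumor_id\tgene\tvar_class\tallele_fraction\timpact\tprotein_change\n")
        for t in cohort.tumors:
            for v in sorted(t.variants, key=lambda v: (v.gene, v.var_class, v.allele_fraction)):
                fh.write(
                    f"{t.tumor_id}\t{v.gene}\t{v.var_class}\t{_fmt(v.allele_fraction)}\t"
                    f"{v.impact}\t{v.protein_change or ''}\n"
                )

    with open(paths["cnv"], "w") as fh:
        fh.write("tumor_id\tgene\tfold_change\n")
        for t in cohort.tumors:
            for c in sorted(t.cnvs, key=lambda c: c.gene):
                fh.write(f"{t.tumor_id}\t{c.gene}\t{_fmt(c.fold_change)}\n")

    with open(paths["viral"], "w") as fh:
        fh.write("tumor_id\tebv_pct\thpv16_pct\thpv18_pct\n")
        for t in cohort.tumors:
            v = t.viral
            fh.write(f"{t.tumor_id}\t{_fmt(v.ebv_pct)}\t{_fmt(v.hpv16_pct)}\t{_fmt(v.hpv18_pct)}\n")

    with open(paths["msi"], "w") as fh:
        fh.write("tumor_id\tindel_count\n")
        for t in cohort.tumors:
            fh.write(f"{t.tumor_id}\t{t.msi_indel_count}\n")

    with open(paths["clinical"], "w") as fh:
        fh.write("tumor_id\tage\tsex\tlauren_type\tstage\n")
        for t in cohort.tumors:
            c = t.clinical
            age = _fmt(c.age) if c.age is not None else ""
            fh.write(f"{t.tumor_id}\t{age}\t{c.sex or ''}\t{c.lauren_type}\t{c.stage or ''}\n")
    return paths


def write_oncoprint(cohort: Cohort, path: str | os.PathLike) -> None:
    """Long-format alteration table: one row per (tumor, gene, class).

    alteration_class is mutation / amplification / deletion; rows are sorted
    by tumor, gene, then class so repeated runs are byte-identical.
    """
    rows: set[tuple[str, str, str]] = set()
    for t in cohort.tumors:
        for v in t.variants:
            rows.add((t.tumor_id, v.gene, "mutation"))
        for c in t.cnvs:
            call = c.call if c.call is not None else call_scna(c.fold_change)
            if call == "gain":
                rows.add((t.tumor_id, c.gene, "amplification"))
            elif call == "loss":
                rows.add((t.tumor_id, c.gene, "deletion"))
    with open(path, "w") as fh:
        fh.write("tumor_id\tgene\talteration_class\n")
        for tid, gene, cls in sorted(rows):
            fh.write(f"{tid}\t{gene}\t{cls}\n")


def write_cohort_summary(cohort: Cohort, path: str | os.PathLike) -> dict:
    """JSON summary of cohort composition; returns the dict written."""
    summary = {
        "n_tumors": len(cohort),
        "panel_size": len(cohort.panel.genes),
        "n_actionable_genes": len(cohort.panel.actionable_genes),
        "roi_size_mb": cohort.panel.roi_size_mb,
        "n_variants": sum(len(t.variants) for t in cohort.tumors),
        "n_cnv_calls": sum(len(t.cnvs) for t in cohort.tumors),
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
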