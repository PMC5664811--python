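"""Synthetic gastric-cancer panel cohorts with known ground truth.

The generator emits cohorts with the statistical structure the downstream
analysis assumes, so every stage — biomarker calling, subtyping,
hypermutation cutoff derivation, co-alteration clustering, association
statistics — can be exercised and validated without any external data:

* a four-way molecular subtype mixture (EBV / MSI / CIN / GS) realized by
  planting the defining biomarker of each subtype (EBV read fraction above
  cutoff, repeat-locus indel burden above threshold, >= 4 distinct SCNA
  loci, SCNA-low respectively);
* bimodal tumor mutation burden: an MSI-H arm (default uniform over
  18.5–66.9 counts/Mb) well separated from the MSS arm (3.1–27.7), with one
  MSI-H tumor anchored at the arm floor so the data-derived hypermutation
  cutoff equals the floor and the planted hypermutated set is recovered
  exactly;
* planted actionable-gene clusters among non-hypermutated tumors (ERBB2
  amplification, CDKN2A/B co-deletion, KRAS, BRCA2 and ATM mutation), each
  label firing with a high within-cluster probability and a low background
  probability elsewhere;
* per-gene background alteration probabilities seeded from a published
  207-tumor frequency table (TP53 53.1% mutation, ERBB2 12.1%
  amplification, ...), with qualitative subtype coupling (TP53 enriched in
  CIN, CDH1 in GS);
* clinicopathological fields with the canonical histology coupling
  (intestinal type enriched in CIN, diffuse in GS).

TMB is realized through actual variant lists: a tumor with target burden t
receives ceil(t * roi) qualifying SNVs when it belongs to a hypermutated arm
and floor(t * roi) otherwise, which guarantees — under count quantization —
that every hypermutated-arm tumor stays at or above the MSI-H arm floor and
every other tumor stays below it. Filler and noise variants for
non-hypermutated tumors avoid actionable genes so the planted cluster
structure is not diluted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import DEFAULT_MSI_THRESHOLD, DEFAULT_VIRAL_CUTOFFS, call_scna
from .models import (
    ClinicalRecord,
    Cohort,
    CopyNumberCall,
    GenePanel,
    TumorProfile,
    VariantCall,
    ViralReadFractions,
)

GENERATOR_VERSION = "1.0"

SUBTYPES = ("EBV", "MSI", "CIN", "GS")

#: genes from the published mutation-frequency column (top 20)
DEFAULT_MUTATION_FREQS = {
    "TP53": 0.531, "ARID1A": 0.159, "CDH1": 0.140, "BRCA2": 0.106,
    "ARID1B": 0.101, "ATM": 0.097, "PIK3CA": 0.087, "APC": 0.082,
    "ACVR2A": 0.072, "CHD2": 0.063, "KMT2D": 0.063, "RNF43": 0.058,
    "EPHA2": 0.058, "TGFBR2": 0.053, "FLCN": 0.043, "PALB2": 0.043,
    "PTPRT": 0.043, "RAD50": 0.043, "BRCA1": 0.039, "STK11": 0.039,
}
#: genes from the published SCNA-frequency column (top 20), class AMP/DEL
DEFAULT_SCNA_FREQS = {
    "ERBB2": ("AMP", 0.121), "CCNE1": ("AMP", 0.068), "KRAS": ("AMP", 0.058),
    "ZNF217": ("AMP", 0.058), "CDKN2A": ("DEL", 0.053), "CDKN2B": ("DEL", 0.053),
    "GATA4": ("AMP", 0.043), "MYC": ("AMP", 0.024), "CCND3": ("AMP", 0.019),
    "CD274": ("AMP", 0.019), "CDK6": ("AMP", 0.019), "EGFR": ("AMP", 0.019),
    "FGFR2": ("AMP", 0.019), "JAK2": ("AMP", 0.019), "GNAS": ("AMP", 0.019),
    "CCND1": ("AMP", 0.014), "MET": ("AMP", 0.014), "HSP90AB1": ("AMP", 0.014),
    "SMAD4": ("DEL", 0.014), "TEK": ("DEL", 0.014),
}

_REAL_ACTIONABLE = (
    "ERBB2", "KRAS", "CDKN2A", "CDKN2B", "BRCA2", "ATM", "PIK3CA", "RNF43",
    "FLCN", "PALB2", "BRCA1", "STK11", "CCND3", "CD274", "CDK6", "EGFR",
    "FGFR2", "JAK2", "CCND1", "MET",
)
_REAL_OTHER = (
    "TP53", "ARID1A", "CDH1", "ARID1B", "APC", "ACVR2A", "CHD2", "KMT2D",
    "EPHA2", "TGFBR2", "PTPRT", "RAD50", "CCNE1", "ZNF217", "GATA4", "MYC",
    "GNAS", "HSP90AB1", "SMAD4", "TEK",
)

#: alteration class of each planted cluster label
_LABEL_CLASSES = {
    "ERBB2": "AMP", "CDKN2A": "DEL", "CDKN2B": "DEL",
    "KRAS": "mutation", "BRCA2": "mutation", "ATM": "mutation",
}


def default_panel(
    n_genes: int = 435,
    n_actionable: int = 69,
    roi_size_mb: float = 1.7,
) -> GenePanel:
    """A 435-gene / 69-actionable panel: published symbols padded with
    synthetic placeholders (ACTxx actionable, PNLxxx background)."""
    actionable = list(_REAL_ACTIONABLE)
    actionable += [f"ACT{i:02d}" for i in range(len(actionable) + 1, n_actionable + 1)]
    genes = list(_REAL_OTHER) + actionable[:]
    genes += [f"PNL{i:03d}" for i in range(1, n_genes - len(genes) + 1)]
    return GenePanel(
        genes=frozenset(genes),
        actionable_genes=frozenset(actionable),
        roi_size_mb=roi_size_mb,
    )


@dataclass(frozen=True)
class PlantedCluster:
    """One planted co-alteration cluster: its label gene(s), size, and the
    per-tumor firing probabilities inside and outside the cluster."""

    label: str                 # e.g. "ERBB2" or "CDKN2A/B" (joint co-deletion)
    size: int
    within_prob: float = 0.9
    background_prob: float = 0.05

    def genes(self) -> tuple[str, ...]:
        if self.label == "CDKN2A/B":
            return ("CDKN2A", "CDKN2B")
        return (self.label,)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All generator parameters. Defaults emulate the 207-tumor study
    conditions; see :func:`paper_default_spec`."""

    n_tumors: int = 207
    seed: int = 0
    subtype_mixture: tuple[float, float, float, float] = (9 / 207, 17 / 207, 119 / 207, 62 / 207)
    hypermutated_count: int = 32
    planted_clusters: tuple[PlantedCluster, ...] = (
        PlantedCluster("ERBB2", 25),
        PlantedCluster("CDKN2A/B", 10),
        PlantedCluster("KRAS", 10),
        PlantedCluster("BRCA2", 9),
        PlantedCluster("ATM", 12),
    )
    tmb_msih: tuple[float, float] = (18.5, 66.9)
    tmb_mss: tuple[float, float] = (3.1, 27.7)
    tmb_shape: str = "uniform"          # or "triangular"
    tmb_msih_median: float = 31.5       # used by the triangular option
    tmb_mss_median: float = 11.2
    mutation_freqs: dict = field(default_factory=lambda: dict(DEFAULT_MUTATION_FREQS))
    scna_freqs: dict = field(default_factory=lambda: dict(DEFAULT_SCNA_FREQS))
    subtype_enrichment: dict = field(
        default_factory=lambda: {"TP53": {"CIN": 1.3, "GS": 0.55}, "CDH1": {"GS": 1.8, "CIN": 0.6}}
    )
    msi_threshold: int = DEFAULT_MSI_THRESHOLD
    msih_indel_extra_mean: float = 25.0
    mss_indel_mean: float = 3.0
    ebv_positive_range: tuple[float, float] = (0.001, 0.05)
    ebv_negative_max: float = 0.0003
    hpv_positive_prob: float = 0.01
    scna_cutoff: int = 4
    cin_extra_loci_mean: float = 3.0
    gain_fold_range: tuple[float, float] = (2.6, 8.0)
    loss_fold_range: tuple[float, float] = (0.25, 0.7)
    neutral_cnv_mean: float = 1.5
    noise_silent_mean: float = 1.5
    noise_lowaf_mean: float = 1.0
    indel_mean_msih: float = 3.0
    indel_mean_other: float = 0.3
    panel: GenePanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if abs(sum(self.subtype_mixture) - 1.0) > 1e-9:
            raise ValueError("subtype_mixture must sum to 1")
        if any(p < 0 for p in self.subtype_mixture):
            raise ValueError("subtype_mixture proportions must be non-negative")
        if self.tmb_shape not in ("uniform", "triangular"):
            raise ValueError("tmb_shape must be 'uniform' or 'triangular'")


def paper_default_spec() -> SyntheticCohortSpec:
    """The default study conditions: 207 tumors, subtype counts 9/17/119/62,
    32 hypermutated, six co-alteration clusters of sizes 25/10/10/9/12/109."""
    return SyntheticCohortSpec()


def scaled_default_spec(n_tumors: int, seed: int = 0) -> SyntheticCohortSpec:
    """Default study conditions scaled to a different cohort size.

    The hypermutated count and planted cluster sizes shrink (or grow)
    proportionally so the cohort structure stays feasible and similar in
    shape at any n.
    """
    base = paper_default_spec()
    if n_tumors == base.n_tumors:
        return replace(base, seed=seed)
    f = n_tumors / base.n_tumors
    hyper = int(round(base.hypermutated_count * f))
    clusters = []
    budget = n_tumors - hyper
    for pc in base.planted_clusters:
        size = min(max(1, int(round(pc.size * f))), budget)
        if size:
            clusters.append(replace(pc, size=size))
            budget -= size
    return replace(
        base,
        n_tumors=n_tumors,
        seed=seed,
        hypermutated_count=hyper,
        planted_clusters=tuple(clusters),
    )


def _largest_remainder_counts(proportions: Sequence[float], n: int) -> list[int]:
    raw = [p * n for p in proportions]
    counts = [math.floor(r) for r in raw]
    shortfall = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def _background_prob(
    gene: str,
    prob: float,
    is_hyper: bool,
    actionable: frozenset[str],
    label_genes: set[str],
    hyper_boost: float,
) -> float:
    """Background alteration probability for one gene in one tumor.

    Label genes in non-hypermutated tumors are governed solely by the
    planted-cluster model; other actionable genes fire only in the
    hypermutated arm (rate scaled to preserve the cohort-level frequency);
    non-actionable genes keep their frequency everywhere.
    """
    if not is_hyper:
        if gene in label_genes or gene in actionable:
            return 0.0
        return prob
    if gene in actionable and gene not in label_genes:
        return min(1.0, prob * hyper_boost)
    return prob


def _triangular_mode(lo: float, hi: float, median: float) -> float:
    if not lo <= median <= hi:
        raise ValueError("median must lie within the range")
    if median >= (lo + hi) / 2:
        return hi - 2 * (hi - median) ** 2 / (hi - lo)
    return lo + 2 * (median - lo) ** 2 / (hi - lo)


def _draw_tmb(rng: np.random.Generator, lo: float, hi: float, shape: str, median: float | None) -> float:
    if hi <= lo:
        return lo
    if shape == "triangular":
        m = median if median is not None else (lo + hi) / 2
        return float(rng.triangular(lo, _triangular_mode(lo, hi, min(max(m, lo), hi)), hi))
    return float(rng.uniform(lo, hi))


def generate_cohort(
    spec: SyntheticCohortSpec,
    seed: Optional[int] = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus its ground-truth table.

    The truth table has one row per tumor: intended subtype, intended
    cluster label ('none' for the background cluster and for hypermutated
    tumors), and the hypermutation flag. Identical seeds give identical
    cohorts.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_tumors
    panel = spec.panel
    roi = panel.roi_size_mb
    cutoff = spec.tmb_msih[0]

    counts = _largest_remainder_counts(spec.subtype_mixture, n)
    subtype_of = np.repeat(SUBTYPES, counts)
    rng.shuffle(subtype_of)

    msi_idx = [i for i in range(n) if subtype_of[i] == "MSI"]
    non_msi_idx = [i for i in range(n) if subtype_of[i] != "MSI"]
    n_extra_hyper = max(0, min(spec.hypermutated_count - len(msi_idx), len(non_msi_idx)))
    extra_hyper = set(
        rng.choice(non_msi_idx, size=n_extra_hyper, replace=False).tolist()
    ) if n_extra_hyper else set()
    hyper = np.array([subtype_of[i] == "MSI" or i in extra_hyper for i in range(n)])

    non_hyper_idx = [i for i in range(n) if not hyper[i]]
    planted_sizes = sum(pc.size for pc in spec.planted_clusters)
    if planted_sizes > len(non_hyper_idx):
        raise ValueError(
            f"planted cluster sizes ({planted_sizes}) exceed the non-hypermutated pool "
            f"({len(non_hyper_idx)})"
        )
    cluster_of = {i: "none" for i in range(n)}
    pool = rng.permutation(non_hyper_idx).tolist()
    for pc in spec.planted_clusters:
        for i in pool[:pc.size]:
            cluster_of[i] = pc.label
        pool = pool[pc.size:]

    label_genes = {g for pc in spec.planted_clusters for g in pc.genes()}
    actionable = panel.actionable_genes
    filler_pool_nonhyper = sorted(panel.genes - actionable)
    filler_pool_all = sorted(panel.genes)
    anchor_msi = min(msi_idx) if msi_idx else None
    # Recurrent non-label actionable alterations are concentrated in the
    # hypermutated arm (mutator phenotype), preserving the cohort-level
    # frequency while keeping the non-hypermutated actionable landscape
    # equal to the planted six-cluster structure.
    n_hyper = int(hyper.sum())
    hyper_boost = n / n_hyper if n_hyper else 1.0

    tumors: list[TumorProfile] = []
    truth_rows = []
    for i in range(n):
        st = str(subtype_of[i])
        is_hyper = bool(hyper[i])
        tid = f"GC{i + 1:03d}"

        # --- target mutation burden and qualifying SNV count ---
        if st == "MSI":
            if i == anchor_msi:
                t = spec.tmb_msih[0]
            else:
                t = _draw_tmb(rng, *spec.tmb_msih, spec.tmb_shape, spec.tmb_msih_median)
            q = math.ceil(t * roi)
        elif is_hyper:
            lo = max(cutoff, spec.tmb_mss[0])
            hi = max(spec.tmb_mss[1], lo)
            t = _draw_tmb(rng, lo, hi, "uniform", None)
            q = math.ceil(t * roi)
        else:
            lo = spec.tmb_mss[0]
            hi = min(spec.tmb_mss[1], cutoff)
            t = _draw_tmb(rng, lo, min(hi, cutoff), spec.tmb_shape, spec.tmb_mss_median) if hi > lo else lo
            q = math.floor(min(t, cutoff) * roi)

        # --- altered gene sets: planted labels, then background frequencies ---
        mutated: set[str] = set()
        scna_gain: set[str] = set()
        scna_loss: set[str] = set()

        def _add(gene: str, cls: str) -> None:
            if cls == "mutation":
                mutated.add(gene)
            elif cls == "AMP":
                scna_gain.add(gene)
            else:
                scna_loss.add(gene)

        if not is_hyper:
            for pc in spec.planted_clusters:
                prob = pc.within_prob if cluster_of[i] == pc.label else pc.background_prob
                if rng.random() < prob:
                    for g in pc.genes():
                        _add(g, _LABEL_CLASSES.get(g, "mutation"))

        for gene, prob in sorted(spec.mutation_freqs.items()):
            p = _background_prob(gene, prob, is_hyper, actionable, label_genes, hyper_boost)
            p *= spec.subtype_enrichment.get(gene, {}).get(st, 1.0)
            if rng.random() < min(p, 1.0):
                mutated.add(gene)
        for gene, (cls, prob) in sorted(spec.scna_freqs.items()):
            p = _background_prob(gene, prob, is_hyper, actionable, label_genes, hyper_boost)
            p *= spec.subtype_enrichment.get(gene, {}).get(st, 1.0)
            if rng.random() < min(p, 1.0):
                _add(gene, cls)

        # --- SCNA locus count control per intended subtype ---
        scna_genes = scna_gain | scna_loss
        planted_scna = scna_genes & label_genes if not is_hyper else set()
        if st == "CIN":
            target = spec.scna_cutoff + rng.poisson(spec.cin_extra_loci_mean)
            target = max(target, spec.scna_cutoff, len(scna_genes))
            pool_sc = [g for g in (filler_pool_nonhyper if not is_hyper else filler_pool_all)
                       if g not in scna_genes]
            extra = rng.choice(pool_sc, size=target - len(scna_genes), replace=False)
            for g in extra:
                (scna_gain if rng.random() < 0.7 else scna_loss).add(str(g))
        else:
            cap = spec.scna_cutoff - 1
            droppable = sorted(scna_genes - planted_scna)
            while len(scna_gain | scna_loss) > max(cap, len(planted_scna)) and droppable:
                g = droppable.pop(int(rng.integers(len(droppable))))
                scna_gain.discard(g)
                scna_loss.discard(g)

        # --- realize variant list ---
        variants: list[VariantCall] = []
        n_qual = max(q, len(mutated))
        filler_n = n_qual - len(mutated)
        pool_m = [g for g in (filler_pool_nonhyper if not is_hyper else filler_pool_all)
                  if g not in mutated]
        filler = rng.choice(pool_m, size=min(filler_n, len(pool_m)), replace=False) if filler_n else []
        qual_genes = sorted(mutated) + [str(g) for g in filler]
        for g in qual_genes:
            variants.append(
                VariantCall(
                    gene=g,
                    var_class="SNV",
                    allele_fraction=float(rng.uniform(0.10, 0.95)),
                    impact=str(rng.choice(["high", "moderate"], p=[0.35, 0.65])),
                )
            )
        # noise: silent / low-impact SNVs and sub-threshold AF SNVs (not TMB-qualifying)
        noise_pool = filler_pool_nonhyper if not is_hyper else filler_pool_all
        for _ in range(rng.poisson(spec.noise_silent_mean)):
            variants.append(
                VariantCall(
                    gene=str(rng.choice(noise_pool)),
                    var_class="SNV",
                    allele_fraction=float(rng.uniform(0.05, 0.9)),
                    impact=str(rng.choice(["silent", "low"])),
                )
            )
        for _ in range(rng.poisson(spec.noise_lowaf_mean)):
            variants.append(
                VariantCall(
                    gene=str(rng.choice(noise_pool)),
                    var_class="SNV",
                    allele_fraction=float(rng.uniform(0.01, 0.0999)),
                    impact="moderate",
                )
            )
        indel_mean = spec.indel_mean_msih if st == "MSI" else spec.indel_mean_other
        for _ in range(rng.poisson(indel_mean)):
            variants.append(
                VariantCall(
                    gene=str(rng.choice(noise_pool)),
                    var_class=str(rng.choice(["insertion", "deletion"])),
                    allele_fraction=float(rng.uniform(0.1, 0.6)),
                    impact="high",
                )
            )

        # --- copy-number calls ---
        cnvs: list[CopyNumberCall] = []
        for g in sorted(scna_gain):
            fc = float(rng.uniform(*spec.gain_fold_range))
            cnvs.append(CopyNumberCall(gene=g, fold_change=fc, call=call_scna(fc)))
        for g in sorted(scna_loss):
            fc = float(rng.uniform(*spec.loss_fold_range))
            cnvs.append(CopyNumberCall(gene=g, fold_change=fc, call=call_scna(fc)))
        taken = scna_gain | scna_loss
        pool_n = [g for g in noise_pool if g not in taken]
        for _ in range(rng.poisson(spec.neutral_cnv_mean)):
            g = str(rng.choice(pool_n))
            fc = float(rng.uniform(0.8, 2.4))
            cnvs.append(CopyNumberCall(gene=g, fold_change=fc, call=call_scna(fc)))

        # --- viral fractions, MSI indel count, clinical record ---
        if st == "EBV":
            lo, hi = spec.ebv_positive_range
            ebv = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
        else:
            ebv = float(rng.uniform(0, spec.ebv_negative_max))
        hpv16 = float(rng.uniform(DEFAULT_VIRAL_CUTOFFS["hpv16"], 5 * DEFAULT_VIRAL_CUTOFFS["hpv16"])) \
            if rng.random() < spec.hpv_positive_prob else float(rng.uniform(0, 0.3 * DEFAULT_VIRAL_CUTOFFS["hpv16"]))
        hpv18 = float(rng.uniform(DEFAULT_VIRAL_CUTOFFS["hpv18"], 5 * DEFAULT_VIRAL_CUTOFFS["hpv18"])) \
            if rng.random() < spec.hpv_positive_prob else float(rng.uniform(0, 0.3 * DEFAULT_VIRAL_CUTOFFS["hpv18"]))

        if st == "MSI":
            msi_count = int(spec.msi_threshold + rng.poisson(spec.msih_indel_extra_mean))
        else:
            msi_count = int(min(rng.poisson(spec.mss_indel_mean), spec.msi_threshold - 1))

        lauren_probs = {
            "CIN": (0.65, 0.20, 0.10, 0.05),
            "GS": (0.20, 0.65, 0.10, 0.05),
            "EBV": (0.45, 0.35, 0.15, 0.05),
            "MSI": (0.45, 0.35, 0.15, 0.05),
        }[st]
        clinical = ClinicalRecord(
            age=float(np.clip(rng.normal(66.0, 11.0), 27.0, 87.0)),
            sex=str(rng.choice(["male", "female"], p=[0.705, 0.295])),
            lauren_type=str(rng.choice(["intestinal", "diffuse", "mixed", "unknown"], p=lauren_probs)),
            stage=str(rng.choice(["I", "II", "III", "IV"], p=[0.25, 0.30, 0.30, 0.15])),
        )

        tumors.append(
            TumorProfile(
                tumor_id=tid,
                variants=variants,
                cnvs=cnvs,
                viral=ViralReadFractions(ebv_pct=ebv, hpv16_pct=hpv16, hpv18_pct=hpv18),
                msi_indel_count=msi_count,
                clinical=clinical,
            )
        )
        # Realized cluster: alteration-defined membership — the first planted
        # label (in cluster order) whose gene the tumor actually carries.
        # This is the ground truth for clustering recovery: cluster 1 *is*
        # the set of ERBB2-altered tumors, so a background tumor that drew
        # an ERBB2 alteration belongs to it, and an intended member whose
        # label did not fire does not.
        realized = "none"
        if not is_hyper:
            altered_all = mutated | scna_gain | scna_loss
            for pc in spec.planted_clusters:
                if any(g in altered_all for g in pc.genes()):
                    realized = pc.label
                    break
        truth_rows.append(
            {
                "tumor_id": tid,
                "subtype": st,
                "cluster": realized,
                "intended_cluster": cluster_of[i] if not is_hyper else "none",
                "hypermutated": is_hyper,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["tumor_id", "subtype", "cluster", "intended_cluster", "hypermutated"],
    )
    return Cohort(panel=panel, tumors=tumors), truth


def generate_cohort_dir(
    spec: SyntheticCohortSpec,
    out_dir: str,
    seed: Optional[int] = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and write it (plus truth table and metadata) to a
    directory in the canonical TSV dialects."""
    import json

    from .io import write_cohort

    cohort, truth = generate_cohort(spec, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "meta.json", "w") as fh:
        json.dump(
            {
                "generator_version": GENERATOR_VERSION,
                "seed": int(spec.seed if seed is None else seed),
                "n_tumors": spec.n_tumors,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return cohort, truth


def spec_with(spec: SyntheticCohortSpec, **overrides) -> SyntheticCohortSpec:
    """Functional update of a spec (thin wrapper over dataclasses.replace)."""
    return replace(spec, **overrides)
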