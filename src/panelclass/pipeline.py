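"""End-to-end orchestration: cohort -> biomarkers -> subtypes -> clusters -> stats.

Stage outputs are written atomically (temp file + rename) so an aborted run
leaves no partially written table. The machine-readable summary collects
subtype counts, the hypermutation cutoff and count, cluster sizes and
labels, and the top of the alteration-frequency table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import biomarkers as bm
from . import clustering, io, simulate, stats, subtyping
from .models import Cohort

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """All knobs of a full run. Defaults match the published thresholds
    (AF >= 0.10, MSI threshold 20 indels, viral cutoffs 0.02/0.01/0.0005%,
    SCNA gain > 2.5 / loss < 0.75, >= 4 loci for SCNA-high)."""

    out_dir: str = "panelclass_out"
    # either simulate a cohort ...
    simulate: bool = True
    n_tumors: int = 207
    seed: int = 0
    # ... or read one from these paths
    variants_path: Optional[str] = None
    cnv_path: Optional[str] = None
    viral_path: Optional[str] = None
    msi_path: Optional[str] = None
    clinical_path: Optional[str] = None
    panel_path: Optional[str] = None

    roi_size_mb: float = io.DEFAULT_ROI_SIZE_MB
    af_min: float = bm.DEFAULT_AF_MIN
    msi_threshold: int = bm.DEFAULT_MSI_THRESHOLD
    viral_cutoffs: dict = field(default_factory=lambda: dict(bm.DEFAULT_VIRAL_CUTOFFS))
    scna_locus_cutoff: int = subtyping.DEFAULT_SCNA_CUTOFF
    hypermutation_cutoff: str | float = "auto"
    gene_set: str = "actionable"       # or "all"
    k: str | int = 6                   # or "auto"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(path: Path, df: pd.DataFrame) -> None:
    _atomic_write(path, lambda fh: df.to_csv(fh, sep="\t", index=False))


def load_or_simulate(config: PipelineConfig) -> tuple[Cohort, Optional[pd.DataFrame]]:
    if config.simulate:
        spec = simulate.spec_with(
            simulate.scaled_default_spec(config.n_tumors, seed=config.seed),
            msi_threshold=config.msi_threshold,
            scna_cutoff=config.scna_locus_cutoff,
        )
        logger.info("stage simulate: n=%d seed=%d", config.n_tumors, config.seed)
        return simulate.generate_cohort(spec)
    required = ("variants_path", "cnv_path", "viral_path", "msi_path", "clinical_path", "panel_path")
    missing = [name for name in required if getattr(config, name) is None]
    if missing:
        raise ValueError(f"simulate=False but input path(s) missing: {missing}")
    logger.info("stage ingest: reading cohort from %s", config.clinical_path)
    cohort = io.read_cohort(
        config.variants_path, config.cnv_path, config.viral_path,
        config.msi_path, config.clinical_path, config.panel_path,
        roi_size_mb=config.roi_size_mb,
    )
    return cohort, None


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort, truth = load_or_simulate(config)
    if config.simulate:
        io.write_cohort(cohort, out / "cohort")
        if truth is not None:
            _write_df(out / "cohort" / "truth.tsv", truth)

    logger.info("stage biomarkers: roi=%.3g Mb af_min=%.2f msi_threshold=%d",
                config.roi_size_mb if not config.simulate else cohort.panel.roi_size_mb,
                config.af_min, config.msi_threshold)
    results = bm.compute_cohort_biomarkers(
        cohort,
        af_min=config.af_min,
        msi_threshold=config.msi_threshold,
        viral_cutoffs=config.viral_cutoffs,
    )
    bm_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    _write_df(out / "biomarkers.tsv", bm_df)

    cutoff = (
        subtyping.derive_hypermutation_cutoff(results)
        if config.hypermutation_cutoff == "auto"
        else float(config.hypermutation_cutoff)
    )
    logger.info("stage classify: scna_cutoff=%d hypermutation_cutoff=%.4g",
                config.scna_locus_cutoff, cutoff)
    calls = subtyping.classify_cohort(
        results, scna_cutoff=config.scna_locus_cutoff, hypermutation_cutoff=cutoff
    )
    sub_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    _write_df(out / "subtypes.tsv", sub_df)

    gene_set = (
        cohort.panel.actionable_genes if config.gene_set == "actionable" else cohort.panel.genes
    )
    non_hyper_ids = {c.tumor_id for c in calls if not c.hypermutated}
    non_hyper = [t for t in cohort.tumors if t.tumor_id in non_hyper_ids]
    k = None if config.k == "auto" else int(config.k)
    logger.info("stage cluster: gene_set=%s k=%s n_non_hypermutated=%d",
                config.gene_set, config.k, len(non_hyper))
    cres = clustering.cluster_cohort(non_hyper, gene_set, k=k)
    assign_df = pd.DataFrame(
        {
            "tumor_id": list(cres.assignments),
            "cluster": list(cres.assignments.values()),
            "label": [cres.labels[c] for c in cres.assignments.values()],
        }
    )
    _write_df(out / "clusters.tsv", assign_df)
    if cres.stability is not None:
        _write_df(out / "stability.tsv", cres.stability)
    merge_df = pd.DataFrame(cres.linkage_record, columns=["left", "right", "distance", "size"])
    _write_df(out / "merge_history.tsv", merge_df)

    logger.info("stage stats")
    freq = stats.alteration_frequencies(cohort)
    _write_df(out / "frequencies.tsv", freq)
    grouping = {tid: f"cluster_{c}" for tid, c in cres.assignments.items()}
    categorical = {
        "lauren_type": {t.tumor_id: t.clinical.lauren_type for t in cohort.tumors},
        "sex": {t.tumor_id: t.clinical.sex or "unknown" for t in cohort.tumors},
    }
    continuous = {
        "age": {t.tumor_id: t.clinical.age for t in cohort.tumors if t.clinical.age is not None},
        "scna_locus_count": {r.tumor_id: float(r.scna_locus_count) for r in results},
    }
    assoc = stats.associate_groups(grouping, categorical=categorical, continuous=continuous)
    _write_df(out / "associations.tsv", assoc)

    io.write_oncoprint(cohort, out / "oncoprint.tsv")

    subtype_counts = {s: 0 for s in subtyping.SUBTYPES}
    for c in calls:
        subtype_counts[c.subtype] += 1
    sizes = cres.sizes()
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_tumors": len(cohort),
        "subtype_counts": subtype_counts,
        "hypermutation_cutoff": cutoff,
        "hypermutated_count": sum(c.hypermutated for c in calls),
        "k": cres.k,
        "cluster_sizes": {str(c): sizes[c] for c in sorted(sizes)},
        "cluster_labels": {str(c): cres.labels[c] for c in sorted(cres.labels)},
        "top_frequencies": freq.head(20).to_dict(orient="records"),
    }
    _atomic_write(out / "summary.json", lambda fh: (json.dump(summary, fh, indent=2, sort_keys=True), fh.write("\n")) and None)
    return summary
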