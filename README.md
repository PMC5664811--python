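# panelclass

Actionable-gene-based molecular classification of gastric cancer from
targeted panel sequencing profiles.

Gastric cancer is molecularly heterogeneous, and most targeted therapies
have failed in unselected patients. Panel sequencing (here modeled on a
435-gene panel containing 69 *actionable* genes — genes paired with an
FDA-approved targeted therapy) makes genotype-driven patient selection
practical. `panelclass` implements the analysis layer of such a panel for
researchers working with gene-level tumor profiles:

* **Biomarker calling** — tumor mutation burden (TMB: peptide-changing SNVs
  per Mb with allele fraction ≥ 10% and high/moderate impact), MSI status
  from repeat-locus indel counts, EBV/HPV positivity from viral read
  fractions (cutoffs 0.0005 / 0.02 / 0.01 % of reads), and gene-level SCNA
  calls (gain > 2.5-fold, loss < 0.75-fold).
* **TCGA-style subtyping** — the sequential decision tree
  EBV⁺ → EBV; else MSI-H → MSI; else ≥ 4 SCNA loci → CIN; else GS,
  plus data-driven derivation of the SCNA locus cutoff and of the
  hypermutation cutoff (the minimum TMB among MSI-H tumors).
* **Co-alteration clustering** — for non-hypermutated donors i, j the
  shared-altered-gene count c_ij is normalized to 1/(c_ij + 1) and the rows
  of the resulting N × N matrix are clustered with Euclidean distance and
  Ward linkage; internal validation (connectivity, silhouette, Dunn) selects
  k, and clusters are labeled by their enriched actionable gene (ERBB2,
  CDKN2A/B, KRAS, BRCA2, ATM, …).
* **Cohort statistics** — alteration frequency tables, two-tailed Fisher and
  Mann–Whitney group associations with BH-adjusted values alongside.
* **A synthetic cohort generator** with ground truth, so the whole pipeline
  is testable end to end without any data download.

## Worked example

Library use — TMB applies the allele-fraction and impact filters and counts
SNVs only:

```python
from panelclass import VariantCall, compute_tmb, call_scna

variants = [
    VariantCall(gene="TP53",   var_class="SNV", allele_fraction=0.42, impact="high"),
    VariantCall(gene="PIK3CA", var_class="SNV", allele_fraction=0.31, impact="moderate"),
    VariantCall(gene="APC",    var_class="SNV", allele_fraction=0.06, impact="high"),      # below 10% AF
    VariantCall(gene="ACVR2A", var_class="deletion", allele_fraction=0.5, impact="high"),  # indel
]
compute_tmb(variants, roi_size_mb=1.7)   # 1.1764… — 2 qualifying SNVs / 1.7 Mb
call_scna(3.1), call_scna(0.6), call_scna(1.2)   # ('gain', 'loss', 'neutral')
```

Full pipeline on a simulated default cohort (207 tumors):

```bash
panelclass run-all --seed 1 --out-dir demo_out
# {"EBV": 9, "MSI": 17, "CIN": 119, "GS": 62}
```

`demo_out/summary.json` then contains (abridged):

```json
{
  "subtype_counts": {"CIN": 119, "EBV": 9, "GS": 62, "MSI": 17},
  "hypermutated_count": 32,
  "hypermutation_cutoff": 18.823529411764707,
  "cluster_sizes":  {"1": 83, "2": 14, "3": 13, "4": 34, "5": 14, "6": 17},
  "cluster_labels": {"1": "unassigned", "2": "CDKN2A", "3": "ATM",
                     "4": "ERBB2", "5": "KRAS", "6": "BRCA2"}
}
```

Reading: the cohort splits into the four molecular subtypes (9 EBV, 17 MSI,
119 chromosomally instable, 62 genomically stable); 32 tumors are
hypermutated, with the cutoff derived as the lowest MSI-H TMB
(18.82 counts/Mb); the 175 non-hypermutated tumors fall into six
co-alteration clusters — five named by their enriched actionable gene and
one background cluster ("unassigned") of tumors with minor or no actionable
alterations. Stage tables (`biomarkers.tsv`, `subtypes.tsv`,
`clusters.tsv`, `frequencies.tsv`, `associations.tsv`, `oncoprint.tsv`)
are written next to the summary.

Stage-wise commands (`panelclass simulate / biomarkers / classify /
cluster / stats`) expose the same pipeline piecemeal on the TSV dialects
documented in `panelclass.io`; a single-sample VCF can replace the variant
TSV.

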