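"""Cohort-level frequency tables and association statistics.

Alteration frequencies are reported per (gene, class) as the percentage of
tumors carrying at least one such alteration, rounded half away from zero to
one decimal — mutation and SCNA (AMP/DEL) tables are built separately, as in
standard panel-cohort landscape tables.

Group associations use two-tailed Fisher's exact tests for categorical
features and Mann–Whitney U for continuous ones, each group compared against
all remaining donors. Raw p-values carry the significance flag (P < 0.05, no
multiple-testing correction, mirroring common practice in this literature);
Benjamini–Hochberg adjusted values are emitted alongside, clearly labeled,
for more conservative reuse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .biomarkers import altered_genes, call_scna
from .models import Cohort

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
#: largest sample size at which the Mann–Whitney p is computed exactly
MW_EXACT_MAX_N = 8


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (prints 0.15 -> 0.2, -0.15 -> -0.2)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class AssociationResult:
    group: str
    feature: str
    level: str | None
    test: str
    p_value: float
    p_adjusted: float | None
    effect_direction: str
    significant: bool


def alteration_frequencies(cohort: Cohort, classes: Sequence[str] = ("mutation", "AMP", "DEL")) -> pd.DataFrame:
    """Per-(gene, class) alteration frequency table.

    Classes: 'mutation' (any SNV/indel), 'AMP' (SCNA gain), 'DEL' (SCNA
    loss). Each tumor contributes at most once per (gene, class). Genes with
    zero altered tumors in a class are omitted. Rows are sorted by class,
    then descending frequency, then gene symbol, and ranked consecutively
    within class.
    """
    n = len(cohort)
    counts: dict[tuple[str, str], int] = {}
    for t in cohort.tumors:
        seen: set[tuple[str, str]] = set()
        for v in t.variants:
            seen.add((v.gene, "mutation"))
        for c in t.cnvs:
            call = c.call if c.call is not None else call_scna(c.fold_change)
            if call == "gain":
                seen.add((c.gene, "AMP"))
            elif call == "loss":
                seen.add((c.gene, "DEL"))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for cls in classes:
        per_class = [
            (gene, cnt) for (gene, c), cnt in counts.items() if c == cls
        ]
        per_class.sort(key=lambda gc: (-gc[1], gc[0]))
        for rank, (gene, cnt) in enumerate(per_class, start=1):
            rows.append(
                {
                    "rank": rank,
                    "gene": gene,
                    "alteration_class": cls,
                    "n_altered": cnt,
                    "frequency_pct": percentage(cnt, n),
                    "actionable": gene in cohort.panel.actionable_genes,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["rank", "gene", "alteration_class", "n_altered", "frequency_pct", "actionable"],
    )


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed that of the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if t.sum() < 1:
        raise ValueError("table grand total must be >= 1")
    return float(fisher_exact(t, alternative="two-sided")[1])


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration when min(n_x, n_y) <= 8 and there are no ties across
    the pooled sample; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= MW_EXACT_MAX_N and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method)[1])


def associate_groups(
    grouping: Mapping[str, str | int],
    categorical: Mapping[str, Mapping[str, str | bool]] | None = None,
    continuous: Mapping[str, Mapping[str, float]] | None = None,
    alpha: float = SIGNIFICANCE_LEVEL,
    reference_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group-vs-rest association tests for every (group, feature) pair.

    ``grouping`` maps tumor_id -> group label. ``categorical`` maps feature
    name -> {tumor_id: level}; multi-level features are dichotomized one
    level at a time. ``continuous`` maps feature name -> {tumor_id: value}.
    ``reference_ids`` restricts the comparison set (e.g. test the
    hypermutated group against non-hypermutated donors as the reference);
    default is all other donors.

    Returns a tidy frame with raw p-values, the P < alpha significance flag
    on the raw values, and a Benjamini–Hochberg adjusted column.
    """
    categorical = categorical or {}
    continuous = continuous or {}
    groups = sorted({str(g) for g in grouping.values()})
    rows: list[dict] = []
    for g in groups:
        inside = [t for t, gg in grouping.items() if str(gg) == g]
        if reference_ids is not None:
            outside = [t for t in reference_ids if t not in inside]
        else:
            outside = [t for t, gg in grouping.items() if str(gg) != g]
        if not inside or not outside:
            logger.warning("group %s skipped: empty group or empty reference", g)
            continue
        for feat, values in sorted(categorical.items()):
            levels = sorted({str(values[t]) for t in (*inside, *outside) if t in values})
            for level in levels:
                a = sum(str(values.get(t)) == level for t in inside)
                b = len(inside) - a
                c = sum(str(values.get(t)) == level for t in outside)
                d = len(outside) - c
                p = fisher_two_tailed([[a, b], [c, d]])
                f_in = a / len(inside)
                f_out = c / len(outside)
                direction = "enriched" if f_in > f_out else ("depleted" if f_in < f_out else "none")
                rows.append(
                    {
                        "group": g,
                        "feature": feat,
                        "level": level,
                        "test": "fisher_two_tailed",
                        "p_value": p,
                        "effect_direction": direction,
                    }
                )
        for feat, values in sorted(continuous.items()):
            xi = [values[t] for t in inside if t in values]
            yi = [values[t] for t in outside if t in values]
            if not xi or not yi:
                logger.warning("feature %s skipped for group %s: no data", feat, g)
                continue
            p = mann_whitney(xi, yi)
            direction = (
                "higher" if np.median(xi) > np.median(yi)
                else ("lower" if np.median(xi) < np.median(yi) else "none")
            )
            rows.append(
                {
                    "group": g,
                    "feature": feat,
                    "level": None,
                    "test": "mann_whitney",
                    "p_value": p,
                    "effect_direction": direction,
                }
            )
    out = pd.DataFrame(
        rows, columns=["group", "feature", "level", "test", "p_value", "effect_direction"]
    )
    if len(out):
        out["p_adjusted_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value"] < alpha
    else:
        out["p_adjusted_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def cohort_alteration_indicator(cohort: Cohort, gene_set: Sequence[str] | None = None) -> pd.DataFrame:
    """Binary tumor x gene altered-indicator frame (variant or SCNA)."""
    genes = sorted(gene_set if gene_set is not None else cohort.panel.genes)
    data = {
        t.tumor_id: [g in altered_genes(t, genes) for g in genes] for t in cohort.tumors
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=genes).astype(int)
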