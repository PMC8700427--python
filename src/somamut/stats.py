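"""Between-group inference and the cohort summary table.

Continuous per-sample quantities (variant counts, spectra percentages) are
compared between groups with the two-sided Mann-Whitney U test — exact
enumeration for small tie-free samples, normal approximation with tie
correction otherwise. Categorical contrasts (2x2 tables of sample counts)
use Fisher's exact test with the probability-mass two-sided convention
(sum of hypergeometric probabilities no larger than the observed table's).
No multiplicity correction is applied by default; Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = ["GroupComparison", "mann_whitney", "fisher_exact", "build_summary",
           "tp53_stratified_comparison", "bh_adjust"]

#: Largest per-group size for which the exact Mann-Whitney null is used
#: (ties force the asymptotic path regardless).
_EXACT_LIMIT = 20


@dataclass(frozen=True)
class GroupComparison:
    label: str
    test: str  # "mann_whitney" | "fisher_exact"
    statistic: float
    p_value: float
    summary: dict

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def mann_whitney(
    x: Sequence[float], y: Sequence[float], label: str = ""
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    Exact enumeration when both samples are small and tie-free; otherwise
    the normal approximation with tie correction. A constant pooled sample
    carries no ordering information and returns p = 1 with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    summary = {"n_x": int(x.size), "n_y": int(y.size),
               "median_x": float(np.median(x)), "median_y": float(np.median(y))}
    if np.all(pooled == pooled[0]):
        log.warning("mann_whitney(%s): constant pooled sample; p = 1", label)
        return GroupComparison(label, "mann_whitney", x.size * y.size / 2.0,
                               1.0, summary)
    ties = np.unique(pooled).size < pooled.size
    method = ("exact"
              if not ties and max(x.size, y.size) <= _EXACT_LIMIT
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(label, "mann_whitney", float(res.statistic),
                           float(min(res.pvalue, 1.0)), summary)


def fisher_exact(
    table: Sequence[Sequence[int]], label: str = ""
) -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact expects a non-negative 2x2 table")
    summary = {"table": t.tolist()}
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        log.warning("fisher_exact(%s): zero margin; p = 1", label)
        return GroupComparison(label, "fisher_exact", np.nan, 1.0, summary)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return GroupComparison(label, "fisher_exact", float(odds),
                           float(min(p, 1.0)), summary)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float),
                                       method="bh")


def tp53_stratified_comparison(
    classified,  # Sequence[tuple[VariantRecord, PathogenicityCall]]
    profiles,  # Sequence[SampleDriverProfile]
    label: str = "TP53-mutated vs TP53-wt: coding variants/sample",
) -> GroupComparison:
    """Mann-Whitney contrast of per-sample coding-variant counts between
    samples with and without an affected TP53 (keyed on driver profiles)."""
    counts = _per_sample_counts(classified)["coding"]
    mutated = {p.sample_id for p in profiles if p.tp53_affected}
    x = [counts.get(p.sample_id, 0) for p in profiles if p.sample_id in mutated]
    y = [counts.get(p.sample_id, 0) for p in profiles
         if p.sample_id not in mutated]
    if not x or not y:
        raise ValueError("both TP53 strata must be non-empty")
    return mann_whitney(x, y, label=label)


def _per_sample_counts(
    classified,  # Sequence[tuple[VariantRecord, PathogenicityCall]]
) -> pd.DataFrame:
    from .variants import VariantClass  # local import avoids cycle at module load

    rows: dict[str, dict[str, int]] = {}
    for record, call in classified:
        bucket = rows.setdefault(
            record.sample_id,
            {"coding": 0, "missense": 0, "pathogenic": 0},
        )
        bucket["coding"] += 1
        if record.variant_class is VariantClass.MISSENSE:
            bucket["missense"] += 1
        if call.is_pathogenic:
            bucket["pathogenic"] += 1
    return pd.DataFrame.from_dict(rows, orient="index")


def build_summary(
    classified_by_group: Mapping[str, Sequence],
    profiles_by_group: Mapping[str, Sequence],
    spectra_table: pd.DataFrame | None = None,
    signature_freq: pd.DataFrame | None = None,
    adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort summary (one column per group) plus pairwise comparisons.

    Rows: per-sample medians (coding, missense, pathogenic, census genes,
    CCGD genes per sample), median C>T percentage, combination / pathway
    fractions, and dominant-signature percentages when available. The
    comparisons table holds one Mann-Whitney or Fisher test per contrast for
    every unordered pair of groups.
    """
    from .drivers import CombinationCategory, classify_combinations, pathway_scan

    groups = list(classified_by_group)
    counts = {g: _per_sample_counts(classified_by_group[g]) for g in groups}
    cgc_per_sample = {
        g: pd.Series({p.sample_id: len(p.cgc_genes) for p in profiles_by_group[g]})
        for g in groups
    }
    ccgd_per_sample = {
        g: pd.Series({p.sample_id: len(p.putative_drivers) for p in profiles_by_group[g]})
        for g in groups
    }
    combos = classify_combinations(profiles_by_group)
    pathways = pathway_scan(profiles_by_group)

    summary_rows: dict[str, dict[str, object]] = {}
    for g in groups:
        col: dict[str, object] = {}
        for metric in ("coding", "missense", "pathogenic"):
            col[f"median_{metric}_per_sample"] = float(counts[g][metric].median())
        col["median_cgc_per_sample"] = float(cgc_per_sample[g].median())
        col["median_ccgd_per_sample"] = float(ccgd_per_sample[g].median())
        if spectra_table is not None and g in spectra_table.index:
            col["median_c_to_t_pct"] = float(spectra_table.loc[g, "median_c_to_t_pct"])
        n = int(combos.loc[g, "n"])
        for cat in CombinationCategory:
            col[f"{cat.value}_count"] = int(combos.loc[g, cat.value])
            col[f"{cat.value}_pct"] = round(100.0 * combos.loc[g, cat.value] / n, 1)
        col["ras_pik3ca_count"] = int(pathways.loc[g, "ras_pik3ca"])
        col["dna_repair_count"] = int(pathways.loc[g, "dna_repair"])
        col["n_samples"] = n
        if signature_freq is not None and g in signature_freq.index:
            for sig in signature_freq.columns:
                col[f"signature_{sig}_pct"] = round(float(signature_freq.loc[g, sig]), 1)
        summary_rows[g] = col
    summary = pd.DataFrame(summary_rows)

    comparisons = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            pair = f"{ga} vs {gb}"
            for metric in ("coding", "missense", "pathogenic"):
                comparisons.append(mann_whitney(
                    counts[ga][metric], counts[gb][metric],
                    label=f"{pair}: {metric}/sample"))
            comparisons.append(mann_whitney(
                cgc_per_sample[ga], cgc_per_sample[gb], label=f"{pair}: CGC/sample"))
            na, nb = int(combos.loc[ga, "n"]), int(combos.loc[gb, "n"])
            for cat in ("combination", "cgc_alone"):
                ka, kb_ = int(combos.loc[ga, cat]), int(combos.loc[gb, cat])
                comparisons.append(fisher_exact(
                    [[ka, na - ka], [kb_, nb - kb_]], label=f"{pair}: {cat}"))
            for cat in ("ras_pik3ca", "dna_repair"):
                ka, kb_ = int(pathways.loc[ga, cat]), int(pathways.loc[gb, cat])
                comparisons.append(fisher_exact(
                    [[ka, na - ka], [kb_, nb - kb_]], label=f"{pair}: {cat}"))
    comp = pd.DataFrame(
        [{"comparison": c.label, "test": c.test, "statistic": c.statistic,
          "p_value": c.p_value} for c in comparisons]
    )
    if adjust and not comp.empty:
        comp["p_adjusted"] = bh_adjust(comp["p_value"])
    return summary, comp
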