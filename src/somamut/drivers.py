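"""Per-sample driver-gene profiles and oncogene/TSG combination calling.

A sample's driver profile collects the Cancer Gene Census genes affected by
potentially/possibly pathogenic variants, split by census role (oncogene,
TSG, dual role). Samples are then categorised:

* ``combination`` — at least one affected oncogene together with at least
  one affected TSG, where a dual-role gene may stand in for either side
  (OG+TSG, OG+dual, TSG+dual, or two or more dual-role genes);
* ``cgc_alone`` — exactly one affected census gene overall;
* ``no_cgc`` — no affected census gene at all; for these samples CCGD
  rank-A genes with pathogenic variants are reported as putative drivers;
* ``same_role_only`` — two or more affected genes all on the same side
  (e.g. several TSGs but no oncogene or dual-role gene). This category is
  required for the four categories to partition every cohort.

Cohort-curated benign exceptions (census genes whose observed variants were
judged non-pathogenic despite the rules) are excluded either gene-wide via
an exception list or per occurrence via the ``b`` marker in driver-table
fixtures. Pathway scans flag Ras/PIK3CA-signalling hits and DNA-repair gene
hits (TP53 itself never counts as a repair hit), including co-mutation with
TP53.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .knowledge import CcgdRank, CgcRole, GeneKnowledgeBase, OncoKbEffect
from .pathogenicity import PathogenicityCall
from .variants import VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "CombinationCategory",
    "SampleDriverProfile",
    "build_profile",
    "classify_combinations",
    "pathway_scan",
    "recurrence_table",
    "load_driver_table",
    "gene_sample_counts",
]


class CombinationCategory(str, enum.Enum):
    COMBINATION = "combination"
    CGC_ALONE = "cgc_alone"
    NO_CGC = "no_cgc"
    SAME_ROLE_ONLY = "same_role_only"


#: Effect glyphs used in driver-table fixtures (the field's shorthand):
#: ++ gain, + likely gain, -- loss, - likely loss, * likely neutral,
#: ? not curated/found; b marks a benign-judged occurrence.
GLYPH_EFFECTS = {
    "++": OncoKbEffect.GAIN_OF_FUNCTION,
    "+": OncoKbEffect.LIKELY_GAIN_OF_FUNCTION,
    "--": OncoKbEffect.LOSS_OF_FUNCTION,
    "-": OncoKbEffect.LIKELY_LOSS_OF_FUNCTION,
    "*": OncoKbEffect.LIKELY_NEUTRAL,
    "?": OncoKbEffect.NOT_REPORTED,
}


@dataclass
class SampleDriverProfile:
    sample_id: str
    og_genes: set[str] = field(default_factory=set)
    tsg_genes: set[str] = field(default_factory=set)
    dual_genes: set[str] = field(default_factory=set)
    putative_drivers: set[str] = field(default_factory=set)
    benign_genes: set[str] = field(default_factory=set)
    oncokb_effects: dict[str, OncoKbEffect] = field(default_factory=dict)
    ras_pik3ca_hit: bool = False
    dna_repair_genes: set[str] = field(default_factory=set)

    @property
    def cgc_genes(self) -> set[str]:
        return self.og_genes | self.tsg_genes | self.dual_genes

    @property
    def combination_category(self) -> CombinationCategory:
        og, tsg, dual = len(self.og_genes), len(self.tsg_genes), len(self.dual_genes)
        total = og + tsg + dual
        if (og and tsg) or (og and dual) or (tsg and dual) or dual >= 2:
            return CombinationCategory.COMBINATION
        if total == 1:
            return CombinationCategory.CGC_ALONE
        if total == 0:
            return CombinationCategory.NO_CGC
        return CombinationCategory.SAME_ROLE_ONLY

    @property
    def tp53_affected(self) -> bool:
        return "TP53" in self.cgc_genes


def _apply_pathways(profile: SampleDriverProfile, genes: Iterable[str],
                    kb: GeneKnowledgeBase) -> None:
    for gene in genes:
        rec = kb.get(gene)
        if rec.ras_pik3ca_pathway:
            profile.ras_pik3ca_hit = True
        if rec.dna_repair and gene != "TP53":
            profile.dna_repair_genes.add(gene)


def build_profile(
    sample_id: str,
    classified: Sequence[tuple[VariantRecord, PathogenicityCall]],
    kb: GeneKnowledgeBase,
    exception_genes: Iterable[str] = (),
) -> SampleDriverProfile:
    """Driver profile for one sample from its classified variants.

    Only potentially/possibly pathogenic variants populate the role sets;
    genes on the cohort's benign-exception list are excluded throughout.
    Benign variants are inert: removing them never changes the profile. The
    DNA-repair scan deliberately includes pathogenic repair genes outside
    the census.
    """
    exceptions = {g.strip().upper() for g in exception_genes}
    profile = SampleDriverProfile(sample_id=sample_id)
    pathogenic_genes: dict[str, str] = {}  # gene -> a protein change seen
    for record, call in classified:
        if record.sample_id != sample_id:
            raise ValueError(
                f"variant for {record.sample_id} passed to profile {sample_id}")
        if not call.is_pathogenic:
            continue
        gene = record.gene.upper()
        if gene in exceptions:
            profile.benign_genes.add(gene)
            continue
        pathogenic_genes.setdefault(gene, record.protein_change)

    for gene, pchange in pathogenic_genes.items():
        rec = kb.get(gene)
        if rec.in_cgc:
            {CgcRole.ONCOGENE: profile.og_genes,
             CgcRole.TSG: profile.tsg_genes,
             CgcRole.DUAL: profile.dual_genes}[rec.cgc_role].add(gene)
            profile.oncokb_effects[gene] = kb.effect_of(gene, pchange)
    _apply_pathways(profile, pathogenic_genes, kb)

    if not profile.cgc_genes:
        profile.putative_drivers = {
            g for g in pathogenic_genes if kb.get(g).ccgd_rank is CcgdRank.A
        }
    return profile


def classify_combinations(
    profiles_by_group: Mapping[str, Sequence[SampleDriverProfile]],
) -> pd.DataFrame:
    """Per-group counts of the four combination categories (plus group size).

    The categories partition each group exactly: the count columns sum to
    ``n``.
    """
    rows = []
    for group, profiles in profiles_by_group.items():
        counts = dict.fromkeys([c.value for c in CombinationCategory], 0)
        for p in profiles:
            counts[p.combination_category.value] += 1
        counts["n"] = len(profiles)
        rows.append({"group": group, **counts})
    return pd.DataFrame(
        rows, columns=["group", *[c.value for c in CombinationCategory], "n"]
    ).set_index("group")


def pathway_scan(
    profiles_by_group: Mapping[str, Sequence[SampleDriverProfile]],
    kb: GeneKnowledgeBase | None = None,
) -> pd.DataFrame:
    """Per-group Ras/PIK3CA and DNA-repair hit counts.

    When ``kb`` is given the pathway flags are (re)derived from each
    profile's pathogenic census genes — useful for profiles loaded from
    driver-table fixtures, which carry gene sets but no pathway flags.
    TP53 is excluded from repair counts; co-mutation counts tally samples
    with both an affected repair gene and affected TP53.
    """
    rows = []
    for group, profiles in profiles_by_group.items():
        ras = repair = repair_tp53 = 0
        for p in profiles:
            if kb is not None:
                p.ras_pik3ca_hit = False
                p.dna_repair_genes = set()
                _apply_pathways(p, p.cgc_genes, kb)
            if p.ras_pik3ca_hit:
                ras += 1
            if p.dna_repair_genes:
                repair += 1
                if p.tp53_affected:
                    repair_tp53 += 1
        rows.append({"group": group, "ras_pik3ca": ras, "dna_repair": repair,
                     "dna_repair_with_tp53": repair_tp53, "n": len(profiles)})
    return pd.DataFrame(rows).set_index("group")


def recurrence_table(
    classified_by_group: Mapping[
        str, Sequence[tuple[VariantRecord, PathogenicityCall]]],
    kb: GeneKnowledgeBase,
    mode: str = "all",
) -> pd.DataFrame:
    """Gene x group affected-sample counts, ranked by total recurrence.

    ``mode="all"`` counts every coding variant regardless of pathogenicity
    (the raw most-commonly-affected view); ``mode="pathogenic"`` counts only
    potentially/possibly pathogenic variants (the census-driver view). A
    gene hit twice in one sample counts once. Columns include the census
    role and whether the gene is on the FLAGS long-gene list.
    """
    if mode not in ("all", "pathogenic"):
        raise ValueError(f"unknown recurrence mode {mode!r}")
    per_group: dict[str, dict[str, set[str]]] = {}
    for group, classified in classified_by_group.items():
        gene_samples: dict[str, set[str]] = {}
        for record, call in classified:
            if mode == "pathogenic" and not call.is_pathogenic:
                continue
            gene_samples.setdefault(record.gene.upper(), set()).add(record.sample_id)
        per_group[group] = gene_samples

    genes = sorted({g for gs in per_group.values() for g in gs})
    rows = []
    for gene in genes:
        rec = kb.get(gene)
        row: dict[str, object] = {
            "gene": gene,
            "cgc_role": rec.cgc_role.value,
            "flags": rec.flags_gene,
        }
        for group, gene_samples in per_group.items():
            row[group] = len(gene_samples.get(gene, ()))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene")
    group_cols = list(per_group)
    df["total"] = df[group_cols].sum(axis=1)
    return df.sort_values(["total", "gene"], ascending=[False, True])


def gene_sample_counts(profiles: Sequence[SampleDriverProfile]) -> pd.Series:
    """Affected-sample count per census gene over a set of driver profiles."""
    counts: dict[str, int] = {}
    for p in profiles:
        for gene in p.cgc_genes:
            counts[gene] = counts.get(gene, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def _parse_cell(cell: str) -> list[tuple[str, str]]:
    cell = str(cell).strip()
    if cell in ("", "-"):
        return []
    out = []
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            gene, code = token.rsplit(":", 1)
        else:
            gene, code = token, "?"
        out.append((gene.strip().upper(), code.strip()))
    return out


def load_driver_table(
    path: str | Path,
    kb: GeneKnowledgeBase | None = None,
) -> list[SampleDriverProfile]:
    """Load a per-sample driver-table fixture into profiles.

    The TSV has columns ``sample_id``, ``og``, ``tsg``, ``dual`` and
    optionally ``putative``; each gene cell is a comma-separated list of
    ``SYMBOL:code`` tokens where the code is an effect glyph (see
    :data:`GLYPH_EFFECTS`) or ``b`` for an occurrence judged benign.
    Benign-marked occurrences are excluded from the role sets (they are the
    curated per-cohort exceptions). With ``kb`` the pathway flags are
    derived from the pathogenic census genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "og", "tsg", "dual"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    profiles = []
    for row in df.to_dict("records"):
        profile = SampleDriverProfile(sample_id=str(row["sample_id"]).strip())
        for col, target in (("og", profile.og_genes), ("tsg", profile.tsg_genes),
                            ("dual", profile.dual_genes)):
            for gene, code in _parse_cell(row[col]):
                if code == "b":
                    profile.benign_genes.add(gene)
                    continue
                if code not in GLYPH_EFFECTS:
                    raise ValueError(f"{path}: unknown effect code {code!r} for {gene}")
                target.add(gene)
                effect = GLYPH_EFFECTS[code]
                if effect is not OncoKbEffect.NOT_REPORTED:
                    profile.oncokb_effects[gene] = effect
        for gene, _ in _parse_cell(row.get("putative", "")):
            profile.putative_drivers.add(gene)
        if kb is not None:
            _apply_pathways(profile, profile.cgc_genes, kb)
        profiles.append(profile)
    return profiles
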