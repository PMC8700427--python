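"""Reading, filtering and writing annotated somatic variant tables.

Input is a MAF-like tab-separated table, one row per variant per sample,
carrying the gene symbol, variant classification, alleles, protein change,
the trinucleotide reference context and the verdicts of five in-silico
effect predictors (SIFT, PolyPhen-2, FATHMM, MutationTaster,
MutationAssessor). Two dialects are supported: generic MAF column names as
produced by common annotators, and the pipeline-native schema written by
:func:`write_variants`.

The cohort-level filter keeps protein-altering coding variants only:
non-coding and silent rows are removed before any downstream analysis.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "PredictorCall",
    "VariantRecord",
    "SampleGroup",
    "read_variants",
    "write_variants",
    "filter_coding_nonsilent",
    "read_groups",
    "PREDICTOR_NAMES",
]


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SILENT = "silent"
    NONCODING = "noncoding"
    OTHER = "other"


class PredictorCall(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    MISSING = "missing"


PREDICTOR_NAMES = ("sift", "polyphen", "fathmm", "mutation_taster", "mutation_assessor")

#: MAF Variant_Classification vocabulary -> pipeline classes. Anything
#: unmapped becomes OTHER (kept by the coding filter).
_MAF_CLASS = {
    "missense_mutation": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "frame_shift_del": VariantClass.FRAMESHIFT,
    "frame_shift_ins": VariantClass.FRAMESHIFT,
    "splice_site": VariantClass.SPLICE_SITE,
    "silent": VariantClass.SILENT,
    "3'utr": VariantClass.NONCODING,
    "5'utr": VariantClass.NONCODING,
    "3'flank": VariantClass.NONCODING,
    "5'flank": VariantClass.NONCODING,
    "intron": VariantClass.NONCODING,
    "igr": VariantClass.NONCODING,
    "rna": VariantClass.NONCODING,
    "lincrna": VariantClass.NONCODING,
}

# Predictor verdict vocabularies (lowercased) counted as a pathogenic call.
_PATHOGENIC_WORDS = {
    "pathogenic", "deleterious", "damaging", "probably_damaging",
    "possibly_damaging", "disease_causing", "high", "medium", "d", "a", "h", "m",
}
_BENIGN_WORDS = {
    "benign", "tolerated", "neutral", "polymorphism", "low", "n", "t", "l", "p",
}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic coding variant in one sample."""

    sample_id: str
    gene: str
    variant_class: VariantClass
    ref_allele: str = ""
    alt_allele: str = ""
    protein_change: str = ""
    trinucleotide_context: str | None = None
    predictor_calls: tuple[PredictorCall, ...] = (PredictorCall.MISSING,) * 5
    splice_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene:
            raise ValueError("sample_id and gene must be non-empty")
        if len(self.predictor_calls) != 5:
            raise ValueError("predictor_calls must have exactly five slots")
        ctx = self.trinucleotide_context
        if ctx is not None and len(ctx) != 3:
            raise ValueError(f"trinucleotide context must be a 3-mer, got {ctx!r}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
            and self.ref_allele != self.alt_allele
        )


@dataclass(frozen=True)
class SampleGroup:
    sample_id: str
    tumor_type: str  # "HGSOC" | "TNBC"
    age_group: str  # "young" | "elderly"

    @property
    def label(self) -> str:
        return f"{self.age_group}-{self.tumor_type}"


_NATIVE_COLUMNS = [
    "sample_id", "gene", "variant_class", "ref_allele", "alt_allele",
    "protein_change", "trinucleotide_context", "splice_offset",
    *PREDICTOR_NAMES,
]

_MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "variant_class": "Variant_Classification",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "protein_change": "Protein_Change",
    "trinucleotide_context": "ref_context",
    "splice_offset": "splice_offset",
    "sift": "SIFT",
    "polyphen": "PolyPhen",
    "fathmm": "FATHMM",
    "mutation_taster": "MutationTaster",
    "mutation_assessor": "MutationAssessor",
}


def _predictor_call(value: str, native: bool) -> PredictorCall:
    v = str(value).strip().lower()
    if not v or v in ("na", "nan", "none", ".", "missing", "unknown"):
        return PredictorCall.MISSING
    if native:
        return PredictorCall(v)
    if v in _PATHOGENIC_WORDS:
        return PredictorCall.PATHOGENIC
    if v in _BENIGN_WORDS:
        return PredictorCall.BENIGN
    return PredictorCall.MISSING


def _variant_class(value: str, native: bool) -> VariantClass:
    v = str(value).strip().lower()
    if native:
        return VariantClass(v)
    return _MAF_CLASS.get(v, VariantClass.OTHER)


def read_variants(path: str | Path, dialect: str = "native") -> list[VariantRecord]:
    """Parse a variant TSV into records.

    ``dialect`` is ``"native"`` (pipeline schema) or ``"maf"`` (generic MAF
    column names). Unmapped variant classifications become ``other``;
    predictor columns absent from the file yield ``missing`` slots.
    Malformed rows are skipped with a logged terminal count; a file with no
    parseable row at all is a fatal error.
    """
    if dialect not in ("native", "maf"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    native = dialect == "native"
    colmap = {c: c for c in _NATIVE_COLUMNS} if native else _MAF_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[VariantRecord] = []
    skipped = 0
    for row in df.to_dict("records"):
        try:
            calls = tuple(
                _predictor_call(row.get(colmap[name], ""), native)
                for name in PREDICTOR_NAMES
            )
            ctx = str(row.get(colmap["trinucleotide_context"], "")).strip().upper()
            # Oncotator-style ref_context may be longer than 3; centre it.
            if len(ctx) > 3 and len(ctx) % 2 == 1:
                mid = len(ctx) // 2
                ctx = ctx[mid - 1 : mid + 2]
            off_raw = str(row.get(colmap["splice_offset"], "")).strip()
            records.append(
                VariantRecord(
                    sample_id=str(row[colmap["sample_id"]]).strip(),
                    gene=str(row[colmap["gene"]]).strip().upper(),
                    variant_class=_variant_class(row[colmap["variant_class"]], native),
                    ref_allele=str(row.get(colmap["ref_allele"], "")).strip().upper(),
                    alt_allele=str(row.get(colmap["alt_allele"], "")).strip().upper(),
                    protein_change=str(row.get(colmap["protein_change"], "")).strip(),
                    trinucleotide_context=ctx if len(ctx) == 3 else None,
                    predictor_calls=calls,
                    splice_offset=int(off_raw) if off_raw not in ("", "na", "nan") else None,
                )
            )
        except (KeyError, ValueError):
            skipped += 1
    if skipped:
        log.warning("read_variants: skipped %d malformed rows in %s", skipped, path)
    if not records:
        raise ValueError(f"no parseable variant rows in {path}")
    return records


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the pipeline-native TSV dialect (round-trip stable)."""
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "gene": r.gene,
            "variant_class": r.variant_class.value,
            "ref_allele": r.ref_allele,
            "alt_allele": r.alt_allele,
            "protein_change": r.protein_change,
            "trinucleotide_context": r.trinucleotide_context or "",
            "splice_offset": "" if r.splice_offset is None else str(r.splice_offset),
        }
        row.update(
            {name: call.value for name, call in zip(PREDICTOR_NAMES, r.predictor_calls)}
        )
        rows.append(row)
    pd.DataFrame(rows, columns=_NATIVE_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_coding_nonsilent(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Drop non-coding and silent rows; keep everything else, in input order.

    Idempotent; an input with no surviving rows returns an empty list with a
    logged warning.
    """
    kept = [
        r for r in records
        if r.variant_class not in (VariantClass.SILENT, VariantClass.NONCODING)
    ]
    if records and not kept:
        log.warning("filter_coding_nonsilent: no coding non-silent variants remain")
    return kept


def read_groups(path: str | Path) -> dict[str, SampleGroup]:
    """Read the sample_id -> (tumor_type, age_group) assignment TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "tumor_type", "age_group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    groups: dict[str, SampleGroup] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id).strip()
        if sid in groups:
            raise ValueError(f"{path}: sample {sid} assigned to more than one group")
        groups[sid] = SampleGroup(sid, str(row.tumor_type).strip(),
                                  str(row.age_group).strip())
    return groups
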