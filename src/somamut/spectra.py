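"""Base-substitution spectra and 96-trinucleotide-context count matrices.

Single-nucleotide substitutions are strand-normalised so the reference base
of the reported class is a pyrimidine (C or T): a purine reference is
reverse-complemented together with its trinucleotide context. This yields
the standard six substitution classes C>A, C>G, C>T, T>A, T>C, T>G and, with
the flanking bases, the 96 pyrimidine-centred context classes used for
mutational-signature analysis. The 96-class ordering is fixed —
lexicographic by (substitution class, 5' base, 3' base) — so matrices are
comparable across runs and against the bundled reference signatures.

Transitions are C>T plus T>C; the other four classes are transversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "SIX_CLASSES",
    "CONTEXTS_96",
    "substitution_class",
    "six_class_fractions",
    "build_context_matrix",
    "SpectrumMatrix",
]

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = ("C>T", "T>C")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 context labels, e.g. "A[C>T]G", in the canonical fixed order.
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SIX_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def substitution_class(
    ref: str, alt: str, context: str | None = None
) -> tuple[str, str | None]:
    """Pyrimidine-normalised substitution class and 3-mer for one SNV.

    Purine references are reverse-complemented (context included, when
    given) so the returned class always has a C or T reference. Raises
    ``ValueError`` for non-ACGT bases, identical ref/alt, or a context whose
    central base does not match the reference.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    ctx = context.upper() if context else None
    if ctx is not None:
        if len(ctx) != 3 or any(b not in _COMPLEMENT for b in ctx):
            raise ValueError(f"bad trinucleotide context {context!r}")
        if ctx[1] != ref:
            raise ValueError(f"context {ctx} is not centred on ref {ref}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ctx = _revcomp(ctx) if ctx is not None else None
    return f"{ref}>{alt}", ctx


def context_label(ref: str, alt: str, context: str) -> str:
    """96-class label ("A[C>T]G") for an SNV with context."""
    sub, ctx = substitution_class(ref, alt, context)
    assert ctx is not None
    return f"{ctx[0]}[{sub}]{ctx[2]}"


@dataclass
class SpectrumMatrix:
    """Per-sample six-class and 96-context mutation counts."""

    sample_ids: list[str]
    six_class_counts: pd.DataFrame  # samples x 6
    context_counts: pd.DataFrame  # samples x 96
    n_dropped_no_context: int = 0
    n_dropped_bad_base: int = 0

    def context_fractions(self) -> pd.DataFrame:
        totals = self.context_counts.sum(axis=1)
        return self.context_counts.div(totals.where(totals > 0, 1), axis=0)


def six_class_fractions(
    records_by_group: Mapping[str, Sequence[VariantRecord]],
) -> pd.DataFrame:
    """Per-group six-class fractions, Ti/Tv split and per-sample C>T medians.

    Only SNVs contribute. Returns one row per group with columns for the six
    class fractions, ``ti``, ``tv`` and ``median_c_to_t_pct`` (median over
    samples of the per-sample C>T percentage, mirroring cohort summary
    tables). Groups with zero usable SNVs are reported as all-NaN.
    """
    rows = []
    for group, records in records_by_group.items():
        counts = dict.fromkeys(SIX_CLASSES, 0)
        per_sample: dict[str, dict[str, int]] = {}
        for r in records:
            if not r.is_snv:
                continue
            try:
                sub, _ = substitution_class(r.ref_allele, r.alt_allele,
                                            r.trinucleotide_context)
            except ValueError:
                continue
            counts[sub] += 1
            bucket = per_sample.setdefault(r.sample_id, {"C>T": 0, "all": 0})
            bucket["all"] += 1
            if sub == "C>T":
                bucket["C>T"] += 1
        total = sum(counts.values())
        row: dict[str, object] = {"group": group, "n_snv": total}
        if total == 0:
            log.warning("six_class_fractions: group %s has no SNVs", group)
            row.update({c: np.nan for c in SIX_CLASSES})
            row.update({"ti": np.nan, "tv": np.nan, "median_c_to_t_pct": np.nan})
        else:
            fracs = {c: counts[c] / total for c in SIX_CLASSES}
            row.update(fracs)
            row["ti"] = fracs["C>T"] + fracs["T>C"]
            row["tv"] = 1.0 - row["ti"]
            pcts = [100.0 * b["C>T"] / b["all"] for b in per_sample.values() if b["all"]]
            row["median_c_to_t_pct"] = float(np.median(pcts)) if pcts else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def build_context_matrix(
    records: Iterable[VariantRecord],
    sample_ids: Sequence[str] | None = None,
) -> SpectrumMatrix:
    """Per-sample 96-context and six-class count matrices.

    Contexts are taken from each record's annotation; SNVs without a
    resolvable context (or whose context centre mismatches the reference)
    are dropped and tallied in the QC counters. Non-SNV records are ignored.
    Row order follows ``sample_ids`` when given, else first appearance.
    """
    records = list(records)
    if sample_ids is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.sample_id, None)
        sample_ids = list(seen)
    else:
        sample_ids = list(sample_ids)
    idx = {s: i for i, s in enumerate(sample_ids)}

    ctx_counts = np.zeros((len(sample_ids), 96), dtype=int)
    six_counts = np.zeros((len(sample_ids), 6), dtype=int)
    six_index = {c: i for i, c in enumerate(SIX_CLASSES)}
    dropped_ctx = dropped_base = 0

    for r in records:
        if not r.is_snv:
            continue
        if r.sample_id not in idx:
            continue
        if r.trinucleotide_context is None:
            dropped_ctx += 1
            continue
        try:
            sub, ctx = substitution_class(r.ref_allele, r.alt_allele,
                                          r.trinucleotide_context)
        except ValueError:
            dropped_base += 1
            continue
        label = f"{ctx[0]}[{sub}]{ctx[2]}"
        ctx_counts[idx[r.sample_id], _CONTEXT_INDEX[label]] += 1
        six_counts[idx[r.sample_id], six_index[sub]] += 1

    if dropped_ctx or dropped_base:
        log.warning(
            "build_context_matrix: dropped %d SNVs without context, "
            "%d with invalid context/base", dropped_ctx, dropped_base,
        )
    return SpectrumMatrix(
        sample_ids=sample_ids,
        six_class_counts=pd.DataFrame(six_counts, index=sample_ids,
                                      columns=list(SIX_CLASSES)),
        context_counts=pd.DataFrame(ctx_counts, index=sample_ids,
                                    columns=list(CONTEXTS_96)),
        n_dropped_no_context=dropped_ctx,
        n_dropped_bad_base=dropped_base,
    )
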