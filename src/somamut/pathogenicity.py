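"""Three-level rule-based variant pathogenicity classification.

The verdict hierarchy is:

* **potentially pathogenic** — truncating variants (nonsense, frameshift,
  canonical splice site within +/-3 of the exon boundary), regardless of
  predictor output;
* **possibly pathogenic** — missense variants called pathogenic by at least
  3 of the 5 effect predictors, or by at least 1 of 5 when the gene is a
  Cancer Gene Census gene (tier 1 or tier 2);
* **benign** — everything else, including in-frame and other coding classes
  the rules do not name.

Missing predictor slots count as non-pathogenic votes and the denominator
stays 5; this is the conservative reading of the "3 out of 5" / "1 of 5"
thresholds. Truncating dominates both vote rules; when both vote rules
would fire, the 3-of-5 rule is the one recorded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .knowledge import GeneKnowledgeBase
from .variants import PredictorCall, VariantClass, VariantRecord

__all__ = ["Verdict", "Rule", "PathogenicityCall", "classify_variant",
           "classify_all", "CANONICAL_SPLICE_WINDOW"]

#: Canonical splice-site half-window in bases around the exon boundary.
CANONICAL_SPLICE_WINDOW = 3


class Verdict(str, enum.Enum):
    POTENTIALLY_PATHOGENIC = "potentially_pathogenic"
    POSSIBLY_PATHOGENIC = "possibly_pathogenic"
    BENIGN = "benign"


class Rule(str, enum.Enum):
    TRUNCATING = "truncating"
    VOTE_3OF5 = "vote_3of5"
    CGC_1OF5 = "cgc_1of5"
    NONE = "none"


@dataclass(frozen=True)
class PathogenicityCall:
    verdict: Verdict
    rule_fired: Rule
    votes_pathogenic: int
    votes_available: int

    def __post_init__(self) -> None:
        if not 0 <= self.votes_pathogenic <= self.votes_available <= 5:
            raise ValueError("vote counts out of range")
        if (self.verdict is Verdict.POTENTIALLY_PATHOGENIC) != (
            self.rule_fired is Rule.TRUNCATING
        ):
            raise ValueError("potentially_pathogenic iff truncating rule")
        if (self.verdict is Verdict.POSSIBLY_PATHOGENIC) != (
            self.rule_fired in (Rule.VOTE_3OF5, Rule.CGC_1OF5)
        ):
            raise ValueError("possibly_pathogenic iff a vote rule fired")

    @property
    def is_pathogenic(self) -> bool:
        """True for either pathogenic level (what driver calling consumes)."""
        return self.verdict is not Verdict.BENIGN


def _is_truncating(record: VariantRecord) -> bool:
    if record.variant_class in (VariantClass.NONSENSE, VariantClass.FRAMESHIFT):
        return True
    if record.variant_class is VariantClass.SPLICE_SITE:
        # A splice variant with no recorded offset was already annotated as a
        # splice-site change; treat it as canonical.
        off = record.splice_offset
        return off is None or abs(off) <= CANONICAL_SPLICE_WINDOW
    return False


def classify_variant(record: VariantRecord, kb: GeneKnowledgeBase) -> PathogenicityCall:
    """Classify one coding, non-silent variant. Total and deterministic."""
    votes = sum(c is PredictorCall.PATHOGENIC for c in record.predictor_calls)
    available = sum(c is not PredictorCall.MISSING for c in record.predictor_calls)

    if _is_truncating(record):
        return PathogenicityCall(Verdict.POTENTIALLY_PATHOGENIC, Rule.TRUNCATING,
                                 votes, available)
    if record.variant_class is VariantClass.MISSENSE:
        if votes >= 3:
            return PathogenicityCall(Verdict.POSSIBLY_PATHOGENIC, Rule.VOTE_3OF5,
                                     votes, available)
        if votes >= 1 and kb.get(record.gene).in_cgc:
            return PathogenicityCall(Verdict.POSSIBLY_PATHOGENIC, Rule.CGC_1OF5,
                                     votes, available)
    return PathogenicityCall(Verdict.BENIGN, Rule.NONE, votes, available)


def classify_all(
    records: Sequence[VariantRecord], kb: GeneKnowledgeBase
) -> list[tuple[VariantRecord, PathogenicityCall]]:
    """Element-wise classification, preserving input order."""
    return [(r, classify_variant(r, kb)) for r in records]
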