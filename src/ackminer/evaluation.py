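"""Score extracted donation records against gold annotations.

Accuracy is reported per field (donor, affiliation, antibody name) plus
their arithmetic mean.  A prediction is correct when it matches the value
of *any* annotator of the document, under an explicit, report-embedded
matching policy (the denominator is the number of gold donations that carry
the field; documents with no gold donation do not contribute).  The module
also computes inter-annotator agreement over documents annotated by at
least two people.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .gold_annotations import GoldDocument
from .rule_extractor import DonationRecord

__all__ = [
    "MatchPolicy",
    "EvaluationReport",
    "DocumentAlignmentError",
    "match_field",
    "evaluate_documents",
    "inter_annotator_agreement",
    "percent",
]

_HONORIFIC_RE = re.compile(
    r"^(?:dr|prof|professor|mr|mrs|ms)\.?\s+", re.IGNORECASE
)
_PUNCT_TABLE = str.maketrans("", "", string.punctuation)
FIELDS = ("donor", "affiliation", "antibody")


class DocumentAlignmentError(ValueError):
    """Predicted document ids that have no gold counterpart."""


@dataclass(frozen=True)
class MatchPolicy:
    """How predicted strings are compared with gold strings."""

    case_fold: bool = True
    strip_punctuation: bool = True
    strip_honorifics: bool = True
    mode: str = "exact"  # "exact" (after normalization) or "containment"

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "containment"):
            raise ValueError(f"unknown match mode: {self.mode!r}")

    def normalize(self, value: str) -> str:
        out = value.strip()
        if self.strip_honorifics:
            out = _HONORIFIC_RE.sub("", out)
        if self.case_fold:
            out = out.lower()
        if self.strip_punctuation:
            out = out.translate(_PUNCT_TABLE)
        return " ".join(out.split())

    def to_dict(self) -> dict:
        return {
            "case_fold": self.case_fold,
            "strip_punctuation": self.strip_punctuation,
            "strip_honorifics": self.strip_honorifics,
            "mode": self.mode,
            "denominator": "gold donations carrying the field",
            "comparison": "match any annotator",
        }


DEFAULT_POLICY = MatchPolicy()


def match_field(
    predicted: Optional[str],
    gold_values: Iterable[str],
    policy: MatchPolicy = DEFAULT_POLICY,
) -> bool:
    """True iff the prediction matches any annotator's value under the policy.

    An absent prediction matches only an all-absent gold value set.
    """
    gold = [g for g in gold_values if g]
    if predicted is None:
        return not gold
    if not gold:
        return False
    p = policy.normalize(predicted)
    for g in gold:
        gn = policy.normalize(g)
        if policy.mode == "exact":
            if p == gn:
                return True
        else:  # containment, either direction
            if p and gn and (p in gn or gn in p):
                return True
    return False


def percent(fraction: float) -> int:
    """Integer-rounded percentage (half rounds up), e.g. 0.5667 -> 57."""
    return int(math.floor(fraction * 100 + 0.5))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-field accuracies with their counts and the policy used."""

    donor: float
    affiliation: float
    antibody: float
    counts: Mapping[str, tuple[int, int]]
    policy: MatchPolicy

    @property
    def mean(self) -> float:
        return (self.donor + self.affiliation + self.antibody) / 3.0

    def to_dict(self) -> dict:
        return {
            "accuracy": {
                "donor": self.donor,
                "affiliation": self.affiliation,
                "antibody": self.antibody,
                "mean": self.mean,
            },
            "percent": {
                "donor": percent(self.donor),
                "affiliation": percent(self.affiliation),
                "antibody": percent(self.antibody),
                "mean": percent(self.mean),
            },
            "counts": {k: list(v) for k, v in self.counts.items()},
            "policy": self.policy.to_dict(),
        }


@dataclass
class _MergedDonation:
    """One gold donation with per-field value sets pooled over annotators."""

    donor: set = field(default_factory=set)
    affiliation: set = field(default_factory=set)
    antibody: set = field(default_factory=set)


def _merge_gold(
    annotator_docs: Sequence[GoldDocument],
    policy: MatchPolicy,
    resource_label: Optional[str],
) -> list[_MergedDonation]:
    """Pool each doc's donations across annotators.

    Donations from different annotators are the same donation when their
    normalized resource names agree (falling back to the normalized donor
    when no resource name was annotated — annotators often write the same
    donor differently, "Keith Gull" vs "K. Gull", so the donor alone is too
    brittle a key).  Each merged donation then accepts any annotator's
    value per field.
    """
    merged: dict[tuple[str, str], _MergedDonation] = {}
    for doc in annotator_docs:
        for don in doc.donations:
            if (
                resource_label is not None
                and don.resource_label.lower() != resource_label
            ):
                continue
            if don.resource_name:
                key = ("resource", policy.normalize(don.resource_name))
            elif don.donor:
                key = ("donor", policy.normalize(don.donor))
            else:
                key = ("anonymous", str(len(merged)))
            slot = merged.setdefault(key, _MergedDonation())
            if don.donor:
                slot.donor.add(don.donor)
            if don.affiliation:
                slot.affiliation.add(don.affiliation)
            if don.resource_name:
                slot.antibody.add(don.resource_name)
    return list(merged.values())


def evaluate_documents(
    predictions: Mapping[str, Sequence[DonationRecord]],
    gold_groups: Mapping[str, Sequence[GoldDocument]],
    policy: MatchPolicy = DEFAULT_POLICY,
    resource_label: Optional[str] = "antibody",
) -> EvaluationReport:
    """Per-field accuracy of predictions against grouped gold documents.

    ``predictions`` and ``gold_groups`` map doc_id to the records extracted
    from, respectively the annotator copies of, that document.  Predicted
    ids without gold raise :class:`DocumentAlignmentError`.
    """
    unmatched = sorted(set(predictions) - set(gold_groups))
    if unmatched:
        raise DocumentAlignmentError(
            f"predictions for documents with no gold annotation: {unmatched}"
        )
    num = {f: 0 for f in FIELDS}
    den = {f: 0 for f in FIELDS}
    for doc_id, annotator_docs in gold_groups.items():
        gold_donations = _merge_gold(annotator_docs, policy, resource_label)
        if not gold_donations:
            continue
        preds = list(predictions.get(doc_id, ()))
        for gd in gold_donations:
            for fname in FIELDS:
                gold_values = getattr(gd, fname)
                if not gold_values:
                    continue
                den[fname] += 1
                if any(
                    match_field(getattr(p, fname), gold_values, policy)
                    for p in preds
                ):
                    num[fname] += 1
    acc = {
        f: (num[f] / den[f]) if den[f] else 0.0 for f in FIELDS
    }
    return EvaluationReport(
        donor=acc["donor"],
        affiliation=acc["affiliation"],
        antibody=acc["antibody"],
        counts={f: (num[f], den[f]) for f in FIELDS},
        policy=policy,
    )


def _donation_fields(don) -> tuple:
    return (don.donor, don.affiliation, don.resource_name, don.attributes)


def inter_annotator_agreement(
    gold_groups: Mapping[str, Sequence[GoldDocument]],
    policy: MatchPolicy = DEFAULT_POLICY,
) -> float:
    """Fraction of annotation fields on which annotator pairs agree.

    Donations of a pair are aligned by position; each aligned pair
    contributes four field comparisons (donor, affiliation, resource name,
    attribute set).  Unaligned surplus donations count as four
    disagreements.  Documents with fewer than two annotators are ignored;
    if none remain the quantity is undefined and an error is raised.
    """
    agree = 0
    total = 0
    for doc_id, docs in gold_groups.items():
        if len(docs) < 2:
            continue
        for i in range(len(docs)):
            for j in range(i + 1, len(docs)):
                a, b = docs[i].donations, docs[j].donations
                n = max(len(a), len(b))
                if n == 0:
                    continue
                for k in range(n):
                    if k >= len(a) or k >= len(b):
                        total += 4
                        continue
                    fa, fb = _donation_fields(a[k]), _donation_fields(b[k])
                    for va, vb in zip(fa, fb):
                        total += 1
                        if isinstance(va, frozenset) or isinstance(vb, frozenset):
                            na = frozenset(policy.normalize(x) for x in (va or ()))
                            nb = frozenset(policy.normalize(x) for x in (vb or ()))
                            agree += na == nb
                        elif va is None and vb is None:
                            agree += 1
                        elif va is not None and vb is not None:
                            agree += policy.normalize(va) == policy.normalize(vb)
    if total == 0:
        raise ValueError(
            "inter-annotator agreement is undefined: no document has two or "
            "more annotators with donations"
        )
    return agree / total
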