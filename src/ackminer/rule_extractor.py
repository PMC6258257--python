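"""Context-window rule-based extraction of antibody donations.

Acknowledgement prose is formulaic, and that regularity is the whole trick:
every occurrence of the keyword "antibody"/"antibodies" anchors a small
context window (4 tokens by default) in which the antibody name is the first
word that is neither an English dictionary word nor part of a named entity.
When the left window yields nothing and the keyword is followed by "of" or
"to" ("antibody to UL7" — the passive form), the right window is searched
instead.  The donor is the nearest person entity left of the antibody name,
with no window bound; the affiliation is the organization closest to the
donor that still sits left of the keyword (affiliations almost always follow
the donor name in brackets).  Attribute tags — primary, secondary,
monoclonal, polyclonal — are read from the left window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .nlp_adapters import (
    EntityMention,
    NLPBackend,
    Token,
    is_wordlike,
    split_sentences,
    tokenize,
)
from .pmc_corpus import Acknowledgement

__all__ = [
    "ATTRIBUTE_TAGS",
    "DEFAULT_WINDOW",
    "AnchorContext",
    "DonationRecord",
    "find_anchors",
    "extract_antibody_name",
    "extract_attributes",
    "extract_donor",
    "extract_affiliation",
    "extract_donations",
]

ATTRIBUTE_TAGS = frozenset({"primary", "secondary", "monoclonal", "polyclonal"})
DEFAULT_WINDOW = 4
ANCHOR_WORDS = frozenset({"antibody", "antibodies"})
_RIGHT_GATE = frozenset({"of", "to"})


@dataclass(frozen=True)
class AnchorContext:
    """A keyword anchor with its left/right windows (half-open tok ranges)."""

    anchor_index: int
    left_window: tuple[int, int]
    right_window: tuple[int, int]
    window: int = DEFAULT_WINDOW


@dataclass(frozen=True)
class DonationRecord:
    """One extracted antibody donation."""

    donor: Optional[str] = None
    affiliation: Optional[str] = None
    antibody: Optional[str] = None
    attributes: frozenset[str] = frozenset()
    anchor_index: int = 0
    article_id: Optional[str] = None
    journal: Optional[str] = None
    year: Optional[int] = None
    method: str = "rule"
    antibody_surface: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = self.attributes - ATTRIBUTE_TAGS
        if unknown:
            raise ValueError(f"unknown attribute tags: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "donor": self.donor,
            "affiliation": self.affiliation,
            "antibody": self.antibody,
            "attributes": sorted(self.attributes),
            "anchor_index": self.anchor_index,
            "article_id": self.article_id,
            "journal": self.journal,
            "year": self.year,
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, rec: dict) -> "DonationRecord":
        return cls(
            donor=rec.get("donor"),
            affiliation=rec.get("affiliation"),
            antibody=rec.get("antibody"),
            attributes=frozenset(rec.get("attributes", ())),
            anchor_index=rec.get("anchor_index", 0),
            article_id=rec.get("article_id"),
            journal=rec.get("journal"),
            year=rec.get("year"),
            method=rec.get("method", "rule"),
        )


def _sentence_bounds(tokens: Sequence[Token]) -> list[tuple[int, int]]:
    bounds = []
    start = 0
    for sent in split_sentences(tokens):
        end = sent[-1].index + 1
        bounds.append((start, end))
        start = end
    return bounds


def find_anchors(
    tokens: Sequence[Token], window: int = DEFAULT_WINDOW
) -> list[AnchorContext]:
    """One context per whole-token "antibody"/"antibodies" match, in order.

    Windows are clipped at sentence boundaries so that a window never leaks
    across a full stop into the neighbouring sentence.
    """
    bounds = _sentence_bounds(tokens)

    def sentence_of(idx: int) -> tuple[int, int]:
        for s, e in bounds:
            if s <= idx < e:
                return s, e
        return 0, len(tokens)

    anchors = []
    for tok in tokens:
        if tok.text.lower() in ANCHOR_WORDS:
            s, e = sentence_of(tok.index)
            left = (max(s, tok.index - window), tok.index)
            right = (tok.index + 1, min(e, tok.index + 1 + window))
            anchors.append(AnchorContext(tok.index, left, right, window))
    return anchors


def _is_name_candidate(
    tok: Token, backend: NLPBackend, entities: Sequence[EntityMention]
) -> bool:
    """A word-like token outside any entity that fails the dictionary test."""
    if not is_wordlike(tok.text):
        return False
    if backend.is_dictionary_word(tok.text):
        return False
    return not any(ent.covers(tok.index) for ent in entities)


def extract_antibody_name(
    tokens: Sequence[Token],
    anchor: AnchorContext,
    backend: NLPBackend,
    entities: Optional[Sequence[EntityMention]] = None,
) -> Optional[tuple[str, str, int]]:
    """The antibody name for one anchor, or ``None``.

    Returns ``(name, side, token_index)`` with ``side`` in {"left",
    "right"}.  The left window is scanned nearest-first; the right window is
    only consulted when the keyword is followed by "of" or "to" within it,
    and only tokens after that preposition are candidates.
    """
    if entities is None:
        entities = backend.tag_entities(tokens)

    ls, le = anchor.left_window
    for idx in range(le - 1, ls - 1, -1):
        if _is_name_candidate(tokens[idx], backend, entities):
            return tokens[idx].text, "left", idx

    rs, re_ = anchor.right_window
    gate = next(
        (i for i in range(rs, re_) if tokens[i].text.lower() in _RIGHT_GATE), None
    )
    if gate is None:
        return None
    for idx in range(gate + 1, re_):
        if _is_name_candidate(tokens[idx], backend, entities):
            return tokens[idx].text, "right", idx
    return None


def extract_attributes(
    tokens: Sequence[Token], anchor: AnchorContext
) -> frozenset[str]:
    """Attribute tags present (case-insensitively) in the left window."""
    ls, le = anchor.left_window
    return frozenset(
        tokens[i].text.lower() for i in range(ls, le)
        if tokens[i].text.lower() in ATTRIBUTE_TAGS
    )


def extract_donor(
    tokens: Sequence[Token],
    search_start: int,
    entities: Sequence[EntityMention],
    sentence_bounded: bool = False,
) -> Optional[EntityMention]:
    """Nearest person mention entirely left of ``search_start``.

    The scan is unbounded by default — donor names typically sit far from
    the antibody mention — but may be restricted to the same sentence.
    """
    lo = 0
    if sentence_bounded:
        for s, e in _sentence_bounds(tokens):
            if s <= search_start < e:
                lo = s
                break
    best: Optional[EntityMention] = None
    for ent in entities:
        if ent.label != "person":
            continue
        if ent.end < search_start and ent.start >= lo:
            if best is None or ent.end > best.end:
                best = ent
    return best


def extract_affiliation(
    tokens: Sequence[Token],
    donor: EntityMention,
    anchor_index: int,
    entities: Sequence[EntityMention],
) -> Optional[EntityMention]:
    """Organization closest to the donor, between donor and the keyword."""
    best: Optional[EntityMention] = None
    for ent in entities:
        if ent.label != "organization":
            continue
        if ent.start > donor.end and ent.end < anchor_index:
            if best is None or ent.start < best.start:
                best = ent
    return best


def extract_donations(
    ack: Acknowledgement,
    backend: NLPBackend,
    window: int = DEFAULT_WINDOW,
    sentence_bounded_donor: bool = False,
) -> list[DonationRecord]:
    """Assemble one donation record per keyword anchor.

    Records with neither donor nor antibody are suppressed, and anchors that
    resolve to an identical (donor, antibody) pair within the paragraph are
    deduplicated — "primary and secondary antibodies" style doublets would
    otherwise double-count a single donation.
    """
    tokens = tokenize(ack.text)
    entities = backend.tag_entities(tokens)
    records: list[DonationRecord] = []
    seen: set[tuple[Optional[str], Optional[str]]] = set()
    for anchor in find_anchors(tokens, window=window):
        found = extract_antibody_name(tokens, anchor, backend, entities)
        if found is not None:
            antibody, _side, name_idx = found
            search_start = name_idx
        else:
            antibody, search_start = None, anchor.anchor_index
        donor = extract_donor(
            tokens, search_start, entities, sentence_bounded=sentence_bounded_donor
        )
        if donor is None and antibody is None:
            continue
        affiliation = (
            extract_affiliation(tokens, donor, anchor.anchor_index, entities)
            if donor is not None
            else None
        )
        key = (donor.text if donor else None, antibody)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            DonationRecord(
                donor=donor.text if donor else None,
                affiliation=affiliation.text if affiliation else None,
                antibody=antibody,
                attributes=extract_attributes(tokens, anchor),
                anchor_index=anchor.anchor_index,
                article_id=ack.article.article_id,
                journal=ack.article.journal,
                year=ack.article.year,
                method="rule",
            )
        )
    return records
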