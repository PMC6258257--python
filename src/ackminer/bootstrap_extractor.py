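"""Bootstrapped pattern learning for antibody names.

Starting from a seed set of known antibody names, the learner alternates two
steps over the sentence pool: (1) for every occurrence of a known name, take
the leaves of the immediate parent noun phrase in a constituency parse and
replace the name with a TARGET wildcard — these token sequences are the
learned patterns; (2) slide every pattern over every sentence and harvest
the tokens aligned with TARGET as new antibody names.  Both sets grow
monotonically; two iterations give the best precision/recall trade-off
before noisy rules start to amplify, so 2 is the default.

Donors, affiliations and attribute tags for each matched name are then
completed with the same context rules the rule-based extractor uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .nlp_adapters import (
    NLPBackend,
    STOP_WORDS,
    Token,
    immediate_parent_np,
    is_wordlike,
    split_sentences,
    tokenize,
)
from .pmc_corpus import Acknowledgement
from .rule_extractor import (
    ATTRIBUTE_TAGS,
    DonationRecord,
    extract_affiliation,
    extract_attributes,
    extract_donor,
    find_anchors,
)

__all__ = [
    "TARGET",
    "Pattern",
    "BootstrapState",
    "induce_patterns",
    "match_patterns",
    "find_pattern_matches",
    "run_bootstrap",
    "extract_donations_bootstrap",
    "corpus_sentences",
    "load_seeds",
    "default_seeds",
]

TARGET = "TARGET"
MAX_TARGET_SPAN = 3
ANCHOR_WORDS = frozenset({"antibody", "antibodies"})


@dataclass(frozen=True)
class Pattern:
    """A literal token sequence with exactly one TARGET wildcard slot.

    ``origin`` records the iteration the pattern was first learned at and
    does not participate in equality: re-learning a pattern later must
    collapse onto the existing one.
    """

    tokens: tuple[str, ...]
    origin: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.tokens.count(TARGET) != 1:
            raise ValueError("pattern must contain exactly one TARGET slot")
        if len(self.tokens) < 2:
            raise ValueError("pattern needs at least one literal besides TARGET")

    @property
    def literals(self) -> tuple[str, ...]:
        return tuple(t for t in self.tokens if t != TARGET)

    def __str__(self) -> str:
        return " ".join(self.tokens)

    @classmethod
    def parse(cls, text: str, origin: int = 0) -> "Pattern":
        return cls(tuple(text.split()), origin=origin)


@dataclass(frozen=True)
class BootstrapState:
    """Names and patterns accumulated after some number of iterations."""

    names: frozenset[str]
    patterns: frozenset[Pattern]
    iteration: int = 0


SentenceLike = Union[str, Sequence[Token]]


def _as_tokens(sentence: SentenceLike) -> list[Token]:
    if isinstance(sentence, str):
        return tokenize(sentence)
    return list(sentence)


def corpus_sentences(acks: Iterable[Acknowledgement]) -> list[list[Token]]:
    """Flatten acknowledgements into one sentence pool (token lists)."""
    pool: list[list[Token]] = []
    for ack in acks:
        pool.extend(split_sentences(tokenize(ack.text)))
    return pool


def _name_occurrences(
    tokens: Sequence[Token], names: frozenset[str]
) -> list[tuple[int, int]]:
    """Inclusive token spans where a known name occurs (longest match)."""
    name_keys = {tuple(t.text.lower() for t in tokenize(n)): n for n in names}
    if not name_keys:
        return []
    max_len = max(len(k) for k in name_keys)
    lowered = [t.text.lower() for t in tokens]
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(tokens):
        matched = False
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            if tuple(lowered[i : i + length]) in name_keys:
                spans.append((i, i + length - 1))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return spans


def _prune(pattern_tokens: tuple[str, ...]) -> bool:
    """Keep only patterns with a contentful literal (not just stop-words)."""
    literals = [t for t in pattern_tokens if t != TARGET]
    if not literals:
        return False
    return any(is_wordlike(t) and t.lower() not in STOP_WORDS for t in literals)


def induce_patterns(
    sentences: Iterable[SentenceLike],
    names: Iterable[str],
    backend: NLPBackend,
    origin: int = 0,
) -> set[Pattern]:
    """Learn TARGET patterns from the parent NP of every known-name mention.

    Occurrences without an NP ancestor (flat fallback parses) are skipped;
    duplicate patterns collapse; patterns whose literals are all stop-words
    are discarded as noise guards.
    """
    name_set = frozenset(n.lower() for n in names if n.strip())
    patterns: set[Pattern] = set()
    for sentence in sentences:
        tokens = _as_tokens(sentence)
        spans = _name_occurrences(tokens, name_set)
        if not spans:
            continue
        tree = backend.constituency_parse(tokens)
        for start, end in spans:
            np_leaves = immediate_parent_np(tree, tokens[start].index)
            if np_leaves is None:
                continue
            leaf_indices = [t.index for t in np_leaves]
            if tokens[end].index not in leaf_indices:
                continue  # NP does not cover the whole multi-token name
            pat_tokens: list[str] = []
            for leaf in np_leaves:
                if tokens[start].index <= leaf.index <= tokens[end].index:
                    if not pat_tokens or pat_tokens[-1] != TARGET:
                        pat_tokens.append(TARGET)
                else:
                    pat_tokens.append(leaf.text.lower())
            tup = tuple(pat_tokens)
            if tup.count(TARGET) == 1 and len(tup) >= 2 and _prune(tup):
                patterns.add(Pattern(tup, origin=origin))
    return patterns


def _filler_ok(
    filler_tokens: Sequence[Token], known_names: frozenset[str]
) -> bool:
    """Word-like and not a bare function word: blocks "the" as a "name".

    A multi-token filler that strictly contains an already-known name is
    rejected too — "mouse TAG1" must not be learned when "TAG1" is known,
    otherwise every modifier around a known name becomes a bogus name.
    """
    if not filler_tokens or len(filler_tokens) > MAX_TARGET_SPAN:
        return False
    if not all(is_wordlike(t.text) for t in filler_tokens):
        return False
    if any(t.text.lower() in STOP_WORDS for t in filler_tokens):
        return False
    # the anchor keyword and the four attribute tags have their own
    # extraction channels; they are never the antibody name itself
    if any(t.text.lower() in ANCHOR_WORDS for t in filler_tokens):
        return False
    if any(t.text.lower() in ATTRIBUTE_TAGS for t in filler_tokens):
        return False
    if len(filler_tokens) > 1 and known_names:
        lowered = [t.text.lower() for t in filler_tokens]
        n = len(lowered)
        for i in range(n):
            for j in range(i + 1, n + 1):
                if j - i == n:
                    continue  # the whole filler itself may be a known name
                if " ".join(lowered[i:j]) in known_names:
                    return False
    return True


def find_pattern_matches(
    sentence: SentenceLike,
    patterns: Iterable[Pattern],
    known_names: frozenset[str] = frozenset(),
) -> list[tuple[Pattern, tuple[int, int], tuple[int, int]]]:
    """All pattern hits in one sentence.

    Returns ``(pattern, filler_span, window_span)`` triples, spans being
    inclusive positions into the sentence token list; TARGET may absorb one
    to three word-like tokens.
    """
    tokens = _as_tokens(sentence)
    lowered = [t.text.lower() for t in tokens]
    hits: list[tuple[Pattern, tuple[int, int], tuple[int, int]]] = []
    for pattern in patterns:
        slot = pattern.tokens.index(TARGET)
        before = [t.lower() for t in pattern.tokens[:slot]]
        after = [t.lower() for t in pattern.tokens[slot + 1 :]]
        for span in range(1, MAX_TARGET_SPAN + 1):
            total = len(before) + span + len(after)
            for start in range(0, len(tokens) - total + 1):
                if lowered[start : start + len(before)] != before:
                    continue
                tail = start + len(before) + span
                if lowered[tail : tail + len(after)] != after:
                    continue
                filler = tokens[start + len(before) : tail]
                if not _filler_ok(filler, known_names):
                    continue
                hits.append(
                    (
                        pattern,
                        (start + len(before), tail - 1),
                        (start, start + total - 1),
                    )
                )
    return hits


def match_patterns(
    sentence: SentenceLike,
    patterns: Iterable[Pattern],
    known_names: frozenset[str] = frozenset(),
) -> set[str]:
    """Lowercased antibody names extracted by any pattern from one sentence."""
    tokens = _as_tokens(sentence)
    names: set[str] = set()
    for _pat, (fs, fe), _win in find_pattern_matches(tokens, patterns, known_names):
        names.add(" ".join(t.text.lower() for t in tokens[fs : fe + 1]))
    return names


def run_bootstrap(
    sentences: Iterable[SentenceLike],
    seeds: Iterable[str],
    backend: NLPBackend,
    n_iterations: int = 2,
) -> BootstrapState:
    """Alternate pattern induction and name extraction for ``n_iterations``.

    Names and patterns grow monotonically; seeds are never removed, even
    when absent from the corpus.  The algorithm is fully deterministic.
    """
    seed_set = frozenset(s.strip().lower() for s in seeds if s.strip())
    if not seed_set:
        raise ValueError("seed set must be non-empty")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    pool = [_as_tokens(s) for s in sentences]
    names: frozenset[str] = seed_set
    patterns: frozenset[Pattern] = frozenset()
    for it in range(1, n_iterations + 1):
        patterns = patterns | induce_patterns(pool, names, backend, origin=it)
        new_names = set(names)
        for sent in pool:
            new_names |= match_patterns(sent, patterns, known_names=names)
        names = frozenset(new_names)
    return BootstrapState(names=names, patterns=patterns, iteration=n_iterations)


def extract_donations_bootstrap(
    ack: Acknowledgement,
    state: BootstrapState,
    backend: NLPBackend,
    sentence_bounded_donor: bool = False,
) -> list[DonationRecord]:
    """Complete donor/affiliation/attributes for every pattern-matched name.

    Antibody names are reported lowercased (the learner's canonical form);
    the surface form is kept on the record for provenance.
    """
    tokens = tokenize(ack.text)
    entities = backend.tag_entities(tokens)
    anchors = {a.anchor_index: a for a in find_anchors(tokens)}
    records: list[DonationRecord] = []
    seen: set[tuple[Optional[str], Optional[str]]] = set()
    for sent in split_sentences(tokens):
        offset = sent[0].index
        for _pat, (fs, fe), (ws, we) in sorted(
            find_pattern_matches(sent, state.patterns, state.names),
            key=lambda h: (h[1][0], h[2][0]),
        ):
            g_fs, g_fe = fs + offset, fe + offset
            name = " ".join(t.text.lower() for t in tokens[g_fs : g_fe + 1])
            surface = ack.text[tokens[g_fs].char_start : tokens[g_fe].char_end]
            donor = extract_donor(
                tokens, g_fs, entities, sentence_bounded=sentence_bounded_donor
            )
            anchor_idx = next(
                (
                    i
                    for i in range(ws + offset, we + offset + 1)
                    if tokens[i].text.lower() in ANCHOR_WORDS
                ),
                g_fs,
            )
            affiliation = (
                extract_affiliation(tokens, donor, anchor_idx, entities)
                if donor is not None
                else None
            )
            attributes: frozenset[str] = frozenset()
            if anchor_idx in anchors:
                attributes = extract_attributes(tokens, anchors[anchor_idx])
            key = (donor.text if donor else None, name)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                DonationRecord(
                    donor=donor.text if donor else None,
                    affiliation=affiliation.text if affiliation else None,
                    antibody=name,
                    attributes=attributes,
                    anchor_index=anchor_idx,
                    article_id=ack.article.article_id,
                    journal=ack.article.journal,
                    year=ack.article.year,
                    method="bootstrap",
                    antibody_surface=surface,
                )
            )
    return records


def load_seeds(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def default_seeds() -> list[str]:
    """The configurable 40-name default seed list shipped with the package."""
    from importlib import resources

    data = resources.files("ackminer.data").joinpath("seed_antibodies.txt")
    return [line.strip() for line in data.read_text("utf-8").splitlines() if line.strip()]
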