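"""Tokenization, dictionary, named-entity and constituency-parse contracts.

The extraction algorithms only ever talk to an :class:`NLPBackend`.  The
package ships a single fully deterministic backend, :class:`FixtureBackend`,
whose behaviour is a pure function of its configuration: a word list for the
English-dictionary test, person/organization/location gazetteers resolved by
longest token-sequence match, and a small hand-written noun-phrase chunk
grammar that covers the syntactic shapes donation sentences take.  Any
statistical tagger or parser can be plugged in behind the same contract.

Conventions: token indices are 0-based; character spans are half-open;
entity token spans are inclusive on both ends.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Protocol, Sequence, Union

__all__ = [
    "Token",
    "EntityMention",
    "ParseTree",
    "NLPBackend",
    "FixtureBackend",
    "Gazetteers",
    "tokenize",
    "split_sentences",
    "load_wordlist",
    "default_wordlist",
    "immediate_parent_np",
    "is_wordlike",
]

ENTITY_LABELS = frozenset({"person", "organization", "location"})

# A period stays attached to single-letter initials and common honorifics so
# that "K. Mackie" tokenizes as ["K.", "Mackie"] and sentence-final periods
# remain standalone tokens (sentence boundaries are read off the token list).
_TOKEN_RE = re.compile(
    r"""
    [A-Z]\.(?![\w.])                              # single initial: "K."
  | (?:Dr|Prof|Mr|Mrs|Ms|Jr|Sr|St)\.(?!\w)        # honorific abbreviations
  | [^\W_]+(?:['’/-][^\W_]+)*                # word, incl. anti-GFP, We'd
  | \S                                            # any other symbol alone
    """,
    re.VERBOSE | re.UNICODE,
)

_SENT_END = frozenset({".", "!", "?"})


@dataclass(frozen=True)
class Token:
    """One token of a source text with its position and character span."""

    text: str
    index: int
    char_start: int
    char_end: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class EntityMention:
    """A labelled entity over an inclusive token span."""

    label: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.label not in ENTITY_LABELS:
            raise ValueError(f"unknown entity label: {self.label!r}")
        if self.start > self.end:
            raise ValueError("entity span start > end")

    def covers(self, token_index: int) -> bool:
        return self.start <= token_index <= self.end


TreeChild = Union["ParseTree", Token]


@dataclass
class ParseTree:
    """A constituency (sub)tree; leaves are :class:`Token` objects."""

    label: str
    children: list[TreeChild] = field(default_factory=list)

    def leaves(self) -> list[Token]:
        out: list[Token] = []
        for child in self.children:
            if isinstance(child, Token):
                out.append(child)
            else:
                out.extend(child.leaves())
        return out

    def __repr__(self) -> str:
        parts = " ".join(
            c.text if isinstance(c, Token) else repr(c) for c in self.children
        )
        return f"({self.label} {parts})"


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into tokens; punctuation and brackets stand alone.

    The concatenation of token texts with the skipped whitespace restores the
    input, and ``text[t.char_start:t.char_end] == t.text`` for every token.
    """
    tokens: list[Token] = []
    for i, m in enumerate(_TOKEN_RE.finditer(text)):
        tokens.append(Token(m.group(0), i, m.start(), m.end()))
    return tokens


def split_sentences(tokens: Sequence[Token]) -> list[list[Token]]:
    """Group a token list into sentences at standalone ``. ! ?`` tokens.

    Abbreviation periods never end a sentence because the tokenizer keeps
    them attached to their word ("Dr.", "Y.").
    """
    sentences: list[list[Token]] = []
    current: list[Token] = []
    for tok in tokens:
        current.append(tok)
        if tok.text in _SENT_END:
            sentences.append(current)
            current = []
    if current:
        sentences.append(current)
    return sentences


def is_wordlike(token_text: str) -> bool:
    """True when the token contains at least one letter or digit."""
    return any(ch.isalnum() for ch in token_text)


def load_wordlist(path: Union[str, Path]) -> frozenset[str]:
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = unicodedata.normalize("NFC", line.strip().lower())
            if word:
                words.add(word)
    return frozenset(words)


def default_wordlist() -> frozenset[str]:
    """The English word list bundled with the package."""
    data = resources.files("ackminer.data").joinpath("wordlist.txt").read_text("utf-8")
    return frozenset(
        unicodedata.normalize("NFC", w.strip().lower())
        for w in data.splitlines()
        if w.strip()
    )


class NLPBackend(Protocol):
    """The contract both extractors program against."""

    def is_dictionary_word(self, token_text: str) -> bool: ...

    def tag_entities(self, tokens: Sequence[Token]) -> list[EntityMention]: ...

    def constituency_parse(self, tokens: Sequence[Token]) -> ParseTree: ...


@dataclass(frozen=True)
class Gazetteers:
    """Entity lexicons for the fixture tagger, one set per label."""

    persons: frozenset[str] = frozenset()
    organizations: frozenset[str] = frozenset()
    locations: frozenset[str] = frozenset()

    @classmethod
    def from_dir(cls, directory: Union[str, Path]) -> "Gazetteers":
        """Read ``persons.txt`` / ``organizations.txt`` / ``locations.txt``."""
        directory = Path(directory)

        def read(name: str) -> frozenset[str]:
            path = directory / name
            if not path.exists():
                return frozenset()
            return frozenset(
                line.strip()
                for line in path.read_text("utf-8").splitlines()
                if line.strip()
            )

        return cls(
            persons=read("persons.txt"),
            organizations=read("organizations.txt"),
            locations=read("locations.txt"),
        )

    def write_dir(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, entries in (
            ("persons.txt", self.persons),
            ("organizations.txt", self.organizations),
            ("locations.txt", self.locations),
        ):
            (directory / name).write_text(
                "".join(e + "\n" for e in sorted(entries)), "utf-8"
            )


# ----------------------------------------------------------------------------
# Fixture backend
# ----------------------------------------------------------------------------

# Closed word classes used by the NP chunker.  Everything word-like outside
# these classes is treated as a potential nominal, which is the right bias
# for acknowledgement prose where the interesting words (antibody names,
# surnames) are exactly the ones no lexicon knows.
DETERMINERS = frozenset(
    {"the", "a", "an", "this", "that", "these", "those", "his", "her",
     "their", "our", "its", "my", "your", "some", "any", "each", "all"}
)
NP_PREPOSITIONS = frozenset({"of", "to"})
FUNCTION_WORDS = frozenset(
    {"is", "was", "were", "are", "am", "be", "been", "being",
     "we", "i", "you", "he", "she", "it", "they", "him", "them", "us", "me",
     "who", "whom", "which",
     "and", "or", "but", "nor", "not", "also", "both",
     "for", "by", "from", "with", "in", "on", "at", "as", "into", "during",
     "thank", "thanks", "thanked", "acknowledge", "acknowledged",
     "provide", "provided", "providing", "give", "gave", "given", "giving",
     "donate", "donated", "donating", "receive", "received", "obtain",
     "obtained", "supply", "supplied", "support", "supported", "fund",
     "funded", "grant", "granted", "share", "shared", "send", "sent",
     "use", "used", "using", "perform", "performed", "help", "helped",
     "read", "reading", "wish", "would", "like", "grateful", "gratefully",
     "kindly", "generously", "very", "most", "much", "many", "several",
     "here", "there", "when", "where", "while", "if", "so", "such", "than",
     "have", "has", "had", "do", "does", "did", "can", "could", "may",
     "might", "will", "shall", "should", "must"}
)
STOP_WORDS = DETERMINERS | NP_PREPOSITIONS | FUNCTION_WORDS


def _is_nominal(text: str) -> bool:
    low = text.lower()
    return is_wordlike(text) and low not in STOP_WORDS


class FixtureBackend:
    """Deterministic dictionary / NER / parser backend.

    * ``is_dictionary_word`` — membership of the lowercased token in the
      configured word list; hyphenated tokens must be listed whole, so
      "anti-tubulin" fails even though "anti" and "tubulin" may not.
    * ``tag_entities`` — greedy longest-match of gazetteer entries against
      the token sequence, case-insensitive, left to right, non-overlapping.
      On equal length, person beats organization beats location.
    * ``constituency_parse`` — NP chunks from determiner/nominal runs, with
      "N of/to X" sub-phrases nested so that the head noun, the preposition
      and the object form their own NP.  Sentences the grammar cannot chunk
      degrade to a flat tree (never an error).
    """

    def __init__(
        self,
        wordlist: Optional[Iterable[str]] = None,
        gazetteers: Optional[Gazetteers] = None,
    ) -> None:
        if wordlist is None:
            self._words = default_wordlist()
        else:
            self._words = frozenset(w.lower() for w in wordlist)
        self._gaz = gazetteers or Gazetteers()
        self._entries = self._compile_gazetteers()

    # -- dictionary ----------------------------------------------------------
    def is_dictionary_word(self, token_text: str) -> bool:
        return unicodedata.normalize("NFC", token_text.lower()) in self._words

    # -- named entities ------------------------------------------------------
    def _compile_gazetteers(self) -> dict[tuple[str, ...], tuple[int, str]]:
        """Map lowercased token tuples to (priority, label)."""
        compiled: dict[tuple[str, ...], tuple[int, str]] = {}
        ordered = (
            ("person", self._gaz.persons),
            ("organization", self._gaz.organizations),
            ("location", self._gaz.locations),
        )
        for priority, (label, entries) in enumerate(ordered):
            for entry in entries:
                key = tuple(t.text.lower() for t in tokenize(entry))
                if key and (key not in compiled or compiled[key][0] > priority):
                    compiled[key] = (priority, label)
        return compiled

    def tag_entities(self, tokens: Sequence[Token]) -> list[EntityMention]:
        if not self._entries:
            return []
        max_len = max(len(k) for k in self._entries)
        lowered = [t.text.lower() for t in tokens]
        mentions: list[EntityMention] = []
        i = 0
        n = len(tokens)
        while i < n:
            best: Optional[tuple[int, int, str]] = None  # (length, prio, label)
            for length in range(min(max_len, n - i), 0, -1):
                key = tuple(lowered[i : i + length])
                hit = self._entries.get(key)
                if hit is not None:
                    prio, label = hit
                    if best is None or length > best[0]:
                        best = (length, prio, label)
                    break  # longest match wins; stop shrinking
            if best is None:
                i += 1
                continue
            length, _, label = best
            surface_start = tokens[i].char_start
            surface = " ".join(t.text for t in tokens[i : i + length])
            mentions.append(EntityMention(label, i, i + length - 1, surface))
            i += length
        return mentions

    # -- constituency parse --------------------------------------------------
    def constituency_parse(self, tokens: Sequence[Token]) -> ParseTree:
        toks = list(tokens)
        if not toks:
            return ParseTree("S", [])
        chunks = self._base_chunks(toks)
        if not chunks:
            return ParseTree("S", list(toks))  # flat degradation
        children = self._attach_and_assemble(toks, chunks)
        return ParseTree("S", children)

    @staticmethod
    def _base_chunks(tokens: Sequence[Token]) -> list[tuple[int, int]]:
        """Half-open index spans of [det]? nominal+ runs."""
        spans: list[tuple[int, int]] = []
        i, n = 0, len(tokens)
        while i < n:
            start = i
            if tokens[i].text.lower() in DETERMINERS:
                i += 1
            j = i
            while j < n and _is_nominal(tokens[j].text):
                j += 1
            if j > i:  # at least one nominal
                spans.append((start, j))
                i = j
            else:
                i = start + 1
        return spans

    def _attach_and_assemble(
        self, tokens: Sequence[Token], chunks: list[tuple[int, int]]
    ) -> list[TreeChild]:
        """Build S-level children, merging ``NP of/to NP`` configurations.

        For a chunk whose head noun is followed by "of"/"to" and another
        chunk, the head + preposition + object tokens become an inner NP so
        that the lowest NP above the object reads e.g. "antibody to UL7";
        any determiner/modifier prefix wraps around it in an outer NP.
        """
        children: list[TreeChild] = []
        used_until = 0
        k = 0
        while k < len(chunks):
            start, end = chunks[k]
            children.extend(tokens[used_until:start])
            prep_idx = end
            merged = False
            if (
                k + 1 < len(chunks)
                and prep_idx < len(tokens)
                and tokens[prep_idx].text.lower() in NP_PREPOSITIONS
                and chunks[k + 1][0] == prep_idx + 1
            ):
                obj_start, obj_end = chunks[k + 1]
                head = end - 1  # last nominal of the left chunk
                inner = ParseTree(
                    "NP",
                    list(tokens[head:end])
                    + [tokens[prep_idx]]
                    + list(tokens[obj_start:obj_end]),
                )
                if head > start:
                    node: TreeChild = ParseTree(
                        "NP", list(tokens[start:head]) + [inner]
                    )
                else:
                    node = inner
                children.append(node)
                used_until = obj_end
                k += 2
                merged = True
            if not merged:
                children.append(ParseTree("NP", list(tokens[start:end])))
                used_until = end
                k += 1
        children.extend(tokens[used_until:])
        return children


def immediate_parent_np(
    tree: ParseTree, target_token_index: int
) -> Optional[list[Token]]:
    """Leaves of the lowest NP ancestor of the leaf at ``target_token_index``.

    Returns ``None`` when the leaf has no NP ancestor (flat fallback trees);
    raises :class:`IndexError` when no leaf carries that index.
    """

    def path_to(node: ParseTree) -> Optional[list[ParseTree]]:
        for child in node.children:
            if isinstance(child, Token):
                if child.index == target_token_index:
                    return [node]
            else:
                sub = path_to(child)
                if sub is not None:
                    return [node] + sub
        return None

    path = path_to(tree)
    if path is None:
        raise IndexError(f"no leaf with token index {target_token_index}")
    for node in reversed(path):
        if node.label == "NP":
            return node.leaves()
    return None
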