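"""Template-based acknowledgement generator with known ground truth.

Every downstream stage — section harvesting, the rule extractor, the
bootstrap learner, evaluation — needs text whose correct answer is known
exactly.  The generator assembles acknowledgement paragraphs from the
sentence shapes donation acknowledgements actually take (active
"the NAME antibody", passive "antibody to NAME", bracketed affiliations,
attribute tags, funding and manuscript-reading distractors), wraps them in
minimal JATS XML, and emits the matching gold annotations plus gazetteers
that cover exactly the planted persons and organizations, so the fixture
entity tagger is perfect by construction.  Antibody names are synthesized
to be absent from the English word list, because the dictionary test is
load-bearing in the extraction rules.

It is a template engine, not a language model: word order never varies
within a template, so extraction on template-only text is exact — that is
the point, and also the limit of what passing tests on it demonstrate.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .gold_annotations import GoldDocument, GoldDonation
from .nlp_adapters import FixtureBackend, Gazetteers, default_wordlist
from .pmc_corpus import Acknowledgement, parse_acknowledgement, parse_article_record

__all__ = [
    "SynthConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_document",
    "synthetic_corpus_counts",
    "TEMPLATES",
]

ATTRIBUTES = ("primary", "secondary", "monoclonal", "polyclonal")
JOURNALS = ("PLoS One", "PLoS Genetics", "PLoS Pathology", "PLoS Biology",
            "BMC Cell Biology")
YEARS = tuple(range(2000, 2015))

_FIRST_NAMES = (
    "Keith", "Peter", "Hugo", "Gary", "Elena", "Ingrid", "Akira", "Chen",
    "Yusuf", "Marta", "Nadia", "Stefan", "Paolo", "Hana", "Ravi", "Olga",
    "Tomas", "Linnea", "Bram", "Sofia",
)
_SYLLABLES = (
    "ka", "mo", "ri", "ta", "shi", "ne", "va", "lo", "du", "gen", "bel",
    "mar", "son", "wit", "cha", "per", "gul", "mak", "nis", "yam", "fun",
    "ber", "hol", "zin", "qua",
)
_ORG_SHAPES = (
    "University of {p}", "{p} University", "{p} Institute",
    "{p} Medical School", "{p} Research Center",
)


@dataclass(frozen=True)
class SynthConfig:
    """Generation rates; identical configs yield byte-identical corpora."""

    n_documents: int = 100
    donation_rate: float = 0.9
    passive_voice_rate: float = 0.2
    bracket_affiliation_rate: float = 0.8
    attribute_rate: float = 0.3
    distractor_rate: float = 0.6
    multi_donation_rate: float = 0.1
    n_antibody_names: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be >= 0")
        for name in (
            "donation_rate", "passive_voice_rate", "bracket_affiliation_rate",
            "attribute_rate", "distractor_rate", "multi_donation_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SyntheticCorpus:
    """Generated acknowledgements with their gold truth and lexicons."""

    acknowledgements: list[Acknowledgement]
    gold: list[GoldDocument]
    gazetteers: Gazetteers
    antibody_names: list[str]
    config: SynthConfig

    def backend(self) -> FixtureBackend:
        return FixtureBackend(gazetteers=self.gazetteers)


# ----------------------------------------------------------------------------
# vocabulary synthesis
# ----------------------------------------------------------------------------

def _proper_noun(rng: random.Random, n_syllables: int = 2) -> str:
    word = "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))
    return word.capitalize()


def _make_person(rng: random.Random, wordlist: frozenset[str]) -> str:
    first = rng.choice(_FIRST_NAMES)
    while True:
        last = _proper_noun(rng, rng.choice((2, 2, 3)))
        if last.lower() not in wordlist:
            break
    if rng.random() < 0.3:
        return f"{first[0]}. {last}"
    return f"{first} {last}"


def _make_org(rng: random.Random, wordlist: frozenset[str]) -> str:
    while True:
        place = _proper_noun(rng, rng.choice((2, 3)))
        if place.lower() not in wordlist:
            break
    return rng.choice(_ORG_SHAPES).format(p=place)


def _make_antibody(rng: random.Random, wordlist: frozenset[str]) -> str:
    """A non-dictionary single-token name: "anti-XYZ" or a code like "UL7"."""
    while True:
        if rng.random() < 0.5:
            stem = "".join(rng.choice("BCDFGHKLMNPRSTVZ") for _ in range(3))
            name = f"anti-{stem}"
        else:
            letters = "".join(rng.choice(string.ascii_uppercase) for _ in range(rng.choice((2, 3))))
            name = f"{letters}{rng.randrange(1, 100)}"
        if name.lower() not in wordlist:
            return name


# ----------------------------------------------------------------------------
# templates
# ----------------------------------------------------------------------------

def _donation_sentence(
    donor: str,
    org: Optional[str],
    antibody: Optional[str],
    attribute: Optional[str],
    passive: bool,
) -> tuple[str, GoldDonation]:
    bracket = f" ( {org} )" if org else ""
    attr_text = f" {attribute}" if attribute else ""
    if antibody is None:
        text = f"We thank {donor}{bracket} for providing antibodies."
    elif passive:
        text = f"{donor}{bracket} is thanked for the{attr_text} antibody to {antibody}."
    else:
        text = f"We thank {donor}{bracket} for the{attr_text} {antibody} antibody."
    gold = GoldDonation(
        resource_label="antibody",
        donor=donor,
        affiliation=org,
        resource_name=antibody,
        attributes=frozenset({attribute} if attribute else ()),
    )
    return text, gold


TEMPLATES = ("active", "passive", "providing", "funding", "reading", "advice")


def generate_document(
    template_id: str, fillers: dict, rng: Optional[random.Random] = None
) -> tuple[str, list[GoldDonation]]:
    """Realize one template; gold lists exactly the planted fields.

    ``fillers`` supplies ``donor``/``org``/``antibody``/``attribute`` as the
    template requires; unknown template ids raise ``ValueError``.
    """
    donor = fillers.get("donor")
    org = fillers.get("org")
    antibody = fillers.get("antibody")
    attribute = fillers.get("attribute")
    if template_id in ("active", "passive"):
        text, gold = _donation_sentence(
            donor, org, antibody, attribute, passive=template_id == "passive"
        )
        return text, [gold]
    if template_id == "providing":
        text, gold = _donation_sentence(donor, org, None, None, passive=False)
        return text, [gold]
    if template_id == "funding":
        return f"This work was supported by grants from {org}.", []
    if template_id == "reading":
        return f"We thank {donor} for critical reading of the manuscript.", []
    if template_id == "advice":
        return (
            f"We thank {donor} for expert advice on antibody cocktails and "
            "flow cytometry data analysis.",
            [],
        )
    raise ValueError(f"unknown template: {template_id!r}")


# ----------------------------------------------------------------------------
# corpus assembly
# ----------------------------------------------------------------------------

def _article_xml(article_id: str, journal: str, year: int, text: str) -> str:
    return (
        "<article><front><journal-meta>"
        f"<journal-title>{journal}</journal-title></journal-meta>"
        "<article-meta>"
        f'<article-id pub-id-type="pmc">{article_id}</article-id>'
        f"<pub-date><year>{year}</year></pub-date>"
        "</article-meta></front><body><p>Not mined.</p></body>"
        f"<back><ack><p>{text}</p></ack></back></article>"
    )


def generate_corpus(config: SynthConfig) -> SyntheticCorpus:
    """Generate a corpus of acknowledgements with exact gold annotations.

    Documents are emitted as JATS XML and re-read through the shallow
    section parser, so the full harvesting path is exercised; the returned
    gazetteers contain exactly the planted persons and organizations.
    """
    rng = random.Random(config.rng_seed)
    wordlist = default_wordlist()

    antibodies = []
    while len(antibodies) < config.n_antibody_names:
        name = _make_antibody(rng, wordlist)
        if name not in antibodies:
            antibodies.append(name)

    persons: set[str] = set()
    orgs: set[str] = set()
    acks: list[Acknowledgement] = []
    gold_docs: list[GoldDocument] = []
    # years weighted toward the present, mimicking open-access growth
    year_weights = [y - 1999 for y in YEARS]

    for i in range(config.n_documents):
        article_id = f"PMC{900000 + i}"
        journal = rng.choice(JOURNALS)
        year = rng.choices(YEARS, weights=year_weights, k=1)[0]
        sentences: list[str] = []
        donations: list[GoldDonation] = []

        if rng.random() < config.donation_rate:
            n_donations = 2 if rng.random() < config.multi_donation_rate else 1
            used_names: set[str] = set()
            for _ in range(n_donations):
                donor = _make_person(rng, wordlist)
                persons.add(donor)
                org = None
                if rng.random() < config.bracket_affiliation_rate:
                    org = _make_org(rng, wordlist)
                    orgs.add(org)
                if rng.random() < 0.12:
                    template, antibody = "providing", None
                else:
                    template = (
                        "passive"
                        if rng.random() < config.passive_voice_rate
                        else "active"
                    )
                    antibody = rng.choice(
                        [a for a in antibodies if a not in used_names]
                    )
                    used_names.add(antibody)
                attribute = (
                    rng.choice(ATTRIBUTES)
                    if antibody and rng.random() < config.attribute_rate
                    else None
                )
                text, gold = generate_document(
                    template,
                    {
                        "donor": donor,
                        "org": org,
                        "antibody": antibody,
                        "attribute": attribute,
                    },
                )
                sentences.append(text)
                donations.extend(gold)

        if rng.random() < config.distractor_rate or not sentences:
            template = rng.choice(("funding", "reading", "advice"))
            donor = _make_person(rng, wordlist)
            org = _make_org(rng, wordlist)
            if template == "funding":
                orgs.add(org)
            else:
                persons.add(donor)
            text, _ = generate_document(template, {"donor": donor, "org": org})
            if rng.random() < 0.5:
                sentences.append(text)
            else:
                sentences.insert(0, text)

        paragraph = " ".join(sentences)
        xml = _article_xml(article_id, journal, year, paragraph)
        article = parse_article_record(xml)
        ack = parse_acknowledgement(xml, article=article)
        assert ack is not None
        acks.append(ack)
        gold_docs.append(
            GoldDocument(
                doc_id=article_id,
                text=ack.text,
                annotator_id="gold",
                donations=tuple(donations),
            )
        )

    gazetteers = Gazetteers(
        persons=frozenset(persons), organizations=frozenset(orgs)
    )
    return SyntheticCorpus(
        acknowledgements=acks,
        gold=gold_docs,
        gazetteers=gazetteers,
        antibody_names=antibodies,
        config=config,
    )


def synthetic_corpus_counts(
    years: Sequence[int] = YEARS,
    start: int = 40_000,
    end: int = 400_000,
) -> dict[int, int]:
    """Per-year article totals growing linearly, for trend normalization."""
    years = sorted(years)
    if len(years) == 1:
        return {years[0]: start}
    step = (end - start) / (len(years) - 1)
    return {y: int(start + i * step) for i, y in enumerate(years)}
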