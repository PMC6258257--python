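import pytest

from ackminer.nlp_adapters import tokenize
from ackminer.pmc_corpus import Acknowledgement, ArticleRecord
from ackminer.rule_extractor import (
    extract_affiliation,
    extract_antibody_name,
    extract_attributes,
    extract_donations,
    extract_donor,
    find_anchors,
)
from oracles import brute_force_rule_records


def ack_of(text: str, doc_id: str = "PMC1") -> Acknowledgement:
    return Acknowledgement(article=ArticleRecord(article_id=doc_id), text=text)


class TestAnchors:
    def test_single_plural_anchor(self):
        tokens = tokenize("for providing antibodies .")
        anchors = find_anchors(tokens)
        assert [a.anchor_index for a in anchors] == [2]

    def test_two_anchors_in_order(self):
        tokens = tokenize(
            "advice on antibody cocktails and notes on antibody usage"
        )
        assert len(find_anchors(tokens)) == 2

    def test_no_keyword(self):
        assert find_anchors(tokenize("we thank the donors")) == []

    def test_windows_clipped_at_sentence_boundary(self):
        tokens = tokenize("UL7 was nice. The antibody was used.")
        anchor = find_anchors(tokens)[0]
        ls, le = anchor.left_window
        # the left window must not reach back across the full stop to "UL7"
        assert all(tokens[i].text != "UL7" for i in range(ls, le))


class TestAntibodyName:
    def test_right_context_via_of_to_gate(self, backend):
        tokens = tokenize("the antibody to UL7")
        anchor = find_anchors(tokens)[0]
        name, side, _ = extract_antibody_name(tokens, anchor, backend)
        assert (name, side) == ("UL7", "right")

    def test_left_context_hyphenated_name(self, backend):
        tokens = tokenize("the anti-GFP antibody was provided")
        anchor = find_anchors(tokens)[0]
        name, side, _ = extract_antibody_name(tokens, anchor, backend)
        assert (name, side) == ("anti-GFP", "left")

    def test_absent_when_window_is_all_dictionary_or_entities(self, backend):
        tokens = tokenize(
            "We thank Peter Merrifield and Stefano Schiaffino for "
            "providing antibodies ."
        )
        anchor = find_anchors(tokens)[0]
        assert extract_antibody_name(tokens, anchor, backend) is None

    def test_right_window_needs_the_gate(self, backend):
        # keyword followed by a non-dictionary token but no "of"/"to"
        tokens = tokenize("the antibody XQZ9 was tested")
        anchor = find_anchors(tokens)[0]
        assert extract_antibody_name(tokens, anchor, backend) is None


class TestAttributes:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("a monoclonal anti-actin antibody", {"monoclonal"}),
            ("primary and secondary antibodies", {"primary", "secondary"}),
            ("the antibody to UL7", set()),
        ],
    )
    def test_left_window_tags(self, text, expected):
        tokens = tokenize(text)
        anchor = find_anchors(tokens)[0]
        assert extract_attributes(tokens, anchor) == frozenset(expected)


class TestDonorAndAffiliation:
    def test_nearest_person_left_unbounded(self, backend):
        tokens = tokenize("Dr. Y. Nishiyama is thanked for the antibody to UL7")
        entities = backend.tag_entities(tokens)
        ul7 = next(t.index for t in tokens if t.text == "UL7")
        donor = extract_donor(tokens, ul7, entities)
        assert donor is not None and donor.text == "Y. Nishiyama"

    def test_no_person_means_absent(self, backend):
        tokens = tokenize("the antibody to UL7 was useful")
        assert extract_donor(tokens, 3, backend.tag_entities(tokens)) is None

    def test_two_persons_nearer_wins(self, backend):
        tokens = tokenize(
            "We thank Keith Gull and later Doris Thelian for the CB1 antibody"
        )
        entities = backend.tag_entities(tokens)
        cb1 = next(t.index for t in tokens if t.text == "CB1")
        donor = extract_donor(tokens, cb1, entities)
        assert donor.text == "Doris Thelian"

    def test_bracketed_affiliation(self, backend):
        tokens = tokenize("K. Mackie ( Indiana University ) for the CB1 antibody")
        entities = backend.tag_entities(tokens)
        donor = next(e for e in entities if e.label == "person")
        anchor = find_anchors(tokens)[0].anchor_index
        aff = extract_affiliation(tokens, donor, anchor, entities)
        assert aff is not None and aff.text == "Indiana University"

    def test_org_right_of_anchor_is_rejected(self, backend):
        tokens = tokenize("K. Mackie for the CB1 antibody ( Indiana University )")
        entities = backend.tag_entities(tokens)
        donor = next(e for e in entities if e.label == "person")
        anchor = find_anchors(tokens)[0].anchor_index
        assert extract_affiliation(tokens, donor, anchor, entities) is None

    def test_org_closest_to_donor_wins(self, backend):
        tokens = tokenize(
            "Keith Gull ( University of Oxford ) at NIH for the CB1 antibody"
        )
        entities = backend.tag_entities(tokens)
        donor = next(e for e in entities if e.label == "person")
        anchor = find_anchors(tokens)[0].anchor_index
        aff = extract_affiliation(tokens, donor, anchor, entities)
        assert aff.text == "University of Oxford"


class TestExtractDonations:
    def test_worked_passive_example(self, backend):
        records = extract_donations(
            ack_of("Dr. Y. Nishiyama is thanked for the antibody to UL7."), backend
        )
        assert len(records) == 1
        assert records[0].donor == "Y. Nishiyama"
        assert records[0].antibody == "UL7"

    def test_two_donation_sentences_two_records(self, backend):
        text = (
            "We thank K. Mackie ( Indiana University ) for the CB1 antibody. "
            "Keith Gull is thanked for the antibody to UL7."
        )
        records = extract_donations(ack_of(text), backend)
        assert [(r.donor, r.antibody) for r in records] == [
            ("K. Mackie", "CB1"),
            ("Keith Gull", "UL7"),
        ]
        assert records[0].affiliation == "Indiana University"

    def test_known_false_positive_advice_sentence(self, backend):
        """The advice-only sentence still produces a donor-only record."""
        text = (
            "We'd like to thank Doris Thelian for her expert advice on "
            "antibody cocktails and flow cytometry data analysis"
        )
        records = extract_donations(ack_of(text), backend)
        assert len(records) == 1
        assert records[0].donor == "Doris Thelian"
        assert records[0].antibody is None

    def test_plural_singular_doublet_deduplicates(self, backend):
        text = "Keith Gull provided the CB1 antibody and more CB1 antibodies."
        records = extract_donations(ack_of(text), backend)
        assert len(records) == 1

    def test_extracted_strings_are_substrings_of_source(self, backend, clean_corpus):
        be = clean_corpus.backend()
        for ack in clean_corpus.acknowledgements[:50]:
            for r in extract_donations(ack, be):
                for value in (r.donor, r.affiliation, r.antibody):
                    if value is not None:
                        assert value in ack.text

    def test_window_discipline(self, clean_corpus):
        """Any left-side antibody name lies within W tokens of its anchor."""
        be = clean_corpus.backend()
        for ack in clean_corpus.acknowledgements[:80]:
            tokens = tokenize(ack.text)
            entities = be.tag_entities(tokens)
            for anchor in find_anchors(tokens):
                found = extract_antibody_name(tokens, anchor, be, entities)
                if found is None:
                    continue
                _name, side, idx = found
                if side == "left":
                    assert 0 < anchor.anchor_index - idx <= anchor.window
                else:
                    assert 0 < idx - anchor.anchor_index <= anchor.window

    def test_determinism(self, backend):
        text = "Dr. Y. Nishiyama is thanked for the antibody to UL7."
        a = extract_donations(ack_of(text), backend)
        b = extract_donations(ack_of(text), backend)
        assert a == b


class TestOracleEquivalence:
    def test_brute_force_agreement_on_generated_paragraphs(self, noisy_corpus):
        """Enumerate-and-filter oracle reproduces every record exactly."""
        be = noisy_corpus.backend()
        for ack in noisy_corpus.acknowledgements:
            got = [
                (r.donor, r.affiliation, r.antibody, r.attributes)
                for r in extract_donations(ack, be)
            ]
            assert got == brute_force_rule_records(ack.text, be)
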