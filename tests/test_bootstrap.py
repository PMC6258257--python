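import pytest

from ackminer.bootstrap_extractor import (
    Pattern,
    corpus_sentences,
    extract_donations_bootstrap,
    find_pattern_matches,
    induce_patterns,
    match_patterns,
    run_bootstrap,
)
from ackminer.nlp_adapters import tokenize
from ackminer.pmc_corpus import Acknowledgement, ArticleRecord
from oracles import fixed_point_bootstrap

FIVE_CONTEXT_CORPUS = [
    "We used the mouse TAG1 antibody in all experiments .",
    "rabbit TAG2 antibodies were a gift .",
    "TAG3 monoclonal antibodies were provided .",
    "TAG4 antibody was used here .",
    "We thank him for the antibody to TAG5 .",
    "An antibody to TAG6 was obtained .",
]
SEEDS = ["TAG1", "TAG2", "TAG3", "TAG4", "TAG5"]

PUBLISHED_PATTERNS = {
    "the mouse TARGET antibody",
    "rabbit TARGET antibodies",
    "TARGET monoclonal antibodies",
    "TARGET antibody",
    "antibody to TARGET",
}


def ack_of(text, doc_id="PMC1"):
    return Acknowledgement(article=ArticleRecord(article_id=doc_id), text=text)


class TestPatternType:
    def test_exactly_one_target_slot(self):
        with pytest.raises(ValueError):
            Pattern(("antibody", "to"))
        with pytest.raises(ValueError):
            Pattern(("TARGET", "to", "TARGET"))

    def test_needs_a_literal(self):
        with pytest.raises(ValueError):
            Pattern(("TARGET",))

    def test_origin_does_not_affect_identity(self):
        assert Pattern(("TARGET", "antibody"), origin=1) == Pattern(
            ("TARGET", "antibody"), origin=2
        )


class TestInduce:
    def test_parent_np_becomes_pattern(self, plain_backend):
        pats = induce_patterns(
            ["We used the mouse TAG1 antibody"], {"TAG1"}, plain_backend
        )
        assert {str(p) for p in pats} == {"the mouse TARGET antibody"}

    def test_plural_context(self, plain_backend):
        pats = induce_patterns(
            ["rabbit TAG2 antibodies were a gift"], {"TAG2"}, plain_backend
        )
        assert {str(p) for p in pats} == {"rabbit TARGET antibodies"}

    def test_sentence_without_seed_yields_nothing(self, plain_backend):
        assert induce_patterns(["no names here"], {"TAG1"}, plain_backend) == set()

    def test_stop_word_only_patterns_are_pruned(self, plain_backend):
        # parent NP would be just "the TAG9": all literals are stop-words
        pats = induce_patterns(["we saw the TAG9"], {"TAG9"}, plain_backend)
        assert pats == set()


class TestMatch:
    def test_right_context_pattern(self):
        names = match_patterns(
            "is thanked for the antibody to UL7",
            {Pattern(("antibody", "to", "TARGET"))},
        )
        assert names == {"ul7"}

    def test_left_context_pattern(self):
        names = match_patterns(
            "the anti-actin antibody", {Pattern(("TARGET", "antibody"))}
        )
        assert names == {"anti-actin"}

    def test_no_window_matches(self):
        assert match_patterns("nothing here", {Pattern(("TARGET", "antibody"))}) == set()

    def test_function_word_fillers_are_rejected(self):
        assert match_patterns(
            "we saw the antibody", {Pattern(("TARGET", "antibody"))}
        ) == set()

    def test_filler_containing_known_name_is_rejected(self):
        names = match_patterns(
            "the mouse TAG1 antibody",
            {Pattern(("TARGET", "antibody"))},
            known_names=frozenset({"tag1"}),
        )
        assert names == {"tag1"}


class TestRunBootstrap:
    def test_learns_exactly_the_five_published_patterns(self, plain_backend):
        state = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 2)
        assert {str(p) for p in state.patterns} == PUBLISHED_PATTERNS

    def test_new_name_discovered_through_shared_context(self, plain_backend):
        state = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 1)
        assert "tag6" in state.names

    def test_monotone_growth_across_iterations(self, plain_backend):
        s1 = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 1)
        s2 = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 2)
        assert s1.names <= s2.names
        assert s1.patterns <= s2.patterns

    def test_seed_absent_from_corpus_persists(self, plain_backend):
        state = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS + ["ghost99"], plain_backend, 2)
        assert "ghost99" in state.names

    def test_empty_corpus_returns_seeds_and_no_patterns(self, plain_backend):
        state = run_bootstrap([], SEEDS, plain_backend, 2)
        assert state.names == frozenset(s.lower() for s in SEEDS)
        assert state.patterns == frozenset()

    def test_patterns_resubstitute_into_corpus_windows(self, plain_backend):
        """TARGET put back yields a real token window of some sentence."""
        state = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 2)
        lowered_sents = [
            [t.text.lower() for t in tokenize(s)] for s in FIVE_CONTEXT_CORPUS
        ]
        for pattern in state.patterns:
            slot = pattern.tokens.index("TARGET")
            witnessed = False
            for sent in lowered_sents:
                n = len(pattern.tokens)
                for start in range(len(sent) - n + 1):
                    window = sent[start : start + n]
                    ok = all(
                        i == slot or window[i] == pattern.tokens[i].lower()
                        for i in range(n)
                    )
                    if ok and window[slot] in state.names:
                        witnessed = True
            assert witnessed, str(pattern)

    def test_fixed_point_oracle_equivalence(self, plain_backend, clean_corpus):
        """Enough iterations reach the exhaustive-rescan fixed point."""
        sentences = corpus_sentences(clean_corpus.acknowledgements[:25])
        seeds = clean_corpus.antibody_names[:10]
        oracle_names, oracle_patterns = fixed_point_bootstrap(
            sentences, seeds, plain_backend, induce_patterns, match_patterns
        )
        state = run_bootstrap(sentences, seeds, plain_backend, n_iterations=6)
        assert state.names == oracle_names
        assert state.patterns == oracle_patterns


class TestExtractDonationsBootstrap:
    def test_composition_with_donor_rules(self, backend, plain_backend):
        state = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 2)
        records = extract_donations_bootstrap(
            ack_of("Dr. Y. Nishiyama is thanked for the antibody to UL7."),
            state,
            backend,
        )
        assert [(r.donor, r.antibody) for r in records] == [("Y. Nishiyama", "ul7")]
        assert records[0].antibody_surface == "UL7"
        assert records[0].method == "bootstrap"

    def test_two_matches_two_records(self, backend, plain_backend):
        state = run_bootstrap(FIVE_CONTEXT_CORPUS, SEEDS, plain_backend, 2)
        text = (
            "Keith Gull is thanked for the antibody to UL7. "
            "K. Mackie gave the CB1 antibody."
        )
        records = extract_donations_bootstrap(ack_of(text), state, backend)
        assert [(r.donor, r.antibody) for r in records] == [
            ("Keith Gull", "ul7"),
            ("K. Mackie", "cb1"),
        ]

    def test_full_recovery_on_clean_corpus(self, clean_corpus):
        """Seeding 40 planted names recovers all of them in 2 iterations."""
        be = clean_corpus.backend()
        planted = {
            d.resource_name.lower()
            for g in clean_corpus.gold
            for d in g.donations
            if d.resource_name
        }
        seeds = sorted(planted)[:40]
        state = run_bootstrap(
            corpus_sentences(clean_corpus.acknowledgements), seeds, be, 2
        )
        assert planted <= state.names
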