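"""Naive reference implementations used only to cross-check the extractors.

These deliberately trade efficiency and structure for obviousness: they
enumerate every candidate exhaustively and apply the stated predicates
directly, sharing as little code as possible with the implementations they
check.
"""

from __future__ import annotations

from ackminer.nlp_adapters import is_wordlike, split_sentences, tokenize
from ackminer.rule_extractor import ATTRIBUTE_TAGS


def brute_force_rule_records(text, backend, window=4):
    """Enumerate-and-filter re-derivation of the rule extractor's output.

    Returns a list of (donor, affiliation, antibody, attributes-frozenset)
    tuples in anchor order, deduplicated on (donor, antibody).
    """
    tokens = tokenize(text)
    entities = backend.tag_entities(tokens)

    def in_entity(i):
        return any(e.start <= i <= e.end for e in entities)

    # sentence span of each token
    sent_of = {}
    for sent in split_sentences(tokens):
        lo, hi = sent[0].index, sent[-1].index
        for t in sent:
            sent_of[t.index] = (lo, hi)

    records = []
    seen = set()
    for anchor in [t.index for t in tokens if t.text.lower() in ("antibody", "antibodies")]:
        lo, hi = sent_of[anchor]
        left = [i for i in range(anchor - window, anchor) if lo <= i]
        right = [i for i in range(anchor + 1, anchor + 1 + window) if i <= hi]

        def candidate(i):
            t = tokens[i].text
            return (
                is_wordlike(t)
                and not backend.is_dictionary_word(t)
                and not in_entity(i)
            )

        antibody_idx = None
        for i in reversed(left):  # nearest first
            if candidate(i):
                antibody_idx = i
                break
        if antibody_idx is None:
            gates = [i for i in right if tokens[i].text.lower() in ("of", "to")]
            if gates:
                for i in right:
                    if i > gates[0] and candidate(i):
                        antibody_idx = i
                        break
        antibody = tokens[antibody_idx].text if antibody_idx is not None else None

        attrs = frozenset(
            tokens[i].text.lower()
            for i in left
            if tokens[i].text.lower() in ATTRIBUTE_TAGS
        )

        start = antibody_idx if antibody_idx is not None else anchor
        persons = [e for e in entities if e.label == "person" and e.end < start]
        donor = max(persons, key=lambda e: e.end) if persons else None

        affiliation = None
        if donor is not None:
            orgs = [
                e
                for e in entities
                if e.label == "organization"
                and e.start > donor.end
                and e.end < anchor
            ]
            if orgs:
                affiliation = min(orgs, key=lambda e: e.start).text

        if donor is None and antibody is None:
            continue
        key = (donor.text if donor else None, antibody)
        if key in seen:
            continue
        seen.add(key)
        records.append((key[0], affiliation, antibody, attrs))
    return records


def naive_bootstrap_records(text, state, backend):
    """Independent re-derivation of bootstrap record extraction.

    Scans every sentence with every pattern at every alignment and target
    span, completes donor/affiliation by exhaustive enumeration, and
    returns (donor, affiliation, antibody-lowercase) tuples in match order,
    deduplicated on (donor, antibody).
    """
    from ackminer.bootstrap_extractor import MAX_TARGET_SPAN, TARGET
    from ackminer.rule_extractor import ATTRIBUTE_TAGS as TAGS
    from ackminer.nlp_adapters import STOP_WORDS

    tokens = tokenize(text)
    entities = backend.tag_entities(tokens)
    lowered = [t.text.lower() for t in tokens]

    def filler_ok(span_lo, span_hi):
        words = lowered[span_lo : span_hi + 1]
        if not all(is_wordlike(w) for w in words):
            return False
        if any(w in STOP_WORDS or w in TAGS or w in ("antibody", "antibodies")
               for w in words):
            return False
        if len(words) > 1:
            for i in range(len(words)):
                for j in range(i + 1, len(words) + 1):
                    if j - i < len(words) and " ".join(words[i:j]) in state.names:
                        return False
        return True

    hits = []
    for sent in split_sentences(tokens):
        lo, hi = sent[0].index, sent[-1].index
        for pattern in state.patterns:
            slot = pattern.tokens.index(TARGET)
            before = [w.lower() for w in pattern.tokens[:slot]]
            after = [w.lower() for w in pattern.tokens[slot + 1 :]]
            for span in range(1, MAX_TARGET_SPAN + 1):
                for start in range(lo, hi - (len(before) + span + len(after)) + 2):
                    f_lo = start + len(before)
                    f_hi = f_lo + span - 1
                    a_lo = f_hi + 1
                    if lowered[start:f_lo] != before:
                        continue
                    if lowered[a_lo : a_lo + len(after)] != after:
                        continue
                    if not filler_ok(f_lo, f_hi):
                        continue
                    win = (start, a_lo + len(after) - 1)
                    hits.append((f_lo, f_hi, win))
    hits.sort(key=lambda h: (h[0], h[2][0]))

    records = []
    seen = set()
    for f_lo, f_hi, (w_lo, w_hi) in hits:
        name = " ".join(lowered[f_lo : f_hi + 1])
        persons = [e for e in entities if e.label == "person" and e.end < f_lo]
        donor = max(persons, key=lambda e: e.end).text if persons else None
        anchor = next(
            (i for i in range(w_lo, w_hi + 1)
             if lowered[i] in ("antibody", "antibodies")),
            f_lo,
        )
        affiliation = None
        if donor is not None:
            d = max(persons, key=lambda e: e.end)
            orgs = [
                e for e in entities
                if e.label == "organization" and e.start > d.end and e.end < anchor
            ]
            if orgs:
                affiliation = min(orgs, key=lambda e: e.start).text
        key = (donor, name)
        if key in seen:
            continue
        seen.add(key)
        records.append((donor, affiliation, name))
    return records


def fixed_point_bootstrap(sentences, seeds, backend, induce, match):
    """Exhaustive re-scan each round until neither set changes."""
    names = frozenset(s.lower() for s in seeds)
    patterns = frozenset()
    while True:
        new_patterns = frozenset(patterns | induce(sentences, names, backend))
        new_names = set(names)
        for sent in sentences:
            new_names |= match(sent, new_patterns, known_names=names)
        new_names = frozenset(new_names)
        if new_names == names and new_patterns == patterns:
            return names, patterns
        names, patterns = new_names, new_patterns
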