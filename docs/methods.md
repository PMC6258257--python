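# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic corpus does and does not
emulate, and the design choices made where the design was genuinely open.

## The extraction problem

An acknowledgement paragraph may mention several unrelated things —
funding, instrument access, manuscript reading — alongside zero or more
reagent donations. A donation statement names up to four things: the donor
(a person), their affiliation (an organization, very often in brackets
immediately after the name), the antibody, and attribute tags (primary /
secondary / monoclonal / polyclonal). Both extractors emit one
`DonationRecord` per detected donation; records with neither a donor nor
an antibody are suppressed, and per-paragraph duplicates of the same
(donor, antibody) pair (e.g. from a singular and a plural keyword in one
sentence) are collapsed.

## Rule-based extractor

Anchors are whole-token, case-insensitive matches of *antibody* /
*antibodies*. Around each anchor:

* **Context window** `window = 4` tokens on each side, clipped at sentence
  boundaries. Four tokens is enough to span "the monoclonal NAME antibody"
  noun phrases without reaching into neighbouring clauses; it is exposed as
  a parameter on `extract_donations` and the CLI.
* **Antibody name** — first left-window token, scanned nearest-first, that
  (a) contains a letter or digit, (b) is not in the English word list
  (hyphenated tokens must be listed whole, so *anti-tubulin* fails), and
  (c) lies inside no entity mention. If the left window yields nothing,
  the right window is searched the same way, but only when the anchor is
  followed by *of* or *to* within the window, and only past that
  preposition — this is what catches the passive "antibody to UL7" form
  while keeping the right window from firing on unrelated clauses.
* **Donor** — nearest person entity ending left of the antibody name
  (of the anchor itself when no name was found; without this fallback every
  "thanks X for providing antibodies" sentence would lose its donor). The
  scan is paragraph-wide by default (`sentence_bounded_donor=False`)
  because donor names routinely sit a clause or more away from the reagent.
* **Affiliation** — organization entity strictly between the donor and the
  anchor, closest to the donor; ties cannot arise for distinct mention
  spans, and overlapping gazetteer entries are already resolved
  longest-match-first by the tagger.
* **Attributes** — the subset of the four tag words present in the left
  window.

The method knowingly over-triggers on keyword sentences that are not
donations (expert-advice thanks produce donor-only records); this is a
property of the keyword-anchored design, not a bug, and the evaluation
counts it against no field because accuracy is gold-denominated.

## Bootstrap pattern learner

State is a pair of monotonically growing sets: lowercased antibody names
(initialized with the seeds) and patterns (token sequences with exactly one
`TARGET` slot). One iteration = induce + match:

* **Induction**: for every corpus occurrence of a known name, take the
  leaves of the lowest noun phrase covering it in the constituency parse
  and replace the name tokens with `TARGET`. Patterns whose literals are
  all stop-words (`the TARGET`) are discarded — without this guard, noise
  amplifies quickly once iteration counts grow.
* **Matching**: each pattern slides over each sentence; literals compare
  case-insensitively and `TARGET` may absorb 1–3 tokens (multi-token
  antibody names exist; an unbounded slot would match runaway spans).
  Fillers are rejected when they contain a non-word token, any stop-word,
  the anchor keyword, an attribute tag, or — for multi-token fillers — an
  already-known name as a strict sub-span ("mouse TAG1" must not become a
  name when "TAG1" is known). Extracted names are canonicalized to
  lowercase; records keep the surface form for provenance.

`n_iterations` defaults to 2: the first iteration learns the patterns the
seeds witness, the second closes over names those patterns discover; in
practice further rounds mostly add noisy rules, and a brute-force
fixed-point oracle in the test suite confirms the iteration converges on
small corpora. The algorithm has no random element, hence no seed
parameter.

## NLP backend

Both extractors depend only on a four-operation contract: dictionary test,
entity tagging, constituency parse, tokenization. The shipped
`FixtureBackend` is deterministic:

* **Tokenizer** — regex-based; punctuation and brackets are standalone
  tokens (the bracket-affiliation heuristic needs this); periods stay
  attached to single-letter initials and honorifics so that sentence
  splitting on standalone `.` `!` `?` is safe. Indices are 0-based,
  character spans half-open.
* **Dictionary** — a bundled ~1,100-word common-English list
  (`data/wordlist.txt`), configurable per call site. Any list biases which
  tokens can be antibody names; the bundled list is deliberately small and
  common-word only, which errs toward extracting rare words (the right
  bias for this task).
* **Entity tagger** — greedy longest-match of gazetteer entries over the
  token sequence, case-insensitive, left-to-right, non-overlapping; on
  equal length person beats organization beats location. A statistical
  tagger can be plugged in behind the same contract, but tests never
  depend on model weights.
* **Parser** — a noun-phrase chunker: base NPs are determiner + nominal
  runs (nominal = word-like token outside a closed function-word list);
  a base NP followed by *of*/*to* and another NP nests the head noun,
  preposition and object into an inner NP, so the lowest NP over "UL7" in
  "the antibody to UL7" reads `antibody to UL7`. Sentences the grammar
  cannot chunk degrade to a flat tree and induction simply skips them.

## Evaluation

Accuracy is reported per field with an explicit `MatchPolicy` embedded in
every report: by default case-folding, punctuation stripping, honorific
stripping, exact match after normalization, and "match any annotator".
The denominator for each field is the number of gold donations carrying
that field (documents with no gold donation contribute nothing); the mean
is the unweighted average of the three fields, printed with integer
rounding. Donations from different annotators are pooled by normalized
resource name, falling back to the donor — annotators write the same donor
differently ("Keith Gull" / "K. Gull"), so the donor alone is too brittle
a merge key. Word-order variants ("University of Oxford" vs "Oxford
University") are deliberately misses under the exact policy; a containment
mode exists for softer matching.

Inter-annotator agreement is the fraction of field comparisons (donor,
affiliation, resource name, attribute set — four per aligned donation
pair, aligned by position) on which annotator pairs agree; surplus
donations count as four disagreements; the quantity is undefined (an
error) when no document has two annotators.

## Synthetic corpus

The generator emulates the sentence shapes donation acknowledgements take:
active ("We thank D ( O ) for the monoclonal X antibody."), passive
("D is thanked for the antibody to X."), donor-only ("… for providing
antibodies."), plus funding, manuscript-reading and expert-advice
distractors (the last contains the keyword without a donation — the
classic false-positive shape). Rates and their defaults:
`donation_rate=0.9` (most keyword-positive paragraphs do describe a
donation), `passive_voice_rate=0.2` (the passive form is the occasional
one), `bracket_affiliation_rate=0.8` (affiliations almost always follow
the donor in brackets), `attribute_rate=0.3`, `distractor_rate=0.6`,
`multi_donation_rate=0.1` (multiple donations per paragraph are rare).
Antibody names are synthesized as `anti-XXX` consonant forms or
letter-digit codes and checked against the word list, so the dictionary
test is exercised deterministically; gazetteers contain exactly the
planted persons and organizations, so fixture NER is perfect. Documents
are emitted as minimal JATS XML and re-read through the shallow section
parser, covering the harvesting path. One `random.Random(rng_seed)`
drives everything; identical configs are byte-identical.

What the generator does **not** emulate: free word order, donors mentioned
after the reagent, coordination ("X and Y antibodies"), anaphora,
misspellings, NER errors. Perfect scores on template-only text therefore
demonstrate correctness of the rules' logic, not real-world accuracy; on
real text the published benchmark (see below) is the measure.

## Problem sizes

The bundled benchmarks use 200-document corpora for the closure and
default-rate runs, 500 paragraphs for the oracle-equivalence check, and a
six-sentence corpus for pattern-list reproduction — large enough that
every template and rate is exercised many times over while the whole suite
runs in seconds.

## Known limitations

* The 50-document expert-annotated gold benchmark is not redistributed;
  `read_gold_xml` provides a `dialect` hook to adapt its XML once obtained,
  and the benchmark test states the expected drop-in location.
* Donor-name normalization ("Keith Gull" vs "K. Gull") is deliberately
  absent from extraction; an initials-folding normalizer exists only as a
  reporting-time option, off by default.
* The exact published accuracy figures depend on the third-party NER,
  dictionary and matching criterion used there; with the deterministic
  fixture backend this package reproduces the algorithms, not those exact
  artefacts, and embeds the matching policy in every report to keep the
  numbers interpretable.
* The pattern learner is unweighted — no confidence scoring or pattern
  promotion; precision control is entirely via the stop-word and filler
  guards plus the iteration cap.
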