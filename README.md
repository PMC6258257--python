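# ackminer

Mining the acknowledgement sections of biomedical articles for **antibody
donations** — statements that a named researcher (often with an affiliation
in brackets) provided an antibody to the authors. Researchers routinely
thank donors of reagents in their acknowledgements; harvesting those
statements at corpus scale reveals who shares which reagents, and is the
raw material for resource-exchange platforms that connect antibody seekers
with potential donors.

The package is aimed at text-mining practitioners and bio-curation groups
working with PubMed Central open-access XML. It implements two extraction
algorithms over acknowledgement paragraphs, plus everything needed to
develop and evaluate them without any download.

## Methods

**Rule-based extraction.** Every occurrence of the keyword *antibody* /
*antibodies* anchors a context window of W = 4 tokens. The antibody name is
the first word in the left window that is neither an English dictionary
word nor part of a named entity; if the left window fails and the keyword
is followed by *of*/*to* ("antibody to UL7" — the passive form), the right
window is searched instead. Attribute tags (*primary, secondary,
monoclonal, polyclonal*) are read from the left window. The donor is the
nearest person entity left of the antibody name with **no** window bound
(donor names sit far from the reagent), and the affiliation is the
organization entity closest to the donor while still left of the keyword.

**Bootstrapped pattern learning.** Starting from a seed set of antibody
names, alternate: (1) for each occurrence of a known name, take the leaves
of its immediate parent noun phrase in a constituency parse and replace the
name with a `TARGET` wildcard — these are the learned patterns (e.g.
`antibody to TARGET`, `the mouse TARGET antibody`); (2) match every pattern
against every sentence and harvest the tokens aligned with `TARGET` as new
names. Both sets grow monotonically; two iterations are the default (more
iterations amplify noisy rules). Donors and affiliations for matched names
are completed with the same context rules as above.

Named-entity tagging, the dictionary test and the constituency parse sit
behind a pluggable backend contract; the shipped backend is a fully
deterministic fixture (gazetteer longest-match NER, bundled word list, a
small noun-phrase chunk grammar), so every result is reproducible bit for
bit. See `docs/methods.md` for the details and the design choices.

## Worked example

```python
from ackminer import (Acknowledgement, ArticleRecord, FixtureBackend,
                      Gazetteers, extract_donations, run_bootstrap)

backend = FixtureBackend(gazetteers=Gazetteers(
    persons=frozenset({"Y. Nishiyama", "K. Mackie"}),
    organizations=frozenset({"Indiana University"}),
))
ack = Acknowledgement(
    article=ArticleRecord(article_id="PMC1"),
    text=("We thank K. Mackie ( Indiana University ) for the CB1 antibody. "
          "Dr. Y. Nishiyama is thanked for the antibody to UL7."),
)
for record in extract_donations(ack, backend):
    print(record.donor, "|", record.affiliation, "|", record.antibody)

state = run_bootstrap(
    ["We used the mouse TAG1 antibody .", "An antibody to TAG2 was obtained ."],
    ["TAG1", "TAG2"], backend, n_iterations=2)
for p in sorted(map(str, state.patterns)):
    print(p)
```

prints

```
K. Mackie | Indiana University | CB1
Y. Nishiyama | None | UL7
antibody to TARGET
the mouse TARGET antibody
```

The first record comes from the active-voice rule (`CB1` fails the
dictionary test inside the left window; the bracketed organization is the
closest one right of the donor). The second comes from the right-context
rule gated on *to*, with the donor found by the unbounded person scan. The
two learned patterns are the parent noun phrases of the seed names with the
name replaced by the wildcard.

The same pipeline is available from the shell:

```bash
ackminer simulate --out-dir sim --n 100 --seed 7
ackminer extract-rule --in sim/ack.jsonl --out records.jsonl --gazetteers sim/gazetteers
ackminer evaluate --pred records.jsonl --gold sim/gold.xml
ackminer report --in records.jsonl --key donor --k 5
```

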