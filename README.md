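# mdrepo

A content-addressed metadata repository engine for clinical study
metadata in CDISC ODM 1.3 format, built around *bottom-up
standardization*: instead of a committee declaring a standard data
element, the engine collects real-world form definitions, aggregates the
ones that are exactly equivalent, and treats the most frequently reused
definition of a concept as its de facto standard.

It is aimed at medical data managers and clinical research informatics
developers who maintain collections of case report forms and want to
find, compare and reuse existing data element definitions rather than
redefine them.

## What it does

- **Parse and decompose** ODM metadata documents into atomic resources
  (Study, Protocol, Form, ItemGroup, Item, CodeList, CodeListItem,
  MeasurementUnit), resolving all references into containment.
- **Aggregate equivalent definitions.** Two resources are *strictly
  equivalent* when they agree in every property including their whole
  subtree. This is decided by a canonical key: a SHA-256 digest over a
  normalized serialization in which each child appears through its own
  digest (a Merkle construction), so any change anywhere in a subtree
  changes every ancestor's key. Each unique definition is stored once,
  with its occurrence count and full provenance.
- **Rank search results** by a tradeoff between text match quality `m`
  (a disjunctive idf-weighted token score over question, name and other
  fields) and reuse frequency `c`:

      score = m · (1 + ln c)

  so widely reused definitions surface first, but a clearly better
  textual match can outrank a more frequent weaker one.
- **Serve a read-only, API-key-guarded HTTP interface** with one
  collection endpoint per resource kind and single resources addressed
  by their canonical key; resource JSON is lossless, so re-keying a
  decoded element reproduces its id.
- **Evaluate standard emergence** per concept query: cumulative
  occurrence curves and the top-k occurrence ratio
  `Σ occ(top k) / Σ occ(all matches)`, under strict equivalence and under
  a *relaxed* equivalence that clusters items by their lowercase English
  question text. The 24 concept queries of the reference evaluation
  (vital signs, common laboratory codes, ischaemic heart disease and
  stroke concepts) ship as a fixture.
- **Measure rater agreement** for quality surveys: ordinal
  Krippendorff's alpha (`α = 1 − D_o/D_e` from the coincidence matrix,
  ordinal distance function) with a unit-resampling bootstrap percentile
  confidence interval, plus Likert response summaries.
- **Generate synthetic corpora** with known ground truth: per concept, a
  planted standard and perturbed variants whose usage frequencies follow
  a Zipf law across documents, plus ordinal rating matrices with a
  controllable agreement level.

## Worked example

```sh
mdrepo synth --seed 7 --out corpus          # 200 synthetic ODM documents
mdrepo ingest corpus/doc-00*.xml --store store.json   # first 100 of them
mdrepo stats --store store.json
```

```
kind                 total    unique   reuse
Study                  100       100    1.00
Form                   100       100    1.00
ItemGroup              100       100    1.00
Item                   500       119    4.20
CodeList               326        27   12.07
CodeListItem           837        21   39.86
MeasurementUnit        106         4   26.50
Total                 2069       471    4.39
```

The 100 documents contained 2,069 atomic resources of which 471 were
unique; `reuse` is total/unique, e.g. each unique item definition was
used 4.20 times on average. Searching ranks by the match/frequency
tradeoff:

```sh
mdrepo search "body height" --store store.json --limit 3
```

```
total matches: 15
  1. [  21x] score=90.851  Body height
  2. [   2x] score=38.033  Body height
  3. [   6x] score=31.355  Body height - maximum
```

The top hit is the definition used 21 times — the emerging bottom-up
standard for this concept; the second is a strict-mode variant with the
same question text but different properties (the relaxed evaluation mode
would merge the two and report 23 summed occurrences).

Other entry points: `mdrepo evaluate` (top-3 occurrence ratios and
cumulative curves over a concept query list), `mdrepo export-codes`
(semantic-code transfer with an expert-time-saved estimate),
`mdrepo alpha` (interrater agreement), `mdrepo serve` (HTTP API).

The same flow is available as a library:

```python
from mdrepo import MetadataStore, build_index, parse_odm

store = MetadataStore()
store.ingest_document(parse_odm("form.xml"))
hits = build_index(store).search("body height").hits
```

## Layout

| Module | Role |
| --- | --- |
| `mdrepo.model` | resource tree types and error hierarchy |
| `mdrepo.odm` | ODM 1.3 parsing, document/fragment serialization |
| `mdrepo.canonical` | canonical serialization, Merkle keys, relaxed question keys |
| `mdrepo.store` | aggregation store, statistics, semantic-code export |
| `mdrepo.search` | inverted index and frequency-weighted ranking |
| `mdrepo.api` | read-only WSGI HTTP service |
| `mdrepo.evaluation` | concept reports, curves, group summaries |
| `mdrepo.agreement` | ordinal Krippendorff's alpha, bootstrap CI, Likert tables |
| `mdrepo.synthetic` | ground-truth corpus and rating generators |

See `docs/methods.md` for the underlying model and design choices.
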