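# Methods

## The model: frequency as a quality signal

The engine implements a *pragmatic* metadata repository: it does not
curate a single authoritative definition per concept but collects every
real-world definition it is given and lets frequency of reuse order
them. The underlying assumption is that a definition used in many
independent data collections has been vetted in practice and is a better
reuse candidate than an equally plausible singleton. The package
operationalizes this with three mechanisms: exact aggregation of
equivalent definitions, log-frequency-boosted search, and the top-k
occurrence ratio as a measure of how strongly a concept's usage
concentrates on few definitions ("standard emergence").

## Strict equivalence and canonical keys

Two resources are strictly equivalent iff they agree in every property,
recursively over their whole subtree. Concretely, equivalence is decided
on a canonical serialization with these normalizations:

- attributes sorted by name; translated texts sorted by (role, language);
  aliases and range checks kept in document order (their order is
  content);
- text payloads NFC-normalized, trimmed, internal whitespace runs
  collapsed — XML serialization artifacts must not break equivalence;
- children represented by the SHA-256 digest of their own canonical
  form (Merkle construction), and child order significant, because ODM
  ordering carries meaning for code lists and item sequences.

The canonical key is the SHA-256 hex digest of this string. Equal keys
are treated as equal definitions (collision-freedom is a working
assumption; tests verify key equality coincides with serialization
equality on generated corpora). OIDs are part of the definition by
default — "every property" read literally — with an `ignore_oids`
switch for corpora whose OIDs are machine-generated noise, since two
byte-identical items with different generated OIDs arguably describe
the same element.

Reference-level attributes (`Mandatory`, `OrderNumber` on `ItemRef` and
friends) describe the *usage context* of a definition inside a form,
not the definition itself, and are therefore not part of the atomic
resource; order is preserved structurally instead.

The relaxed equivalence used by the evaluation compares only the
lowercase, whitespace-normalized English question text of items — the
text users actually see. English means a tag of `en` or an `en-` prefix;
an untagged text counts as English only when the item has no tagged
question at all (configurable). Items without an English question drop
out of question-level clustering and of the evaluation.

## Decomposition and the resource model

Eight resource kinds are stored by default: Study, Protocol, Form,
ItemGroup, Item, CodeList, CodeListItem, MeasurementUnit. StudyEvent is
recognized but skipped by default (`include_study_events` restores it
between Protocol and Form); for flat form collections the event layer
only duplicates the Study→Form path. Reference resolution duplicates
shared subtrees: a code list referenced by two items appears under both,
so occurrence counts measure *usages*. One occurrence is one appearance
in one ingested document path — a definition used twice within a
document counts twice. Re-ingesting a known document id is rejected
outright to keep repeated synchronizations from inflating counts.

## Search scoring

Tokenization is lowercase with splits on non-alphanumeric characters; no
stemming, no stop words — deliberately minimal so every score can be
recomputed by hand and in the full-scan oracle tests. For a query token
present in a record the contribution is `idf(t) · w(field)` with
`idf = ln(1 + U/df)` (U unique records of the kind, df records
containing the token anywhere) and field weights question 2.0, name 1.0,
other fields (description, code-list decodes, alias names) 0.5, taking
the best field per token. A whole-query exact match of the question
doubles the sum. The final rank order uses
`score = m · (1 + ln c)`; the `+1` keeps singletons visible, and ties
break by (occurrences desc, key asc) so orderings are total and stable.
BM25-style scoring was deliberately avoided: the goal is a deterministic,
hand-checkable ranking that exhibits the qualitative behaviors of
interest (partial matches score lower; a much better match can beat a
much more frequent one), not retrieval-benchmark performance.

## Evaluation statistics

For a concept query, *all* results means every definition with a
positive match score (no truncation). The top-k occurrence ratio is
`Σ occ(top k) / Σ occ(all matches)`; with at most k matches it is 1,
with zero matches it is undefined and flagged rather than raised. In
relaxed mode, matching items are merged by relaxed question key with
occurrences summed; clusters are re-ranked by the combined score of
their highest-occurrence member using the summed count, and both the
cluster count and the pre-merge record count are reported, since either
could be read as "total results". Group summaries are the arithmetic
mean and *sample* (n−1) standard deviation of the ratios, reported as
percentages with two decimals. Cumulative curves report
`curve(t) = |{d : occ(d) ≥ t}|`, so `curve(1)` is the number of distinct
matching definitions.

## Krippendorff's alpha

Alpha is computed from the coincidence matrix over all pairable values
(units with ≥ 2 non-missing ratings): `α = 1 − D_o/D_e`, with the
ordinal difference function built from the coincidence marginals —
`δ²(c,k) = (Σ_{g=c}^{k} n_g − (n_c + n_k)/2)²` for categories `c < k`.
Degenerate inputs: with zero expected *and* observed disagreement alpha
is defined as 1 (constant ratings agree perfectly); zero expected with
nonzero observed disagreement is an error. The bootstrap resamples
survey units (item × property pairs) with replacement, recomputes alpha
B times (default 1000) and takes the percentile interval; degenerate
resamples are redrawn and counted. All bootstrap randomness flows from
one seed. The even-length ordinal median reports the lower of two
distinct middle categories, so every summary cell names a single
category. Invalid responses are treated as missing.

## Synthetic ground truth

The corpus generator emulates the one robust empirical feature of real
form collections this engine targets: heavy-tailed reuse. Per concept it
plants a rank-1 "standard" definition and `defs_per_concept − 1`
perturbed variants (question casing, question rewording with a
controlled qualifier vocabulary, datatype changes, code-list edits);
each document slot draws a concept uniformly and a variant rank from a
Zipf(`zipf_exponent`) law. Casing-only variants collide under relaxed
but not strict equivalence, reproducing the strict-vs-clustered contrast
of real evaluations. Defaults — 20 concepts × 8 variants, 200 documents
× 5 items, exponent 1.5, casing/rewording/datatype/code-list
perturbation probabilities 0.35/0.45/0.15/0.15, alias rate 0.6, English
rate 0.9 — describe a desk-scale snapshot in which standards emerge but
the tail dominates counts of uniques.

What the generator does *not* emulate: genuine medical content (concept
names come from a fixed controlled vocabulary), UMLS-coherent semantic
codes (alias codes are synthetic tokens), cross-concept semantic
overlap beyond shared tokens, multi-form studies, or annotator drift in
the rating model (raters err only to adjacent categories). Passing
tests therefore demonstrate the correctness of the machinery —
aggregation, ranking, statistics — under known ground truth, not that
bottom-up standards emerge in any particular real corpus; headline
numbers from external snapshots are treated as format illustrations
only.

The ratings generator draws a latent category per unit; raters report it
with probability `agreement_level`, otherwise an adjacent category, and
entries go missing at `missing_rate`. This yields alpha monotone in the
agreement level and supports bootstrap coverage checks against a
large-sample reference alpha.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: dedup oracles on five
50-document corpora (~1,000 elements each), ranking oracles on a
200-document corpus with ≥ 200 unique item definitions, standard
recovery on 500 documents × 20 concepts, bootstrap checks at B = 200–400
with 120-replication coverage at n = 60 units. Exact-arithmetic checks
(scoring sums, alpha vs. brute force, variance) use absolute tolerances
of 1e-9–1e-12; everything else is exact. The expert-time-saved estimate
in the semantic-code export is `coded items × 1 minute` (configurable),
reported in exact hours plus a rounded display value, reflecting the
rule of thumb that semantic coding takes a medical expert about one
minute per item.

## Known limitations

- Only the ODM 1.3 metadata subset is handled: no ClinicalData, no
  ODM 2.0, no vendor extensions, no schema validation beyond structure.
- The store is in-memory with JSON persistence; it targets desk-scale
  corpora, not the multi-hundred-thousand-definition scale of a
  production portal.
- Search is monolingual and exact-token based; synonym expansion, fuzzy
  matching and stemming are out of scope.
- The HTTP API is read-only by design; content enters through batch
  ingest.
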