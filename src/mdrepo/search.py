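"""Frequency-weighted search over aggregated definitions.

Ranking trades off text match quality against the logarithm of a
definition's number of occurrences::

    combined_score = match_score * (1 + ln(occurrences))

so a frequently reused definition outranks an equally matching rare one,
while a clearly better textual match can still beat a more frequent but
weaker match.  The ``+1`` keeps singletons (occurrences = 1) visible.

Match scoring is disjunctive (OR) over query tokens: each query token
present in a record contributes ``idf(token) * field_weight`` with
``idf = ln(1 + U/df)`` (U = unique records of the kind, df = records
containing the token) and the maximum weight over the fields where it
occurs (question 2.0, name 1.0, everything else 0.5).  A whole-query
exact match of the question field doubles the sum.  Tokenization is
lowercase, split on non-alphanumeric characters, no stemming or stop
words — deliberately simple so scores can be recomputed by hand.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .canonical import CanonicalKey, english_question, normalize_text
from .model import MdrError, OdmElement, ResourceKind
from .store import AggregateRecord, MetadataStore

_TOKEN = re.compile(r"[0-9a-z]+")

FIELD_WEIGHTS = {"question": 2.0, "name": 1.0, "other": 0.5}
EXACT_QUESTION_BONUS = 2.0


class QueryError(MdrError):
    """Empty or untokenizable query."""


def tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text.lower())


def record_fields(element: OdmElement) -> dict[str, str]:
    """Searchable text fields of a record.

    ``question`` is the English question; ``name`` the Name attribute;
    ``other`` pools description, code-list item decodes and alias names.
    """
    question = english_question(element) or ""
    name = element.attributes.get("Name", "")
    other_parts: list[str] = []
    for texts in element.translated_texts.get("Description", {}).values():
        other_parts.append(texts)
    for node in element.walk():
        if node.kind is ResourceKind.CODE_LIST_ITEM:
            other_parts.extend(node.translated_texts.get("Decode", {}).values())
    other_parts.extend(name_ for _ctx, name_ in element.aliases)
    return {"question": question, "name": name, "other": " ".join(other_parts)}


@dataclass
class SearchHit:
    key: CanonicalKey
    kind: ResourceKind
    match_score: float
    occurrences: int
    combined_score: float
    matched_fields: list[str] = field(default_factory=list)


@dataclass
class SearchResult:
    hits: list[SearchHit]
    total_matches: int  # count before truncation ("total results")


class SearchIndex:
    """Deterministic inverted index over the records of a store."""

    def __init__(self, store: MetadataStore) -> None:
        self.store = store
        # kind -> token -> set of digests; kind -> digest -> record
        self._postings: dict[ResourceKind, dict[str, set[str]]] = {}
        self._records: dict[ResourceKind, dict[str, AggregateRecord]] = {}
        self._fields: dict[str, dict[str, str]] = {}
        for record in store.iter_records():
            kind = record.element.kind
            fields = record_fields(record.element)
            self._fields[record.key.digest] = fields
            self._records.setdefault(kind, {})[record.key.digest] = record
            postings = self._postings.setdefault(kind, {})
            for field_name, text in fields.items():
                for token in set(tokenize(text)):
                    postings.setdefault(token, set()).add(record.key.digest)

    def unique_count(self, kind: ResourceKind) -> int:
        return len(self._records.get(kind, {}))

    def document_frequency(self, kind: ResourceKind, token: str) -> int:
        return len(self._postings.get(kind, {}).get(token, ()))

    def idf(self, kind: ResourceKind, token: str) -> float:
        df = self.document_frequency(kind, token)
        if df == 0:
            return 0.0
        return math.log(1.0 + self.unique_count(kind) / df)

    def _score(
        self, query_tokens: list[str], query_norm: str, kind: ResourceKind,
        record: AggregateRecord,
    ) -> tuple[float, list[str]]:
        fields = self._fields[record.key.digest]
        token_sets = {name: set(tokenize(text)) for name, text in fields.items()}
        score = 0.0
        matched: set[str] = set()
        for token in dict.fromkeys(query_tokens):  # unique, query order
            best = 0.0
            best_field = None
            for field_name in ("question", "name", "other"):
                if token in token_sets[field_name]:
                    weight = FIELD_WEIGHTS[field_name]
                    if weight > best:
                        best = weight
                        best_field = field_name
            if best_field is not None:
                score += self.idf(kind, token) * best
                matched.add(best_field)
        if score > 0 and query_norm and normalize_text(fields["question"]).lower() == query_norm:
            score *= EXACT_QUESTION_BONUS
        return score, sorted(matched)

    def match_score(self, query: str, record: AggregateRecord) -> float:
        """Text-match component of the score for one record."""
        tokens = tokenize(query)
        if not tokens:
            raise QueryError("query is empty after tokenization")
        score, _ = self._score(tokens, normalize_text(query).lower(),
                               record.element.kind, record)
        return score

    def search(
        self, query: str, kind: ResourceKind = ResourceKind.ITEM, limit: int = 20
    ) -> SearchResult:
        """Ranked hits for ``query`` among records of ``kind``.

        Hits carry ``match_score > 0`` and are sorted by combined score
        descending, ties broken by (occurrences desc, key asc);
        ``total_matches`` counts all matches before truncation.
        """
        if limit < 1:
            raise ValueError("limit must be >= 1")
        tokens = tokenize(query)
        if not tokens:
            raise QueryError("query is empty after tokenization")
        query_norm = normalize_text(query).lower()
        postings = self._postings.get(kind, {})
        candidates: set[str] = set()
        for token in tokens:
            candidates |= postings.get(token, set())
        hits: list[SearchHit] = []
        for digest in candidates:
            record = self._records[kind][digest]
            score, matched = self._score(tokens, query_norm, kind, record)
            if score <= 0:
                continue
            hits.append(
                SearchHit(
                    key=record.key,
                    kind=kind,
                    match_score=score,
                    occurrences=record.occurrences,
                    combined_score=combined_score(score, record.occurrences),
                    matched_fields=matched,
                )
            )
        hits.sort(key=lambda h: (-h.combined_score, -h.occurrences, h.key.digest))
        return SearchResult(hits=hits[:limit], total_matches=len(hits))


def combined_score(match_score: float, occurrences: int) -> float:
    """The match/frequency tradeoff: ``match * (1 + ln(occurrences))``."""
    if occurrences < 1:
        raise ValueError("occurrences must be >= 1")
    return match_score * (1.0 + math.log(occurrences))


def build_index(store: MetadataStore) -> SearchIndex:
    """Build the inverted index for a store (rebuildable deterministically)."""
    return SearchIndex(store)
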