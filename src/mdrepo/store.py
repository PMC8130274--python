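"""Content-addressed store of aggregated metadata definitions.

Every atomic resource of every ingested document lands here exactly once
per *unique definition*: equivalent elements (equal canonical key) are
merged into a single :class:`AggregateRecord` whose occurrence count and
provenance list track every original appearance.  The occurrence counts
drive the frequency-based ("bottom-up") scoring of the search layer.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

from .canonical import CanonicalKey, canonical_key
from .model import IntegrityError, MdrError, OdmElement, ResourceKind, SourceDocument
from .odm import decompose

Path_t = tuple[tuple[ResourceKind, str], ...]


class DuplicateDocumentError(MdrError):
    """The document_id was ingested before; re-ingest is a no-op."""


class NotFoundError(MdrError):
    """No record with the requested key."""


@dataclass
class AggregateRecord:
    """One unique definition with its usage history."""

    key: CanonicalKey
    element: OdmElement  # representative: first-ingested copy
    occurrences: int
    provenance: list[tuple[str, Path_t]] = field(default_factory=list)


@dataclass
class IngestReport:
    document_id: str
    elements_seen: dict[ResourceKind, int]
    new_uniques: dict[ResourceKind, int]
    merged_into_existing: dict[ResourceKind, int]


@dataclass
class KindStats:
    total: int
    unique: int

    @property
    def reuse(self) -> float | None:
        """Average number of equivalent definitions; undefined when empty."""
        return self.total / self.unique if self.unique else None


@dataclass
class CorpusStats:
    per_kind: dict[ResourceKind, KindStats]

    @property
    def total(self) -> int:
        return sum(s.total for s in self.per_kind.values())

    @property
    def unique(self) -> int:
        return sum(s.unique for s in self.per_kind.values())

    @property
    def reuse(self) -> float | None:
        return self.total / self.unique if self.unique else None

    def as_rows(self) -> list[dict]:
        rows = []
        for kind in ResourceKind:
            stats = self.per_kind.get(kind)
            if stats is None:
                continue
            rows.append(
                {"kind": kind.value, "total": stats.total, "unique": stats.unique,
                 "reuse": stats.reuse}
            )
        rows.append({"kind": "Total", "total": self.total, "unique": self.unique,
                     "reuse": self.reuse})
        return rows


class MetadataStore:
    """In-memory aggregation store keyed by canonical digest.

    Parameters
    ----------
    ignore_oids
        Exclude OIDs from the equivalence key (for corpora with
        machine-generated OIDs); the default keeps them, reading strict
        equivalence as agreement in *every* property.
    """

    def __init__(self, *, ignore_oids: bool = False) -> None:
        self.ignore_oids = ignore_oids
        self._records: dict[CanonicalKey, AggregateRecord] = {}
        self._documents: set[str] = set()

    # -- ingest -------------------------------------------------------------

    def ingest_document(self, document: SourceDocument) -> IngestReport:
        """Aggregate every atomic resource of ``document`` into the store.

        Atomic: the store is unchanged if decomposition or key
        computation fails, and re-ingesting a known document_id raises
        :class:`DuplicateDocumentError` without side effects.
        """
        if document.document_id in self._documents:
            raise DuplicateDocumentError(
                f"document {document.document_id!r} was already ingested"
            )
        # compute everything up front so errors cannot leave partial state
        staged: list[tuple[CanonicalKey, OdmElement, Path_t]] = []
        for element, path in decompose(document):
            key = canonical_key(element, ignore_oids=self.ignore_oids)
            staged.append((key, element, path))

        seen: dict[ResourceKind, int] = {}
        new: dict[ResourceKind, int] = {}
        merged: dict[ResourceKind, int] = {}
        for key, element, path in staged:
            kind = element.kind
            seen[kind] = seen.get(kind, 0) + 1
            record = self._records.get(key)
            if record is None:
                self._records[key] = AggregateRecord(
                    key=key,
                    element=copy.deepcopy(element),
                    occurrences=1,
                    provenance=[(document.document_id, path)],
                )
                new[kind] = new.get(kind, 0) + 1
            else:
                record.occurrences += 1
                record.provenance.append((document.document_id, path))
                merged[kind] = merged.get(kind, 0) + 1
        self._documents.add(document.document_id)
        return IngestReport(
            document_id=document.document_id,
            elements_seen=seen,
            new_uniques=new,
            merged_into_existing=merged,
        )

    # -- queries ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    @property
    def document_ids(self) -> frozenset[str]:
        return frozenset(self._documents)

    def get_record(self, key: CanonicalKey | str) -> AggregateRecord:
        """Look up one unique definition; the copy is detached from the store."""
        if isinstance(key, str):
            key = CanonicalKey(key)
        record = self._records.get(key)
        if record is None:
            raise NotFoundError(f"no record with key {key.digest}")
        return AggregateRecord(
            key=record.key,
            element=copy.deepcopy(record.element),
            occurrences=record.occurrences,
            provenance=list(record.provenance),
        )

    def iter_records(self):
        return iter(self._records.values())

    def list_records(
        self, kind: ResourceKind, min_occurrences: int = 1
    ) -> list[AggregateRecord]:
        """Records of ``kind`` with occurrences >= threshold.

        Deterministic order: occurrences descending, then key ascending.
        """
        records = [
            r for r in self._records.values()
            if r.element.kind is kind and r.occurrences >= min_occurrences
        ]
        records.sort(key=lambda r: (-r.occurrences, r.key.digest))
        return records

    def corpus_statistics(self) -> CorpusStats:
        per_kind: dict[ResourceKind, KindStats] = {}
        for record in self._records.values():
            kind = record.element.kind
            stats = per_kind.setdefault(kind, KindStats(total=0, unique=0))
            stats.total += record.occurrences
            stats.unique += 1
        return CorpusStats(per_kind=per_kind)

    # -- semantic-code export ----------------------------------------------

    def export_semantic_codes(
        self,
        identifiers: list[str],
        *,
        by: str = "oid",
        minutes_per_item: float = 1.0,
    ) -> dict:
        """Alias (semantic-code) pairs for the requested items.

        Mirrors a dictionary-synchronization workflow: items already
        annotated with semantic codes (e.g. UMLS aliases) are exported so
        another institution's data dictionary can absorb the coding.  The
        report estimates the expert time saved at ``minutes_per_item``
        per coded item (experts need about one minute to code an item),
        expressed in hours.

        Parameters
        ----------
        identifiers
            Item OIDs (``by="oid"``) or canonical-key digests
            (``by="key"``).
        """
        if by not in ("oid", "key"):
            raise ValueError("by must be 'oid' or 'key'")
        codes: dict[str, list[tuple[str, str]]] = {}
        skipped: list[str] = []
        by_oid: dict[str, AggregateRecord] = {}
        if by == "oid":
            for record in self.list_records(ResourceKind.ITEM):
                # highest-occurrence record wins an OID collision
                by_oid.setdefault(record.element.oid, record)
        for identifier in identifiers:
            if by == "key":
                record = self._records.get(CanonicalKey(identifier))
                if record is None or record.element.kind is not ResourceKind.ITEM:
                    skipped.append(identifier)
                    continue
            else:
                record = by_oid.get(identifier)
                if record is None:
                    skipped.append(identifier)
                    continue
            codes[identifier] = list(record.element.aliases)
        n_coded = sum(1 for pairs in codes.values() if pairs)
        hours = n_coded * minutes_per_item / 60.0
        return {
            "codes": codes,
            "skipped": skipped,
            "items_resolved": len(codes),
            "items_with_codes": n_coded,
            "time_saved_hours": hours,
            "time_saved_hours_rounded": round(hours),
        }

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist to JSON (digest-keyed index); see :meth:`load`."""
        from .api import element_to_json  # lossless element codec

        payload = {
            "ignore_oids": self.ignore_oids,
            "documents": sorted(self._documents),
            "records": [
                {
                    "key": r.key.digest,
                    "occurrences": r.occurrences,
                    "provenance": [
                        [doc, [[k.value, oid] for k, oid in path]]
                        for doc, path in r.provenance
                    ],
                    "element": element_to_json(r.element),
                }
                for r in self._records.values()
            ],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "MetadataStore":
        from .api import element_from_json

        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        store = cls(ignore_oids=payload["ignore_oids"])
        store._documents = set(payload["documents"])
        for entry in payload["records"]:
            element = element_from_json(entry["element"])
            key = CanonicalKey(entry["key"])
            expected = canonical_key(element, ignore_oids=store.ignore_oids)
            if expected != key:
                raise IntegrityError(f"stored record {key.digest} fails re-keying")
            store._records[key] = AggregateRecord(
                key=key,
                element=element,
                occurrences=entry["occurrences"],
                provenance=[
                    (doc, tuple((ResourceKind(k), oid) for k, oid in path))
                    for doc, path in entry["provenance"]
                ],
            )
        return store
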