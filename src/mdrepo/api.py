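"""Resource-oriented read-only HTTP interface to the store.

Each resource kind gets a collection endpoint (``/items``, ``/forms``,
...) answering GET requests: with a ``query`` parameter it returns
ranked search hits, without one a paged listing by occurrences.  Single
resources live at ``/<collection>/<digest>`` where the id is the
definition's canonical key — stable, unique, and recomputable from the
JSON body: the resource representation is lossless, so decoding it and
re-keying the element reproduces its id.

Access is guarded by an API key (header ``X-API-Key``, query-parameter
``api_key`` as fallback).  There are no write endpoints; content enters
the store through batch ingest only.

The application is a plain WSGI callable (servable with the stdlib
``wsgiref`` server), so it can be exercised in-process without sockets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from urllib.parse import parse_qs

from .canonical import CanonicalKey, canonical_key
from .model import OdmElement, RangeCheck, ResourceKind
from .search import SearchIndex
from .store import MetadataStore, NotFoundError

COLLECTIONS: dict[str, ResourceKind] = {
    "studies": ResourceKind.STUDY,
    "protocols": ResourceKind.PROTOCOL,
    "studyevents": ResourceKind.STUDY_EVENT,
    "forms": ResourceKind.FORM,
    "itemgroups": ResourceKind.ITEM_GROUP,
    "items": ResourceKind.ITEM,
    "codelists": ResourceKind.CODE_LIST,
    "codelistitems": ResourceKind.CODE_LIST_ITEM,
    "measurementunits": ResourceKind.MEASUREMENT_UNIT,
}


@dataclass
class ApiConfig:
    api_keys: set[str] = field(default_factory=set)
    host: str = "127.0.0.1"
    port: int = 8080
    max_page_size: int = 100

    @property
    def auth_enabled(self) -> bool:
        return bool(self.api_keys)


# -- element <-> JSON codec (lossless for equivalence) ----------------------


def element_to_json(element: OdmElement) -> dict:
    return {
        "kind": element.kind.value,
        "oid": element.oid,
        "attributes": dict(element.attributes),
        "translated_texts": {r: dict(t) for r, t in element.translated_texts.items()},
        "aliases": [[c, n] for c, n in element.aliases],
        "range_checks": [
            {
                "comparator": rc.comparator,
                "soft_hard": rc.soft_hard,
                "check_values": list(rc.check_values),
                "measurement_unit_oid": rc.measurement_unit_oid,
            }
            for rc in element.range_checks
        ],
        "children": [element_to_json(child) for child in element.children],
    }


def element_from_json(data: dict) -> OdmElement:
    return OdmElement(
        kind=ResourceKind(data["kind"]),
        oid=data["oid"],
        attributes=dict(data.get("attributes", {})),
        translated_texts={r: dict(t) for r, t in data.get("translated_texts", {}).items()},
        aliases=[(c, n) for c, n in data.get("aliases", [])],
        range_checks=[
            RangeCheck(
                comparator=rc["comparator"],
                soft_hard=rc["soft_hard"],
                check_values=tuple(rc["check_values"]),
                measurement_unit_oid=rc.get("measurement_unit_oid"),
            )
            for rc in data.get("range_checks", [])
        ],
        children=[element_from_json(child) for child in data.get("children", [])],
    )


def _summary(element: OdmElement) -> dict:
    from .canonical import english_question

    return {
        "kind": element.kind.value,
        "oid": element.oid,
        "name": element.attributes.get("Name", ""),
        "question": english_question(element),
        "n_children": len(element.children),
    }


def create_app(store: MetadataStore, index: SearchIndex, config: ApiConfig):
    """Build the WSGI application over a store and its search index."""

    def respond(start_response, status: str, payload) -> list[bytes]:
        body = json.dumps(payload).encode("utf-8") if payload is not None else b""
        start_response(status, [("Content-Type", "application/json"),
                                ("Content-Length", str(len(body)))])
        return [body]

    def app(environ, start_response):
        if environ.get("REQUEST_METHOD", "GET") != "GET":
            return respond(start_response, "405 Method Not Allowed",
                           {"error": "read-only API: GET only"})
        params = {k: v[0] for k, v in parse_qs(environ.get("QUERY_STRING", "")).items()}
        if config.auth_enabled:
            supplied = environ.get("HTTP_X_API_KEY") or params.get("api_key")
            if supplied not in config.api_keys:
                return respond(start_response, "401 Unauthorized", None)

        path = [p for p in environ.get("PATH_INFO", "/").split("/") if p]
        if not path or path[0] not in COLLECTIONS:
            return respond(start_response, "404 Not Found", {"error": "unknown endpoint"})
        kind = COLLECTIONS[path[0]]

        if len(path) == 1:
            return collection(start_response, kind, params)
        if len(path) == 2:
            return resource(start_response, kind, path[1])
        return respond(start_response, "404 Not Found", {"error": "unknown endpoint"})

    def collection(start_response, kind: ResourceKind, params: dict):
        try:
            limit = int(params.get("limit", 20))
            offset = int(params.get("offset", 0))
        except ValueError:
            return respond(start_response, "400 Bad Request",
                           {"error": "limit and offset must be integers"})
        if limit < 1 or offset < 0:
            return respond(start_response, "400 Bad Request",
                           {"error": "limit must be >= 1 and offset >= 0"})
        limit = min(limit, config.max_page_size)
        query = params.get("query")
        if query is not None:
            if not query.strip():
                return respond(start_response, "400 Bad Request",
                               {"error": "query must be non-empty"})
            result = index.search(query, kind=kind, limit=offset + limit)
            hits = []
            for hit in result.hits[offset:]:
                record = store.get_record(hit.key)
                hits.append(
                    {
                        "id": hit.key.digest,
                        "kind": hit.kind.value,
                        "match_score": hit.match_score,
                        "occurrences": hit.occurrences,
                        "combined_score": hit.combined_score,
                        "matched_fields": hit.matched_fields,
                        "resource": _summary(record.element),
                    }
                )
            return respond(start_response, "200 OK",
                           {"hits": hits, "total_matches": result.total_matches})
        records = store.list_records(kind)
        page = records[offset:offset + limit]
        return respond(
            start_response, "200 OK",
            {
                "resources": [
                    {"id": r.key.digest, "occurrences": r.occurrences,
                     "resource": _summary(r.element)}
                    for r in page
                ],
                "total": len(records),
                "offset": offset,
                "limit": limit,
            },
        )

    def resource(start_response, kind: ResourceKind, digest: str):
        try:
            record = store.get_record(CanonicalKey(digest))
        except NotFoundError:
            return respond(start_response, "404 Not Found", {"error": "unknown id"})
        if record.element.kind is not kind:
            return respond(start_response, "404 Not Found",
                           {"error": "id does not belong to this collection"})
        return respond(
            start_response, "200 OK",
            {
                "id": record.key.digest,
                "kind": record.element.kind.value,
                "occurrences": record.occurrences,
                "provenance": [
                    {"document_id": doc,
                     "path": [[k.value, oid] for k, oid in path]}
                    for doc, path in record.provenance
                ],
                "element": element_to_json(record.element),
            },
        )

    return app


def rekey_resource_json(payload: dict, *, ignore_oids: bool = False) -> CanonicalKey:
    """Recompute the canonical key from a single-resource JSON body."""
    return canonical_key(element_from_json(payload["element"]), ignore_oids=ignore_oids)


def serve(store: MetadataStore, index: SearchIndex, config: ApiConfig) -> None:
    """Run the API with the stdlib WSGI server (blocking)."""
    from wsgiref.simple_server import make_server

    app = create_app(store, index, config)
    with make_server(config.host, config.port, app) as httpd:
        httpd.serve_forever()
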