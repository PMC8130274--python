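"""Aggregation, occurrence accounting, statistics and code export."""

import random

import pytest

from mdrepo import (
    DuplicateDocumentError,
    MetadataStore,
    NotFoundError,
    ResourceKind,
    canonical_key,
)
from mdrepo.canonical import CanonicalKey

from conftest import brute_force_counts, make_document, make_item


class TestAggregation:
    def test_shared_item_and_codelist_aggregate(self, aggregation_scenario):
        doc1, doc2 = aggregation_scenario
        store = MetadataStore()
        store.ingest_document(doc1)
        store.ingest_document(doc2)
        items = store.list_records(ResourceKind.ITEM)
        assert len(items) == 1 and items[0].occurrences == 2
        codelists = store.list_records(ResourceKind.CODE_LIST)
        assert len(codelists) == 1 and codelists[0].occurrences == 2
        forms = store.list_records(ResourceKind.FORM)
        assert sorted(f.occurrences for f in forms) == [1, 1]
        stats = store.corpus_statistics()
        item_stats = stats.per_kind[ResourceKind.ITEM]
        assert (item_stats.total, item_stats.unique, item_stats.reuse) == (2, 1, 2.0)
        form_stats = stats.per_kind[ResourceKind.FORM]
        assert (form_stats.total, form_stats.unique, form_stats.reuse) == (2, 2, 1.0)

    def test_provenance_tracks_every_occurrence(self, aggregation_scenario):
        doc1, doc2 = aggregation_scenario
        store = MetadataStore()
        store.ingest_document(doc1)
        store.ingest_document(doc2)
        (item,) = store.list_records(ResourceKind.ITEM)
        docs = [doc for doc, _path in item.provenance]
        assert docs == ["model-1", "model-2"]
        assert item.occurrences == len(item.provenance)

    def test_all_distinct_document_yields_all_singletons(self):
        doc = make_document("d1", [make_item("I.1", "Pulse"), make_item("I.2", "Weight")])
        store = MetadataStore()
        report = store.ingest_document(doc)
        assert report.elements_seen == report.new_uniques
        assert all(r.occurrences == 1 for r in store.iter_records())

    def test_duplicate_document_id_is_atomic_noop(self, aggregation_scenario):
        doc1, _ = aggregation_scenario
        store = MetadataStore()
        store.ingest_document(doc1)
        before = {r.key: r.occurrences for r in store.iter_records()}
        with pytest.raises(DuplicateDocumentError):
            store.ingest_document(doc1)
        after = {r.key: r.occurrences for r in store.iter_records()}
        assert before == after

    def test_matches_brute_force_dedup_oracle(self, small_corpus):
        documents, _ = small_corpus
        store = MetadataStore()
        for doc in documents:
            store.ingest_document(doc)
        oracle = brute_force_counts(documents)
        assert len(store) == len(oracle)
        from mdrepo import canonical_serialize

        for record in store.iter_records():
            assert oracle[canonical_serialize(record.element)] == record.occurrences

    def test_ingest_order_independence(self, small_corpus):
        documents, _ = small_corpus
        subset = documents[:15]
        baseline = MetadataStore()
        for doc in subset:
            baseline.ingest_document(doc)
        shuffled = list(subset)
        random.Random(3).shuffle(shuffled)
        permuted = MetadataStore()
        for doc in shuffled:
            permuted.ingest_document(doc)
        base = {r.key: (r.occurrences, frozenset(r.provenance)) for r in baseline.iter_records()}
        perm = {r.key: (r.occurrences, frozenset(r.provenance)) for r in permuted.iter_records()}
        assert base == perm

    def test_conservation_after_every_ingest(self, small_corpus):
        documents, _ = small_corpus
        store = MetadataStore()
        ingested_per_kind: dict[ResourceKind, int] = {}
        for doc in documents[:20]:
            report = store.ingest_document(doc)
            for kind, n in report.elements_seen.items():
                ingested_per_kind[kind] = ingested_per_kind.get(kind, 0) + n
            stats = store.corpus_statistics()
            for kind, n in ingested_per_kind.items():
                assert stats.per_kind[kind].total == n
                assert stats.per_kind[kind].unique <= stats.per_kind[kind].total
                assert stats.per_kind[kind].reuse >= 1.0


class TestLookup:
    def test_get_record_returns_detached_copy(self, ingested):
        store, _, _ = ingested
        record = store.list_records(ResourceKind.ITEM)[0]
        fetched = store.get_record(record.key)
        fetched.element.attributes["Name"] = "tampered"
        fetched.occurrences = 999
        again = store.get_record(record.key)
        assert again.element.attributes.get("Name") != "tampered"
        assert again.occurrences == record.occurrences

    def test_unknown_key_not_found(self):
        store = MetadataStore()
        with pytest.raises(NotFoundError):
            store.get_record(CanonicalKey("0" * 64))

    def test_every_listed_record_is_retrievable(self, ingested):
        store, _, _ = ingested
        for kind in ResourceKind:
            for record in store.list_records(kind):
                assert store.get_record(record.key).key == record.key

    def test_list_records_ordering_and_threshold(self, ingested):
        store, _, _ = ingested
        records = store.list_records(ResourceKind.ITEM)
        pairs = [(-r.occurrences, r.key.digest) for r in records]
        assert pairs == sorted(pairs)
        max_occ = records[0].occurrences
        assert store.list_records(ResourceKind.ITEM, min_occurrences=max_occ + 1) == []
        filtered = store.list_records(ResourceKind.ITEM, min_occurrences=2)
        assert all(r.occurrences >= 2 for r in filtered)

    def test_unique_counts_match_statistics(self, ingested):
        store, _, _ = ingested
        stats = store.corpus_statistics()
        for kind, kind_stats in stats.per_kind.items():
            assert len(store.list_records(kind)) == kind_stats.unique


class TestSemanticCodeExport:
    def test_exported_codes_match_generator_ledger(self, ingested):
        store, _, ledger = ingested
        planted = [d for d in ledger.definitions if d.occurrences > 0]
        report = store.export_semantic_codes([d.key.digest for d in planted], by="key")
        assert report["skipped"] == []
        for definition in planted:
            assert report["codes"][definition.key.digest] == definition.aliases

    def test_time_saved_estimate_arithmetic(self):
        store = MetadataStore()
        items = [
            make_item(f"I.{i}", f"question {i}", aliases=[("UMLS", f"C{i:07d}")])
            for i in range(12)
        ]
        store.ingest_document(make_document("d", items))
        report = store.export_semantic_codes([f"I.{i}" for i in range(12)], by="oid")
        assert report["items_with_codes"] == 12
        assert report["time_saved_hours"] == pytest.approx(12 / 60)

    def test_item_without_aliases_maps_to_empty_list(self):
        store = MetadataStore()
        store.ingest_document(make_document("d", [make_item("I.1", "Pulse")]))
        report = store.export_semantic_codes(["I.1"], by="oid")
        assert report["codes"]["I.1"] == []
        assert report["items_with_codes"] == 0

    def test_unresolvable_identifiers_are_skipped_not_fatal(self):
        store = MetadataStore()
        store.ingest_document(make_document("d", [make_item("I.1", "Pulse")]))
        report = store.export_semantic_codes(["I.1", "I.MISSING"], by="oid")
        assert report["skipped"] == ["I.MISSING"]
        assert "I.1" in report["codes"]


class TestPersistence:
    def test_save_load_round_trip(self, ingested, tmp_path):
        store, _, _ = ingested
        path = tmp_path / "store.json"
        store.save(path)
        loaded = MetadataStore.load(path)
        assert loaded.document_ids == store.document_ids
        original = {r.key: r.occurrences for r in store.iter_records()}
        restored = {r.key: r.occurrences for r in loaded.iter_records()}
        assert original == restored
        for record in loaded.iter_records():
            assert canonical_key(record.element) == record.key
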