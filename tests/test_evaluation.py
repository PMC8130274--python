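"""Bottom-up standardization statistics: curves, top-k ratios, reports."""

import random

import pytest

from mdrepo import (
    ConceptQuery,
    MetadataStore,
    build_index,
    cumulative_curve,
    evaluate_concept,
    group_summary,
    load_concept_queries,
    render_report,
)
from mdrepo.evaluation import InsufficientReportsError, REPORT_COLUMNS, load_report_csv

from conftest import make_document, make_item


def store_with_occurrences(spec: list[tuple[str, str, int]]) -> MetadataStore:
    store = MetadataStore()
    doc_items: dict[int, list] = {}
    for oid, question, occ in spec:
        for d in range(occ):
            doc_items.setdefault(d, []).append(make_item(oid, question))
    for d, items in sorted(doc_items.items()):
        store.ingest_document(make_document(f"doc-{d}", items, form_oid=f"F.{d}"))
    return store


class TestCumulativeCurve:
    def test_direct_counts(self):
        curve = cumulative_curve([3, 2, 2, 1])
        assert (curve(1), curve(2), curve(3)) == (4, 3, 1)
        assert curve(4) == 0

    def test_empty_multiset(self):
        assert cumulative_curve([]).points == {}

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            cumulative_curve([2, 0, 1])

    def test_matches_sort_and_scan_oracle_and_monotone(self):
        rng = random.Random(5)
        for _ in range(20):
            occs = [rng.randint(1, 30) for _ in range(rng.randint(1, 80))]
            curve = cumulative_curve(occs)
            ordered = sorted(occs, reverse=True)
            for t in range(1, max(occs) + 1):
                # sort-and-scan: position of the last value >= t
                expected = sum(1 for v in ordered if v >= t)
                assert curve(t) == expected
            values = [curve(t) for t in range(1, max(occs) + 1)]
            assert values == sorted(values, reverse=True)
            assert curve(1) == len(occs)


class TestTopKRatio:
    def test_three_or_fewer_matches_give_ratio_one(self):
        store = store_with_occurrences([
            ("I.1", "Dysarthria", 4), ("I.2", "Dysarthria severity", 2)])
        index = build_index(store)
        report = evaluate_concept(index, store, ConceptQuery("g", "Dysarthria"), k=3)
        assert report.total_results == 2
        assert report.topk_ratio == pytest.approx(1.0)

    def test_forced_arithmetic_example(self):
        # ranked occurrence list [10, 5, 3, 1, 1] -> top-3 ratio 18/20
        store = store_with_occurrences([
            ("I.1", "Pulse", 10),
            ("I.2", "Pulse rate", 5),
            ("I.3", "Pulse measured", 3),
            ("I.4", "Pulse baseline", 1),
            ("I.5", "Pulse maximum", 1),
        ])
        index = build_index(store)
        report = evaluate_concept(index, store, ConceptQuery("g", "Pulse"), k=3)
        assert sorted(report.occurrences, reverse=True) == [10, 5, 3, 1, 1]
        assert report.topk_ratio == pytest.approx(18 / 20)

    def test_ratio_equals_full_hit_list_recomputation(self, ingested):
        store, index, _ = ingested
        for query in ("body height", "serum sodium", "blood glucose"):
            for mode in ("strict", "relaxed"):
                report = evaluate_concept(index, store, ConceptQuery("g", query), mode=mode)
                if report.topk_ratio is None:
                    continue
                expected = sum(report.occurrences[:3]) / sum(report.occurrences)
                assert report.topk_ratio == pytest.approx(expected)

    def test_ratio_non_decreasing_in_k_and_one_at_infinity(self, ingested):
        store, index, _ = ingested
        previous = 0.0
        for k in (1, 2, 3, 5, 10, 10_000):
            report = evaluate_concept(index, store, ConceptQuery("g", "body height"), k=k)
            assert report.topk_ratio >= previous - 1e-12
            previous = report.topk_ratio
        assert previous == pytest.approx(1.0)

    def test_zero_matches_flagged_not_raised(self, ingested):
        store, index, _ = ingested
        report = evaluate_concept(index, store, ConceptQuery("g", "zzzznope"), k=3)
        assert report.total_results == 0
        assert report.topk_ratio is None


class TestRelaxedMode:
    def test_casing_variants_merge_and_conserve_occurrences(self):
        store = store_with_occurrences([
            ("I.1", "Body height", 6),
            ("I.2", "body height", 3),
            ("I.3", "BODY HEIGHT", 1),
            ("I.4", "Body height - standing", 2),
        ])
        index = build_index(store)
        cq = ConceptQuery("g", "Body height")
        strict = evaluate_concept(index, store, cq, mode="strict")
        relaxed = evaluate_concept(index, store, cq, mode="relaxed")
        assert strict.total_results == 4
        assert relaxed.total_results == 2  # cluster + the reworded variant
        assert sum(relaxed.occurrences) == sum(strict.occurrences)
        top_question, top_occ = relaxed.top_k[0]
        assert top_occ == 10  # 6 + 3 + 1 merged by lowercase question
        assert top_question == "Body height"  # highest-occurrence member represents

    def test_relaxed_total_never_exceeds_strict(self, ingested):
        store, index, _ = ingested
        for query in ("body height", "serum", "pulse rate", "smoking status"):
            cq = ConceptQuery("g", query)
            strict = evaluate_concept(index, store, cq, mode="strict")
            relaxed = evaluate_concept(index, store, cq, mode="relaxed")
            assert relaxed.total_results <= strict.total_results
            assert relaxed.total_results_strict == strict.total_results


class TestGroupSummary:
    def test_closed_form_fixture(self):
        reports = [
            _report(ratio) for ratio in (0.1, 0.2, 0.3)
        ]
        mean, sd = group_summary(reports)
        assert mean == pytest.approx(20.00)
        assert sd == pytest.approx(10.00)

    def test_identical_ratios_zero_sd(self):
        mean, sd = group_summary([_report(0.25)] * 4)
        assert (mean, sd) == (pytest.approx(25.0), pytest.approx(0.0))

    def test_insufficient_defined_ratios_rejected(self):
        with pytest.raises(InsufficientReportsError):
            group_summary([_report(0.5), _report(None)])

    def test_matches_two_pass_variance_oracle(self):
        rng = random.Random(11)
        for _ in range(50):
            ratios = [rng.random() for _ in range(rng.randint(2, 12))]
            mean, sd = group_summary([_report(r) for r in ratios])
            n = len(ratios)
            m = sum(ratios) / n
            var = sum((x - m) ** 2 for x in ratios) / (n - 1)
            assert mean == pytest.approx(m * 100, abs=1e-12)
            assert sd == pytest.approx(var ** 0.5 * 100, abs=1e-10)


def _report(ratio):
    from mdrepo.evaluation import ConceptReport

    return ConceptReport(group_label="g", query="q", mode="strict",
                         total_results=5, total_results_strict=5,
                         top_k=[("q", 1)], topk_ratio=ratio)


class TestRenderReport:
    def test_bundled_query_fixture_has_24_queries_in_4_groups(self):
        queries = load_concept_queries()
        assert len(queries) == 24
        groups = list(dict.fromkeys(q.group_label for q in queries))
        assert len(groups) == 4
        assert all(sum(q.group_label == g for q in queries) == 6 for g in groups)
        assert ConceptQuery("CDASH vital signs", "Diastolic BP") in queries

    def test_csv_schema_and_round_trip(self, ingested, tmp_path):
        store, index, _ = ingested
        reports = [
            evaluate_concept(index, store, ConceptQuery("g", q), mode=m)
            for q in ("body height", "serum sodium")
            for m in ("strict", "relaxed")
        ]
        curves = {"body height": cumulative_curve(reports[0].occurrences)}
        written = render_report(reports, curves, tmp_path)
        csv_path = written[0]
        header = csv_path.read_text().splitlines()[0].split(",")
        assert header == REPORT_COLUMNS
        reloaded = load_report_csv(csv_path)
        by_key = {(r.query, r.mode): r for r in reloaded}
        for report in reports:
            back = by_key[(report.query, report.mode)]
            assert back.total_results == report.total_results
            assert back.top_k == report.top_k
            assert back.topk_ratio == pytest.approx(report.topk_ratio)

    def test_empty_report_list_yields_header_only(self, tmp_path):
        written = render_report([], None, tmp_path)
        lines = written[0].read_text().splitlines()
        assert lines == [",".join(REPORT_COLUMNS)]
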