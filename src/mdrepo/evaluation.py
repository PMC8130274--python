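"""Evaluation of bottom-up standardization.

For a set of concept queries this module measures how strongly the most
frequent definitions dominate: per query it reports the total number of
matching definitions, the top-k questions with their occurrence counts,
and the *top-k occurrence ratio* — summed occurrences of the top-k
ranked results over summed occurrences of all results.  Two equivalence
modes are supported:

``strict``
    Definitions are the store's aggregate records (agreement in every
    property).
``relaxed``
    Matching items are first merged by their lowercase English question
    text, summing occurrences; clusters are re-ranked by combined score
    using the summed count, represented by their highest-occurrence
    member.

Both modes restrict the evaluation to items with an English question.
Cumulative occurrence curves describe the long tail: curve(t) counts the
definitions occurring at least t times.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .canonical import english_question, relaxed_question_key
from .model import MdrError, ResourceKind
from .search import SearchHit, SearchIndex, combined_score
from .store import MetadataStore


@dataclass(frozen=True)
class ConceptQuery:
    group_label: str
    query: str

    def __post_init__(self) -> None:
        if not self.query.strip():
            raise ValueError("concept query must be non-empty")


def load_concept_queries(path: str | Path | None = None) -> list[ConceptQuery]:
    """The bundled 24 evaluation queries (or a custom group-tagged file)."""
    if path is None:
        text = (resources.files("mdrepo") / "data" / "concept_queries.txt").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    queries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        group, _, query = line.partition("\t")
        queries.append(ConceptQuery(group_label=group.strip(), query=query.strip()))
    return queries


@dataclass
class ConceptReport:
    group_label: str
    query: str
    mode: str  # strict | relaxed
    total_results: int
    total_results_strict: int  # pre-merge record count (== total_results when strict)
    top_k: list[tuple[str, int]]  # (question text, occurrences)
    topk_ratio: float | None  # undefined (None) when there are no matches
    occurrences: list[int] = field(default_factory=list)  # ranked, all matches


@dataclass
class CumulativeCurve:
    """curve(t) = number of definitions occurring at least t times."""

    points: dict[int, int]

    def __call__(self, threshold: int) -> int:
        return self.points.get(threshold, 0)


def cumulative_curve(occurrences: list[int]) -> CumulativeCurve:
    """Cumulative occurrence counts for a multiset of positive counts.

    curve(1) equals the number of distinct definitions; the curve is
    non-increasing in the threshold.
    """
    if any(occ < 1 for occ in occurrences):
        raise ValueError("occurrence counts must be positive")
    if not occurrences:
        return CumulativeCurve(points={})
    max_occ = max(occurrences)
    points = {}
    for t in range(1, max_occ + 1):
        points[t] = sum(1 for occ in occurrences if occ >= t)
    return CumulativeCurve(points=points)


def _matching_items(index: SearchIndex, query: str):
    """All item hits (no truncation), restricted to English-question items."""
    result = index.search(query, kind=ResourceKind.ITEM, limit=max(1, len(index.store)))
    hits = []
    for hit in result.hits:
        record = index.store.get_record(hit.key)
        if english_question(record.element) is None:
            continue
        hits.append((hit, record))
    return hits


def evaluate_concept(
    index: SearchIndex,
    store: MetadataStore,
    cq: ConceptQuery,
    k: int = 3,
    mode: str = "strict",
) -> ConceptReport:
    """Per-query standardization report.

    ``topk_ratio`` is the summed occurrences of the first ``k`` ranked
    results over the summed occurrences of every match; with at most
    ``k`` matches it is 1.0, with zero matches it is undefined (None).
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    matches = _matching_items(index, cq.query)
    n_strict = len(matches)

    if mode == "strict":
        ranked: list[tuple[str, int, float]] = [
            (english_question(record.element) or "", hit.occurrences, hit.combined_score)
            for hit, record in matches
        ]
    else:
        clusters: dict[str, list[tuple[SearchHit, object]]] = {}
        for hit, record in matches:
            rk = relaxed_question_key(record.element)
            if rk is None:
                continue
            clusters.setdefault(rk, []).append((hit, record))
        ranked = []
        for members in clusters.values():
            total_occ = sum(hit.occurrences for hit, _rec in members)
            # representative: highest-occurrence member, key ascending on ties
            rep_hit, rep_record = sorted(
                members, key=lambda m: (-m[0].occurrences, m[0].key.digest)
            )[0]
            question = english_question(rep_record.element) or ""
            score = combined_score(rep_hit.match_score, total_occ)
            ranked.append((question, total_occ, score))
        ranked.sort(key=lambda r: (-r[2], -r[1], r[0]))

    occ_all = [occ for _q, occ, _s in ranked]
    total = len(ranked)
    if total == 0:
        return ConceptReport(
            group_label=cq.group_label, query=cq.query, mode=mode,
            total_results=0, total_results_strict=n_strict,
            top_k=[], topk_ratio=None, occurrences=[],
        )
    top = ranked[:k]
    ratio = sum(occ for _q, occ, _s in top) / sum(occ_all)
    return ConceptReport(
        group_label=cq.group_label, query=cq.query, mode=mode,
        total_results=total, total_results_strict=n_strict,
        top_k=[(q, occ) for q, occ, _s in top], topk_ratio=ratio,
        occurrences=occ_all,
    )


class InsufficientReportsError(MdrError):
    pass


def group_summary(reports: list[ConceptReport]) -> tuple[float, float]:
    """Mean and sample standard deviation of the top-k ratios, in percent.

    Uses the n-1 denominator; requires at least two defined ratios.
    """
    ratios = [r.topk_ratio for r in reports if r.topk_ratio is not None]
    if len(ratios) < 2:
        raise InsufficientReportsError("need >= 2 reports with defined ratios")
    n = len(ratios)
    mean = sum(ratios) / n
    var = sum((x - mean) ** 2 for x in ratios) / (n - 1)
    return mean * 100.0, math.sqrt(var) * 100.0


REPORT_COLUMNS = ["group", "query", "mode", "total", "rank", "question",
                  "occurrences", "ratio"]


def render_report(
    reports: list[ConceptReport],
    curves: dict[str, CumulativeCurve] | None,
    output_dir: str | Path,
) -> list[Path]:
    """Write the tabular report (CSV) and per-group cumulative plots.

    The CSV has one row per (report, top-k rank); ``total`` and ``ratio``
    repeat per report so the file reconstructs the reports losslessly.
    Plots show one panel per concept group with one curve per query.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "concept_reports.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for report in reports:
            ratio = "" if report.topk_ratio is None else f"{report.topk_ratio:.10g}"
            if not report.top_k:
                writer.writerow([report.group_label, report.query, report.mode,
                                 report.total_results, "", "", "", ratio])
            for rank, (question, occ) in enumerate(report.top_k, start=1):
                writer.writerow([report.group_label, report.query, report.mode,
                                 report.total_results, rank, question, occ, ratio])
    written.append(csv_path)

    if curves:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        groups: dict[str, list[str]] = {}
        label_of: dict[str, str] = {}
        for report in reports:
            if report.query in curves and report.query not in label_of:
                groups.setdefault(report.group_label, []).append(report.query)
                label_of[report.query] = report.group_label
        n_groups = max(1, len(groups))
        fig, axes = plt.subplots(1, n_groups, figsize=(4 * n_groups, 3.2), squeeze=False)
        for ax, (group, queries) in zip(axes[0], groups.items()):
            for query in queries:
                curve = curves[query]
                if not curve.points:
                    continue
                ts = sorted(curve.points)
                ax.plot(ts, [curve.points[t] for t in ts], label=query)
            ax.set_yscale("log")
            ax.set_title(group, fontsize=8)
            ax.set_xlabel("occurrence threshold t")
            ax.set_ylabel("definitions with occ >= t")
            ax.legend(fontsize=5)
        fig.tight_layout()
        plot_path = out / "cumulative_occurrences.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        written.append(plot_path)
    return written


def load_report_csv(path: str | Path) -> list[ConceptReport]:
    """Rebuild ConceptReports (minus full occurrence lists) from the CSV."""
    rows_by_key: dict[tuple[str, str, str], list[dict]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rows_by_key.setdefault((row["group"], row["query"], row["mode"]), []).append(row)
    reports = []
    for (group, query, mode), rows in rows_by_key.items():
        ratio = rows[0]["ratio"]
        top_k = [
            (r["question"], int(r["occurrences"]))
            for r in sorted(rows, key=lambda r: int(r["rank"] or 0))
            if r["rank"]
        ]
        reports.append(
            ConceptReport(
                group_label=group, query=query, mode=mode,
                total_results=int(rows[0]["total"]),
                total_results_strict=int(rows[0]["total"]) if mode == "strict" else -1,
                top_k=top_k,
                topk_ratio=float(ratio) if ratio else None,
            )
        )
    return reports
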