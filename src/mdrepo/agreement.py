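"""Interrater agreement for ordinal quality ratings.

Implements Krippendorff's alpha with the ordinal difference function and
a unit-resampling bootstrap percentile confidence interval, plus the
Likert response summaries used to describe a two-rater quality survey.

Alpha is computed from the coincidence matrix of all pairable values:

    alpha = 1 - D_o / D_e

where ``D_o`` is the observed disagreement (coincidence-weighted mean of
the squared ordinal distances) and ``D_e`` the disagreement expected by
chance from the category marginals.  The ordinal distance between
categories ``c < k`` is the sum of the marginal frequencies of all
categories between them (inclusive), minus half of the two endpoint
frequencies, squared.  Units contribute only when at least two raters
rated them; missing values are excluded by pairability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import MdrError

#: Ordinal Likert labels in order, mapped to 1..5.
LIKERT_LABELS = ("SD", "D", "N", "A", "SA")


class InsufficientDataError(MdrError):
    """Not enough pairable ratings to compute the statistic."""


@dataclass
class RatingMatrix:
    """Units x raters ordinal ratings (1-5, missing allowed).

    ``unit_properties`` optionally maps each unit to the rated item
    property (Question, CodeList, ...), used by the Likert summaries.
    """

    units: list[str]
    raters: list[str]
    ratings: dict[tuple[str, str], int]
    unit_properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (unit, rater), value in self.ratings.items():
            if not 1 <= value <= 5:
                raise ValueError(f"rating {value} for ({unit}, {rater}) outside 1..5")

    def unit_values(self, unit: str) -> list[int]:
        return [
            self.ratings[(unit, rater)]
            for rater in self.raters
            if (unit, rater) in self.ratings
        ]

    def subset(self, unit_ids: list[str]) -> "RatingMatrix":
        """New matrix with the given units (repeats allowed, re-identified)."""
        units: list[str] = []
        ratings: dict[tuple[str, str], int] = {}
        props: dict[str, str] = {}
        for i, unit in enumerate(unit_ids):
            new_id = f"{unit}#{i}"
            units.append(new_id)
            if unit in self.unit_properties:
                props[new_id] = self.unit_properties[unit]
            for rater in self.raters:
                if (unit, rater) in self.ratings:
                    ratings[(new_id, rater)] = self.ratings[(unit, rater)]
        return RatingMatrix(units=units, raters=list(self.raters), ratings=ratings,
                            unit_properties=props)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingMatrix":
        """Read rows of ``unit,property,rater,rating`` (rating may be empty)."""
        units: list[str] = []
        raters: list[str] = []
        ratings: dict[tuple[str, str], int] = {}
        props: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                unit = row["unit"]
                rater = row["rater"]
                if unit not in units:
                    units.append(unit)
                if rater not in raters:
                    raters.append(rater)
                if row.get("property"):
                    props[unit] = row["property"]
                raw = (row.get("rating") or "").strip()
                if raw:
                    ratings[(unit, rater)] = int(raw)
        return cls(units=units, raters=raters, ratings=ratings, unit_properties=props)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["unit", "property", "rater", "rating"])
            for unit in self.units:
                for rater in self.raters:
                    value = self.ratings.get((unit, rater))
                    writer.writerow(
                        [unit, self.unit_properties.get(unit, ""), rater,
                         "" if value is None else value]
                    )


def _coincidence(matrix: RatingMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Coincidence matrix over observed categories; returns (o, cats, n_units_used)."""
    observed = sorted({v for vals in
                       (matrix.unit_values(u) for u in matrix.units) for v in vals})
    index = {c: i for i, c in enumerate(observed)}
    k = len(observed)
    o = np.zeros((k, k))
    used = 0
    for unit in matrix.units:
        values = matrix.unit_values(unit)
        m = len(values)
        if m < 2:
            continue
        used += 1
        for i, vi in enumerate(values):
            for j, vj in enumerate(values):
                if i != j:
                    o[index[vi], index[vj]] += 1.0 / (m - 1)
    return o, np.array(observed, dtype=float), used


def _ordinal_delta_sq(marginals: np.ndarray) -> np.ndarray:
    """delta^2[c, k] from coincidence-matrix marginals."""
    k = len(marginals)
    delta = np.zeros((k, k))
    for c in range(k):
        for d in range(c + 1, k):
            between = marginals[c:d + 1].sum() - (marginals[c] + marginals[d]) / 2.0
            delta[c, d] = delta[d, c] = between ** 2
    return delta


def krippendorff_alpha(matrix: RatingMatrix, metric: str = "ordinal") -> float:
    """Krippendorff's alpha for ordinal (or nominal) data.

    Raises
    ------
    InsufficientDataError
        No unit has two or more ratings, or expected disagreement is
        zero while observed disagreement is not.
    """
    o, cats, used = _coincidence(matrix)
    n = o.sum()
    if used == 0 or n <= 1:
        raise InsufficientDataError("no pairable ratings")
    marginals = o.sum(axis=1)
    if metric == "ordinal":
        delta = _ordinal_delta_sq(marginals)
    elif metric == "nominal":
        delta = 1.0 - np.eye(len(cats))
    elif metric == "interval":
        delta = (cats[:, None] - cats[None, :]) ** 2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d_obs = (o * delta).sum()
    d_exp = (np.outer(marginals, marginals) * delta).sum() / (n - 1)
    if d_exp == 0:
        if d_obs == 0:
            return 1.0
        raise InsufficientDataError("zero expected but nonzero observed disagreement")
    return float(1.0 - (d_obs / d_exp))


@dataclass
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    n_units_used: int
    bootstrap: dict


def bootstrap_ci(
    matrix: RatingMatrix,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    metric: str = "ordinal",
) -> tuple[float, float]:
    """Percentile bootstrap interval for alpha, resampling survey units.

    Deterministic given ``seed``.  Degenerate resamples (no pairable
    values) are redrawn; with ``B < 100`` the interval is noisy and a
    warning is raised via the returned :func:`alpha_with_ci` report.
    """
    low, high, _ = _bootstrap(matrix, B, level, seed, metric)
    return low, high


def _bootstrap(matrix, B, level, seed, metric):
    rng = np.random.default_rng(seed)
    units = list(matrix.units)
    n = len(units)
    samples = []
    redrawn = 0
    while len(samples) < B:
        chosen = [units[i] for i in rng.integers(0, n, size=n)]
        try:
            samples.append(krippendorff_alpha(matrix.subset(chosen), metric=metric))
        except InsufficientDataError:
            redrawn += 1
            if redrawn > 10 * B:
                raise InsufficientDataError("bootstrap resamples persistently degenerate")
    tail = (1.0 - level) / 2.0
    low = float(np.quantile(samples, tail))
    high = float(np.quantile(samples, 1.0 - tail))
    return low, high, redrawn


def alpha_with_ci(
    matrix: RatingMatrix,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    metric: str = "ordinal",
) -> AlphaResult:
    """Alpha plus its bootstrap CI in one report."""
    alpha = krippendorff_alpha(matrix, metric=metric)
    low, high, redrawn = _bootstrap(matrix, B, level, seed, metric)
    _, _, used = _coincidence(matrix)
    return AlphaResult(
        alpha=alpha, ci_low=low, ci_high=high, n_units_used=used,
        bootstrap={"B": B, "seed": seed, "level": level, "redrawn": redrawn,
                   "warning": "B < 100 gives unstable intervals" if B < 100 else None},
    )


def ordinal_median(values: list[int]) -> int | None:
    """Median category; even-length ties report the lower middle category."""
    if not values:
        return None
    ordered = sorted(values)
    n = len(ordered)
    if n % 2 == 1:
        return ordered[n // 2]
    return ordered[n // 2 - 1]


def summarize_likert(matrix: RatingMatrix) -> list[dict]:
    """Response counts and median per (property, rater).

    Each row carries the counts of SD/D/N/A/SA responses, the number of
    units the rater left unrated (undefined), and the median category;
    counts + undefined always equal the number of units of the property.
    A final ``Total`` row per rater pools all properties.
    """
    properties = list(dict.fromkeys(matrix.unit_properties.get(u, "") for u in matrix.units))
    rows: list[dict] = []
    for prop in properties + ["Total"]:
        if prop == "Total":
            unit_ids = list(matrix.units)
        else:
            unit_ids = [u for u in matrix.units if matrix.unit_properties.get(u, "") == prop]
        for rater in matrix.raters:
            values = [matrix.ratings[(u, rater)] for u in unit_ids
                      if (u, rater) in matrix.ratings]
            counts = {label: 0 for label in LIKERT_LABELS}
            for v in values:
                counts[LIKERT_LABELS[v - 1]] += 1
            median = ordinal_median(values)
            rows.append(
                {
                    "property": prop,
                    "rater": rater,
                    **counts,
                    "undefined": len(unit_ids) - len(values),
                    "n_units": len(unit_ids),
                    "median": LIKERT_LABELS[median - 1] if median else None,
                }
            )
    return rows
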