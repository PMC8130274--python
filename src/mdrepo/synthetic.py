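"""Synthetic ODM corpora and rating matrices with known ground truth.

Real metadata collections show a heavy-tailed reuse pattern: a few
definitions of a concept are used very often while a long tail occurs
once or twice.  The corpus generator emulates this with a Zipf law over
per-concept definition variants: variant rank 1 is the planted
"bottom-up standard", lower ranks are perturbations of it (question
casing or wording, datatype, code-list changes).  Casing-only variants
collide under relaxed (question-level) equivalence but not under strict
equivalence, mirroring how question clustering merges counts in real
corpora.  A ledger records every planted definition, its canonical key
and its realized occurrence count, so store, search and evaluation
layers can be checked against exact ground truth.

All randomness flows from one seeded generator; the same config yields
byte-identical ODM output.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .agreement import RatingMatrix
from .canonical import CanonicalKey, canonical_key, relaxed_question_key
from .model import MdrError, OdmElement, ResourceKind, SourceDocument
from .odm import decompose, write_odm

#: Controlled vocabulary of concept names.  Two-word clinical measurements
#: so queries behave like real concept searches (shared tokens such as
#: "serum" produce partial matches across concepts).
CONCEPT_POOL = [
    "body height", "body weight", "diastolic blood pressure",
    "systolic blood pressure", "pulse rate", "body temperature",
    "serum creatinine", "hemoglobin level", "serum potassium",
    "blood glucose", "serum sodium", "urea nitrogen", "heart rate",
    "respiratory rate", "oxygen saturation", "waist circumference",
    "hip circumference", "smoking status", "alcohol consumption",
    "physical activity", "platelet count", "white cell count",
    "total cholesterol", "ldl cholesterol", "hdl cholesterol",
    "triglyceride level", "serum calcium", "serum albumin",
    "bilirubin total", "alanine aminotransferase",
    "aspartate aminotransferase", "thyroid stimulating hormone",
    "vitamin d level", "ferritin level", "c reactive protein",
    "urine protein", "grip strength", "medication adherence",
    "pain intensity", "sleep duration",
]

#: Qualifiers appended by the question-rewording perturbation.
QUALIFIERS = [
    "unit", "measured", "at admission", "baseline", "follow up",
    "self reported", "left", "right", "maximum", "average", "past week",
    "current", "standing", "supine",
]

DATATYPES = ["float", "integer", "text"]
UNIT_SYMBOLS = ["kg", "cm", "mmHg", "bpm", "mg/dL", "mmol/L", "%"]
DECODE_SETS = [
    ["Yes", "No"],
    ["Yes", "No", "Unknown"],
    ["Normal", "Abnormal"],
    ["Never", "Former", "Current"],
]

#: Item properties rated in the quality survey, cycled over rating units.
SURVEY_PROPERTIES = [
    "Question", "CodeList", "Name", "DataType", "Length", "Description",
    "Alias", "RangeCheck", "Good match", "Relevancy",
]


class ConfigError(MdrError):
    """Infeasible generator configuration."""


@dataclass
class SynthConfig:
    """Study conditions for corpus generation.

    Defaults emulate a desk-scale snapshot of a form collection: 20
    concepts with 8 definition variants each, reused across 200
    documents with Zipf(1.5) rank frequencies; roughly a third of the
    variants differ only in question casing, and most questions carry an
    English language tag.
    """

    seed: int = 0
    n_concepts: int = 20
    n_documents: int = 200
    zipf_exponent: float = 1.5
    defs_per_concept: int = 8
    items_per_document: int = 5
    perturbation_probs: dict[str, float] = field(
        default_factory=lambda: {
            "question_case": 0.35,
            "question_rewording": 0.45,
            "datatype_change": 0.15,
            "codelist_change": 0.15,
        }
    )
    alias_rate: float = 0.6
    english_rate: float = 0.9

    def validate(self) -> None:
        for name in ("n_concepts", "n_documents", "defs_per_concept",
                     "items_per_document"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent must be positive")
        probs = dict(self.perturbation_probs)
        probs["alias_rate"] = self.alias_rate
        probs["english_rate"] = self.english_rate
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {name}={p} outside [0, 1]")
        if self.n_concepts > len(CONCEPT_POOL):
            raise ConfigError(
                f"n_concepts={self.n_concepts} exceeds concept pool "
                f"({len(CONCEPT_POOL)})"
            )
        if self.defs_per_concept > 1 + len(QUALIFIERS):
            raise ConfigError(
                f"defs_per_concept={self.defs_per_concept} exceeds qualifier pool"
            )


@dataclass
class PlantedDefinition:
    """Ledger entry for one generated item variant."""

    concept: str
    rank: int  # 1 = planted bottom-up standard
    item_oid: str
    key: CanonicalKey
    relaxed_key: str | None
    question: str
    language: str
    occurrences: int
    aliases: list[tuple[str, str]]
    is_standard: bool


@dataclass
class GroundTruthLedger:
    config: SynthConfig
    definitions: list[PlantedDefinition]
    element_counts: dict[ResourceKind, int]
    concept_aliases: dict[str, list[tuple[str, str]]]

    def by_concept(self, concept: str) -> list[PlantedDefinition]:
        return [d for d in self.definitions if d.concept == concept]

    def standard(self, concept: str) -> PlantedDefinition:
        return next(d for d in self.definitions if d.concept == concept and d.is_standard)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "definitions": [
                {
                    "concept": d.concept, "rank": d.rank, "item_oid": d.item_oid,
                    "key": d.key.digest, "relaxed_key": d.relaxed_key,
                    "question": d.question, "language": d.language,
                    "occurrences": d.occurrences, "aliases": d.aliases,
                    "is_standard": d.is_standard,
                }
                for d in self.definitions
            ],
            "element_counts": {k.value: v for k, v in self.element_counts.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _zipf_ranks(rng: random.Random, n_ranks: int, exponent: float, draws: int) -> list[int]:
    weights = [r ** -exponent for r in range(1, n_ranks + 1)]
    return rng.choices(range(1, n_ranks + 1), weights=weights, k=draws)


def _build_variant(
    rng: random.Random,
    concept: str,
    ci: int,
    rank: int,
    standard: OdmElement,
    probs: dict[str, float],
    english_rate: float,
    used_qualifiers: set[str],
) -> OdmElement:
    import copy

    item = copy.deepcopy(standard)
    item.oid = f"I.{ci}.{rank}"
    question = concept.capitalize()
    if rng.random() < probs["question_case"]:
        question = question.lower() if rng.random() < 0.5 else question.upper()
    free = [q for q in QUALIFIERS if q not in used_qualifiers]
    if free and rng.random() < probs["question_rewording"]:
        qualifier = rng.choice(free)
        used_qualifiers.add(qualifier)
        question = f"{question} - {qualifier}"
    language = "en" if rng.random() < english_rate else "de"
    item.translated_texts["Question"] = {language: question}
    if rng.random() < probs["datatype_change"]:
        others = [d for d in DATATYPES if d != item.attributes["DataType"]]
        item.attributes["DataType"] = rng.choice(others)
    codelists = [c for c in item.children if c.kind is ResourceKind.CODE_LIST]
    if codelists and rng.random() < probs["codelist_change"]:
        cl = codelists[0]
        cl.oid = f"{cl.oid}.{rank}"
        victim = rng.choice(cl.children)
        decode = victim.translated_texts["Decode"]["en"]
        victim.translated_texts["Decode"]["en"] = f"{decode} (v{rank})"
    return item


def generate_corpus(config: SynthConfig) -> tuple[list[SourceDocument], GroundTruthLedger]:
    """Generate ODM documents plus the exact ground truth they encode.

    Returns documents whose ingestion reproduces the ledger's occurrence
    counts: variant usage frequencies are drawn per document-item slot
    (concept uniform, variant rank Zipf-distributed), so a definition
    used twice in one document counts twice, matching the store's
    occurrence unit.
    """
    config.validate()
    rng = random.Random(config.seed)
    concepts = CONCEPT_POOL[: config.n_concepts]
    probs = config.perturbation_probs

    variants: dict[tuple[int, int], OdmElement] = {}
    concept_aliases: dict[str, list[tuple[str, str]]] = {}
    for ci, concept in enumerate(concepts):
        name = concept.title()
        aliases: list[tuple[str, str]] = []
        if rng.random() < config.alias_rate:
            aliases.append(("UMLS", f"C{rng.randrange(10**6, 10**7)}"))
        concept_aliases[concept] = aliases
        standard = OdmElement(
            kind=ResourceKind.ITEM,
            oid=f"I.{ci}.1",
            attributes={"Name": name, "DataType": rng.choice(DATATYPES), "Length": "20"},
            translated_texts={"Question": {"en": concept.capitalize()}},
            aliases=list(aliases),
        )
        if rng.random() < 0.5:
            decodes = rng.choice(DECODE_SETS)
            codelist = OdmElement(
                kind=ResourceKind.CODE_LIST,
                oid=f"CL.{ci}",
                attributes={"Name": f"{name} codes", "DataType": "integer"},
                children=[
                    OdmElement(
                        kind=ResourceKind.CODE_LIST_ITEM,
                        oid=str(i + 1),
                        attributes={"CodedValue": str(i + 1)},
                        translated_texts={"Decode": {"en": decode}},
                    )
                    for i, decode in enumerate(decodes)
                ],
            )
            standard.children.append(codelist)
        elif rng.random() < 0.6:
            unit = OdmElement(
                kind=ResourceKind.MEASUREMENT_UNIT,
                oid=f"MU.{ci}",
                attributes={"Name": rng.choice(UNIT_SYMBOLS)},
                translated_texts={"Symbol": {"en": rng.choice(UNIT_SYMBOLS)}},
            )
            standard.children.append(unit)
        variants[(ci, 1)] = standard

        used_qualifiers: set[str] = set()
        seen_keys = {canonical_key(standard)}
        for rank in range(2, config.defs_per_concept + 1):
            for _attempt in range(20):
                variant = _build_variant(
                    rng, concept, ci, rank, standard, probs,
                    config.english_rate, used_qualifiers,
                )
                key = canonical_key(variant)
                if key not in seen_keys:
                    break
            else:  # force a distinguishing qualifier
                free = [q for q in QUALIFIERS if q not in used_qualifiers]
                if not free:
                    raise ConfigError("qualifier pool exhausted while forcing uniqueness")
                qualifier = free[0]
                used_qualifiers.add(qualifier)
                lang = next(iter(variant.translated_texts["Question"]))
                q = variant.translated_texts["Question"][lang]
                variant.translated_texts["Question"][lang] = f"{q} - {qualifier}"
                key = canonical_key(variant)
            seen_keys.add(key)
            variants[(ci, rank)] = variant

    # assemble documents; tally realized occurrences per variant
    occurrences: dict[tuple[int, int], int] = {}
    documents: list[SourceDocument] = []
    element_counts: dict[ResourceKind, int] = {}
    import copy as _copy

    for d in range(config.n_documents):
        items: list[OdmElement] = []
        for _slot in range(config.items_per_document):
            ci = rng.randrange(config.n_concepts)
            rank = _zipf_ranks(rng, config.defs_per_concept, config.zipf_exponent, 1)[0]
            occurrences[(ci, rank)] = occurrences.get((ci, rank), 0) + 1
            items.append(_copy.deepcopy(variants[(ci, rank)]))
        group = OdmElement(
            kind=ResourceKind.ITEM_GROUP, oid=f"IG.{d}",
            attributes={"Name": f"Group {d}", "Repeating": "No"}, children=items,
        )
        form = OdmElement(
            kind=ResourceKind.FORM, oid=f"F.{d}",
            attributes={"Name": f"Synthetic form {d}", "Repeating": "No"}, children=[group],
        )
        study = OdmElement(
            kind=ResourceKind.STUDY, oid=f"S.{d}",
            attributes={"StudyName": f"Synthetic study {d}"}, children=[form],
        )
        doc = SourceDocument(document_id=f"doc-{d:04d}",
                             origin_label=f"Synthetic study {d}", roots=[study])
        documents.append(doc)
        for el, _path in decompose(doc):
            element_counts[el.kind] = element_counts.get(el.kind, 0) + 1

    definitions = [
        PlantedDefinition(
            concept=concepts[ci],
            rank=rank,
            item_oid=variant.oid,
            key=canonical_key(variant),
            relaxed_key=relaxed_question_key(variant),
            question=next(iter(variant.translated_texts["Question"].values())),
            language=next(iter(variant.translated_texts["Question"])),
            occurrences=occurrences.get((ci, rank), 0),
            aliases=list(variant.aliases),
            is_standard=rank == 1,
        )
        for (ci, rank), variant in sorted(variants.items())
    ]
    ledger = GroundTruthLedger(
        config=config,
        definitions=definitions,
        element_counts=element_counts,
        concept_aliases=concept_aliases,
    )
    return documents, ledger


def write_corpus(
    documents: list[SourceDocument], ledger: GroundTruthLedger, out_dir: str | Path
) -> list[Path]:
    """Write ODM XML files plus the ledger JSON; returns the XML paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc in documents:
        path = out / f"{doc.document_id}.xml"
        write_odm(doc, path)
        paths.append(path)
    ledger.to_json(out / "ledger.json")
    return paths


def generate_ratings(
    n_units: int,
    n_raters: int = 2,
    agreement_level: float = 0.8,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> RatingMatrix:
    """Rating matrix with a latent ordinal truth per unit.

    Each rater reports the unit's latent category with probability
    ``agreement_level`` and a neighboring category otherwise; entries go
    missing at ``missing_rate``.  Unit properties cycle through the ten
    survey properties so Likert summaries group naturally.
    """
    if n_raters < 2:
        raise ConfigError("n_raters must be >= 2")
    for name, p in (("agreement_level", agreement_level), ("missing_rate", missing_rate)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name}={p} outside [0, 1]")
    rng = random.Random(seed)
    units = [f"u{i:04d}" for i in range(n_units)]
    raters = [chr(ord("A") + i) for i in range(n_raters)]
    ratings: dict[tuple[str, str], int] = {}
    props = {unit: SURVEY_PROPERTIES[i % len(SURVEY_PROPERTIES)]
             for i, unit in enumerate(units)}
    for unit in units:
        truth = rng.randint(1, 5)
        for rater in raters:
            if rng.random() < missing_rate:
                continue
            if rng.random() < agreement_level:
                value = truth
            else:
                step = rng.choice([-1, 1])
                value = truth + step
                if not 1 <= value <= 5:
                    value = truth - step
            ratings[(unit, rater)] = value
    return RatingMatrix(units=units, raters=raters, ratings=ratings,
                        unit_properties=props)
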