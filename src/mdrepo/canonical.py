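"""Canonical serialization and content-addressed keys for metadata resources.

Two resources are *strictly equivalent* when they agree in every property,
including their whole subtree.  This is decided on a deterministic
canonical serialization: attributes sorted by name, texts sorted by
(role, language), whitespace and Unicode normalized, and every child
represented by the digest of its own canonical serialization (a Merkle
construction, so any change in a descendant propagates to all ancestors).

The *relaxed* equivalence used for question-level clustering only
compares the lowercase English question text of an item.
"""

from __future__ import annotations

import hashlib
import re
import unicodedata
from dataclasses import dataclass

from .model import KindError, OdmElement, ResourceKind, StructureError

_WS_RUN = re.compile(r"\s+")


def normalize_text(value: str) -> str:
    """NFC-normalize, trim, and collapse internal whitespace runs."""
    value = unicodedata.normalize("NFC", value)
    return _WS_RUN.sub(" ", value.strip())


@dataclass(frozen=True, order=True)
class CanonicalKey:
    """Content address of a resource: hex digest of its canonical form."""

    digest: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.digest


def canonical_serialize(element: OdmElement, *, ignore_oids: bool = False) -> str:
    """Return the canonical string form of ``element``.

    Children appear only through their digests; sibling order is kept
    because ODM order carries meaning (code-list ordering, item order).

    Parameters
    ----------
    ignore_oids
        Exclude OIDs from the serialization.  Strict equivalence reads
        "agreed in every property" literally and includes the OID; this
        switch serves corpora whose OIDs are machine-generated noise.

    Raises
    ------
    StructureError
        If the child structure is cyclic.
    """
    return _serialize(element, ignore_oids, on_stack=set())


def _serialize(element: OdmElement, ignore_oids: bool, on_stack: set[int]) -> str:
    if id(element) in on_stack:
        raise StructureError(f"cyclic child structure at oid={element.oid!r}")
    on_stack.add(id(element))
    try:
        parts = [f"K:{element.kind.value}"]
        if not ignore_oids:
            parts.append(f"O:{normalize_text(element.oid)}")
        for name in sorted(element.attributes):
            parts.append(f"A:{normalize_text(name)}={normalize_text(element.attributes[name])}")
        for role in sorted(element.translated_texts):
            texts = element.translated_texts[role]
            for lang in sorted(texts):
                parts.append(f"T:{role}|{lang}|{normalize_text(texts[lang])}")
        for context, name in element.aliases:  # document order
            parts.append(f"L:{normalize_text(context)}|{normalize_text(name)}")
        for rc in element.range_checks:  # document order
            values = ",".join(normalize_text(v) for v in rc.check_values)
            unit = normalize_text(rc.measurement_unit_oid or "")
            parts.append(f"R:{rc.comparator}|{rc.soft_hard}|{values}|{unit}")
        for child in element.children:
            digest = _digest(_serialize(child, ignore_oids, on_stack))
            parts.append(f"C:{digest}")
        return "\n".join(parts)
    finally:
        on_stack.discard(id(element))


def _digest(serialized: str) -> str:
    return hashlib.sha256(serialized.encode("utf-8")).hexdigest()


def canonical_key(element: OdmElement, *, ignore_oids: bool = False) -> CanonicalKey:
    """Digest of the canonical serialization; stable across runs and platforms."""
    return CanonicalKey(_digest(canonical_serialize(element, ignore_oids=ignore_oids)))


def english_question(
    item: OdmElement, *, untagged_as_english: bool = True
) -> str | None:
    """The item's English question text, or ``None``.

    English means a language tag of ``en`` or an ``en-`` prefix.  An
    untagged text counts as English only when the item carries no tagged
    question at all (and ``untagged_as_english`` is set).
    """
    questions = item.translated_texts.get("Question", {})
    for lang, text in questions.items():
        if lang == "en" or lang.startswith("en-"):
            return text
    tagged = [lang for lang in questions if lang]
    if untagged_as_english and not tagged and "" in questions:
        return questions[""]
    return None


def relaxed_question_key(
    item: OdmElement, *, untagged_as_english: bool = True
) -> str | None:
    """Lowercased, whitespace-normalized English question of an Item.

    Returns ``None`` when the item has no English question, so such items
    drop out of question-level clustering.
    """
    if item.kind is not ResourceKind.ITEM:
        raise KindError(f"relaxed_question_key requires an Item, got {item.kind.value}")
    question = english_question(item, untagged_as_english=untagged_as_english)
    if question is None:
        return None
    return normalize_text(question).lower()
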