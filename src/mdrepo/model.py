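"""Core metadata model: the tree of atomic ODM-derived resources.

A study document decomposes into atomic resources (forms, item groups,
items, code lists, ...).  Each resource is an :class:`OdmElement` carrying
its XML attributes, translated texts, semantic-code aliases, range checks
and child resources.  Equivalence of two resources is decided on a
canonical serialization of this structure (see :mod:`mdrepo.canonical`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator


class ResourceKind(str, Enum):
    """Closed enumeration of atomic resource kinds.

    Unknown ODM elements are rejected or skipped by the parser, never
    silently coerced into one of these.
    """

    STUDY = "Study"
    PROTOCOL = "Protocol"
    STUDY_EVENT = "StudyEvent"
    FORM = "Form"
    ITEM_GROUP = "ItemGroup"
    ITEM = "Item"
    CODE_LIST = "CodeList"
    CODE_LIST_ITEM = "CodeListItem"
    MEASUREMENT_UNIT = "MeasurementUnit"


#: Kinds stored by default: all candidates minus StudyEvent.  StudyEvent
#: handling is configurable because containment through study events is
#: redundant with the Study -> Form path for flat corpora.
DEFAULT_KINDS: frozenset[ResourceKind] = frozenset(
    k for k in ResourceKind if k is not ResourceKind.STUDY_EVENT
)

#: Kinds that may be serialized as standalone metadata fragments.
FRAGMENT_KINDS: frozenset[ResourceKind] = frozenset(
    {
        ResourceKind.FORM,
        ResourceKind.ITEM_GROUP,
        ResourceKind.ITEM,
        ResourceKind.CODE_LIST,
        ResourceKind.CODE_LIST_ITEM,
        ResourceKind.MEASUREMENT_UNIT,
    }
)


@dataclass
class RangeCheck:
    """A constraint on an item's values (``RangeCheck`` in ODM)."""

    comparator: str
    soft_hard: str
    check_values: tuple[str, ...]
    measurement_unit_oid: str | None = None


@dataclass
class OdmElement:
    """One node of the metadata tree.

    Attributes
    ----------
    kind
        The atomic resource kind.
    oid
        The ODM object identifier.  Elements without a native OID in ODM
        (Protocol) receive a constant placeholder.
    attributes
        Ordered name -> value map of XML attributes (``Name``,
        ``DataType``, ``Length``, ``Mandatory``, ...).  Values are
        whitespace-trimmed strings.
    translated_texts
        role -> {language-tag -> text}.  Roles used: ``Question`` and
        ``Description`` on items, ``Decode`` on code-list items,
        ``Symbol`` on measurement units.  Language tags are lowercase;
        the empty string stands for an untagged text.
    aliases
        ``(context, name)`` pairs from ODM ``Alias`` elements (e.g. UMLS
        codes).
    range_checks
        Item range checks in document order.
    children
        Child resources in document order (reference order in the source
        XML).
    """

    kind: ResourceKind
    oid: str
    attributes: dict[str, str] = field(default_factory=dict)
    translated_texts: dict[str, dict[str, str]] = field(default_factory=dict)
    aliases: list[tuple[str, str]] = field(default_factory=list)
    range_checks: list[RangeCheck] = field(default_factory=list)
    children: list["OdmElement"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.oid:
            raise ValueError("OdmElement requires a non-empty oid")

    def walk(self) -> Iterator["OdmElement"]:
        """Yield this element and all descendants in document order."""
        yield self
        for child in self.children:
            yield from child.walk()

    def text(self, role: str, language: str) -> str | None:
        return self.translated_texts.get(role, {}).get(language)


@dataclass
class SourceDocument:
    """A parsed metadata document: one or more Study trees plus identity."""

    document_id: str
    origin_label: str = ""
    roots: list[OdmElement] = field(default_factory=list)

    def elements(self) -> Iterator[OdmElement]:
        for root in self.roots:
            yield from root.walk()


class MdrError(Exception):
    """Base class for package errors."""


class OdmParseError(MdrError):
    """Malformed XML or non-ODM content; carries line/column when known."""


class IntegrityError(MdrError):
    """Dangling reference or inconsistent document structure."""


class KindError(MdrError):
    """Operation applied to an element of an unsupported kind."""


class StructureError(MdrError):
    """Structurally invalid element tree (e.g. a cycle)."""
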