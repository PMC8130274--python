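"""Reading and writing the CDISC ODM 1.3 metadata subset.

The parser turns an ODM document into a :class:`~mdrepo.model.SourceDocument`
whose Study trees have all references (FormRef, ItemGroupRef, ItemRef,
CodeListRef, MeasurementUnitRef) resolved into containment.  Reference
order becomes child order; a definition referenced twice appears twice
(occurrences count usages).  The writer emits valid ODM again, both for
whole documents and for standalone fragments of a single resource.

Only study *metadata* is handled: ClinicalData sections, ODM 2.0 and
vendor extensions are out of scope.  Reference-level attributes such as
``Mandatory`` and ``OrderNumber`` describe the usage context, not the
definition, and are not part of the atomic resource (order is preserved
structurally).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

from .model import (
    FRAGMENT_KINDS,
    DEFAULT_KINDS,
    IntegrityError,
    KindError,
    OdmElement,
    OdmParseError,
    RangeCheck,
    ResourceKind,
    SourceDocument,
)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"

_DEF_TAGS = {
    "StudyEventDef": ResourceKind.STUDY_EVENT,
    "FormDef": ResourceKind.FORM,
    "ItemGroupDef": ResourceKind.ITEM_GROUP,
    "ItemDef": ResourceKind.ITEM,
    "CodeList": ResourceKind.CODE_LIST,
}


@dataclass
class ParseConfig:
    """Knobs for document decomposition.

    include_study_events
        When False (default) StudyEvent nodes are skipped and forms hang
        directly off the Study, which matches the eight-kind resource
        model; when True study events appear between Protocol and Form.
    untagged_as_english
        Treat untagged translated texts as English when no tagged text
        exists (used by question-level clustering downstream).
    """

    include_study_events: bool = False
    untagged_as_english: bool = True


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _children(el: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def _attrs(el: etree._Element, *, skip: tuple[str, ...] = ("OID",)) -> dict[str, str]:
    out: dict[str, str] = {}
    for name, value in el.attrib.items():
        if name.startswith("{"):  # namespaced (xml:lang etc.) handled elsewhere
            continue
        if name in skip:
            continue
        out[name] = value.strip()
    return out


def _translated(el: etree._Element) -> dict[str, str]:
    """lang -> text for the TranslatedText children of ``el``."""
    texts: dict[str, str] = {}
    for tt in _children(el, "TranslatedText"):
        lang = (tt.get(XML_LANG) or "").strip().lower()
        texts[lang] = tt.text or ""
    return texts


def parse_odm(
    xml_source: bytes | str | Path,
    *,
    document_id: str | None = None,
    config: ParseConfig | None = None,
) -> SourceDocument:
    """Parse an ODM metadata document into a reference-resolved tree.

    Parameters
    ----------
    xml_source
        Raw XML bytes, an XML string, or a path to a file.
    document_id
        Identity of the document within a store; defaults to the ODM
        ``FileOID`` or the file stem.

    Raises
    ------
    OdmParseError
        Malformed XML (the message names line and column) or a non-ODM
        root element.
    IntegrityError
        A reference to an OID with no definition.
    """
    config = config or ParseConfig()
    origin = None
    if isinstance(xml_source, Path) or (
        isinstance(xml_source, str) and not xml_source.lstrip().startswith("<")
    ):
        path = Path(xml_source)
        origin = path.stem
        data = path.read_bytes()
    elif isinstance(xml_source, str):
        data = xml_source.encode("utf-8")
    else:
        data = xml_source
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        raise OdmParseError(f"malformed XML at line {line}, column {col}: {exc.msg}") from exc
    if _local(root) != "ODM":
        raise OdmParseError(f"expected ODM root element, found {_local(root)!r}")

    doc_id = document_id or root.get("FileOID") or origin or "document"
    studies = []
    label = ""
    for study_el in _children(root, "Study"):
        study = _parse_study(study_el, config)
        studies.append(study)
        label = label or study.attributes.get("StudyName", "")
    if not studies:
        raise OdmParseError("ODM document contains no Study element")
    return SourceDocument(document_id=doc_id, origin_label=label, roots=studies)


def _parse_study(study_el: etree._Element, config: ParseConfig) -> OdmElement:
    oid = study_el.get("OID") or "Study"
    attributes: dict[str, str] = {}
    for gv in _children(study_el, "GlobalVariables"):
        for name in ("StudyName", "StudyDescription", "ProtocolName"):
            for el in _children(gv, name):
                if el.text and el.text.strip():
                    attributes[name] = el.text.strip()
    study = OdmElement(kind=ResourceKind.STUDY, oid=oid, attributes=attributes)

    unit_defs: dict[str, OdmElement] = {}
    for bd in _children(study_el, "BasicDefinitions"):
        for mu in _children(bd, "MeasurementUnit"):
            unit = _parse_measurement_unit(mu)
            unit_defs[unit.oid] = unit

    referenced_units: set[str] = set()
    for mdv in _children(study_el, "MetaDataVersion"):
        _parse_metadata_version(mdv, study, unit_defs, referenced_units, config)

    for oid_, unit in unit_defs.items():  # orphan units stay reachable
        if oid_ not in referenced_units:
            study.children.append(copy.deepcopy(unit))
    return study


def _parse_measurement_unit(mu: etree._Element) -> OdmElement:
    unit = OdmElement(
        kind=ResourceKind.MEASUREMENT_UNIT,
        oid=mu.get("OID") or "MU",
        attributes=_attrs(mu),
    )
    for symbol in _children(mu, "Symbol"):
        unit.translated_texts.setdefault("Symbol", {}).update(_translated(symbol))
    return unit


def _parse_metadata_version(
    mdv: etree._Element,
    study: OdmElement,
    unit_defs: dict[str, OdmElement],
    referenced_units: set[str],
    config: ParseConfig,
) -> None:
    defs: dict[ResourceKind, dict[str, etree._Element]] = {k: {} for k in _DEF_TAGS.values()}
    for el in mdv:
        if isinstance(el.tag, str) and _local(el) in _DEF_TAGS:
            defs[_DEF_TAGS[_local(el)]][el.get("OID") or ""] = el

    used: set[tuple[ResourceKind, str]] = set()

    def lookup(kind: ResourceKind, oid: str, ref_tag: str) -> etree._Element:
        el = defs[kind].get(oid)
        if el is None:
            raise IntegrityError(f"{ref_tag} references missing OID {oid!r}")
        used.add((kind, oid))
        return el

    def build_codelist(el: etree._Element) -> OdmElement:
        node = OdmElement(
            kind=ResourceKind.CODE_LIST, oid=el.get("OID") or "CL", attributes=_attrs(el)
        )
        for cli in _children(el, "CodeListItem"):
            child = OdmElement(
                kind=ResourceKind.CODE_LIST_ITEM,
                oid=cli.get("CodedValue") or "?",
                attributes=_attrs(cli, skip=()),
            )
            for dec in _children(cli, "Decode"):
                child.translated_texts.setdefault("Decode", {}).update(_translated(dec))
            node.children.append(child)
        return node

    def build_item(el: etree._Element) -> OdmElement:
        node = OdmElement(
            kind=ResourceKind.ITEM, oid=el.get("OID") or "I", attributes=_attrs(el)
        )
        for role in ("Question", "Description"):
            for holder in _children(el, role):
                node.translated_texts.setdefault(role, {}).update(_translated(holder))
        for alias in _children(el, "Alias"):
            node.aliases.append((alias.get("Context", "").strip(), alias.get("Name", "").strip()))
        for rc in _children(el, "RangeCheck"):
            unit_ref = None
            for mur in _children(rc, "MeasurementUnitRef"):
                unit_ref = mur.get("MeasurementUnitOID")
            node.range_checks.append(
                RangeCheck(
                    comparator=rc.get("Comparator", "").strip(),
                    soft_hard=rc.get("SoftHard", "Soft").strip(),
                    check_values=tuple(
                        (cv.text or "").strip() for cv in _children(rc, "CheckValue")
                    ),
                    measurement_unit_oid=unit_ref,
                )
            )
        for ref in el:
            if not isinstance(ref.tag, str):
                continue
            tag = _local(ref)
            if tag == "CodeListRef":
                cl = lookup(ResourceKind.CODE_LIST, ref.get("CodeListOID") or "", tag)
                node.children.append(build_codelist(cl))
            elif tag == "MeasurementUnitRef":
                mu_oid = ref.get("MeasurementUnitOID") or ""
                if mu_oid not in unit_defs:
                    raise IntegrityError(f"MeasurementUnitRef references missing OID {mu_oid!r}")
                referenced_units.add(mu_oid)
                node.children.append(copy.deepcopy(unit_defs[mu_oid]))
        for rc in node.range_checks:
            if rc.measurement_unit_oid:
                if rc.measurement_unit_oid not in unit_defs:
                    raise IntegrityError(
                        f"RangeCheck references missing MeasurementUnit OID "
                        f"{rc.measurement_unit_oid!r}"
                    )
                referenced_units.add(rc.measurement_unit_oid)
        return node

    def build_item_group(el: etree._Element) -> OdmElement:
        node = OdmElement(
            kind=ResourceKind.ITEM_GROUP, oid=el.get("OID") or "IG", attributes=_attrs(el)
        )
        for desc in _children(el, "Description"):
            node.translated_texts.setdefault("Description", {}).update(_translated(desc))
        for ref in _children(el, "ItemRef"):
            item = lookup(ResourceKind.ITEM, ref.get("ItemOID") or "", "ItemRef")
            node.children.append(build_item(item))
        return node

    def build_form(el: etree._Element) -> OdmElement:
        node = OdmElement(
            kind=ResourceKind.FORM, oid=el.get("OID") or "F", attributes=_attrs(el)
        )
        for desc in _children(el, "Description"):
            node.translated_texts.setdefault("Description", {}).update(_translated(desc))
        for ref in _children(el, "ItemGroupRef"):
            ig = lookup(ResourceKind.ITEM_GROUP, ref.get("ItemGroupOID") or "", "ItemGroupRef")
            node.children.append(build_item_group(ig))
        return node

    def build_study_event(el: etree._Element) -> OdmElement:
        node = OdmElement(
            kind=ResourceKind.STUDY_EVENT, oid=el.get("OID") or "SE", attributes=_attrs(el)
        )
        for ref in _children(el, "FormRef"):
            form = lookup(ResourceKind.FORM, ref.get("FormOID") or "", "FormRef")
            node.children.append(build_form(form))
        return node

    # Protocol -> StudyEvent -> Form chain; with study events disabled the
    # referenced forms are promoted to Study children in first-reference order.
    protocol_el = next(iter(_children(mdv, "Protocol")), None)
    promoted_forms: list[OdmElement] = []
    protocol_node: OdmElement | None = None
    if protocol_el is not None:
        protocol_node = OdmElement(kind=ResourceKind.PROTOCOL, oid="Protocol")
        for ref in _children(protocol_el, "StudyEventRef"):
            se = lookup(ResourceKind.STUDY_EVENT, ref.get("StudyEventOID") or "", "StudyEventRef")
            if config.include_study_events:
                protocol_node.children.append(build_study_event(se))
            else:
                used.add((ResourceKind.STUDY_EVENT, se.get("OID") or ""))
                for fref in _children(se, "FormRef"):
                    form = lookup(ResourceKind.FORM, fref.get("FormOID") or "", "FormRef")
                    promoted_forms.append(build_form(form))
        study.children.append(protocol_node)
    study.children.extend(promoted_forms)

    # Definitions never referenced (fragments, flat documents) attach
    # directly under the Study so every definition stays reachable.
    builders = {
        ResourceKind.FORM: build_form,
        ResourceKind.ITEM_GROUP: build_item_group,
        ResourceKind.ITEM: build_item,
        ResourceKind.CODE_LIST: build_codelist,
    }
    for el in mdv:
        if not isinstance(el.tag, str) or _local(el) not in _DEF_TAGS:
            continue
        kind = _DEF_TAGS[_local(el)]
        oid = el.get("OID") or ""
        if (kind, oid) in used:
            continue
        if kind is ResourceKind.STUDY_EVENT:
            if config.include_study_events and protocol_node is not None:
                protocol_node.children.append(build_study_event(el))
            continue
        study.children.append(builders[kind](el))


def decompose(document: SourceDocument) -> list[tuple[OdmElement, tuple[tuple[ResourceKind, str], ...]]]:
    """Every node of every root tree exactly once, with its path from root.

    The path is the sequence of ``(kind, oid)`` pairs from the Study root
    down to (and including) the element itself; output order is document
    order.
    """
    out: list[tuple[OdmElement, tuple[tuple[ResourceKind, str], ...]]] = []

    def visit(el: OdmElement, prefix: tuple[tuple[ResourceKind, str], ...]) -> None:
        path = prefix + ((el.kind, el.oid),)
        out.append((el, path))
        for child in el.children:
            visit(child, path)

    for root in document.roots:
        visit(root, ())
    return out


# --------------------------------------------------------------------------
# Writing


def _collect_defs(elements: Iterable[OdmElement]) -> dict[ResourceKind, dict[str, OdmElement]]:
    """First definition per (kind, OID); later copies must agree."""
    from .canonical import canonical_key

    defs: dict[ResourceKind, dict[str, OdmElement]] = {}
    for el in elements:
        for node in el.walk():
            if node.kind in (
                ResourceKind.STUDY,
                ResourceKind.PROTOCOL,
                ResourceKind.CODE_LIST_ITEM,  # nested inline within CodeList
            ):
                continue
            bucket = defs.setdefault(node.kind, {})
            prior = bucket.get(node.oid)
            if prior is None:
                bucket[node.oid] = node
            elif canonical_key(prior) != canonical_key(node):
                raise IntegrityError(
                    f"conflicting {node.kind.value} definitions share OID {node.oid!r}"
                )
    return defs


def _emit_translated(parent: etree._Element, tag: str, texts: dict[str, str]) -> None:
    holder = etree.SubElement(parent, f"{{{ODM_NS}}}{tag}")
    for lang in sorted(texts):
        tt = etree.SubElement(holder, f"{{{ODM_NS}}}TranslatedText")
        if lang:
            tt.set(XML_LANG, lang)
        tt.text = texts[lang]


def _emit_item_def(mdv: etree._Element, item: OdmElement) -> None:
    el = etree.SubElement(mdv, f"{{{ODM_NS}}}ItemDef", OID=item.oid, **item.attributes)
    if "Description" in item.translated_texts:
        _emit_translated(el, "Description", item.translated_texts["Description"])
    if "Question" in item.translated_texts:
        _emit_translated(el, "Question", item.translated_texts["Question"])
    for child in item.children:
        if child.kind is ResourceKind.CODE_LIST:
            etree.SubElement(el, f"{{{ODM_NS}}}CodeListRef", CodeListOID=child.oid)
        elif child.kind is ResourceKind.MEASUREMENT_UNIT:
            etree.SubElement(el, f"{{{ODM_NS}}}MeasurementUnitRef", MeasurementUnitOID=child.oid)
        else:
            raise KindError(f"Item cannot contain {child.kind.value}")
    for rc in item.range_checks:
        rc_el = etree.SubElement(
            el, f"{{{ODM_NS}}}RangeCheck", Comparator=rc.comparator, SoftHard=rc.soft_hard
        )
        for value in rc.check_values:
            cv = etree.SubElement(rc_el, f"{{{ODM_NS}}}CheckValue")
            cv.text = value
        if rc.measurement_unit_oid:
            etree.SubElement(
                rc_el, f"{{{ODM_NS}}}MeasurementUnitRef",
                MeasurementUnitOID=rc.measurement_unit_oid,
            )
    for context, name in item.aliases:
        etree.SubElement(el, f"{{{ODM_NS}}}Alias", Context=context, Name=name)


def _emit_codelist(mdv: etree._Element, cl: OdmElement) -> None:
    el = etree.SubElement(mdv, f"{{{ODM_NS}}}CodeList", OID=cl.oid, **cl.attributes)
    for cli in cl.children:
        attrs = dict(cli.attributes)
        attrs.setdefault("CodedValue", cli.oid)
        cli_el = etree.SubElement(el, f"{{{ODM_NS}}}CodeListItem", **attrs)
        if "Decode" in cli.translated_texts:
            _emit_translated(cli_el, "Decode", cli.translated_texts["Decode"])


def _emit_measurement_unit(bd: etree._Element, mu: OdmElement) -> None:
    el = etree.SubElement(bd, f"{{{ODM_NS}}}MeasurementUnit", OID=mu.oid, **mu.attributes)
    if "Symbol" in mu.translated_texts:
        _emit_translated(el, "Symbol", mu.translated_texts["Symbol"])


def _emit_group_def(mdv: etree._Element, ig: OdmElement) -> None:
    el = etree.SubElement(mdv, f"{{{ODM_NS}}}ItemGroupDef", OID=ig.oid, **ig.attributes)
    if "Description" in ig.translated_texts:
        _emit_translated(el, "Description", ig.translated_texts["Description"])
    for child in ig.children:
        if child.kind is not ResourceKind.ITEM:
            raise KindError(f"ItemGroup cannot contain {child.kind.value}")
        etree.SubElement(el, f"{{{ODM_NS}}}ItemRef", ItemOID=child.oid)


def _emit_form_def(mdv: etree._Element, form: OdmElement) -> None:
    el = etree.SubElement(mdv, f"{{{ODM_NS}}}FormDef", OID=form.oid, **form.attributes)
    if "Description" in form.translated_texts:
        _emit_translated(el, "Description", form.translated_texts["Description"])
    for child in form.children:
        if child.kind is not ResourceKind.ITEM_GROUP:
            raise KindError(f"Form cannot contain {child.kind.value}")
        etree.SubElement(el, f"{{{ODM_NS}}}ItemGroupRef", ItemGroupOID=child.oid)


def _odm_root(file_oid: str) -> etree._Element:
    return etree.Element(
        f"{{{ODM_NS}}}ODM",
        nsmap={None: ODM_NS},
        FileOID=file_oid,
        FileType="Snapshot",
        ODMVersion="1.3.2",
        CreationDateTime="1970-01-01T00:00:00",
    )


def _emit_study(parent: etree._Element, study: OdmElement, defs, study_name: str) -> None:
    study_el = etree.SubElement(parent, f"{{{ODM_NS}}}Study", OID=study.oid)
    gv = etree.SubElement(study_el, f"{{{ODM_NS}}}GlobalVariables")
    for name in ("StudyName", "StudyDescription", "ProtocolName"):
        el = etree.SubElement(gv, f"{{{ODM_NS}}}{name}")
        el.text = study.attributes.get(name, "" if name != "StudyName" else study_name)
    units = defs.get(ResourceKind.MEASUREMENT_UNIT, {})
    if units:
        bd = etree.SubElement(study_el, f"{{{ODM_NS}}}BasicDefinitions")
        for oid in units:
            _emit_measurement_unit(bd, units[oid])
    mdv = etree.SubElement(
        study_el, f"{{{ODM_NS}}}MetaDataVersion", OID=f"MDV.{study.oid}", Name="Metadata"
    )
    for kind, emitter in (
        (ResourceKind.FORM, _emit_form_def),
        (ResourceKind.ITEM_GROUP, _emit_group_def),
        (ResourceKind.ITEM, _emit_item_def),
        (ResourceKind.CODE_LIST, _emit_codelist),
    ):
        for oid in defs.get(kind, {}):
            emitter(mdv, defs[kind][oid])


def write_odm(document: SourceDocument, path: str | Path | None = None) -> bytes:
    """Serialize a document back to ODM XML (and optionally write it).

    Forms are emitted as unreferenced FormDefs (no Protocol/StudyEvent
    scaffolding), which the parser re-attaches under the Study; the
    decomposition of the round-tripped document is unchanged.
    """
    root = _odm_root(document.document_id)
    for study in document.roots:
        defs = _collect_defs([study])
        defs.pop(ResourceKind.STUDY_EVENT, None)
        _emit_study(root, study, defs, document.origin_label or study.oid)
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        Path(path).write_bytes(data)
    return data


def serialize_fragment(element: OdmElement) -> str:
    """Standalone ODM fragment for one resource and its descendants.

    Refs are regenerated from the containment tree; the result reparses
    with :func:`parse_odm` to an element with the same canonical key.
    A bare CodeListItem is wrapped in a carrier CodeList (OID
    ``CL.__wrap__``) since ODM has no standalone representation for it.
    """
    if element.kind not in FRAGMENT_KINDS:
        raise KindError(f"cannot serialize {element.kind.value} as a fragment")
    if element.kind is ResourceKind.CODE_LIST_ITEM:
        carrier = OdmElement(
            kind=ResourceKind.CODE_LIST,
            oid="CL.__wrap__",
            attributes={"Name": "Fragment carrier", "DataType": "text"},
            children=[element],
        )
        return serialize_fragment(carrier)
    root = _odm_root("fragment")
    study = OdmElement(
        kind=ResourceKind.STUDY, oid="S.__fragment__",
        attributes={"StudyName": "Fragment"}, children=[element],
    )
    defs = _collect_defs([element])
    _emit_study(root, study, defs, "Fragment")
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return data.decode("utf-8")


def read_fragment(xml_source: bytes | str, kind: ResourceKind) -> OdmElement:
    """Parse a fragment back to the element of ``kind`` it carries."""
    doc = parse_odm(xml_source, document_id="fragment")
    for el, _path in decompose(doc):
        if el.kind is kind:
            return el
    raise IntegrityError(f"fragment contains no {kind.value} element")
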