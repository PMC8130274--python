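"""Shared fixtures: a hand-written ODM document and synthetic corpora."""

from __future__ import annotations

import pytest

from mdrepo import (
    MetadataStore,
    OdmElement,
    ResourceKind,
    SourceDocument,
    SynthConfig,
    build_index,
    canonical_serialize,
    generate_corpus,
)

# A small form in the style of a body-weight-classification CRF: one Study,
# a Protocol/StudyEvent chain, one Form -> ItemGroup -> Item with a code
# list, a UMLS alias, a range check and a measurement unit.
VITALS_ODM = """<?xml version="1.0" encoding="UTF-8"?>
<ODM xmlns="http://www.cdisc.org/ns/odm/v1.3" FileOID="vitals-1" FileType="Snapshot"
     ODMVersion="1.3.2" CreationDateTime="2020-01-01T00:00:00">
 <Study OID="S.VITALS">
  <GlobalVariables>
   <StudyName>Vital signs demo</StudyName>
   <StudyDescription>Example form</StudyDescription>
   <ProtocolName>VS</ProtocolName>
  </GlobalVariables>
  <BasicDefinitions>
   <MeasurementUnit OID="MU.KG" Name="kg">
    <Symbol><TranslatedText xml:lang="en">kg</TranslatedText></Symbol>
   </MeasurementUnit>
  </BasicDefinitions>
  <MetaDataVersion OID="MDV.1" Name="v1">
   <Protocol>
    <StudyEventRef StudyEventOID="SE.1" OrderNumber="1" Mandatory="Yes"/>
   </Protocol>
   <StudyEventDef OID="SE.1" Name="Baseline" Repeating="No" Type="Scheduled">
    <FormRef FormOID="F.VS" OrderNumber="1" Mandatory="Yes"/>
   </StudyEventDef>
   <FormDef OID="F.VS" Name="Vital signs" Repeating="No">
    <ItemGroupRef ItemGroupOID="IG.VS" OrderNumber="1" Mandatory="Yes"/>
   </FormDef>
   <ItemGroupDef OID="IG.VS" Name="Vital signs" Repeating="No">
    <ItemRef ItemOID="I.BWC" OrderNumber="1" Mandatory="Yes"/>
   </ItemGroupDef>
   <ItemDef OID="I.BWC" Name="Body weight classification" DataType="integer" Length="1">
    <Question>
     <TranslatedText xml:lang="en">Body weight classification</TranslatedText>
     <TranslatedText xml:lang="de">Klassifikation des Koerpergewichts</TranslatedText>
    </Question>
    <CodeListRef CodeListOID="CL.BWC"/>
    <MeasurementUnitRef MeasurementUnitOID="MU.KG"/>
    <RangeCheck Comparator="GE" SoftHard="Soft">
     <CheckValue>1</CheckValue>
     <MeasurementUnitRef MeasurementUnitOID="MU.KG"/>
    </RangeCheck>
    <Alias Context="UMLS" Name="C1305855"/>
   </ItemDef>
   <CodeList OID="CL.BWC" Name="Weight classes" DataType="integer">
    <CodeListItem CodedValue="1">
     <Decode><TranslatedText xml:lang="en">Underweight</TranslatedText></Decode>
    </CodeListItem>
    <CodeListItem CodedValue="2">
     <Decode><TranslatedText xml:lang="en">Normal weight</TranslatedText></Decode>
    </CodeListItem>
    <CodeListItem CodedValue="3">
     <Decode><TranslatedText xml:lang="en">Overweight</TranslatedText></Decode>
    </CodeListItem>
   </CodeList>
  </MetaDataVersion>
 </Study>
</ODM>
"""


@pytest.fixture
def vitals_xml() -> str:
    return VITALS_ODM


def make_item(oid: str, question: str, *, name: str = "", datatype: str = "text",
              lang: str = "en", children: list | None = None,
              aliases: list | None = None) -> OdmElement:
    return OdmElement(
        kind=ResourceKind.ITEM,
        oid=oid,
        attributes={"Name": name or question, "DataType": datatype},
        translated_texts={"Question": {lang: question}},
        aliases=aliases or [],
        children=children or [],
    )


def make_codelist(oid: str, decodes: list[str]) -> OdmElement:
    return OdmElement(
        kind=ResourceKind.CODE_LIST,
        oid=oid,
        attributes={"Name": oid, "DataType": "integer"},
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


def make_document(doc_id: str, items: list[OdmElement], *, form_oid: str = "F.1") -> SourceDocument:
    group = OdmElement(kind=ResourceKind.ITEM_GROUP, oid=f"IG.{form_oid}",
                       attributes={"Name": "Group", "Repeating": "No"}, children=items)
    form = OdmElement(kind=ResourceKind.FORM, oid=form_oid,
                      attributes={"Name": form_oid, "Repeating": "No"}, children=[group])
    study = OdmElement(kind=ResourceKind.STUDY, oid=f"S.{doc_id}",
                       attributes={"StudyName": doc_id}, children=[form])
    return SourceDocument(document_id=doc_id, origin_label=doc_id, roots=[study])


@pytest.fixture
def aggregation_scenario():
    """Two models sharing one item (with its code list): the shared pair
    aggregates to two occurrences, the distinct forms stay singletons."""
    codelist = make_codelist("CL.B", ["Yes", "No"])
    item_b = make_item("I.B", "Item B question", children=[codelist])
    import copy

    doc1 = make_document("model-1", [copy.deepcopy(item_b)], form_oid="F.A")
    doc2 = make_document("model-2", [copy.deepcopy(item_b)], form_oid="F.C")
    return doc1, doc2


def brute_force_counts(documents, *, ignore_oids: bool = False) -> dict[str, int]:
    """Independent dedup oracle: canonical serialization string -> count."""
    from mdrepo.odm import decompose

    counts: dict[str, int] = {}
    for doc in documents:
        for element, _path in decompose(doc):
            s = canonical_serialize(element, ignore_oids=ignore_oids)
            counts[s] = counts.get(s, 0) + 1
    return counts


@pytest.fixture(scope="session")
def small_corpus():
    """50-document corpus (~1000 elements) with ground-truth ledger."""
    config = SynthConfig(seed=42, n_documents=50)
    return generate_corpus(config)


@pytest.fixture(scope="session")
def ingested(small_corpus):
    documents, ledger = small_corpus
    store = MetadataStore()
    for doc in documents:
        store.ingest_document(doc)
    return store, build_index(store), ledger
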