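"""Read, write and validate gold-standard annotation XML.

The gold standard is a set of expert-annotated acknowledgement sections:
each document carries the paragraph text, the annotator's id, zero or more
donation annotations (donor, affiliation, resource label + name, free-form
attributes — gold may label resources other than antibodies, e.g. cell
lines or fly stocks), and any person/organization mentions that are *not*
part of a donation.  Several annotators may annotate the same document;
``merge_annotators`` groups the copies.

Schema (all leaf text UTF-8, character offsets deliberately optional):

.. code-block:: xml

    <documents>
      <document id="doc1" annotator="a1">
        <text>We thank K. Mackie (Indiana University) ...</text>
        <donation>
          <donor>K. Mackie</donor>
          <affiliation>Indiana University</affiliation>
          <resource label="antibody">CB1</resource>
          <attribute>polyclonal</attribute>
        </donation>
        <entity label="person">Doris Thelian</entity>
      </document>
    </documents>

``read_gold_xml`` accepts a ``dialect`` callable hook so that external
annotation files with a different element layout can be adapted without
touching the native reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "GoldDonation",
    "GoldDocument",
    "GoldValidationError",
    "read_gold_xml",
    "write_gold_xml",
    "merge_annotators",
]


class GoldValidationError(ValueError):
    """A gold file or document violates the schema invariants."""


@dataclass(frozen=True)
class GoldDonation:
    """One annotated resource donation."""

    resource_label: str
    donor: Optional[str] = None
    affiliation: Optional[str] = None
    resource_name: Optional[str] = None
    attributes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.resource_label:
            raise ValueError("resource_label must be non-empty")


@dataclass(frozen=True)
class GoldDocument:
    """All annotations of one acknowledgement by one annotator."""

    doc_id: str
    text: str
    annotator_id: str
    donations: tuple[GoldDonation, ...] = ()
    non_donation_entities: tuple[tuple[str, str], ...] = ()

    def annotated_strings(self) -> list[str]:
        out: list[str] = []
        for d in self.donations:
            out.extend(s for s in (d.donor, d.affiliation, d.resource_name) if s)
        out.extend(text for _label, text in self.non_donation_entities)
        return out


def _validate_substrings(doc: GoldDocument, strict: bool = False) -> list[str]:
    bad = [s for s in doc.annotated_strings() if s not in doc.text]
    if bad and strict:
        raise GoldValidationError(
            f"document {doc.doc_id!r}: annotations not found in text: {bad}"
        )
    for s in bad:
        logger.warning(
            "document %r: annotation %r is not a substring of the text",
            doc.doc_id,
            s,
        )
    return bad


def read_gold_xml(
    path: Union[str, Path],
    dialect: Optional[Callable[[etree._ElementTree], list[GoldDocument]]] = None,
) -> list[GoldDocument]:
    """Parse a gold file; every document loads or a located error is raised.

    Substring violations are reported as warnings with the offending doc id
    but the annotation is kept.  A ``dialect`` hook may take over the whole
    conversion for foreign schemas.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GoldValidationError(f"malformed XML in {path}: {exc}") from exc
    if dialect is not None:
        docs = dialect(tree)
    else:
        docs = _read_native(tree)
    for doc in docs:
        _validate_substrings(doc)
    return docs


def _read_native(tree: etree._ElementTree) -> list[GoldDocument]:
    root = tree.getroot()
    if root.tag != "documents":
        raise GoldValidationError(f"expected root <documents>, got <{root.tag}>")
    docs: list[GoldDocument] = []
    seen: set[tuple[str, str]] = set()
    for el in root.iter("document"):
        doc_id = el.get("id")
        annotator = el.get("annotator", "")
        if not doc_id:
            raise GoldValidationError("found <document> without an id attribute")
        text_el = el.find("text")
        if text_el is None or not (text_el.text or "").strip():
            raise GoldValidationError(f"document {doc_id!r} has no <text>")
        key = (doc_id, annotator)
        if key in seen:
            raise GoldValidationError(
                f"duplicate (doc_id, annotator) pair: {key}"
            )
        seen.add(key)
        donations = []
        for don in el.findall("donation"):
            res = don.find("resource")
            donations.append(
                GoldDonation(
                    resource_label=(res.get("label") if res is not None else None)
                    or "antibody",
                    resource_name=(res.text or "").strip() or None
                    if res is not None
                    else None,
                    donor=_leaf(don, "donor"),
                    affiliation=_leaf(don, "affiliation"),
                    attributes=frozenset(
                        (a.text or "").strip()
                        for a in don.findall("attribute")
                        if (a.text or "").strip()
                    ),
                )
            )
        entities = tuple(
            (ent.get("label", ""), (ent.text or "").strip())
            for ent in el.findall("entity")
            if (ent.text or "").strip()
        )
        docs.append(
            GoldDocument(
                doc_id=doc_id,
                text=text_el.text,
                annotator_id=annotator,
                donations=tuple(donations),
                non_donation_entities=entities,
            )
        )
    return docs


def _leaf(parent: etree._Element, tag: str) -> Optional[str]:
    el = parent.find(tag)
    if el is None:
        return None
    value = (el.text or "").strip()
    return value or None


def write_gold_xml(docs: list[GoldDocument], path: Union[str, Path]) -> None:
    """Serialize documents; invariants are checked before anything is written."""
    seen: set[tuple[str, str]] = set()
    for doc in docs:
        key = (doc.doc_id, doc.annotator_id)
        if key in seen:
            raise GoldValidationError(f"duplicate (doc_id, annotator) pair: {key}")
        seen.add(key)
        _validate_substrings(doc, strict=True)

    root = etree.Element("documents")
    for doc in docs:
        el = etree.SubElement(root, "document", id=doc.doc_id)
        if doc.annotator_id:
            el.set("annotator", doc.annotator_id)
        etree.SubElement(el, "text").text = doc.text
        for don in doc.donations:
            don_el = etree.SubElement(el, "donation")
            if don.donor:
                etree.SubElement(don_el, "donor").text = don.donor
            if don.affiliation:
                etree.SubElement(don_el, "affiliation").text = don.affiliation
            res_el = etree.SubElement(don_el, "resource", label=don.resource_label)
            if don.resource_name:
                res_el.text = don.resource_name
            for attr in sorted(don.attributes):
                etree.SubElement(don_el, "attribute").text = attr
        for label, text in doc.non_donation_entities:
            ent_el = etree.SubElement(el, "entity", label=label)
            ent_el.text = text
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )


def merge_annotators(docs: list[GoldDocument]) -> dict[str, list[GoldDocument]]:
    """Group documents by doc_id, preserving annotator separation."""
    groups: dict[str, list[GoldDocument]] = {}
    for doc in docs:
        groups.setdefault(doc.doc_id, []).append(doc)
    return groups
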