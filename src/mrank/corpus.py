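"""Parse SBML documents, extract MIRIAM annotations, classify into features.

A model is treated as a tuple of machine-readable source and annotation
information.  The source contributes element names and ids, notes, persons
and dates; the annotations contribute qualifier-typed MIRIAM URNs such as
``urn:miriam:obo.chebi:CHEBI%3A18021``.  ``featurize`` splits a parsed model
into (feature, term-multiset) and (feature, URI-entry) assignments — the
per-model representation every index in this package is built from.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass, field

from lxml import etree

from mrank.tokens import QUALIFIER_NAMES, URNError, normalize_urn, split_urn, tokenize

logger = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
DC_NS = "http://purl.org/dc/elements/1.1/"
DCTERMS_NS = "http://purl.org/dc/terms/"
VCARD_NS = "http://www.w3.org/2001/vcard-rdf/3.0#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"

_QUALIFIER_VOCAB = {BQBIOL_NS: "bqbiol", BQMODEL_NS: "bqmodel"}

#: Namespaces whose model-level isDescribedBy annotations denote the
#: reference publication rather than the model's own identity.
PUBLICATION_NAMESPACES = frozenset({"pubmed", "doi", "isbn"})

ELEMENT_KINDS = ("species", "compartment", "reaction", "parameter", "event", "function")

# SBML tag local-name per element kind.
_KIND_TAGS = {
    "species": "species",
    "compartment": "compartment",
    "reaction": "reaction",
    "parameter": "parameter",
    "event": "event",
    "function": "functionDefinition",
}


class SBMLParseError(ValueError):
    """Malformed XML or a document without an SBML model element."""


@dataclass(frozen=True)
class Annotation:
    """One MIRIAM triplet: (data type, identifier, qualifier).

    ``uri`` is the canonical URN text; ``identifier`` is stored decoded
    (``CHEBI:18021``), ``data_type`` lowercased (``obo.chebi``).
    """

    uri: str
    data_type: str
    identifier: str
    qualifier: str
    vocabulary: str = "bqbiol"

    @property
    def qualified(self) -> str:
        """Vocabulary-prefixed qualifier, e.g. ``bqbiol_is``."""
        return f"{self.vocabulary}_{self.qualifier}"

    @classmethod
    def from_urn(cls, urn: str, qualifier: str, vocabulary: str = "bqbiol") -> "Annotation":
        namespace, identifier = split_urn(urn)
        return cls(
            uri=normalize_urn(urn),
            data_type=namespace,
            identifier=identifier,
            qualifier=qualifier,
            vocabulary=vocabulary,
        )


@dataclass
class ModelElement:
    element_kind: str
    element_id: str
    element_name: str = ""
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind: {self.element_kind!r}")
        if not self.element_id:
            raise ValueError("element_id must be non-empty")


@dataclass
class AnnotatedModel:
    """A parsed model plus everything its annotations say about it."""

    model_id: str
    source_format: str = "SBML-L2"
    name: str = ""
    description_text: str = ""
    elements: list[ModelElement] = field(default_factory=list)
    model_level_annotations: list[Annotation] = field(default_factory=list)
    creation_date: _dt.date | None = None
    modification_date: _dt.date | None = None
    persons: list[tuple[str, str]] = field(default_factory=list)  # (role, name)
    publication: tuple[str, str] = ("", "")  # (uri, free text)
    file_path: str = ""
    additional_ids: list[str] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)

    def elements_of(self, kind: str) -> list[ModelElement]:
        return [e for e in self.elements if e.element_kind == kind]


# ---------------------------------------------------------------------------
# Feature schema


DIMENSIONS = (
    "constituents",
    "persons",
    "dates",
    "publication",
    "user_content",
    "administrative",
)

#: element kind -> description feature / URI feature
DESCRIPTION_FEATURES = {k: k for k in ELEMENT_KINDS}
URI_FEATURES = {k: f"{k}URI" for k in ELEMENT_KINDS}


@dataclass(frozen=True)
class FeatureSchema:
    """The set of indexable features and the dimension each belongs to."""

    dimensions: dict[str, str]  # feature -> dimension

    def __post_init__(self) -> None:
        bad = set(self.dimensions.values()) - set(DIMENSIONS)
        if bad:
            raise ValueError(f"unknown dimensions: {sorted(bad)}")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.dimensions)

    def __contains__(self, feature: str) -> bool:
        return feature in self.dimensions

    def constituent_term_features(self) -> tuple[str, ...]:
        """Description features of the constituents dimension (term-valued)."""
        return tuple(
            f
            for f, d in self.dimensions.items()
            if d == "constituents" and not f.endswith("URI")
        )


def default_schema() -> FeatureSchema:
    dims: dict[str, str] = {}
    for f in ("modelName", *ELEMENT_KINDS, "modelDescription"):
        dims[f] = "constituents"
    for f in ("modelURI", *URI_FEATURES.values()):
        dims[f] = "constituents"
    for f in ("author", "encoder", "submitter"):
        dims[f] = "persons"
    dims["publicationURI"] = "publication"
    dims["publicationText"] = "publication"
    dims["content"] = "user_content"
    dims["creationDate"] = "dates"
    dims["modificationDate"] = "dates"
    for f in ("id", "additionalID", "path"):
        dims[f] = "administrative"
    return FeatureSchema(dims)


DEFAULT_SCHEMA = default_schema()


# ---------------------------------------------------------------------------
# Dates


def parse_date(text: str) -> _dt.date:
    """Parse a day-precision date from ISO-8601 (prefix) or dd/MM/yyyy."""
    text = text.strip()
    if "/" in text:
        return _dt.datetime.strptime(text, "%d/%m/%Y").date()
    return _dt.date.fromisoformat(text[:10])


# ---------------------------------------------------------------------------
# SBML parsing


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) and tag[0] == "{" else str(tag)


def _find_by_local(parent, name: str):
    for child in parent:
        if isinstance(child.tag, str) and etree.QName(child).localname == name:
            yield child


def _parse_rdf_annotations(element) -> list[Annotation]:
    """Collect MIRIAM annotations from an element's <annotation> block."""
    out: list[Annotation] = []
    for ann in _find_by_local(element, "annotation"):
        for node in ann.iter():
            if not isinstance(node.tag, str):
                continue
            qname = etree.QName(node)
            vocab = _QUALIFIER_VOCAB.get(qname.namespace)
            if vocab is None:
                continue
            qualifier = qname.localname
            if qualifier not in QUALIFIER_NAMES:
                logger.warning("skipping unknown qualifier %r", qualifier)
                continue
            for li in node.iter(f"{{{RDF_NS}}}li"):
                resource = li.get(f"{{{RDF_NS}}}resource")
                if not resource:
                    continue
                try:
                    out.append(Annotation.from_urn(resource, qualifier, vocab))
                except URNError:
                    logger.warning("skipping non-MIRIAM resource %r", resource)
    return out


def _sbo_annotation(element) -> Annotation | None:
    sbo = element.get("sboTerm")
    if not sbo:
        return None
    return Annotation(
        uri=normalize_urn(f"urn:miriam:biomodels.sbo:{sbo}"),
        data_type="biomodels.sbo",
        identifier=sbo,
        qualifier="is",
        vocabulary="bqbiol",
    )


def _text_content(node) -> str:
    return " ".join(" ".join(node.itertext()).split())


def _parse_model_header(model_node, model: AnnotatedModel) -> None:
    """Model-level RDF: creators, dates, publication reference."""
    for ann in _find_by_local(model_node, "annotation"):
        for created in ann.iter(f"{{{DCTERMS_NS}}}created"):
            for w3c in created.iter(f"{{{DCTERMS_NS}}}W3CDTF"):
                model.creation_date = parse_date(w3c.text or "")
        for modified in ann.iter(f"{{{DCTERMS_NS}}}modified"):
            for w3c in modified.iter(f"{{{DCTERMS_NS}}}W3CDTF"):
                model.modification_date = parse_date(w3c.text or "")
        for creator in ann.iter(f"{{{DC_NS}}}creator"):
            for n in creator.iter(f"{{{VCARD_NS}}}N"):
                family = given = ""
                for part in n.iter(f"{{{VCARD_NS}}}Family"):
                    family = (part.text or "").strip()
                for part in n.iter(f"{{{VCARD_NS}}}Given"):
                    given = (part.text or "").strip()
                name = " ".join(p for p in (given, family) if p)
                if name:
                    model.persons.append(("author", name))


def parse_model(document: str | bytes, model_id: str) -> AnnotatedModel:
    """Parse one SBML document into an :class:`AnnotatedModel`.

    Raises :class:`SBMLParseError` for malformed XML or a document without
    an SBML ``model`` element.  Annotations with unknown qualifiers or
    non-MIRIAM resources are skipped with a logged warning.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"{model_id}: malformed XML ({exc})") from exc
    if etree.QName(root).localname != "sbml" or "sbml.org" not in (
        etree.QName(root).namespace or ""
    ):
        raise SBMLParseError(f"{model_id}: root element is not SBML")
    model_nodes = list(_find_by_local(root, "model"))
    if not model_nodes:
        raise SBMLParseError(f"{model_id}: no model element")
    mnode = model_nodes[0]

    level = root.get("level", "2")
    model = AnnotatedModel(model_id=model_id, source_format=f"SBML-L{level}")
    model.name = mnode.get("name", "") or ""

    for notes in _find_by_local(mnode, "notes"):
        model.description_text = _text_content(notes)

    _parse_model_header(mnode, model)

    raw_model_annotations = _parse_rdf_annotations(mnode)
    sbo = _sbo_annotation(mnode)
    if sbo is not None:
        raw_model_annotations.append(sbo)
    for a in raw_model_annotations:
        if a.qualifier == "isDescribedBy" and a.data_type in PUBLICATION_NAMESPACES:
            if not model.publication[0]:
                model.publication = (a.uri, model.publication[1])
        else:
            model.model_level_annotations.append(a)

    for kind, tag in _KIND_TAGS.items():
        for node in mnode.iter():
            if not isinstance(node.tag, str) or etree.QName(node).localname != tag:
                continue
            elem = ModelElement(
                element_kind=kind,
                element_id=node.get("id", "") or node.get("metaid", "") or f"{kind}_?",
                element_name=node.get("name", "") or "",
            )
            elem.annotations = _parse_rdf_annotations(node)
            esbo = _sbo_annotation(node)
            if esbo is not None:
                elem.annotations.append(esbo)
            model.elements.append(elem)
    return model


def extract_annotations(
    model: AnnotatedModel,
) -> list[tuple[str | None, Annotation]]:
    """Flat list of (element id or None for the model itself, annotation).

    URNs are already normalized at parse time; duplicates are retained.
    """
    out: list[tuple[str | None, Annotation]] = [
        (None, a) for a in model.model_level_annotations
    ]
    for element in model.elements:
        out.extend((element.element_id, a) for a in element.annotations)
    return out


# ---------------------------------------------------------------------------
# Featurization


@dataclass
class ModelRepresentation:
    """A model split into per-feature term multisets and URI entries."""

    model_id: str
    assignments: dict[str, Counter] = field(default_factory=dict)
    uri_assignments: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def terms(self, feature: str) -> Counter:
        return self.assignments.get(feature, Counter())


def featurize(model: AnnotatedModel, schema: FeatureSchema = DEFAULT_SCHEMA) -> ModelRepresentation:
    """Map a parsed model onto the feature schema.

    Element names are tokenized into the feature of their kind, with the
    element id as fallback token for unnamed elements (the ``re1``-style
    auto-generated names).  URNs land in the matching URI feature together
    with their vocabulary-prefixed qualifier.
    """
    rep = ModelRepresentation(model_id=model.model_id)

    def add_terms(feature: str, tokens: list[str]) -> None:
        if tokens and feature in schema:
            rep.assignments.setdefault(feature, Counter()).update(tokens)

    def add_uri(feature: str, uri: str, qualified: str) -> None:
        if feature in schema:
            rep.uri_assignments.setdefault(feature, []).append((uri, qualified))

    for element in model.elements:
        tokens = tokenize(element.element_name) or tokenize(element.element_id)
        add_terms(DESCRIPTION_FEATURES[element.element_kind], tokens)
        for a in element.annotations:
            add_uri(URI_FEATURES[element.element_kind], a.uri, a.qualified)

    add_terms("modelName", tokenize(model.name or model.model_id))
    add_terms("modelDescription", tokenize(model.description_text))
    for a in model.model_level_annotations:
        add_uri("modelURI", a.uri, a.qualified)

    for role, name in model.persons:
        if role in ("author", "encoder", "submitter"):
            add_terms(role, tokenize(name))

    pub_uri, pub_text = model.publication
    if pub_uri:
        add_uri("publicationURI", pub_uri, "bqmodel_isDescribedBy")
    add_terms("publicationText", tokenize(pub_text))

    if model.creation_date is not None:
        add_terms("creationDate", [model.creation_date.isoformat()])
    if model.modification_date is not None:
        add_terms("modificationDate", [model.modification_date.isoformat()])

    add_terms("id", tokenize(model.model_id))
    for extra in model.additional_ids:
        add_terms("additionalID", tokenize(extra))
    add_terms("path", tokenize(model.file_path))
    for tag in model.tags:
        add_terms("content", tokenize(tag))

    return rep
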