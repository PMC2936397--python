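"""Deterministic fixtures: synthetic annotated-SBML corpora, the worked
caffeine example, an offline lexicon and a mini-ontology.

Everything here is generated from explicit seeds and packaged text so the
rest of the package is testable without network access.  Generated SBML is
Level 2 Version 4 with RDF annotations in the BioModels style and must
re-parse through :mod:`mrank.corpus` with zero warnings.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field
from importlib import resources

from mrank.ontology import OntologyGraph, load_obo
from mrank.semantic_index import Lexicon

SBML_NS = "http://www.sbml.org/sbml/level2/version4"

_RDF_XMLNS = (
    'xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#" '
    'xmlns:dc="http://purl.org/dc/elements/1.1/" '
    'xmlns:dcterms="http://purl.org/dc/terms/" '
    'xmlns:vCard="http://www.w3.org/2001/vcard-rdf/3.0#" '
    'xmlns:bqbiol="http://biomodels.net/biology-qualifiers/" '
    'xmlns:bqmodel="http://biomodels.net/model-qualifiers/"'
)

# ---------------------------------------------------------------------------
# Built-in vocabulary for the synthetic generator: (name, URN, lexicon text)

SPECIES_VOCAB: list[tuple[str, str, str]] = [
    ("caffeine", "urn:miriam:obo.chebi:CHEBI%3A27732",
     "caffeine 1,3,7-trimethylxanthine purine alkaloid stimulant c8h10n4o2"),
    ("xanthine", "urn:miriam:kegg.compound:C00385",
     "xanthine purine base c5h4n4o2 caffeine metabolism"),
    ("theobromine", "urn:miriam:obo.chebi:CHEBI%3A28946",
     "theobromine 3,7-dimethylxanthine cacao alkaloid c7h8n4o2"),
    ("glucose", "urn:miriam:obo.chebi:CHEBI%3A17234",
     "glucose dextrose aldohexose sugar c6h12o6"),
    ("atp", "urn:miriam:obo.chebi:CHEBI%3A15422",
     "atp adenosine triphosphate nucleotide energy currency c10h16n5o13p3"),
    ("calcium", "urn:miriam:obo.chebi:CHEBI%3A29108",
     "calcium ca2 cation second messenger signalling ion"),
    ("pyruvate", "urn:miriam:obo.chebi:CHEBI%3A15361",
     "pyruvate pyruvic acid 2-oxopropanoate glycolysis c3h4o3"),
    ("phosphoenolpyruvate", "urn:miriam:obo.chebi:CHEBI%3A18021",
     "phosphoenolpyruvate pep 2-phosphoenolpyruvate glycolysis c3h5o6p"),
    ("cyclic amp", "urn:miriam:obo.chebi:CHEBI%3A17489",
     "cyclic amp camp adenosine 3 5 monophosphate second messenger"),
    ("glutathione", "urn:miriam:obo.chebi:CHEBI%3A16856",
     "glutathione gsh tripeptide antioxidant thiol c10h17n3o6s"),
]

COMPARTMENT_VOCAB: list[tuple[str, str, str]] = [
    ("cytosol", "urn:miriam:obo.go:GO%3A0005829", "cytosol cytoplasm intracellular fluid"),
    ("nucleus", "urn:miriam:obo.go:GO%3A0005634", "nucleus nuclear organelle chromatin"),
    ("mitochondrion", "urn:miriam:obo.go:GO%3A0005739",
     "mitochondrion mitochondria organelle respiration"),
    ("gut", "urn:miriam:obo.bto:BTO%3A0000545",
     "gut intestine gastrointestinal tract digestive"),
    ("plasma membrane", "urn:miriam:obo.go:GO%3A0005886",
     "plasma membrane cell membrane lipid bilayer"),
]

REACTION_VOCAB: list[tuple[str, str, str]] = [
    ("hexokinase activity", "urn:miriam:obo.go:GO%3A0004396",
     "hexokinase activity glucose phosphorylation atp kinase"),
    ("glycolysis", "urn:miriam:obo.go:GO%3A0006096",
     "glycolysis glycolytic process glucose catabolism pyruvate"),
    ("calcium ion transport", "urn:miriam:obo.go:GO%3A0006816",
     "calcium ion transport channel flux signalling"),
    ("caffeine metabolic process", "urn:miriam:obo.go:GO%3A0009822",
     "caffeine metabolic process alkaloid catabolism demethylation"),
    ("protein phosphorylation", "urn:miriam:obo.go:GO%3A0006468",
     "protein phosphorylation kinase signalling cascade"),
]

AUTHOR_POOL = [
    ("Jane", "Roe"),
    ("Richard", "Miles"),
    ("Ada", "Stone"),
    ("Tomas", "Novak"),
    ("Mei", "Chen"),
    ("Lars", "Berg"),
]

DEFAULT_QUALIFIER_MIX: dict[str, float] = {
    "is": 0.55,
    "isVersionOf": 0.20,
    "hasPart": 0.10,
    "hasVersion": 0.05,
    "isDescribedBy": 0.10,
}


def default_lexicon() -> Lexicon:
    """Lexicon over the whole built-in generator vocabulary."""
    entries = {
        urn: text
        for _name, urn, text in SPECIES_VOCAB + COMPARTMENT_VOCAB + REACTION_VOCAB
    }
    return Lexicon.from_json(json.dumps(entries))


def xanthine_ontology() -> OntologyGraph:
    """The packaged mini-ontology of the xanthine family."""
    text = (resources.files("mrank.data") / "xanthines.obo").read_text()
    return load_obo(text)


# ---------------------------------------------------------------------------
# SBML emission


def _annotation_block(metaid: str, entries: list[tuple[str, str, str]], indent: str) -> str:
    """RDF block for (vocabulary, qualifier, urn) triplets on one element."""
    if not entries:
        return ""
    by_qualifier: dict[tuple[str, str], list[str]] = {}
    for vocab, qualifier, urn in entries:
        by_qualifier.setdefault((vocab, qualifier), []).append(urn)
    lines = [
        f"{indent}<annotation>",
        f"{indent}  <rdf:RDF {_RDF_XMLNS}>",
        f'{indent}    <rdf:Description rdf:about="#{metaid}">',
    ]
    for (vocab, qualifier), urns in by_qualifier.items():
        lines.append(f"{indent}      <{vocab}:{qualifier}>")
        lines.append(f"{indent}        <rdf:Bag>")
        for urn in urns:
            lines.append(f'{indent}          <rdf:li rdf:resource="{urn}"/>')
        lines.append(f"{indent}        </rdf:Bag>")
        lines.append(f"{indent}      </{vocab}:{qualifier}>")
    lines.append(f"{indent}    </rdf:Description>")
    lines.append(f"{indent}  </rdf:RDF>")
    lines.append(f"{indent}</annotation>")
    return "\n".join(lines) + "\n"


def _model_header_block(
    metaid: str,
    authors: list[tuple[str, str]],
    created: _dt.date,
    modified: _dt.date,
    publication_urn: str | None,
) -> str:
    creator_lines = []
    for given, family in authors:
        creator_lines.append(
            "          <rdf:li rdf:parseType=\"Resource\">\n"
            "            <vCard:N rdf:parseType=\"Resource\">\n"
            f"              <vCard:Family>{family}</vCard:Family>\n"
            f"              <vCard:Given>{given}</vCard:Given>\n"
            "            </vCard:N>\n"
            "          </rdf:li>"
        )
    creators = "\n".join(creator_lines)
    pub = ""
    if publication_urn:
        pub = (
            "        <bqmodel:isDescribedBy>\n"
            "          <rdf:Bag>\n"
            f'            <rdf:li rdf:resource="{publication_urn}"/>\n'
            "          </rdf:Bag>\n"
            "        </bqmodel:isDescribedBy>\n"
        )
    return (
        "    <annotation>\n"
        f"      <rdf:RDF {_RDF_XMLNS}>\n"
        f'        <rdf:Description rdf:about="#{metaid}">\n'
        "        <dc:creator>\n"
        "          <rdf:Bag>\n"
        f"{creators}\n"
        "          </rdf:Bag>\n"
        "        </dc:creator>\n"
        '        <dcterms:created rdf:parseType="Resource">\n'
        f"          <dcterms:W3CDTF>{created.isoformat()}T00:00:00Z</dcterms:W3CDTF>\n"
        "        </dcterms:created>\n"
        '        <dcterms:modified rdf:parseType="Resource">\n'
        f"          <dcterms:W3CDTF>{modified.isoformat()}T00:00:00Z</dcterms:W3CDTF>\n"
        "        </dcterms:modified>\n"
        f"{pub}"
        "        </rdf:Description>\n"
        "      </rdf:RDF>\n"
        "    </annotation>\n"
    )


@dataclass
class _Element:
    tag: str  # SBML tag name
    elem_id: str
    name: str = ""
    annotations: list[tuple[str, str, str]] = field(default_factory=list)
    extra_attrs: str = ""

    def render(self, indent: str) -> str:
        name_attr = f' name="{self.name}"' if self.name else ""
        metaid = f"meta_{self.elem_id}"
        if not self.annotations:
            return f'{indent}<{self.tag} metaid="{metaid}" id="{self.elem_id}"{name_attr}{self.extra_attrs}/>\n'
        body = _annotation_block(metaid, self.annotations, indent + "  ")
        return (
            f'{indent}<{self.tag} metaid="{metaid}" id="{self.elem_id}"{name_attr}{self.extra_attrs}>\n'
            f"{body}{indent}</{self.tag}>\n"
        )


def _render_sbml(
    model_id: str,
    name: str,
    notes: str,
    authors: list[tuple[str, str]],
    created: _dt.date,
    modified: _dt.date,
    publication_urn: str | None,
    compartments: list[_Element],
    species: list[_Element],
    reactions: list[_Element],
    parameters: list[_Element] | None = None,
) -> str:
    parameters = parameters or []
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<sbml xmlns="{SBML_NS}" level="2" version="4">\n',
        f'  <model metaid="meta_{model_id}" id="{model_id}" name="{name}">\n',
        "    <notes>\n"
        '      <body xmlns="http://www.w3.org/1999/xhtml">\n'
        f"        <p>{notes}</p>\n"
        "      </body>\n"
        "    </notes>\n",
        _model_header_block(f"meta_{model_id}", authors, created, modified, publication_urn),
    ]
    if compartments:
        parts.append("    <listOfCompartments>\n")
        parts.extend(c.render("      ") for c in compartments)
        parts.append("    </listOfCompartments>\n")
    if species:
        parts.append("    <listOfSpecies>\n")
        parts.extend(s.render("      ") for s in species)
        parts.append("    </listOfSpecies>\n")
    if parameters:
        parts.append("    <listOfParameters>\n")
        parts.extend(p.render("      ") for p in parameters)
        parts.append("    </listOfParameters>\n")
    if reactions:
        parts.append("    <listOfReactions>\n")
        parts.extend(r.render("      ") for r in reactions)
        parts.append("    </listOfReactions>\n")
    parts.append("  </model>\n</sbml>\n")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Synthetic corpus generator


@dataclass
class GeneratorSpec:
    """Conditions under which a synthetic corpus is generated.

    With the defaults most eligible elements carry one MIRIAM annotation
    and qualifiers are dominated by ``is``, mirroring a curated repository
    where identity annotations are the rule.
    """

    n_models: int = 10
    seed: int = 0
    annotation_density: float = 0.9
    qualifier_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QUALIFIER_MIX)
    )

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0.0 <= self.annotation_density <= 1.0:
            raise ValueError("annotation_density must be in [0, 1]")


def gen_corpus(spec: GeneratorSpec) -> list[tuple[str, str]]:
    """Generate ``spec.n_models`` annotated SBML documents.

    Identical specs produce byte-identical output: a single
    ``random.Random(seed)`` stream drives every draw and the XML is
    templated text, never serializer-dependent.
    """
    rng = random.Random(spec.seed)
    qualifiers = sorted(spec.qualifier_mix)
    weights = [spec.qualifier_mix[q] for q in qualifiers]
    out: list[tuple[str, str]] = []

    def maybe_annotate(urn: str) -> list[tuple[str, str, str]]:
        # draw both numbers unconditionally so corpus structure is
        # independent of the density parameter
        coin = rng.random()
        qualifier = rng.choices(qualifiers, weights=weights)[0]
        if coin < spec.annotation_density:
            vocab = "bqmodel" if qualifier == "isDescribedBy" else "bqbiol"
            return [(vocab, qualifier, urn)]
        return []

    for i in range(1, spec.n_models + 1):
        model_id = f"SYN{i:07d}"
        reaction_choices = rng.sample(REACTION_VOCAB, rng.randint(1, 3))
        species_choices = rng.sample(SPECIES_VOCAB, rng.randint(2, 5))
        compartment_choices = rng.sample(COMPARTMENT_VOCAB, rng.randint(1, 2))
        name = f"Model of {reaction_choices[0][0]}"
        notes = (
            f"Synthetic model describing {reaction_choices[0][0]} involving "
            f"{species_choices[0][0]}."
        )
        authors = rng.sample(AUTHOR_POOL, rng.randint(1, 2))
        created = _dt.date(2007, 1, 1) + _dt.timedelta(days=rng.randrange(1400))
        modified = created + _dt.timedelta(days=rng.randrange(400))
        publication = (
            f"urn:miriam:pubmed:{rng.randrange(10000000, 20000000)}"
            if rng.random() < 0.8
            else None
        )

        compartments = []
        for j, (cname, curn, _txt) in enumerate(compartment_choices, 1):
            compartments.append(
                _Element("compartment", f"c{j}", cname, maybe_annotate(curn))
            )
        species = []
        for j, (sname, surn, _txt) in enumerate(species_choices, 1):
            # every fourth species keeps only its auto-generated id, like
            # the semantically poor names common in deposited models
            shown = "" if j % 4 == 0 else sname
            species.append(
                _Element(
                    "species",
                    f"s{j}",
                    shown,
                    maybe_annotate(surn),
                    extra_attrs=' compartment="c1"',
                )
            )
        reactions = []
        for j, (rname, rurn, _txt) in enumerate(reaction_choices, 1):
            shown = "" if j % 3 == 0 else rname
            reactions.append(_Element("reaction", f"re{j}", shown, maybe_annotate(rurn)))
        parameters = []
        if rng.random() < 0.5:
            parameters.append(
                _Element("parameter", "k1", "rate constant", [], extra_attrs=' value="0.1"')
            )

        out.append(
            (
                model_id,
                _render_sbml(
                    model_id,
                    name,
                    notes,
                    authors,
                    created,
                    modified,
                    publication,
                    compartments,
                    species,
                    reactions,
                    parameters,
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Worked example (caffeine)


#: The advanced-search expression of the caffeine example: the species must
#: be exactly caffeine (is-qualified), the compartment should be gut, the
#: author must not be John Doe, submission from 2009 on.
WORKED_EXAMPLE_QUERY = (
    "+species@is:(caffeine) compartment:(gut) -author:(john doe) "
    "date:([01/01/2009 - *])"
)

CHEBI_CAFFEINE = "urn:miriam:obo.chebi:CHEBI%3A27732"
KEGG_CAFFEINE = "urn:miriam:kegg.compound:C07481"
KEGG_XANTHINE = "urn:miriam:kegg.compound:C00385"
KEGG_GLYOXYLATE = "urn:miriam:kegg.compound:C00048"


def worked_example_lexicon() -> Lexicon:
    """Packaged four-entry lexicon for the caffeine example.

    The content strings carry the resolved keyword streams for the two
    caffeine entries (ChEBI and KEGG), plus xanthine and glyoxylate —
    names, synonyms, formulae and cross-reference text as a resolver would
    return them.
    """
    text = (resources.files("mrank.data") / "worked_example_lexicon.json").read_text()
    return Lexicon.from_json(text)


def worked_example_fixture() -> tuple[list[tuple[str, str]], Lexicon, OntologyGraph]:
    """(corpus, lexicon, ontology) realizing the caffeine worked example.

    Three models: A links both caffeine URIs via ``is`` and encodes a gut
    compartment; B links xanthine via ``is``; C links xanthine and
    glyoxylate only via ``isVersionOf`` — a deliberately weak,
    synthetic stand-in for the faint match ranked last in the example.
    """
    model_a = _render_sbml(
        "modelA",
        "Caffeine intestinal absorption",
        "Absorption of caffeine from the gut after oral intake.",
        [("Jane", "Roe")],
        _dt.date(2009, 6, 15),
        _dt.date(2009, 8, 1),
        "urn:miriam:pubmed:19189362",
        compartments=[_Element("compartment", "c1", "gut")],
        species=[
            _Element("species", "sp_1", "", [("bqbiol", "is", CHEBI_CAFFEINE)],
                     extra_attrs=' compartment="c1"'),
            _Element("species", "sp_2", "", [("bqbiol", "is", KEGG_CAFFEINE)],
                     extra_attrs=' compartment="c1"'),
        ],
        reactions=[_Element("reaction", "re1", "absorption")],
    )
    model_b = _render_sbml(
        "modelB",
        "Xanthine oxidation",
        "Oxidation of xanthine in hepatocytes.",
        [("Richard", "Miles")],
        _dt.date(2009, 3, 1),
        _dt.date(2009, 4, 2),
        "urn:miriam:pubmed:18234919",
        compartments=[_Element("compartment", "c1", "liver")],
        species=[
            _Element("species", "x1", "", [("bqbiol", "is", KEGG_XANTHINE)],
                     extra_attrs=' compartment="c1"'),
        ],
        reactions=[_Element("reaction", "re1", "oxidation")],
    )
    model_c = _render_sbml(
        "modelC",
        "Purine degradation",
        "Generic purine degradation pathway.",
        [("Ada", "Stone")],
        _dt.date(2009, 2, 10),
        _dt.date(2009, 2, 20),
        "urn:miriam:pubmed:17912369",
        compartments=[_Element("compartment", "c1", "hepatocyte")],
        species=[
            _Element("species", "p1", "", [("bqbiol", "isVersionOf", KEGG_XANTHINE)],
                     extra_attrs=' compartment="c1"'),
            _Element("species", "p2", "", [("bqbiol", "isVersionOf", KEGG_GLYOXYLATE)],
                     extra_attrs=' compartment="c1"'),
        ],
        reactions=[_Element("reaction", "re1", "degradation")],
    )
    corpus = [("modelA", model_a), ("modelB", model_b), ("modelC", model_c)]
    return corpus, worked_example_lexicon(), xanthine_ontology()
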