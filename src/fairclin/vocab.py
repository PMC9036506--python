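"""Pinned vocabulary constants: namespaces and the term table used by the RDF models.

This is the single versioned constants table for the ontological data model,
the severity-score module, and the DCAT2-based metadata extension. Every class
and predicate the RDFizer or metadata builder emits is named here, so tests
can assert against stable IRIs and downstream deployments can swap a term by
editing one place.

Ontology term choice
--------------------
Terms come from the vocabularies a clinical FAIRification stack normally
draws on: RDF(S), XSD, Dublin Core, DCAT2, FOAF, PROV-O, SIO, OBO ontologies
(NCIT, OBI, CMO, RO, MONDO, UO), EFO, the DataCite ontology, the Allotrope
namespace, and a study-specific namespace (``bco:``) for classes that have no
published term. Widely-used IRIs (e.g. ``obo:RO_0000086`` *has quality*,
``obo:MONDO_0100096`` *COVID-19*, ``obo:OBI_0000299`` *has specified
output*) are used verbatim; where an exact released term id is not publicly
pinned (the per-analyte measurement classes, the generic fallback classes,
the two Allotrope properties) the table carries a documented default under
the correct namespace. Nothing is resolved over the network at runtime.
"""

from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import DCAT, DCTERMS, FOAF, PROV, RDF, RDFS, SKOS, XSD

__all__ = [
    "OBO", "SIO", "EFO", "AFO", "UP", "UPTAXON", "UNIPROT", "DATACITE", "BCO",
    "PREFIXES", "DEFAULT_BASE_IRI",
]

# ---------------------------------------------------------------------------
# Namespaces
# ---------------------------------------------------------------------------

OBO = Namespace("http://purl.obolibrary.org/obo/")
SIO = Namespace("http://semanticscience.org/resource/")
EFO = Namespace("http://www.ebi.ac.uk/efo/")
AFO = Namespace("http://purl.allotrope.org/ontologies/common#")
UP = Namespace("http://purl.uniprot.org/core/")
UPTAXON = Namespace("http://purl.uniprot.org/taxonomy/")
UNIPROT = Namespace("http://purl.uniprot.org/uniprot/")
DATACITE = Namespace("http://purl.org/spar/datacite/")
#: Study-specific namespace for classes with no published ontology term.
BCO = Namespace("https://w3id.org/fair-clinical-cytokines/ontology#")

#: Default GUPRID minting base, modelled on a W3ID persistent-identifier base.
DEFAULT_BASE_IRI = "https://w3id.org/fair-clinical-cytokines/"

#: Prefix map used for all serializations; emitted in alphabetical order.
PREFIXES: dict[str, str] = {
    "afo": str(AFO),
    "bco": str(BCO),
    "datacite": str(DATACITE),
    "dcat": str(DCAT),
    "dct": str(DCTERMS),
    "efo": str(EFO),
    "foaf": str(FOAF),
    "obo": str(OBO),
    "prov": str(PROV),
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "sio": str(SIO),
    "skos": str(SKOS),
    "up": str(UP),
    "uniprot": str(UNIPROT),
    "uptaxon": str(UPTAXON),
    "xsd": str(XSD),
}

# ---------------------------------------------------------------------------
# Measurement data model (process-centred: every datum is a process output)
# ---------------------------------------------------------------------------

PATIENT_CLASS = OBO.NCIT_C16960          # Patient
SPECIMEN_CLASS = OBO.OBI_0100051         # specimen (the biosample)
AGE_CLASS = OBO.NCIT_C25150              # Age

HAS_VALUE = SIO.SIO_000300               # has value
HAS_ATTRIBUTE = SIO.SIO_000008           # has attribute
HAS_UNIT = SIO.SIO_000221                # has unit
HAS_SPECIFIED_INPUT = OBO.OBI_0000293    # has specified input
HAS_SPECIFIED_OUTPUT = OBO.OBI_0000299   # has specified output

#: Single configured unit term for cytokine concentrations (pg/mL).
UNIT_PG_PER_ML = OBO.UO_0000205

#: Generic fallback datum class for interleukin analytes with no specific
#: term: "blood interleukin measurement" (pinned default CMO id; swappable).
GENERIC_INTERLEUKIN_DATUM = OBO.CMO_0000745
#: Generic fallback process class "Cytokine Measurement" (pinned default
#: NCIT id; swappable).
GENERIC_CYTOKINE_PROCESS = OBO.NCIT_C181898

# ---------------------------------------------------------------------------
# Severity-score semantic module
# ---------------------------------------------------------------------------

SCORE_TYPES = ("ApacheIV", "SOFA", "Leiden")

#: Score datum classes (study namespace; no published terms for these).
SCORE_DATUM_CLASSES = {
    "ApacheIV": BCO.ApacheIVScore,
    "SOFA": BCO.SofaScore,
    "Leiden": BCO.LeidenSeverityScore,
}

#: Severity-assessment process classes, one per score type.
ASSESSMENT_PROCESS_CLASSES = {
    "ApacheIV": BCO.ApacheIVScoreAssessment,
    "SOFA": BCO.SofaScoreAssessment,
    "Leiden": BCO.LeidenSeverityScoreAssessment,
}

# ---------------------------------------------------------------------------
# DCAT2 metadata extension: four elements from three vocabularies
# ---------------------------------------------------------------------------

#: The metadata record explicitly names the identifier of the data it
#: describes (findability principle F3).
DATA_IDENTIFIER_PREDICATE = DATACITE.hasIdentifier

EXT_TYPE = DCTERMS.type                  # "TYPE", recommended by DCAT2
EXT_DESCRIBES = AFO.describes            # "DESCRIBES", Allotrope namespace
EXT_DATA_INPUT_OF = AFO.isDataInputOf    # "DATA INPUT OF", Allotrope namespace
EXT_HAS_QUALITY = OBO.RO_0000086         # "HAS QUALITY", OBO Relations Ontology

#: Extension property → source vocabulary (exactly 3 distinct vocabularies).
EXTENSION_PREDICATES = {
    EXT_TYPE: "dcat2",
    EXT_DESCRIBES: "afo",
    EXT_DATA_INPUT_OF: "afo",
    EXT_HAS_QUALITY: "ro",
}

#: Default objects of the four extension edges, with human-readable labels
#: (the metadata GUI best practice: always ship an rdfs:label).
RESOURCE_TYPE_KNOWLEDGE_BASE = BCO.KnowledgeBase
DISEASE_COVID19 = OBO.MONDO_0100096      # COVID-19
CLINICAL_STUDY = OBO.NCIT_C15206         # Clinical Study
QUALITY_SYNTHETIC = BCO.SyntheticDataQuality

TERM_LABELS = {
    RESOURCE_TYPE_KNOWLEDGE_BASE: "knowledge base",
    DISEASE_COVID19: "COVID-19",
    CLINICAL_STUDY: "clinical study",
    QUALITY_SYNTHETIC: "synthetic data quality",
    UNIT_PG_PER_ML: "picogram per milliliter",
    GENERIC_INTERLEUKIN_DATUM: "blood interleukin measurement",
    GENERIC_CYTOKINE_PROCESS: "cytokine measurement",
}
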