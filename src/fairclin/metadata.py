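"""DCAT2-based dataset metadata with the four-element extension, laid out as
FAIR-Data-Point-style records.

A dataset metadata record carries the DCAT2 baseline (title, description,
license, publisher, issued/modified, version, themes, distributions) plus
exactly four extension edges drawn from exactly three vocabularies:

* ``dct:type`` (recommended by DCAT2) — the kind of resource, e.g. a
  *knowledge base*;
* ``afo:describes`` and ``afo:isDataInputOf`` (Allotrope namespace) — the
  disease the data describes (e.g. *COVID-19*) and the activity it feeds
  (e.g. a *clinical study*);
* ``obo:RO_0000086`` *has quality* (OBO Relations Ontology) — e.g.
  *synthetic data quality*.

Every record also names the identifier of the data it describes with an
explicit ``datacite:hasIdentifier`` triple (findability principle F3), and
every extension-edge object gets a human-readable ``rdfs:label``.

The FAIR-Data-Point layout is emitted as files on disk — one Turtle file per
record (root → catalogs → datasets → distributions) with bidirectional
parent/child links — rather than as a live metadata service.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCAT, DCTERMS, FOAF, RDF, RDFS, XSD

from .errors import MetadataError
from .guprid import GupridPolicy
from .serialize import new_graph, parse, serialize
from .vocab import (
    CLINICAL_STUDY,
    DATA_IDENTIFIER_PREDICATE,
    DISEASE_COVID19,
    EXT_DATA_INPUT_OF,
    EXT_DESCRIBES,
    EXT_HAS_QUALITY,
    EXT_TYPE,
    EXTENSION_PREDICATES,
    QUALITY_SYNTHETIC,
    RESOURCE_TYPE_KNOWLEDGE_BASE,
    TERM_LABELS,
)

__all__ = [
    "Distribution", "DatasetDescriptor", "CatalogInfo", "FdpLayout",
    "build_dataset_metadata", "emit_fdp_layout", "extension_edges",
    "load_descriptor", "write_fdp_layout", "read_fdp_layout",
]


class Distribution(BaseModel):
    """One downloadable/accessible form of a dataset."""

    media_type: str = "text/turtle"
    access_iri: str
    download_iri: Optional[str] = None


class DatasetDescriptor(BaseModel):
    """The metadata payload a dataset record is built from.

    A *complete* descriptor has a license, the identifier of the data it
    describes, and at least one distribution; :meth:`require_complete`
    enforces this and lists anything missing.
    """

    title: str
    description: str = ""
    license: Optional[str] = None
    publisher: str = ""
    publisher_iri: Optional[str] = None
    issued: Optional[date] = None
    modified: Optional[date] = None
    version: str = "1.0"
    themes: list[str] = Field(default_factory=list)
    resource_type: str = str(RESOURCE_TYPE_KNOWLEDGE_BASE)
    describes: str = str(DISEASE_COVID19)
    data_input_of: str = str(CLINICAL_STUDY)
    has_quality: str = str(QUALITY_SYNTHETIC)
    data_identifier: Optional[str] = None
    distributions: list[Distribution] = Field(default_factory=list)

    def require_complete(self) -> None:
        missing = []
        if not self.license:
            missing.append("license (reusability principle R1.1)")
        if not self.data_identifier:
            missing.append("data_identifier (findability principle F3)")
        if not self.distributions:
            missing.append("distributions (at least one)")
        for name in ("resource_type", "describes", "data_input_of", "has_quality",
                     "license", "data_identifier"):
            value = getattr(self, name)
            if value and not str(value).startswith(("http://", "https://")):
                missing.append(f"{name} must be an absolute IRI, got {value!r}")
        if missing:
            raise MetadataError(
                "incomplete dataset descriptor; missing/invalid fields: "
                + "; ".join(missing)
            )


class CatalogInfo(BaseModel):
    """Catalog-level metadata for the FDP layout."""

    title: str = "FAIR clinical cytokine data catalog"
    description: str = ""
    publisher: str = ""


def load_descriptor(path) -> DatasetDescriptor:
    """Load a dataset descriptor from YAML or JSON (schema-validated)."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        payload = yaml.safe_load(text)
        return DatasetDescriptor(**payload)
    except Exception as exc:
        raise MetadataError(f"{path}: invalid dataset descriptor: {exc}") from exc


def _add_label(graph: Graph, term: URIRef) -> None:
    label = TERM_LABELS.get(term)
    if label is None:
        # GUI best practice: fall back to a readable form of the last segment
        label = str(term).rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    graph.add((term, RDFS.label, Literal(label)))


def build_dataset_metadata(desc: DatasetDescriptor,
                           policy: Optional[GupridPolicy] = None) -> Graph:
    """Build the metadata graph for one dataset record.

    The graph holds the DCAT2 baseline description plus exactly the four
    extension edges and the explicit data-identifier triple. Raises
    :class:`MetadataError` for incomplete descriptors.
    """
    if policy is None:
        policy = GupridPolicy()
    desc.require_complete()
    g = new_graph()
    ds = policy.mint("dataset", desc.title, desc.version)
    g.add((ds, RDF.type, DCAT.Dataset))
    g.add((ds, DCTERMS.title, Literal(desc.title)))
    if desc.description:
        g.add((ds, DCTERMS.description, Literal(desc.description)))
    g.add((ds, DCTERMS.license, URIRef(desc.license)))
    if desc.publisher or desc.publisher_iri:
        agent = (URIRef(desc.publisher_iri) if desc.publisher_iri
                 else policy.mint("agent", desc.publisher))
        g.add((ds, DCTERMS.publisher, agent))
        g.add((agent, RDF.type, FOAF.Agent))
        if desc.publisher:
            g.add((agent, FOAF.name, Literal(desc.publisher)))
    if desc.issued:
        g.add((ds, DCTERMS.issued, Literal(desc.issued, datatype=XSD.date)))
    if desc.modified:
        g.add((ds, DCTERMS.modified, Literal(desc.modified, datatype=XSD.date)))
    g.add((ds, DCTERMS.hasVersion, Literal(desc.version)))
    for theme in desc.themes:
        g.add((ds, DCAT.theme, URIRef(theme)))

    # F3: the metadata explicitly includes the identifier of the data.
    g.add((ds, DATA_IDENTIFIER_PREDICATE, URIRef(desc.data_identifier)))

    # The four extension edges (three source vocabularies), with labels.
    for predicate, obj in (
        (EXT_TYPE, URIRef(desc.resource_type)),
        (EXT_DESCRIBES, URIRef(desc.describes)),
        (EXT_DATA_INPUT_OF, URIRef(desc.data_input_of)),
        (EXT_HAS_QUALITY, URIRef(desc.has_quality)),
    ):
        g.add((ds, predicate, obj))
        _add_label(g, obj)

    for dist in desc.distributions:
        node = policy.mint("distribution", desc.title, desc.version,
                           dist.media_type, dist.access_iri)
        g.add((ds, DCAT.distribution, node))
        g.add((node, RDF.type, DCAT.Distribution))
        g.add((node, DCAT.mediaType, Literal(dist.media_type)))
        g.add((node, DCAT.accessURL, URIRef(dist.access_iri)))
        if dist.download_iri:
            g.add((node, DCAT.downloadURL, URIRef(dist.download_iri)))
    return g


def extension_edges(graph: Graph) -> list[tuple[URIRef, URIRef, str]]:
    """The extension edges present in *graph*: (predicate, object, vocabulary)."""
    edges = []
    for predicate, vocab in EXTENSION_PREDICATES.items():
        for s, o in graph.subject_objects(predicate):
            edges.append((predicate, o, vocab))
    return edges


@dataclass
class FdpLayout:
    """The record tree of a FAIR-Data-Point-style metadata layout.

    Each entry is ``(record IRI, record graph)``; every record is
    independently serializable and linked to its parent and children.
    """

    root: tuple[URIRef, Graph]
    catalogs: list[tuple[URIRef, Graph]] = field(default_factory=list)
    datasets: list[tuple[URIRef, Graph]] = field(default_factory=list)
    distributions: list[tuple[URIRef, Graph]] = field(default_factory=list)

    def records(self) -> list[tuple[str, URIRef, Graph]]:
        out = [("root", *self.root)]
        out += [("catalog", iri, g) for iri, g in self.catalogs]
        out += [("dataset", iri, g) for iri, g in self.datasets]
        out += [("distribution", iri, g) for iri, g in self.distributions]
        return out

    def merged(self) -> Graph:
        g = new_graph()
        for _, _, record in self.records():
            for triple in record:
                g.add(triple)
        return g


def emit_fdp_layout(catalog: CatalogInfo,
                    descriptors: Sequence[DatasetDescriptor],
                    policy: Optional[GupridPolicy] = None) -> FdpLayout:
    """Mint and cross-link the root → catalog → dataset → distribution records.

    Duplicate dataset titles only produce a warning-free layout because
    record IRIs include the version; every minted IRI is unique.
    """
    if policy is None:
        policy = GupridPolicy()
    if not descriptors:
        raise MetadataError("at least one dataset descriptor is required")

    root_iri = policy.mint("root", "root")
    root_g = new_graph()
    root_g.add((root_iri, RDF.type, DCAT.Catalog))
    root_g.add((root_iri, DCTERMS.title,
                Literal("FAIR Data Point root metadata record")))

    cat_iri = policy.mint("catalog", catalog.title)
    cat_g = new_graph()
    cat_g.add((cat_iri, RDF.type, DCAT.Catalog))
    cat_g.add((cat_iri, DCTERMS.title, Literal(catalog.title)))
    if catalog.description:
        cat_g.add((cat_iri, DCTERMS.description, Literal(catalog.description)))
    root_g.add((root_iri, DCTERMS.hasPart, cat_iri))
    cat_g.add((cat_iri, DCTERMS.isPartOf, root_iri))

    layout = FdpLayout(root=(root_iri, root_g), catalogs=[(cat_iri, cat_g)])
    for desc in descriptors:
        ds_g = build_dataset_metadata(desc, policy)
        ds_iri = next(ds_g.subjects(RDF.type, DCAT.Dataset))
        cat_g.add((cat_iri, DCAT.dataset, ds_iri))
        cat_g.add((cat_iri, DCTERMS.hasPart, ds_iri))
        ds_g.add((ds_iri, DCTERMS.isPartOf, cat_iri))
        layout.datasets.append((ds_iri, ds_g))
        for dist_iri in ds_g.objects(ds_iri, DCAT.distribution):
            dist_g = new_graph()
            for triple in ds_g.triples((dist_iri, None, None)):
                dist_g.add(triple)
            dist_g.add((dist_iri, DCTERMS.isPartOf, ds_iri))
            ds_g.add((dist_iri, DCTERMS.isPartOf, ds_iri))
            layout.distributions.append((dist_iri, dist_g))
    return layout


def write_fdp_layout(layout: FdpLayout, out_dir) -> list[Path]:
    """Write one Turtle file per record plus an ``index.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    index = []
    for kind, iri, graph in layout.records():
        token = str(iri).rstrip("/").rsplit("/", 1)[-1]
        name = "root.ttl" if kind == "root" else f"{kind}-{token}.ttl"
        path = out / name
        path.write_bytes(serialize(graph, "turtle"))
        written.append(path)
        index.append({"kind": kind, "iri": str(iri), "file": name})
    index_path = out / "index.json"
    index_path.write_text(json.dumps(index, indent=2) + "\n", encoding="utf-8")
    written.append(index_path)
    return written


def read_fdp_layout(out_dir) -> Graph:
    """Parse every record file of a written layout into one merged graph."""
    out = Path(out_dir)
    g = new_graph()
    for path in sorted(out.glob("*.ttl")):
        for triple in parse(path.read_bytes(), "turtle"):
            g.add(triple)
    return g
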