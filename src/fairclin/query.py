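"""Embedded SPARQL store and the catalog of driving medical questions.

Graphs are loaded into an in-memory rdflib store (set semantics: re-loading
the same graph adds nothing) and queried with SPARQL. The catalog mirrors
the decorated-query convention used for grlc-style Linked Data APIs: each
``.rq`` file carries a YAML front-matter block in ``#+``-prefixed comment
lines declaring its name, description, parameters and result schema. The
query texts are plain SPARQL 1.1 and stay portable to an external triple
store.

The cytokine→protein profile joins patient measurement data against a
packaged protein-annotation fixture graph shaped like UniProt RDF (protein
class, preferred name, organism) — a desk-scale stand-in for live
federation, which is off by default and not exercised here. Join semantics
are an inner join (only annotated cytokines are retrieved); a left-join
variant is catalogued separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF
from rdflib.plugins.sparql import prepareQuery

from .errors import QueryError
from .serialize import new_graph
from .vocab import PATIENT_CLASS, SPECIMEN_CLASS

__all__ = [
    "CatalogQuery", "QueryCatalog", "load_graphs", "count_patients",
    "count_biosamples", "cytokine_protein_profile", "run_query",
    "load_annotation_fixture",
]

_FIXTURE_RESOURCE = "data/uniprot_synthetic_fixture.ttl"


@dataclass(frozen=True)
class CatalogQuery:
    """One documented catalog entry."""

    name: str
    description: str
    text: str
    #: parameter name → required flag
    params: Mapping[str, bool]
    #: declared result schema: column name → type name
    schema: Mapping[str, str]


class QueryCatalog:
    """Named, documented SPARQL queries, parsed and validated at load."""

    def __init__(self, queries: Iterable[CatalogQuery]):
        self._queries = {q.name: q for q in queries}

    def __contains__(self, name: str) -> bool:
        return name in self._queries

    def names(self) -> list[str]:
        return sorted(self._queries)

    def get(self, name: str) -> CatalogQuery:
        if name not in self._queries:
            raise QueryError(
                f"unknown query {name!r}; catalog has {self.names()}"
            )
        return self._queries[name]

    @classmethod
    def default(cls) -> "QueryCatalog":
        """Load the packaged catalog from ``data/queries/*.rq``."""
        queries = []
        root = resources.files("fairclin").joinpath("data/queries")
        for entry in sorted(root.iterdir(), key=lambda e: e.name):
            if entry.name.endswith(".rq"):
                queries.append(_parse_rq(entry.name, entry.read_text(encoding="utf-8")))
        return cls(queries)


def _parse_rq(filename: str, text: str) -> CatalogQuery:
    """Parse a decorated ``.rq`` file: ``#+`` front matter, then SPARQL."""
    meta_lines, body_lines = [], []
    for line in text.splitlines():
        if line.startswith("#+"):
            # strip the marker and one following space, keep YAML indentation
            meta_lines.append(line[3:] if line.startswith("#+ ") else line[2:])
        else:
            body_lines.append(line)
    try:
        meta = yaml.safe_load("\n".join(meta_lines)) or {}
    except yaml.YAMLError as exc:
        raise QueryError(f"{filename}: bad front matter: {exc}") from exc
    body = "\n".join(body_lines).strip()
    try:
        prepareQuery(body)
    except Exception as exc:
        raise QueryError(f"{filename}: SPARQL syntax error: {exc}") from exc
    params = {
        p["name"]: bool(p.get("required", True))
        for p in meta.get("params", [])
    }
    schema = {c["name"]: c.get("type", "string") for c in meta.get("schema", [])}
    return CatalogQuery(
        name=meta.get("name", filename[:-3]),
        description=meta.get("description", ""),
        text=body,
        params=params,
        schema=schema,
    )


# ---------------------------------------------------------------------------
# Store operations
# ---------------------------------------------------------------------------


def load_graphs(store: Optional[Graph], graphs: Iterable[Graph]) -> Graph:
    """Load *graphs* into *store* (a new store if None); returns the store.

    Under RDF set semantics the final size is the size of the union.
    """
    if store is None:
        store = new_graph()
    for graph in graphs:
        for triple in graph:
            store.add(triple)
    return store


def count_patients(store: Graph) -> int:
    """Distinct patient nodes in the store (direct graph traversal; the
    catalog's ``count_patients`` SPARQL query is the cross-checkable route)."""
    return len(set(store.subjects(RDF.type, PATIENT_CLASS)))


def count_biosamples(store: Graph) -> int:
    """Distinct biosample nodes in the store."""
    return len(set(store.subjects(RDF.type, SPECIMEN_CLASS)))


def load_annotation_fixture() -> Graph:
    """The packaged UniProt-shaped protein-annotation fixture graph."""
    text = resources.files("fairclin").joinpath(_FIXTURE_RESOURCE).read_text(
        encoding="utf-8"
    )
    g = new_graph()
    g.parse(data=text, format="turtle")
    return g


def _to_dataframe(result, schema: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    columns = [str(v) for v in result.vars]
    rows = [
        [None if cell is None else cell.toPython() if isinstance(cell, Literal)
         else str(cell) for cell in row]
        for row in result
    ]
    df = pd.DataFrame(rows, columns=columns)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise QueryError(
                f"result does not conform to declared schema; missing columns {missing}"
            )
    return df


def run_query(store: Graph, catalog: QueryCatalog, name: str,
              params: Optional[Mapping[str, object]] = None,
              out_csv=None) -> pd.DataFrame:
    """Run catalog query *name* with *params* bound into its slots.

    Raises :class:`QueryError` for unknown names or missing required
    parameters. The result conforms to the query's declared schema and is
    optionally written as CSV.
    """
    entry = catalog.get(name)
    params = dict(params or {})
    missing = [p for p, required in entry.params.items()
               if required and p not in params]
    if missing:
        raise QueryError(
            f"query {name!r}: missing required parameter(s) {missing}"
        )
    unknown = [p for p in params if p not in entry.params]
    if unknown:
        raise QueryError(f"query {name!r}: unknown parameter(s) {unknown}")
    bindings = {
        key: value if isinstance(value, (URIRef, Literal)) else Literal(value)
        for key, value in params.items()
    }
    result = store.query(entry.text, initBindings=bindings)
    df = _to_dataframe(result, entry.schema)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def cytokine_protein_profile(store: Graph, fixture: Optional[Graph] = None,
                             catalog: Optional[QueryCatalog] = None
                             ) -> pd.DataFrame:
    """Patient cytokine profile with protein annotation (inner join).

    One row per (measurement datum, matching protein annotation):
    patient, date, analyte term, value, protein IRI, protein name. Rows
    whose analyte term has no annotation in *fixture* are absent.
    """
    if catalog is None:
        catalog = QueryCatalog.default()
    if fixture is None:
        fixture = load_annotation_fixture()
    merged = load_graphs(None, [store, fixture])
    return run_query(merged, catalog, "cytokine_protein_profile")
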