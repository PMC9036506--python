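"""Local, deterministic FAIR checklist for metadata graphs.

Evaluates a metadata graph against a pinned subset of the FAIR principles —
F1–F3 for findability, A1/A1.1 for accessibility, I1/I2 for
interoperability, R1–R1.3 for reusability — as purely syntactic, offline
checks. This deliberately diverges from hosted maturity-indicator
evaluators: F1/A1 verify that identifiers are *shaped* like resolvable
persistent IRIs (absolute http(s) IRIs under a recognised
persistent-identifier host), never that they actually resolve. F4
(searchable-resource registration), A1.2 (authentication/authorization) and
A2 (metadata persistence) are reported ``not_applicable``: they concern a
deployed service, not a graph on disk.

Check design: indicators that quantify over every occurrence (F1, A1, A1.1,
I2) pass vacuously on an empty graph, while the presence checks (F2, F3,
R1.1, R1.2, R1.3) fail on it. Each pass/fail indicator inspects its own
field, so ablating exactly that field flips exactly that indicator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import urlparse

from rdflib import Graph, URIRef
from rdflib.namespace import DCAT, DCTERMS, RDF

from .errors import AssessmentError
from .serialize import parse
from .vocab import DATA_IDENTIFIER_PREDICATE, EXTENSION_PREDICATES, PREFIXES

__all__ = ["FairIndicator", "FairReport", "assess_metadata", "PID_HOSTS"]

#: Hosts whose IRIs count as persistent-identifier shaped.
PID_HOSTS = ("w3id.org", "purl.org", "doi.org", "identifiers.org", "purl.obolibrary.org")

#: Indicator evaluation order.
INDICATORS = ("F1", "F2", "F3", "F4", "A1", "A1.1", "A1.2", "A2",
              "I1", "I2", "R1", "R1.1", "R1.2", "R1.3")

NOT_APPLICABLE = {
    "F4": "metadata indexing in a searchable resource is a deployment concern",
    "A1.2": "authentication/authorization protocol is a deployment concern",
    "A2": "metadata persistence beyond data lifetime is a deployment concern",
}


@dataclass(frozen=True)
class FairIndicator:
    id: str
    status: str  # "pass" | "fail" | "not_applicable"
    message: str


@dataclass
class FairReport:
    indicators: list[FairIndicator] = field(default_factory=list)

    def status(self, indicator_id: str) -> str:
        return next(i.status for i in self.indicators if i.id == indicator_id)

    def passed(self) -> list[str]:
        return [i.id for i in self.indicators if i.status == "pass"]

    def failed(self) -> list[str]:
        return [i.id for i in self.indicators if i.status == "fail"]

    def to_json(self, path=None) -> str:
        payload = [
            {"indicator": i.id, "status": i.status, "message": i.message}
            for i in self.indicators
        ]
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _is_absolute_http(iri: str) -> bool:
    parsed = urlparse(iri)
    return parsed.scheme in ("http", "https") and bool(parsed.netloc)


def _is_pid_shaped(iri: str) -> bool:
    parsed = urlparse(iri)
    return (_is_absolute_http(iri)
            and any(parsed.netloc == host or parsed.netloc.endswith("." + host)
                    for host in PID_HOSTS))


def assess_metadata(source: Graph | bytes | str) -> FairReport:
    """Assess a metadata graph (or Turtle bytes/path) against the checklist.

    Unreadable input raises :class:`AssessmentError`; everything else is
    reported as indicator statuses, never as an exception.
    """
    if isinstance(source, Graph):
        graph = source
    else:
        try:
            if isinstance(source, bytes):
                graph = parse(source, "turtle")
            else:
                graph = parse(Path(source).read_bytes(), "turtle")
        except Exception as exc:
            raise AssessmentError(f"unreadable metadata input: {exc}") from exc

    datasets = sorted(set(graph.subjects(RDF.type, DCAT.Dataset)))
    report = FairReport()

    def add(indicator: str, ok: bool, detail: str) -> None:
        report.indicators.append(
            FairIndicator(indicator, "pass" if ok else "fail", detail)
        )

    # F1 — every metadata record identifier is a PID-shaped absolute IRI.
    bad_f1 = [str(d) for d in datasets if not _is_pid_shaped(str(d))]
    add("F1", not bad_f1,
        "all dataset record IRIs are persistent-identifier shaped" if not bad_f1
        else f"record IRIs not under a persistent-identifier host: {bad_f1}")

    # F2 — rich human metadata present: title and description.
    has_title = any(graph.triples((None, DCTERMS.title, None)))
    has_desc = any(graph.triples((None, DCTERMS.description, None)))
    add("F2", has_title and has_desc,
        "title and description present" if has_title and has_desc else
        "missing " + " and ".join(
            name for name, ok in (("dct:title", has_title),
                                  ("dct:description", has_desc)) if not ok))

    # F3 — the metadata explicitly includes the identifier of the data.
    data_ids = [o for o in graph.objects(None, DATA_IDENTIFIER_PREDICATE)]
    ok_f3 = bool(data_ids) and all(_is_absolute_http(str(o)) for o in data_ids)
    add("F3", ok_f3,
        f"data identifier triple(s) present: {[str(o) for o in data_ids]}"
        if ok_f3 else "no valid data-identifier triple "
        f"({DATA_IDENTIFIER_PREDICATE} with an absolute IRI object)")

    report.indicators.append(FairIndicator("F4", "not_applicable", NOT_APPLICABLE["F4"]))

    # A1 — every dataset record points at an access/download URL.
    no_access = [
        str(d) for d in datasets
        if not [
            url
            for dist in graph.objects(d, DCAT.distribution)
            for p in (DCAT.accessURL, DCAT.downloadURL)
            for url in graph.objects(dist, p)
        ]
    ]
    add("A1", not no_access,
        "every dataset record has an access or download URL" if not no_access
        else f"dataset records without access/download URLs: {no_access}")

    # A1.1 — every access/download URL uses an open standard protocol.
    urls = [str(o) for p in (DCAT.accessURL, DCAT.downloadURL)
            for o in graph.objects(None, p)]
    bad_proto = [u for u in urls if urlparse(u).scheme not in ("http", "https")]
    add("A1.1", not bad_proto,
        "all access protocols are http(s)" if not bad_proto
        else f"non-open-protocol URLs: {bad_proto}")

    report.indicators.append(
        FairIndicator("A1.2", "not_applicable", NOT_APPLICABLE["A1.2"]))
    report.indicators.append(
        FairIndicator("A2", "not_applicable", NOT_APPLICABLE["A2"]))

    # I1 — the (meta)data is expressed in a formal RDF language. The input
    # was parsed into an RDF graph, so this records as a pass; unparseable
    # input never reaches the report.
    add("I1", True, "input parses as RDF")

    # I2 — every vocabulary IRI (predicates, classes) is absolute and from
    # the declared namespace table.
    namespaces = tuple(PREFIXES.values())
    vocab_iris = {str(p) for _, p, _ in graph}
    vocab_iris |= {str(o) for o in graph.objects(None, RDF.type)
                   if isinstance(o, URIRef)}
    undeclared = sorted(
        iri for iri in vocab_iris
        if not (_is_absolute_http(iri) and iri.startswith(namespaces))
    )
    add("I2", not undeclared,
        "all vocabulary IRIs come from the declared namespace table"
        if not undeclared else f"vocabulary IRIs outside the declared table: {undeclared}")

    # R1 — plurality of relevant attributes: every dataset record carries
    # version and theme annotations.
    poor = [
        str(d) for d in datasets
        if not (any(graph.objects(d, DCTERMS.hasVersion))
                and any(graph.objects(d, DCAT.theme)))
    ]
    add("R1", not poor,
        "every dataset record carries version and theme attributes" if not poor
        else f"dataset records missing dct:hasVersion or dcat:theme: {poor}")

    # R1.1 — a clear data usage license.
    licenses = list(graph.objects(None, DCTERMS.license))
    add("R1.1", bool(licenses),
        f"license present: {[str(o) for o in licenses]}" if licenses
        else "no dct:license triple")

    # R1.2 — provenance: publisher plus issued/modified dates.
    has_pub = any(graph.triples((None, DCTERMS.publisher, None)))
    has_dates = (any(graph.triples((None, DCTERMS.issued, None)))
                 and any(graph.triples((None, DCTERMS.modified, None))))
    add("R1.2", has_pub and has_dates,
        "publisher and issued/modified dates present" if has_pub and has_dates
        else "missing " + " and ".join(
            name for name, ok in (("dct:publisher", has_pub),
                                  ("dct:issued+dct:modified", has_dates)) if not ok))

    # R1.3 — community standard: the four extension elements are present.
    present = [p for p in EXTENSION_PREDICATES
               if any(graph.triples((None, p, None)))]
    add("R1.3", len(present) == len(EXTENSION_PREDICATES),
        "all four extension elements present" if len(present) == 4
        else f"extension elements present: {[str(p) for p in present]} "
        f"(require all of {[str(p) for p in EXTENSION_PREDICATES]})")

    order = {ind: i for i, ind in enumerate(INDICATORS)}
    report.indicators.sort(key=lambda i: order[i.id])
    return report
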