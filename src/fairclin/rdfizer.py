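"""The RDFizer: instantiate tabular measurements as a process-centred RDF graph.

The ontological data model treats the *process of measurement* as the core
concept: every value in the table is the specified output of a measurement
process that took a biosample as its specified input, and the biosample was
derived from a patient. Concretely, for each measurement record the graph
contains:

* a patient node (typed, with the clinical identifier as ``dct:identifier``),
  shared across the patient's records;
* a biosample node per (patient, sampling date), derived from the patient
  (``prov:wasDerivedFrom``) and dated with the sampling date (``dct:date``);
* an age datum node per record attached to the patient (``sio:has attribute``,
  one ``sio:has value`` integer literal);
* one measurement-process node per (record, panel) — mirroring a multiplex
  (Luminex-style) panel run — typed by the mapped process class(es) of its
  analytes, with the biosample as specified input, the measurement date as
  ``dct:date`` and the record timestamp as ``prov:generatedAtTime``;
* one output datum node per (record, measured analyte), typed by the mapped
  datum class, carrying exactly one ``sio:has value`` decimal literal and
  exactly one ``sio:has unit`` term (pg/mL).

Blank nodes are never used; every node gets a policy-minted IRI, so in
content-hash mode the graph is identical across runs and re-RDFizing the
same input adds zero triples on merge.

Triple counts per record (the documented constants of the pattern):
2 patient triples + 3 age triples + 3 per biosample + (3 + number of
distinct process classes) per panel with data + 4 per measured analyte
(datum type/value/unit + process output link), deduplicated across records
under RDF set semantics.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from rdflib import Graph, Literal
from rdflib.namespace import DCTERMS, PROV, RDF, XSD

from .cohort import MeasurementRecord
from .errors import RdfizeError
from .guprid import GupridPolicy
from .mapping import AnalyteMapping
from .serialize import new_graph
from .vocab import (
    AGE_CLASS,
    ASSESSMENT_PROCESS_CLASSES,
    HAS_ATTRIBUTE,
    HAS_SPECIFIED_INPUT,
    HAS_SPECIFIED_OUTPUT,
    HAS_UNIT,
    HAS_VALUE,
    PATIENT_CLASS,
    SCORE_DATUM_CLASSES,
    SCORE_TYPES,
    SPECIMEN_CLASS,
    UNIT_PG_PER_ML,
)

__all__ = ["rdfize_measurements", "rdfize_severity"]


def _record_key(record: MeasurementRecord) -> str:
    return f"{record.patient_id}|{record.record_timestamp.isoformat()}"


def rdfize_measurements(
    records: Sequence[MeasurementRecord],
    mapping: Sequence[AnalyteMapping],
    policy: Optional[GupridPolicy] = None,
) -> Graph:
    """Convert measurement records into the process-centred RDF graph.

    Every analyte with a value must have a mapping row; unmapped analytes
    raise :class:`RdfizeError` listing them all. With a ``content_hash``
    policy the output graph is a pure function of its inputs.
    """
    if policy is None:
        policy = GupridPolicy()
    by_label = {m.analyte_label: m for m in mapping}
    unmapped = sorted({
        analyte for rec in records for analyte in rec.levels
        if analyte not in by_label
    })
    if unmapped:
        raise RdfizeError(f"analytes without a mapping entry: {unmapped}")

    g = new_graph()
    for rec in records:
        patient = policy.mint("patient", rec.patient_id)
        g.add((patient, RDF.type, PATIENT_CLASS))
        g.add((patient, DCTERMS.identifier, Literal(rec.patient_id)))

        sample = policy.mint("biosample", rec.patient_id, rec.sampling_date)
        g.add((sample, RDF.type, SPECIMEN_CLASS))
        g.add((sample, PROV.wasDerivedFrom, patient))
        g.add((sample, DCTERMS.date, Literal(rec.sampling_date, datatype=XSD.date)))

        age = policy.mint("datum", "age", _record_key(rec))
        g.add((age, RDF.type, AGE_CLASS))
        g.add((age, HAS_VALUE, Literal(rec.patient_age, datatype=XSD.integer)))
        g.add((patient, HAS_ATTRIBUTE, age))

        panels: dict[Optional[int], list[str]] = {}
        for analyte in rec.levels:
            panels.setdefault(rec.panel_by_analyte.get(analyte), []).append(analyte)

        for panel_id, analytes in sorted(
                panels.items(), key=lambda kv: (kv[0] is None, kv[0])):
            process = policy.mint("process", _record_key(rec), panel_id)
            for analyte in analytes:
                g.add((process, RDF.type, by_label[analyte].process_class_iri_ref))
            g.add((process, HAS_SPECIFIED_INPUT, sample))
            g.add((process, DCTERMS.date,
                   Literal(rec.measurement_date, datatype=XSD.date)))
            g.add((process, PROV.generatedAtTime,
                   Literal(rec.record_timestamp.isoformat(),
                           datatype=XSD.dateTime)))
            for analyte in analytes:
                datum = policy.mint("datum", _record_key(rec), analyte)
                g.add((process, HAS_SPECIFIED_OUTPUT, datum))
                g.add((datum, RDF.type, by_label[analyte].datum_class_iri_ref))
                g.add((datum, HAS_VALUE,
                       Literal(str(rec.levels[analyte]), datatype=XSD.decimal)))
                g.add((datum, HAS_UNIT, UNIT_PG_PER_ML))
    return g


def rdfize_severity(rows: Iterable, policy: Optional[GupridPolicy] = None) -> Graph:
    """Instantiate scored severity results as RDF.

    Each row (any object with ``patient_id``, ``date``, ``score_type`` and
    ``value`` attributes, e.g. a :class:`~fairclin.severity.SeverityResult`)
    becomes an assessment-process node with the patient as specified input,
    the assessment date, and one output score-datum node typed by the score
    type and carrying one integer value literal.
    """
    if policy is None:
        policy = GupridPolicy()
    g = new_graph()
    for row in rows:
        score_type = row.score_type
        if score_type not in SCORE_DATUM_CLASSES:
            raise RdfizeError(
                f"unknown score_type {score_type!r}; expected one of {SCORE_TYPES}"
            )
        patient = policy.mint("patient", row.patient_id)
        g.add((patient, RDF.type, PATIENT_CLASS))
        g.add((patient, DCTERMS.identifier, Literal(row.patient_id)))

        assessment = policy.mint("assessment", row.patient_id, row.date, score_type)
        g.add((assessment, RDF.type, ASSESSMENT_PROCESS_CLASSES[score_type]))
        g.add((assessment, HAS_SPECIFIED_INPUT, patient))
        g.add((assessment, DCTERMS.date, Literal(row.date, datatype=XSD.date)))

        datum = policy.mint("score", row.patient_id, row.date, score_type)
        g.add((assessment, HAS_SPECIFIED_OUTPUT, datum))
        g.add((datum, RDF.type, SCORE_DATUM_CLASSES[score_type]))
        g.add((datum, HAS_VALUE, Literal(int(row.value), datatype=XSD.integer)))
    return g
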