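"""Declarative node-shape validation for the instantiation patterns.

A :class:`NodeShape` targets every node carrying a given ``rdf:type`` and
checks per-property cardinalities, literal datatypes and node kinds — the
constraint subset the RDFizer's patterns actually need. Violations are data,
not errors: validation always returns a report listing (node, shape,
constraint, message) for each breach, and an empty report means the graph
conforms.

:func:`default_shapes` encodes the exact measurement/severity instantiation
pattern, so any graph the RDFizer produces validates with zero violations
and any structural mutation (dropped value literal, duplicated unit, wrong
datatype...) is pinpointed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, PROV, RDF, XSD

from .mapping import AnalyteMapping, default_mapping
from .vocab import (
    AGE_CLASS,
    ASSESSMENT_PROCESS_CLASSES,
    HAS_SPECIFIED_INPUT,
    HAS_SPECIFIED_OUTPUT,
    HAS_UNIT,
    HAS_VALUE,
    PATIENT_CLASS,
    SCORE_DATUM_CLASSES,
    SPECIMEN_CLASS,
)

__all__ = [
    "PropertyConstraint", "NodeShape", "Violation", "ShapeReport",
    "validate_shape", "default_shapes",
]


@dataclass(frozen=True)
class PropertyConstraint:
    """Constraint on one property path of a focus node."""

    path: URIRef
    min_count: int = 0
    max_count: Optional[int] = None
    #: Required literal datatype of every value, if set.
    datatype: Optional[URIRef] = None
    #: "iri" | "literal" | None (any).
    node_kind: Optional[str] = None

    def describe(self) -> str:
        parts = [f"path={self.path}"]
        if self.min_count:
            parts.append(f"min={self.min_count}")
        if self.max_count is not None:
            parts.append(f"max={self.max_count}")
        if self.datatype is not None:
            parts.append(f"datatype={self.datatype}")
        if self.node_kind:
            parts.append(f"kind={self.node_kind}")
        return " ".join(parts)


@dataclass(frozen=True)
class NodeShape:
    """Constraints applying to every instance of ``target_class``."""

    name: str
    target_class: URIRef
    constraints: tuple[PropertyConstraint, ...] = ()


@dataclass(frozen=True)
class Violation:
    node: URIRef
    shape: str
    constraint: str
    message: str


@dataclass
class ShapeReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def conforms(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_shape(graph: Graph, shapes: Sequence[NodeShape]) -> ShapeReport:
    """Check *graph* against *shapes*; returns the conformance report."""
    report = ShapeReport()
    for shape in shapes:
        for node in sorted(graph.subjects(RDF.type, shape.target_class)):
            for constraint in shape.constraints:
                values = list(graph.objects(node, constraint.path))
                n = len(values)
                if n < constraint.min_count:
                    report.violations.append(Violation(
                        node, shape.name, constraint.describe(),
                        f"{node} has {n} value(s) for {constraint.path}, "
                        f"requires at least {constraint.min_count}",
                    ))
                    continue
                if constraint.max_count is not None and n > constraint.max_count:
                    report.violations.append(Violation(
                        node, shape.name, constraint.describe(),
                        f"{node} has {n} value(s) for {constraint.path}, "
                        f"allows at most {constraint.max_count}",
                    ))
                    continue
                for value in values:
                    if constraint.node_kind == "iri" and not isinstance(value, URIRef):
                        report.violations.append(Violation(
                            node, shape.name, constraint.describe(),
                            f"value {value!r} of {constraint.path} on {node} "
                            "must be an IRI",
                        ))
                    elif constraint.node_kind == "literal" and not isinstance(value, Literal):
                        report.violations.append(Violation(
                            node, shape.name, constraint.describe(),
                            f"value {value!r} of {constraint.path} on {node} "
                            "must be a literal",
                        ))
                    if constraint.datatype is not None:
                        if (not isinstance(value, Literal)
                                or value.datatype != constraint.datatype):
                            report.violations.append(Violation(
                                node, shape.name, constraint.describe(),
                                f"value {value!r} of {constraint.path} on {node} "
                                f"must be a literal of datatype {constraint.datatype}",
                            ))
    return report


def _datum_constraints(datatype: URIRef, with_unit: bool
                       ) -> tuple[PropertyConstraint, ...]:
    constraints = [
        PropertyConstraint(HAS_VALUE, min_count=1, max_count=1, datatype=datatype),
    ]
    if with_unit:
        constraints.append(
            PropertyConstraint(HAS_UNIT, min_count=1, max_count=1, node_kind="iri")
        )
    return tuple(constraints)


_PROCESS_CONSTRAINTS = (
    PropertyConstraint(HAS_SPECIFIED_INPUT, min_count=1, max_count=1, node_kind="iri"),
    PropertyConstraint(HAS_SPECIFIED_OUTPUT, min_count=1, node_kind="iri"),
    PropertyConstraint(DCTERMS.date, min_count=1, max_count=1, datatype=XSD.date),
)


def default_shapes(mapping: Optional[Sequence[AnalyteMapping]] = None
                   ) -> list[NodeShape]:
    """Shapes encoding the measurement and severity instantiation patterns.

    Datum/process shapes are derived from the distinct classes of *mapping*
    (default: the shipped 103-analyte mapping).
    """
    if mapping is None:
        mapping = default_mapping()
    shapes: list[NodeShape] = [
        NodeShape("PatientShape", PATIENT_CLASS, (
            PropertyConstraint(DCTERMS.identifier, min_count=1, max_count=1,
                               node_kind="literal"),
        )),
        NodeShape("BiosampleShape", SPECIMEN_CLASS, (
            PropertyConstraint(PROV.wasDerivedFrom, min_count=1, max_count=1,
                               node_kind="iri"),
            PropertyConstraint(DCTERMS.date, min_count=1, max_count=1,
                               datatype=XSD.date),
        )),
        NodeShape("AgeShape", AGE_CLASS,
                  _datum_constraints(XSD.integer, with_unit=False)),
    ]
    for datum_class in sorted({m.datum_class_iri for m in mapping}):
        shapes.append(NodeShape(
            f"MeasurementDatumShape[{datum_class}]", URIRef(datum_class),
            _datum_constraints(XSD.decimal, with_unit=True),
        ))
    for process_class in sorted({m.process_class_iri for m in mapping}):
        shapes.append(NodeShape(
            f"MeasurementProcessShape[{process_class}]", URIRef(process_class),
            _PROCESS_CONSTRAINTS + (
                PropertyConstraint(PROV.generatedAtTime, min_count=1, max_count=1,
                                   datatype=XSD.dateTime),
            ),
        ))
    for score_type, cls in SCORE_DATUM_CLASSES.items():
        shapes.append(NodeShape(
            f"ScoreDatumShape[{score_type}]", cls,
            _datum_constraints(XSD.integer, with_unit=False),
        ))
    for score_type, cls in ASSESSMENT_PROCESS_CLASSES.items():
        shapes.append(NodeShape(
            f"AssessmentProcessShape[{score_type}]", cls, _PROCESS_CONSTRAINTS,
        ))
    return shapes
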