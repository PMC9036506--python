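"""Analyte → ontology-term mapping for the measurement data model.

Each analyte label maps to two term IRIs: the class of its measurement
*datum* (the output value) and the class of its measurement *process* (the
assay step). Most analytes map to a specific experimental-factor term; where
no specific term exists the mapping falls back to a declared generic
superclass — the generic "blood interleukin measurement" datum class for
interleukins without their own term (e.g. interleukin-11, -26, -32), and
the generic "Cytokine Measurement" process class for TNF-superfamily ligands
— and the row is flagged ``specificity=generalized``.

The mapping table is a CSV with header
``analyte_label,datum_class_iri,process_class_iri,source_vocab,specificity``.
The shipped default covers the full 103-analyte panel and needs two
vocabularies (EFO for the specific terms, OBO for the generic fallbacks).
The per-analyte term ids are deterministic pinned defaults; a deployment
with a curated mapping simply loads its own table.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from rdflib import URIRef

from .cohort import default_panel
from .errors import MappingError
from .vocab import EFO, GENERIC_CYTOKINE_PROCESS, GENERIC_INTERLEUKIN_DATUM

__all__ = [
    "AnalyteMapping",
    "default_mapping",
    "load_mapping",
    "write_mapping",
    "mapping_summary",
]

MAPPING_COLUMNS = (
    "analyte_label", "datum_class_iri", "process_class_iri",
    "source_vocab", "specificity",
)

#: Interleukins mapped to the generic blood-interleukin-measurement datum
#: class because no specific datum term exists.
GENERALIZED_INTERLEUKINS = frozenset({"IL-11", "IL-26", "IL-32", "IL-34", "IL-37"})


@dataclass(frozen=True)
class AnalyteMapping:
    """One mapping row: analyte label → datum and process term IRIs."""

    analyte_label: str
    datum_class_iri: str
    process_class_iri: str
    source_vocab: str
    specificity: str  # "exact" | "generalized"

    def __post_init__(self) -> None:
        for field_name in ("datum_class_iri", "process_class_iri"):
            iri = getattr(self, field_name)
            if not iri:
                raise MappingError(
                    f"missing {field_name} for analyte {self.analyte_label!r}"
                )
            if not iri.startswith(("http://", "https://")):
                raise MappingError(
                    f"{field_name} for analyte {self.analyte_label!r} must be an "
                    f"absolute http(s) IRI, got {iri!r}"
                )
        if self.specificity not in ("exact", "generalized"):
            raise MappingError(
                f"specificity for analyte {self.analyte_label!r} must be "
                f"'exact' or 'generalized', got {self.specificity!r}"
            )

    @property
    def datum_class_iri_ref(self) -> "URIRef":
        return URIRef(self.datum_class_iri)

    @property
    def process_class_iri_ref(self) -> "URIRef":
        return URIRef(self.process_class_iri)


def _exact_datum_iri(index: int) -> str:
    return str(EFO[f"EFO_09{index:04d}"])


def _exact_process_iri(index: int) -> str:
    return str(EFO[f"EFO_08{index:04d}"])


def default_mapping(panel: Optional[Sequence[tuple[str, int]]] = None
                    ) -> list[AnalyteMapping]:
    """Return the shipped mapping for *panel* (default: the 103-analyte panel).

    Deterministic: term ids derive from the analyte's position in the panel.
    Generalization rules: interleukins in :data:`GENERALIZED_INTERLEUKINS`
    get the generic datum class; ``TNFSF*`` ligands get the generic process
    class. Either fallback flags the row ``generalized`` with source ``obo``.
    """
    if panel is None:
        panel = default_panel()
    rows: list[AnalyteMapping] = []
    for index, (label, _panel_id) in enumerate(panel, start=1):
        datum = _exact_datum_iri(index)
        process = _exact_process_iri(index)
        vocab, specificity = "efo", "exact"
        if label in GENERALIZED_INTERLEUKINS:
            datum = str(GENERIC_INTERLEUKIN_DATUM)
            vocab, specificity = "obo", "generalized"
        elif label.startswith("TNFSF"):
            process = str(GENERIC_CYTOKINE_PROCESS)
            vocab, specificity = "obo", "generalized"
        rows.append(AnalyteMapping(label, datum, process, vocab, specificity))
    return rows


def load_mapping(path) -> list[AnalyteMapping]:
    """Load a mapping CSV; one validated entry per analyte.

    Raises :class:`MappingError` on duplicate analyte rows, missing columns
    or missing/malformed IRIs (naming the analyte). An empty file yields an
    empty list with a warning.
    """
    try:
        fh = open(path, "r", encoding="utf-8", newline="")
    except OSError as exc:
        raise MappingError(f"cannot read mapping file {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty mapping file", stacklevel=2)
            return []
        missing = [c for c in MAPPING_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise MappingError(f"{path}: mapping header missing columns {missing}")
        rows: list[AnalyteMapping] = []
        seen: set[str] = set()
        for rec in reader:
            label = (rec["analyte_label"] or "").strip()
            if not label:
                raise MappingError(f"{path}: row with empty analyte_label")
            if label in seen:
                raise MappingError(f"{path}: duplicate mapping row for analyte {label!r}")
            seen.add(label)
            rows.append(AnalyteMapping(
                analyte_label=label,
                datum_class_iri=(rec["datum_class_iri"] or "").strip(),
                process_class_iri=(rec["process_class_iri"] or "").strip(),
                source_vocab=(rec["source_vocab"] or "").strip(),
                specificity=(rec["specificity"] or "").strip(),
            ))
    if not rows:
        warnings.warn(f"{path}: mapping file has a header but no rows", stacklevel=2)
    return rows


def write_mapping(rows: Sequence[AnalyteMapping], path) -> None:
    """Write a mapping table as CSV (inverse of :func:`load_mapping`)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MAPPING_COLUMNS)
        for row in rows:
            writer.writerow([
                row.analyte_label, row.datum_class_iri, row.process_class_iri,
                row.source_vocab, row.specificity,
            ])


def mapping_summary(rows: Sequence[AnalyteMapping]) -> dict:
    """Counts per source vocabulary and per specificity flag."""
    return {
        "n_analytes": len(rows),
        "per_source_vocab": dict(Counter(r.source_vocab for r in rows)),
        "per_specificity": dict(Counter(r.specificity for r in rows)),
    }
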