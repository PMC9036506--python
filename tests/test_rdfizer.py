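"""RDFizer: pattern conformance against an independent brute-force
triple-enumeration oracle, identifier properties, idempotence."""

from __future__ import annotations

from datetime import date, datetime, timezone

import numpy as np
import pytest
from rdflib import URIRef
from rdflib.namespace import DCTERMS, PROV, RDF

from fairclin.cohort import MeasurementRecord, generate_cohort
from fairclin.errors import RdfizeError
from fairclin.guprid import GupridPolicy
from fairclin.mapping import AnalyteMapping, default_mapping
from fairclin.rdfizer import rdfize_measurements, rdfize_severity
from fairclin.severity import SeverityResult
from fairclin.vocab import (
    AGE_CLASS,
    ASSESSMENT_PROCESS_CLASSES,
    HAS_ATTRIBUTE,
    HAS_SPECIFIED_INPUT,
    HAS_SPECIFIED_OUTPUT,
    HAS_UNIT,
    HAS_VALUE,
    PATIENT_CLASS,
    SCORE_DATUM_CLASSES,
    SPECIMEN_CLASS,
    UNIT_PG_PER_ML,
)

from conftest import small_config


def enumerate_expected_triples(records, mapping, policy):
    """Independent oracle: walk the documented instantiation pattern over the
    input table and enumerate, as plain string tuples, every triple the graph
    must contain. Deduplication mirrors RDF set semantics."""
    by_label = {m.analyte_label: m for m in mapping}
    expected = set()
    for rec in records:
        key = f"{rec.patient_id}|{rec.record_timestamp.isoformat()}"
        patient = str(policy.mint("patient", rec.patient_id))
        expected.add((patient, str(RDF.type), str(PATIENT_CLASS)))
        expected.add((patient, str(DCTERMS.identifier), rec.patient_id))
        sample = str(policy.mint("biosample", rec.patient_id, rec.sampling_date))
        expected.add((sample, str(RDF.type), str(SPECIMEN_CLASS)))
        expected.add((sample, str(PROV.wasDerivedFrom), patient))
        expected.add((sample, str(DCTERMS.date), rec.sampling_date.isoformat()))
        age = str(policy.mint("datum", "age", key))
        expected.add((age, str(RDF.type), str(AGE_CLASS)))
        expected.add((age, str(HAS_VALUE), str(rec.patient_age)))
        expected.add((patient, str(HAS_ATTRIBUTE), age))
        panels = {}
        for analyte in rec.levels:
            panels.setdefault(rec.panel_by_analyte.get(analyte), []).append(analyte)
        for panel_id, analytes in panels.items():
            process = str(policy.mint("process", key, panel_id))
            for analyte in analytes:
                expected.add((process, str(RDF.type),
                              by_label[analyte].process_class_iri))
            expected.add((process, str(HAS_SPECIFIED_INPUT), sample))
            expected.add((process, str(DCTERMS.date),
                          rec.measurement_date.isoformat()))
            expected.add((process, str(PROV.generatedAtTime),
                          rec.record_timestamp.isoformat()))
            for analyte in analytes:
                datum = str(policy.mint("datum", key, analyte))
                expected.add((process, str(HAS_SPECIFIED_OUTPUT), datum))
                expected.add((datum, str(RDF.type),
                              by_label[analyte].datum_class_iri))
                expected.add((datum, str(HAS_VALUE), str(rec.levels[analyte])))
                expected.add((datum, str(HAS_UNIT), str(UNIT_PG_PER_ML)))
    return expected


def as_string_triples(graph):
    return {(str(s), str(p), str(o)) for s, p, o in graph}


def one_record(levels, panel_by_analyte, patient_id="P0001"):
    return MeasurementRecord(
        patient_id=patient_id,
        record_timestamp=datetime(2020, 4, 2, 10, 30, tzinfo=timezone.utc),
        sampling_date=date(2020, 4, 1),
        measurement_date=date(2020, 4, 2),
        patient_age=55,
        care_setting="ICU",
        levels=levels,
        panel_by_analyte=panel_by_analyte,
    )


class TestMeasurementPattern:
    def test_empty_input_gives_empty_graph(self, policy):
        assert len(rdfize_measurements([], [], policy)) == 0

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_single_record_triple_count_is_fixed_plus_per_analyte(self, k, policy):
        """With one panel and k analytes of pairwise distinct process
        classes, the instance-triple count is 11 + 5k."""
        analytes = [f"A{i}" for i in range(k)]
        mapping = [
            AnalyteMapping(a, f"http://example.org/datum/{a}",
                           f"http://example.org/process/{a}", "efo", "exact")
            for a in analytes
        ]
        record = one_record({a: 1.0 + i for i, a in enumerate(analytes)},
                            {a: 1 for a in analytes})
        graph = rdfize_measurements([record], mapping, policy)
        assert len(graph) == 11 + 5 * k
        assert as_string_triples(graph) == enumerate_expected_triples(
            [record], mapping, policy)

    def test_pilot_cohort_matches_oracle(self, pilot_cohort, pilot_mapping, policy):
        graph = rdfize_measurements(pilot_cohort, pilot_mapping, policy)
        assert as_string_triples(graph) == enumerate_expected_triples(
            pilot_cohort, pilot_mapping, policy)

    def test_one_process_node_per_record_and_panel(self, pilot_graph):
        """Process granularity mirrors multiplex panels: the pilot cohort has
        9 records x 4 panels = 36 distinct measurement-process nodes."""
        processes = set(pilot_graph.subjects(HAS_SPECIFIED_INPUT, None))
        assert len(processes) == 9 * 4

    @pytest.mark.parametrize("case_seed", range(6))
    def test_random_cohorts_match_oracle(self, case_seed, policy):
        rng = np.random.default_rng(100 + case_seed)
        config = small_config(rng)
        records = generate_cohort(config)
        mapping = default_mapping(config.analyte_panel)
        graph = rdfize_measurements(records, mapping, policy)
        assert as_string_triples(graph) == enumerate_expected_triples(
            records, mapping, policy)

    def test_unmapped_analyte_error_lists_analytes(self, policy):
        record = one_record({"IL-6": 1.0, "unmapped-x": 2.0},
                            {"IL-6": 1, "unmapped-x": 1})
        mapping = [m for m in default_mapping() if m.analyte_label == "IL-6"]
        with pytest.raises(RdfizeError, match="unmapped-x"):
            rdfize_measurements([record], mapping, policy)


class TestGraphProperties:
    def test_idempotent_under_content_hash_minting(self, pilot_cohort,
                                                   pilot_mapping, policy):
        first = rdfize_measurements(pilot_cohort, pilot_mapping, policy)
        second = rdfize_measurements(pilot_cohort, pilot_mapping, policy)
        assert set(first) == set(second)
        merged = set(first) | set(second)
        assert len(merged) == len(set(first))  # merging adds zero triples

    def test_every_datum_has_exactly_one_value_unit_and_type(self, pilot_graph):
        datums = set(pilot_graph.subjects(HAS_UNIT, None))
        assert datums
        for datum in datums:
            assert len(list(pilot_graph.objects(datum, HAS_VALUE))) == 1
            assert len(list(pilot_graph.objects(datum, HAS_UNIT))) == 1
            assert len(list(pilot_graph.objects(datum, RDF.type))) == 1

    def test_no_orphan_nodes(self, pilot_graph):
        """Every instance node is connected (undirected) to a patient node."""
        adjacency = {}
        for s, _, o in pilot_graph:
            if isinstance(o, URIRef):
                adjacency.setdefault(s, set()).add(o)
                adjacency.setdefault(o, set()).add(s)
        frontier = set(pilot_graph.subjects(RDF.type, PATIENT_CLASS))
        reachable = set(frontier)
        while frontier:
            frontier = {n for node in frontier for n in adjacency.get(node, ())
                        } - reachable
            reachable |= frontier
        base = GupridPolicy().base_iri
        instance_nodes = {n for n in adjacency if str(n).startswith(base)}
        assert instance_nodes <= reachable

    def test_minted_iris_under_base_and_pairwise_distinct(
            self, pilot_cohort, pilot_mapping):
        policy = GupridPolicy()
        graph = rdfize_measurements(pilot_cohort, pilot_mapping, policy)
        minted = {t for triple in graph for t in triple
                  if isinstance(t, URIRef) and str(t).startswith("https://w3id.org/")}
        assert minted
        assert all(str(iri).startswith(policy.base_iri) for iri in minted)

    def test_uuid_minting_still_yields_valid_unique_iris(self, pilot_cohort,
                                                         pilot_mapping):
        policy = GupridPolicy(minting_mode="uuid")
        graph = rdfize_measurements(pilot_cohort[:2], pilot_mapping, policy)
        patients = list(graph.subjects(RDF.type, PATIENT_CLASS))
        assert len(patients) == len(set(patients))
        assert all(str(p).startswith(policy.base_iri) for p in patients)


class TestSeverityPattern:
    def make_results(self, n, score_type="Leiden"):
        return [
            SeverityResult(f"P{i:04d}", date(2020, 4, 1 + i % 20), score_type,
                           value=i % 10)
            for i in range(1, n + 1)
        ]

    def test_empty_input_gives_empty_graph(self, policy):
        assert len(rdfize_severity([], policy)) == 0

    def test_single_score_row_yields_one_process_and_one_datum(self, policy):
        graph = rdfize_severity(self.make_results(1), policy)
        processes = list(graph.subjects(RDF.type,
                                        ASSESSMENT_PROCESS_CLASSES["Leiden"]))
        datums = list(graph.subjects(RDF.type, SCORE_DATUM_CLASSES["Leiden"]))
        assert len(processes) == 1 and len(datums) == 1
        assert len(list(graph.objects(datums[0], HAS_VALUE))) == 1

    @pytest.mark.parametrize("n", [2, 9, 25])
    def test_n_rows_give_n_score_datums(self, n, policy):
        graph = rdfize_severity(self.make_results(n), policy)
        datums = set(graph.subjects(RDF.type, SCORE_DATUM_CLASSES["Leiden"]))
        assert len(datums) == n  # brute-force count over the typed nodes

    def test_unknown_score_type_rejected(self, policy):
        bad = [SeverityResult("P0001", date(2020, 4, 1), "NEWS2", 3)]
        with pytest.raises(RdfizeError, match="NEWS2"):
            rdfize_severity(bad, policy)

    @pytest.mark.parametrize("score_type", ["ApacheIV", "SOFA", "Leiden"])
    def test_each_score_type_typed_by_its_class(self, score_type, policy):
        graph = rdfize_severity(self.make_results(3, score_type), policy)
        assert len(set(graph.subjects(
            RDF.type, SCORE_DATUM_CLASSES[score_type]))) == 3
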