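# fairclin

**FAIRification toolkit for longitudinal clinical cytokine measurements.**

Hospitals collect laboratory measurements — here, multiplex (Luminex-style)
cytokine panels assayed from patient blood samples over time — in systems
that are well structured for humans but not machine-actionable: no global
identifiers, no shared semantics, no machine-readable metadata. `fairclin`
is a desk-scale implementation of the FAIRification workflow that turns such
tabular data into FAIR Digital Objects (FDOs): data and metadata expressed
in RDF against ontological models, identified by globally unique persistent
resolvable identifiers (GUPRIDs), exposed as FAIR-Data-Point-style metadata
records, queryable with SPARQL alongside open knowledge sources, and
scorable against a FAIR-principles checklist. It is aimed at clinical data
stewards, FAIR data modellers and bioinformaticians who want a working,
fully testable reference for each step — with synthetic data only, so no
patient privacy is ever at risk.

## What it implements

* **Synthetic cohort generator** (`fairclin.cohort`) — longitudinal
  measurement records with the pilot dataset's shape: 9 records over 3
  patients, 103 cytokines in 4 panels, per-analyte concentrations drawn
  log-uniformly (seeded, byte-reproducible CSV), plus a companion table of
  daily clinical parameters.
* **The RDFizer** (`fairclin.rdfizer`) — a process-centred semantic model:
  every value is the *specified output* of a measurement process whose
  *specified input* is a biosample derived from a patient,

  ```
  patient ←prov:wasDerivedFrom– biosample ←obi:has_specified_input– process
  process –obi:has_specified_output→ datum –sio:has_value→ "x"^^xsd:decimal
                                           –sio:has_unit→ pg/mL
  ```

  with every node minted a content-hash GUPRID (re-runs are byte-identical
  and idempotent under merge). Analytes map to ontology terms through a
  103-row mapping table; analytes with no specific term fall back to
  declared generic classes ("blood interleukin measurement" for datum types,
  "Cytokine Measurement" for process types) and are flagged `generalized`.
* **Severity scoring** (`fairclin.severity`) — a banded point engine for
  the daily disease-severity score derived from the 4C mortality score:
  fixed admission parameters (age, sex, comorbidities) removed, daily
  oxygen parameters added (oxygen flow on the ward; p/f ratio and FiO2 in
  the ICU). The engine is the contract; band tables are overridable YAML.
  Scores are RDFized as dated assessment processes with typed score datums
  (Apache IV, SOFA, Leiden).
* **DCAT2 / FDP metadata** (`fairclin.metadata`) — dataset metadata with
  exactly four extension elements from exactly three vocabularies
  (`dct:type`; Allotrope *describes* and *is data input of*; OBO Relations
  *has quality*), an explicit `datacite:hasIdentifier` triple naming the
  data the record describes (principle F3), and a root → catalog → dataset
  → distribution record layout written as one Turtle file per record.
* **SPARQL query catalog** (`fairclin.query`) — an embedded in-memory store
  and grlc-style decorated `.rq` queries answering the driving questions:
  count patients, and retrieve measured cytokines joined with protein
  annotation from a packaged UniProt-shaped fixture graph (a desk-scale
  stand-in for live federation).
* **FAIR checklist** (`fairclin.assess`) — a local, deterministic,
  offline assessment of F1–F3, A1/A1.1, I1/I2 and R1–R1.3; F4, A1.2 and A2
  are reported *not applicable*.
* **Pipeline CLI** (`fairclin.cli`) — `fairclin generate | score | rdfize |
  metadata | query | assess | pipeline`, with a machine-readable run
  manifest.

## Worked example

```python
from fairclin import (CohortConfig, generate_cohort, default_mapping,
                      rdfize_measurements, load_graphs, count_patients,
                      cytokine_protein_profile, assess_metadata)
from fairclin.guprid import GupridPolicy
from fairclin.metadata import build_dataset_metadata, extension_edges
from fairclin.pipeline import default_descriptor

cohort = generate_cohort(CohortConfig(seed=1))
graph = rdfize_measurements(cohort, default_mapping(), GupridPolicy())
store = load_graphs(None, [graph])
print(len(cohort), len(cohort[0].levels), len(graph), count_patients(store))
# 9 103 4740 3

profile = cytokine_protein_profile(store)
print(len(profile))
print(profile[["patient", "value", "protein_name"]].head(3).to_string(index=False))
# 90
# patient               value  protein_name
#   P0001  173.70065874506514 Interleukin-2
#   P0001   0.919148682509402 Interleukin-4
#   P0001 0.12020325713587415 Interleukin-6

meta = build_dataset_metadata(default_descriptor(), GupridPolicy())
report = assess_metadata(meta)
print(len(extension_edges(meta)), len(report.passed()), len(report.failed()))
# 4 11 0
```

Reading: the 9-record cohort carries all 103 cytokines; the RDFizer emits a
4740-triple knowledge graph in which SPARQL finds the 3 generated patients;
the annotation join returns 90 rows (9 records × the 10 cytokines the
packaged protein fixture annotates), each pairing a measured concentration
(pg/mL) with a protein name; and the example metadata record carries the
four extension edges and passes all eleven checked FAIR indicators.

The same flow from a shell:

```sh
fairclin pipeline --seed 1 --out run/
cat run/manifest.json
```

## Scope notes

Live deployments are out of scope by design: no FAIR Data Point web
service, no external triple store, no REST API generation, no live
federation against UniProt, and no handling of real patient data. See
`docs/methods.md` for the model, its assumptions, and known limitations.
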