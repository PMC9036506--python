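# Methods

This note documents the models and procedures `fairclin` implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not demonstrate.

## The semantic data model

The measurement model is process-centred, following the core pattern used
for common data elements in patient registries: every recorded value is the
outcome of a process, and the *process of measurement* is the hub concept.
For each tabular measurement record the RDFizer instantiates:

| node | class | key properties |
|---|---|---|
| patient | `obo:NCIT_C16960` | `dct:identifier` (clinical id, literal) |
| biosample | `obo:OBI_0100051` | `prov:wasDerivedFrom` patient; `dct:date` sampling date |
| age datum | `obo:NCIT_C25150` | `sio:SIO_000300` integer; attached via `sio:SIO_000008` |
| measurement process | mapped process class(es) | `obo:OBI_0000293` biosample; `dct:date` measurement date; `prov:generatedAtTime` record timestamp |
| measurement datum | mapped datum class | `sio:SIO_000300` decimal; `sio:SIO_000221` unit (pg/mL, `obo:UO_0000205`) |

**Process granularity.** One measurement-process node is minted per
(record, panel), with one output datum per measured analyte in that panel.
This mirrors how a multiplex Luminex panel is actually run — one assay
yields many analyte values — and keeps the graph compact. The alternative
(one process per analyte) is equally defensible; the triple-count oracle in
the test suite is parameterized by the documented choice. A process node
carries one `rdf:type` per distinct mapped process class among its panel's
analytes.

**Severity module.** Each scored day becomes an assessment process
(`has_specified_input` the patient, `dct:date` the day) with one output
score datum typed by score kind (Apache IV, SOFA, Leiden) carrying a single
integer value and no unit (scores are dimensionless points).

**Term table.** All namespaces and term IRIs are pinned in one constants
module (`fairclin.vocab`). Widely published IRIs are used verbatim
(`obo:RO_0000086` *has quality*, `obo:MONDO_0100096` COVID-19,
`obo:OBI_0000293/0000299`, SIO attribute/value/unit relations). Where a
released term id is not publicly pinned — the per-analyte measurement
datum/process classes, the two generic fallback classes, the two Allotrope
extension properties, the score classes — the table carries syntactically
valid, documented defaults under the appropriate namespace (EFO positional
ids for per-analyte terms, a study namespace `bco:` for study-specific
classes). These are configuration defaults meant to be swapped for curated
terms in a real deployment; nothing resolves them over the network at
runtime, and no claim is made that the placeholder ids match live ontology
releases.

**Identifiers.** Every instance node gets a GUPRID under one
persistent-identifier-shaped base (default
`https://w3id.org/fair-clinical-cytokines/`, a W3ID-style base chosen so as
not to collide with any live registration). Default minting is
`content_hash`: SHA-256 of (entity kind, natural key) truncated to 16 hex
characters, making the whole pipeline a pure function of its inputs —
re-runs are byte-identical, graphs merge idempotently, and diffs are
meaningful. `uuid` mode exists for contexts where identifiers must not be
derivable from natural keys (at the cost of reproducibility). Blank nodes
are banned outright: they break canonical serialization and federation.
Resolvability of minted IRIs is a deployment property and is never checked.

**Canonical serialization.** The byte-determinism contract is implemented
in-package: Turtle output is an alphabetical `@prefix` block over the fixed
namespace table followed by one sorted `s p o .` statement per line
(N-Triples analogously). rdflib's serializers do not guarantee a canonical
form, so they are used only for parsing; round trips are validated as
triple-set equality.

## The synthetic cohort

The generator reproduces the *structural* conditions of the pilot dataset:
9 measurement records, 103 cytokines in 4 panels, record timestamp,
sampling date, measurement date, patient age, and a patient clinical
identifier linking records over time. Defaults: 3 patients × 3 time points
(so the identifier actually exercises longitudinal linking), admission
window 2020-03-01..2020-06-30, ages 18–90 years, 50 % ICU, no missing
values.

* **Concentrations** are log-uniform over 0.1–10 000 pg/mL: cytokine panels
  span several orders of magnitude, and a log-uniform draw weights every
  decade equally. The distribution is a declared, seeded choice — the
  original synthetic data was produced with spreadsheet randomization whose
  distribution is unspecified.
* **Analyte labels**: the shipped 103-label list (35 interleukins, 22
  TNF-superfamily/interferons, 24 chemokines, 22 growth factors/soluble
  receptors) is the package's own deterministic roster, built so that the
  mapping module's generalization rules are genuinely exercised (IL-11,
  IL-26, IL-32, IL-34, IL-37 fall back to the generic interleukin datum
  class; `TNFSF*` ligands to the generic measurement process class).
* **Missingness** is a per-cell drop probability; a missing level is an
  absent cell/key, never 0 or a sentinel.
* **Temporal invariant**: sampling date ≤ measurement date ≤ record date,
  enforced at construction and on CSV read.

What this does **not** emulate: any immunology. There is no disease-course
correlation between analytes, no ward/ICU level shift, no within-patient
autocorrelation. Passing tests therefore demonstrate the correctness of the
*infrastructure* (conversion, identification, metadata, query, assessment)
on data of realistic shape — they say nothing about biological plausibility
or about the messiness of real hospital exports (encodings, unit mixtures,
free-text fields).

## Severity score

The daily score derives from the 4C mortality score by removing its fixed
admission parameters (age, sex at birth, comorbidity count) — so the score
can track day-to-day state — and adding daily oxygen parameters: oxygen
flow (L/min) for ward patients, p/f ratio (kPa) and FiO2 (%) for ICU
patients. The engine evaluates ordered, disjoint half-open bands
`[lo, hi) → points` per parameter and sums integer points over the
parameters applicable to the care setting.

The shipped table keeps the published 4C bands for the retained components
(respiratory rate ≥30 → 2, 20–29.9 → 1; SpO2 < 92 % → 2; GCS < 15 → 2;
urea 7–14 mmol/L → 1, > 14 → 3; CRP 50–99 mg/L → 1, ≥ 100 → 2). No point
assignment for the three added oxygen parameters has been published;
their bands ship as placeholders flagged `provisional: true` and must be
replaced by a clinically validated table before any real-world use. The
engine — interval validation (disjoint, gap-free cover of the declared
range), applicability rules, integer summation, per-parameter breakdown —
is the tested contract; the property suite runs on randomized synthetic
band tables precisely so that no test encodes unvalidated clinical values.

Band lookup uses bisection over the sorted band edges; the test oracle
evaluates the same tables by independent linear scan.

## Metadata model and FAIR checklist

A dataset record carries the DCAT2 baseline (title, description, license,
publisher, issued/modified, version, themes, distributions with media type
and access/download URLs) plus exactly four extension edges from exactly
three vocabularies: `dct:type` (the resource is a *knowledge base*),
`afo:describes` (*COVID-19*), `afo:isDataInputOf` (*clinical study*),
`obo:RO_0000086` *has quality* (*synthetic data quality*). Every extension
object gets an `rdfs:label`, following the best practice that metadata GUIs
should never have to render a bare IRI fragment. F3 is realised as an
explicit `datacite:hasIdentifier` triple from the metadata record to the
GUPRID of the data it describes. The FDP layout is files on disk — root,
catalog, dataset and distribution records, each independently parseable and
bidirectionally linked via `dct:hasPart`/`dct:isPartOf` (plus
`dcat:dataset`/`dcat:distribution`) — not a web service.

The FAIR checklist is local, deterministic and purely syntactic:

* universal checks — F1 (record IRIs persistent-identifier-shaped: http(s)
  under w3id.org/purl.org/doi.org/identifiers.org), A1 (every dataset has
  an access or download URL), A1.1 (all such URLs use http(s)), I2 (every
  predicate and class IRI comes from the declared namespace table), R1
  (every dataset carries version and theme) — pass vacuously on an empty
  graph;
* presence checks — F2 (title + description), F3 (data-identifier triple),
  R1.1 (license), R1.2 (publisher + issued/modified), R1.3 (all four
  extension elements) — fail on an empty graph;
* I1 records that the input parses as RDF (unparseable input raises
  instead of producing a report, so I1 cannot fail in a report and is
  excluded from the ablation suite);
* F4, A1.2 and A2 are *not applicable*: indexing, authentication and
  metadata persistence are properties of a deployed service, not of a graph
  on disk.

Each pass/fail indicator inspects its own field, giving ablation soundness:
removing exactly that field flips exactly that indicator (verified for all
ten field-checkable indicators). A strict "adding triples never flips a
pass to a fail" monotonicity cannot coexist with universal checks (adding a
non-conformant triple legitimately fails I2 or A1.1); the tested guarantee
is therefore monotonicity under *benign* additions — descriptive triples in
declared vocabularies.

## Query layer

Graphs load into an embedded in-memory rdflib store (set semantics;
re-loading is a no-op), and the query catalog is a directory of `.rq` files
with `#+` YAML front matter declaring name, description, parameters and
result schema — the decorated-query convention used by grlc-style Linked
Data APIs, kept so the texts remain portable to an external triple store.
Measurement datums are selected by carrying a unit term, which cleanly
separates them from age and score datums.

The cytokine→protein profile is an inner join (only annotated cytokines are
returned; a left-join variant is catalogued separately) against a packaged
annotation graph shaped like UniProt RDF: ten human cytokine proteins with
accession IRIs, preferred names and organism, each linked via
`rdfs:seeAlso` from the measurement-datum term of the analyte it annotates.
The fixture is a synthetic stand-in for the live knowledgebase, not a
mirror; live SPARQL federation (`SERVICE`) is deliberately absent from the
code paths exercised here.

## Shape validation

Graph conformance is checked by a small declarative node-shape engine:
shapes target nodes by `rdf:type` and constrain per-property cardinality,
literal datatype and node kind — the constraint subset the instantiation
patterns need. Violations are data (node, shape, constraint, message), not
exceptions. The shipped shapes encode the exact patterns above, derived
from the active mapping, so RDFizer output validates with zero violations
and any single structural mutation is pinpointed to one violation.

## Numerical and procedural choices

* All randomness flows through seeded NumPy generators; the severity-row
  generator derives an independent stream from `[seed, 1]` so cohort and
  clinical-parameter draws do not interleave.
* CSV levels are written with `repr(float)` (shortest round-trip form), so
  CSV↔table round trips are exact and files are byte-stable.
* Dates are ISO-8601 `xsd:date`; timestamps UTC `xsd:dateTime` with
  Z-designator in CSV.
* Degenerate inputs: `n_records = 0` yields an empty cohort; empty graphs
  serialize to the prefix block alone and conform vacuously to all shapes;
  empty stores answer every catalog query with zero/empty results.
* Problem sizes in the test and acceptance suites — 100 random cohorts of
  ≤ 8 records × ≤ 10 analytes for oracle equivalence, 1 000 randomized
  (row, band-table) pairs for severity properties — are the package's
  chosen verification scale: large enough to exercise every code path and
  fallback rule, small enough that the full suite runs in seconds.

## Known limitations

* The per-analyte ontology term ids are positional placeholders, not
  curated mappings; a deployment must supply its own mapping CSV.
* The severity bands for oxygen flow, p/f ratio and FiO2 are provisional
  placeholders with no clinical validity.
* The FAIR checklist is syntactic: it never dereferences an IRI, so a
  well-shaped but dead identifier still passes F1/A1.
* Mixed measurement units are unsupported (one configured unit term per
  run); the unit is assumed pg/mL.
* The synthetic generator models structure, not biology (see above), and
  the UniProt-shaped fixture covers ten proteins only.
* No access control, consent semantics, or live service deployment of any
  kind.
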