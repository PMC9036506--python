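"""End-to-end orchestration: generate → score → rdfize → metadata → query → assess.

Each stage writes its outputs under one run directory and updates a machine-
readable ``manifest.json`` recording the tool version, a hash of the
configuration, the seed, per-stage row/triple counts and timestamps. With
content-hash identifier minting, re-running with identical configuration and
seed reproduces identical counts and identical RDF bytes. The first failing
stage aborts the run with an error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .assess import assess_metadata
from .cohort import (
    CohortConfig,
    generate_cohort,
    generate_severity_rows,
    write_severity_table,
    write_table,
)
from .errors import ConfigurationError, FairclinError, PipelineIOError
from .guprid import GupridPolicy
from .mapping import default_mapping, load_mapping, write_mapping
from .metadata import (
    CatalogInfo,
    DatasetDescriptor,
    Distribution,
    emit_fdp_layout,
    write_fdp_layout,
)
from .query import (
    QueryCatalog,
    count_patients,
    cytokine_protein_profile,
    load_annotation_fixture,
    load_graphs,
    run_query,
)
from .rdfizer import rdfize_measurements, rdfize_severity
from .serialize import serialize
from .severity import default_bands, load_bands, score_cohort, write_scores
from .vocab import DEFAULT_BASE_IRI

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "default_descriptor"]


def default_descriptor(base_iri: str = DEFAULT_BASE_IRI) -> DatasetDescriptor:
    """The example dataset descriptor: a knowledge base describing COVID-19,
    data input of clinical studies, of synthetic quality."""
    data_iri = base_iri + "rdf/cytokine-knowledge-graph.ttl"
    return DatasetDescriptor(
        title="Synthetic longitudinal clinical cytokine measurements",
        description=(
            "Process-centred RDF knowledge graph of synthetic longitudinal "
            "cytokine panel measurements of hospitalised patients, with "
            "daily disease-severity scores."
        ),
        license="https://creativecommons.org/licenses/by/4.0/",
        publisher="Example University Medical Center",
        issued=datetime(2020, 11, 1).date(),
        modified=datetime(2020, 12, 1).date(),
        version="1.0",
        themes=["http://purl.obolibrary.org/obo/MONDO_0100096"],
        data_identifier=data_iri,
        distributions=[
            Distribution(media_type="text/turtle", access_iri=data_iri,
                         download_iri=data_iri),
        ],
    )


class PipelineConfig(BaseModel):
    """Configuration of a full pipeline run."""

    out_dir: str = "fairclin-run"
    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    descriptor: Optional[DatasetDescriptor] = None
    base_iri: str = DEFAULT_BASE_IRI
    minting_mode: str = "content_hash"
    #: Optional paths overriding the shipped defaults.
    mapping_path: Optional[str] = None
    bands_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
            return cls(**payload)
        except OSError as exc:
            raise PipelineIOError(f"cannot read pipeline config {path}: {exc}") from exc
        except Exception as exc:
            raise ConfigurationError(f"{path}: invalid pipeline config: {exc}") from exc


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    tool_version: str
    config_hash: str
    seed: int
    started: str
    stages: dict = field(default_factory=dict)
    finished: Optional[str] = None

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, default=str) + "\n",
            encoding="utf-8",
        )


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage; the first failing stage aborts, naming the stage.

    Returns the manifest, which is also written (and progressively updated)
    as ``manifest.json`` in the run directory.
    """
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineIOError(f"cannot create output directory {out}: {exc}") from exc

    cohort_config = config.cohort.model_copy(update={"seed": config.seed})
    policy = GupridPolicy(base_iri=config.base_iri,
                          minting_mode=config.minting_mode)
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
        started=_now(),
    )
    manifest_path = out / "manifest.json"

    def record(stage_name: str, **info) -> None:
        info["at"] = _now()
        manifest.stages[stage_name] = info
        manifest.write(manifest_path)

    stage = "generate"
    try:
        records = generate_cohort(cohort_config)
        severity_rows = generate_severity_rows(cohort_config)
        cohort_csv = out / "cohort.csv"
        severity_csv = out / "severity.csv"
        write_table(records, cohort_csv, panel=cohort_config.analyte_panel)
        write_severity_table(severity_rows, severity_csv)
        record(
            "generate",
            n_records=len(records),
            n_analytes=len(cohort_config.analyte_panel),
            n_panels=cohort_config.n_panels,
            n_patients=len({r.patient_id for r in records}),
            n_severity_rows=len(severity_rows),
            cohort=str(cohort_csv), severity=str(severity_csv),
        )

        stage = "score"
        bands = (load_bands(config.bands_path) if config.bands_path
                 else default_bands())
        results = score_cohort(severity_rows, bands)
        scores_csv = out / "scores.csv"
        write_scores(results, scores_csv, bands)
        record("score", n_scores=len(results), scores=str(scores_csv))

        stage = "rdfize"
        if config.mapping_path:
            mapping = load_mapping(config.mapping_path)
        else:
            mapping = default_mapping(cohort_config.analyte_panel)
            write_mapping(mapping, out / "mapping.csv")
        data_graph = load_graphs(None, [
            rdfize_measurements(records, mapping, policy),
            rdfize_severity(results, policy),
        ])
        graph_ttl = out / "cytokine-knowledge-graph.ttl"
        graph_ttl.write_bytes(serialize(data_graph, "turtle"))
        record("rdfize", n_triples=len(data_graph), graph=str(graph_ttl))

        stage = "metadata"
        descriptor = config.descriptor or default_descriptor(config.base_iri)
        layout = emit_fdp_layout(CatalogInfo(), [descriptor], policy)
        fdp_dir = out / "fdp"
        write_fdp_layout(layout, fdp_dir)
        record(
            "metadata",
            n_dataset_records=len(layout.datasets),
            n_records_total=len(layout.records()),
            fdp=str(fdp_dir),
        )

        stage = "query"
        catalog = QueryCatalog.default()
        store = load_graphs(None, [data_graph])
        fixture = load_annotation_fixture()
        n_patients = count_patients(store)
        run_query(store, catalog, "count_patients",
                  out_csv=out / "query_count_patients.csv")
        profile = cytokine_protein_profile(store, fixture, catalog)
        profile.to_csv(out / "query_cytokine_protein_profile.csv", index=False)
        record("query", n_patients=n_patients, n_profile_rows=len(profile))

        stage = "assess"
        report = assess_metadata(layout.datasets[0][1])
        report_path = out / "fair_report.json"
        report.to_json(report_path)
        record(
            "assess",
            passed=report.passed(),
            failed=report.failed(),
            report=str(report_path),
        )
    except FairclinError as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    manifest.finished = _now()
    manifest.write(manifest_path)
    return manifest
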