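"""Exception hierarchy with the pipeline's exit-code contract.

Exit codes: 1 = configuration, 2 = data/graph validation, 3 = I/O.
"""


class FairclinError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ConfigurationError(FairclinError):
    """Invalid configuration (bad field value, missing required field)."""

    exit_code = 1


class DataValidationError(FairclinError):
    """Input data violates a declared invariant (bad row, bad graph)."""

    exit_code = 2


class MappingError(FairclinError):
    """Analyte→ontology mapping table is malformed or incomplete."""

    exit_code = 2


class RdfizeError(FairclinError):
    """Tabular records cannot be instantiated as RDF (e.g. unmapped analyte)."""

    exit_code = 2


class MetadataError(FairclinError):
    """Dataset descriptor incomplete or metadata graph malformed."""

    exit_code = 2


class SeverityError(FairclinError):
    """Severity row or band configuration violates the scoring contract."""

    exit_code = 2


class QueryError(FairclinError):
    """Query catalog problem: unknown name, bad SPARQL, missing parameter."""

    exit_code = 2


class AssessmentError(FairclinError):
    """FAIR assessment input is unreadable."""

    exit_code = 3


class PipelineIOError(FairclinError):
    """File system problem during a pipeline stage."""

    exit_code = 3
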