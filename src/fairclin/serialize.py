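"""Canonical, deterministic RDF serialization.

The FAIR graphs this package emits must be byte-identical across runs when
identifiers are content-hash minted, so serialization is canonical by
construction: triples are sorted, one statement per line, and the prefix
block is emitted in fixed alphabetical order. Turtle is the primary format,
N-Triples the secondary. Parsing goes through rdflib, so anything the wider
RDF toolchain produces can be read back.
"""

from __future__ import annotations

import re

from rdflib import Graph, Literal, URIRef

from .errors import DataValidationError
from .vocab import PREFIXES

__all__ = ["new_graph", "serialize", "parse"]

_FORMATS = {"turtle", "nt"}
#: Conservative prefixed-name local part (no dots/percent escapes).
_PN_LOCAL = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*$")

_SORTED_PREFIXES = sorted(PREFIXES.items())


def new_graph() -> Graph:
    """Return an empty rdflib graph with the package's namespace bindings."""
    g = Graph()
    for prefix, ns in _SORTED_PREFIXES:
        g.bind(prefix, ns, replace=True)
    return g


def _compact_iri(iri: str) -> str:
    """Compact an IRI to a prefixed name where the local part is safe."""
    best = None
    for prefix, ns in _SORTED_PREFIXES:
        if iri.startswith(ns) and (best is None or len(ns) > len(best[1])):
            best = (prefix, ns)
    if best is not None:
        local = iri[len(best[1]):]
        if _PN_LOCAL.match(local):
            return f"{best[0]}:{local}"
    return f"<{iri}>"


def _turtle_term(term) -> str:
    if isinstance(term, URIRef):
        return _compact_iri(str(term))
    if isinstance(term, Literal):
        text = term.n3()
        # compact a trailing ^^<datatype IRI>
        if text.endswith(">") and "^^<" in text:
            lexical, dtype = text.rsplit("^^<", 1)
            return f"{lexical}^^{_compact_iri(dtype[:-1])}"
        return text
    raise DataValidationError(
        f"blank nodes are not allowed in canonical graphs, got {term!r}"
    )


def _sorted_triples(graph: Graph):
    return sorted(graph, key=lambda t: tuple(term.n3() for term in t))


def serialize(graph: Graph, format: str = "turtle") -> bytes:
    """Serialize *graph* canonically; identical triple sets give identical bytes.

    ``turtle``: alphabetical ``@prefix`` block for the full package prefix
    map, then one sorted ``s p o .`` statement per line with prefixed names.
    ``nt``: sorted N-Triples.
    """
    if format not in _FORMATS:
        raise DataValidationError(
            f"unsupported serialization format {format!r}; choose from {sorted(_FORMATS)}"
        )
    lines: list[str] = []
    if format == "turtle":
        for prefix, ns in _SORTED_PREFIXES:
            lines.append(f"@prefix {prefix}: <{ns}> .")
        if len(graph):
            lines.append("")
        for s, p, o in _sorted_triples(graph):
            lines.append(f"{_turtle_term(s)} {_turtle_term(p)} {_turtle_term(o)} .")
    else:
        for s, p, o in _sorted_triples(graph):
            lines.append(f"{s.n3()} {p.n3()} {o.n3()} .")
    return ("\n".join(lines) + "\n").encode("utf-8")


def parse(data: bytes | str, format: str = "turtle") -> Graph:
    """Parse Turtle or N-Triples into a graph with the package's bindings.

    Syntax errors raise :class:`DataValidationError` carrying rdflib's
    line/position diagnostics.
    """
    if format not in _FORMATS:
        raise DataValidationError(
            f"unsupported serialization format {format!r}; choose from {sorted(_FORMATS)}"
        )
    g = new_graph()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    try:
        g.parse(data=data, format="turtle" if format == "turtle" else "nt")
    except Exception as exc:
        raise DataValidationError(f"RDF parse error ({format}): {exc}") from exc
    return g
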