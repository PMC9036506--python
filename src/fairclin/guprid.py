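"""Minting of globally unique persistent resolvable identifiers (GUPRIDs).

Every instance node in the data and metadata graphs gets an IRI minted under
a single persistent-identifier-shaped base (a W3ID/PURL-style base). Two
minting modes:

``content_hash`` (default)
    The IRI is a pure function of (entity kind, natural key): a truncated
    SHA-256 of the key. Re-running the same pipeline yields byte-identical
    graphs, which makes runs diffable and idempotent.

``uuid``
    A random UUID4 token per mint; use when identifiers must not leak any
    information about the natural key.

Resolvability of the base is a deployment property and is never checked at
runtime.
"""

from __future__ import annotations

import hashlib
import uuid
from dataclasses import dataclass, field
from typing import Mapping

from rdflib import URIRef

from .errors import ConfigurationError
from .vocab import DEFAULT_BASE_IRI

__all__ = ["GupridPolicy", "DEFAULT_PATH_TEMPLATES"]

#: Path template per entity kind, appended to the base IRI.
DEFAULT_PATH_TEMPLATES: Mapping[str, str] = {
    "patient": "patient/{token}",
    "biosample": "biosample/{token}",
    "process": "process/{token}",
    "datum": "datum/{token}",
    "assessment": "assessment/{token}",
    "score": "score/{token}",
    "agent": "agent/{token}",
    "root": "fdp/{token}",
    "catalog": "catalog/{token}",
    "dataset": "dataset/{token}",
    "distribution": "distribution/{token}",
}

_MINTING_MODES = ("content_hash", "uuid")


@dataclass(frozen=True)
class GupridPolicy:
    """Identifier-minting policy for all instance IRIs of a run."""

    base_iri: str = DEFAULT_BASE_IRI
    minting_mode: str = "content_hash"
    path_templates: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PATH_TEMPLATES)
    )
    #: Truncation length (hex chars) of the content hash token.
    hash_length: int = 16

    def __post_init__(self) -> None:
        if not self.base_iri.startswith(("http://", "https://")):
            raise ConfigurationError(
                f"base_iri must be an absolute http(s) IRI, got {self.base_iri!r}"
            )
        if not self.base_iri.endswith("/"):
            raise ConfigurationError("base_iri must end with '/'")
        if self.minting_mode not in _MINTING_MODES:
            raise ConfigurationError(
                f"minting_mode must be one of {_MINTING_MODES}, got {self.minting_mode!r}"
            )

    def token(self, kind: str, *natural_key: object) -> str:
        """Return the path token for an entity of *kind* with *natural_key*."""
        if kind not in self.path_templates:
            raise ConfigurationError(f"no path template for entity kind {kind!r}")
        if self.minting_mode == "uuid":
            return uuid.uuid4().hex
        material = "|".join([kind, *(str(part) for part in natural_key)])
        return hashlib.sha256(material.encode("utf-8")).hexdigest()[: self.hash_length]

    def mint(self, kind: str, *natural_key: object) -> URIRef:
        """Mint the IRI for an entity of *kind* identified by *natural_key*.

        In ``content_hash`` mode this is a pure function of its arguments.
        """
        template = self.path_templates[kind] if kind in self.path_templates else None
        if template is None:
            raise ConfigurationError(f"no path template for entity kind {kind!r}")
        return URIRef(self.base_iri + template.format(token=self.token(kind, *natural_key)))
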