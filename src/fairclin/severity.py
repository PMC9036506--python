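"""Daily disease-severity scoring via a configurable banded point engine.

The daily severity score is derived from the 4C mortality score: the fixed
admission parameters (age, sex at birth, number of comorbidities) are
removed so the score tracks day-to-day clinical state, and three daily
oxygen parameters are added — oxygen flow (L/min) for ward patients, and
p/f ratio (kPa) plus FiO2 (%) for ICU patients. Each applicable parameter
falls into exactly one half-open band ``[lo, hi) → points`` and the score is
the integer sum of band points.

The engine, not any particular band table, is the contract: band tables are
YAML, schema-validated, and overridable per deployment. The shipped default
keeps the published 4C bands for the retained components; the bands for the
three added oxygen parameters have no published point assignment and are
flagged ``provisional: true``.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml

from .cohort import SeverityDailyRow
from .errors import ConfigurationError, SeverityError

__all__ = [
    "Band", "ParameterBands", "ScoreBandConfig", "SeverityResult",
    "daily_severity_score", "score_cohort", "load_bands", "default_bands",
    "write_scores", "WARD_PARAMETERS", "ICU_PARAMETERS",
]

#: Applicable parameters per care setting.
WARD_PARAMETERS = ("respiratory_rate", "spo2", "gcs", "urea", "crp", "oxygen_flow")
ICU_PARAMETERS = ("respiratory_rate", "spo2", "gcs", "urea", "crp",
                  "pf_ratio", "fio2")

_APPLICABILITY = ("ward", "ICU", "both")


@dataclass(frozen=True)
class Band:
    """Half-open interval ``[lo, hi)`` worth ``points`` points."""

    lo: float
    hi: float
    points: int

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ConfigurationError(f"band [{self.lo}, {self.hi}) is empty")
        if int(self.points) != self.points or self.points < 0:
            raise ConfigurationError(
                f"band points must be a non-negative integer, got {self.points}"
            )


@dataclass(frozen=True)
class ParameterBands:
    """Ordered, disjoint bands covering one parameter's physiologic range."""

    name: str
    applicability: str  # "ward" | "ICU" | "both"
    unit: str
    bands: tuple[Band, ...]
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.applicability not in _APPLICABILITY:
            raise ConfigurationError(
                f"{self.name}: applicability must be one of {_APPLICABILITY}, "
                f"got {self.applicability!r}"
            )
        if not self.bands:
            raise ConfigurationError(f"{self.name}: at least one band required")
        ordered = sorted(self.bands, key=lambda b: b.lo)
        for left, right in zip(ordered, ordered[1:]):
            if left.hi != right.lo:
                raise ConfigurationError(
                    f"{self.name}: bands must be disjoint and cover the range "
                    f"without gaps; [{left.lo}, {left.hi}) is followed by "
                    f"[{right.lo}, {right.hi})"
                )
        object.__setattr__(self, "bands", tuple(ordered))

    @property
    def range(self) -> tuple[float, float]:
        return (self.bands[0].lo, self.bands[-1].hi)

    def points_for(self, value: float) -> int:
        """Points of the unique band containing *value*.

        Raises :class:`SeverityError` for out-of-range values.
        """
        lo, hi = self.range
        if not (lo <= value < hi):
            raise SeverityError(
                f"value {value} for parameter {self.name!r} outside the "
                f"declared range [{lo}, {hi})"
            )
        edges = [b.lo for b in self.bands]
        return self.bands[bisect.bisect_right(edges, value) - 1].points


@dataclass(frozen=True)
class ScoreBandConfig:
    """The complete banded point scheme: one :class:`ParameterBands` per
    clinical parameter, with care-setting applicability."""

    parameters: dict[str, ParameterBands]
    score_type: str = "Leiden"

    def applicable(self, care_setting: str) -> list[str]:
        return [
            name for name, p in self.parameters.items()
            if p.applicability == "both" or p.applicability == care_setting
        ]


@dataclass
class SeverityResult:
    """A scored day: integer total plus the per-parameter breakdown."""

    patient_id: str
    date: object
    score_type: str
    value: int
    breakdown: dict[str, int] = field(default_factory=dict)


def _config_from_dict(payload: dict) -> ScoreBandConfig:
    if not isinstance(payload, dict) or "parameters" not in payload:
        raise ConfigurationError("band config must be a mapping with a 'parameters' key")
    parameters: dict[str, ParameterBands] = {}
    for name, spec in payload["parameters"].items():
        try:
            bands = tuple(
                Band(float(b["lo"]), float(b["hi"]), int(b["points"]))
                for b in spec["bands"]
            )
            parameters[name] = ParameterBands(
                name=name,
                applicability=spec["applicability"],
                unit=spec.get("unit", ""),
                bands=bands,
                provisional=bool(spec.get("provisional", False)),
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"band config parameter {name!r} is missing key {exc}"
            ) from exc
    return ScoreBandConfig(
        parameters=parameters,
        score_type=payload.get("score_type", "Leiden"),
    )


def load_bands(path) -> ScoreBandConfig:
    """Load and validate a YAML band configuration."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigurationError(f"cannot read band config {path}: {exc}") from exc
    return _config_from_dict(payload)


def default_bands() -> ScoreBandConfig:
    """The shipped daily band table (4C bands for the retained components,
    provisional bands for the added oxygen parameters)."""
    text = resources.files("fairclin").joinpath("data/leiden_bands.yml").read_text(
        encoding="utf-8"
    )
    return _config_from_dict(yaml.safe_load(text))


def daily_severity_score(row: SeverityDailyRow, bands: ScoreBandConfig
                         ) -> SeverityResult:
    """Score one day: sum of band points over the parameters applicable to
    the row's care setting, with per-parameter breakdown.

    Age, sex and comorbidities never contribute — they are not parameters of
    the engine at all. A row carrying a non-applicable parameter (e.g. a
    ward row with a p/f ratio) or missing an applicable one is rejected.
    """
    applicable = bands.applicable(row.care_setting)
    breakdown: dict[str, int] = {}
    for name in applicable:
        value = getattr(row, name, None)
        if value is None:
            raise SeverityError(
                f"missing applicable parameter {name!r} for "
                f"({row.patient_id}, {row.date}, {row.care_setting})"
            )
        breakdown[name] = bands.parameters[name].points_for(float(value))
    inapplicable = [
        name for name in bands.parameters
        if name not in applicable and getattr(row, name, None) is not None
    ]
    if inapplicable:
        raise SeverityError(
            f"{row.care_setting} row ({row.patient_id}, {row.date}) carries "
            f"non-applicable parameter(s) {inapplicable}"
        )
    return SeverityResult(
        patient_id=row.patient_id,
        date=row.date,
        score_type=bands.score_type,
        value=sum(breakdown.values()),
        breakdown=breakdown,
    )


def score_cohort(rows: Sequence[SeverityDailyRow], bands: ScoreBandConfig
                 ) -> list[SeverityResult]:
    """Score every row, order-preserving; per-row errors carry the row index."""
    results: list[SeverityResult] = []
    for index, row in enumerate(rows):
        try:
            results.append(daily_severity_score(row, bands))
        except SeverityError as exc:
            raise SeverityError(f"row {index}: {exc}") from exc
    return results


def write_scores(results: Sequence[SeverityResult], path,
                 bands: Optional[ScoreBandConfig] = None) -> None:
    """Write scored results as CSV with one component column per parameter."""
    if bands is None:
        bands = default_bands()
    components = list(bands.parameters)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "date", "score_type", "value"] + components)
        for r in results:
            writer.writerow(
                [r.patient_id, r.date, r.score_type, r.value]
                + [r.breakdown.get(c, "") for c in components]
            )
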