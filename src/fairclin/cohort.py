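"""Synthetic longitudinal cytokine cohorts.

Generates cohorts with the structural shape of the study's pilot dataset:
measurement records of 103 cytokines assayed in 4 multiplex (Luminex-style)
panels, one CSV row per record with record timestamp, sampling date,
measurement date, patient age, care setting and per-analyte concentrations.
The default configuration produces the pilot shape — 9 records over 3
patients — and a companion table of daily clinical parameters for the
severity-score module.

Concentrations are drawn log-uniformly over the configured range: cytokine
levels span orders of magnitude, so a log-uniform draw gives every decade
equal weight. Missing values are absent cells, never zero or a sentinel.
All randomness flows through one seeded NumPy generator, so identical
(config, seed) pairs give byte-identical CSV output.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError, DataValidationError

__all__ = [
    "CARE_SETTINGS",
    "CohortConfig",
    "MeasurementRecord",
    "SeverityDailyRow",
    "default_panel",
    "generate_cohort",
    "generate_severity_rows",
    "write_table",
    "read_table",
    "write_severity_table",
    "read_severity_table",
]

CARE_SETTINGS = ("ward", "ICU")

#: Fixed (non-analyte) CSV columns, in order.
FIXED_COLUMNS = (
    "patient_id",
    "record_timestamp",
    "sampling_date",
    "measurement_date",
    "patient_age",
    "care_setting",
    "panel_id",
)

# ---------------------------------------------------------------------------
# The default 103-analyte / 4-panel definition
# ---------------------------------------------------------------------------

_PANEL_1_INTERLEUKINS = (
    "IL-1alpha", "IL-1beta", "IL-1RA", "IL-2", "IL-3", "IL-4", "IL-5",
    "IL-6", "IL-7", "IL-8", "IL-9", "IL-10", "IL-11", "IL-12p40",
    "IL-12p70", "IL-13", "IL-15", "IL-16", "IL-17A", "IL-17F", "IL-18",
    "IL-21", "IL-22", "IL-23", "IL-26", "IL-27", "IL-28A", "IL-29",
    "IL-31", "IL-32", "IL-33", "IL-34", "IL-35", "IL-36beta", "IL-37",
)
_PANEL_2_TNF_IFN = (
    "TNF-alpha", "TNF-beta", "TNFSF10", "TNFSF11", "TNFSF12", "TNFSF13",
    "TNFSF13B", "TNFSF14", "TNFSF15", "TNFSF18", "CD40L", "FasL", "OX40L",
    "4-1BBL", "sCD30", "IFN-alpha2", "IFN-beta", "IFN-gamma",
    "IFN-lambda1", "IFN-lambda2", "IFN-lambda3", "IFN-omega",
)
_PANEL_3_CHEMOKINES = (
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL7", "CCL8", "CCL11", "CCL13",
    "CCL17", "CCL19", "CCL20", "CCL21", "CCL22", "CCL24", "CCL26",
    "CCL27", "CXCL1", "CXCL5", "CXCL9", "CXCL10", "CXCL11", "CXCL12",
    "CXCL13", "CX3CL1",
)
_PANEL_4_GROWTH_FACTORS = (
    "EGF", "FGF-2", "G-CSF", "GM-CSF", "M-CSF", "HGF", "LIF", "NGF-beta",
    "PDGF-AA", "PDGF-BB", "PlGF", "SCF", "TGF-alpha", "TGF-beta1", "TSLP",
    "VEGF-A", "VEGF-D", "Flt-3L", "sIL-2Ralpha", "sIL-6Ralpha", "sTNF-RI",
    "sTNF-RII",
)

_DEFAULT_PANEL: tuple[tuple[str, int], ...] = tuple(
    (label, panel_id)
    for panel_id, labels in enumerate(
        (_PANEL_1_INTERLEUKINS, _PANEL_2_TNF_IFN, _PANEL_3_CHEMOKINES,
         _PANEL_4_GROWTH_FACTORS),
        start=1,
    )
    for label in labels
)


def default_panel() -> list[tuple[str, int]]:
    """Return the default analyte panel: 103 cytokines over 4 panels.

    The list is a constant: labels, order and panel assignment are stable
    across calls. Panel ids are the contiguous integers 1–4.
    """
    return list(_DEFAULT_PANEL)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class CohortConfig(BaseModel):
    """Parameters of a synthetic cohort; validated on construction.

    Defaults reproduce the pilot dataset shape: 9 measurement records over 3
    patients (three time points each), the full 103-analyte/4-panel assay,
    hospital admission window in spring 2020, ages 18–90, concentrations
    0.1–10000 pg/mL, no missing values.
    """

    n_records: int = Field(default=9, ge=0)
    n_patients: int = Field(default=3, ge=0)
    analyte_panel: list[tuple[str, int]] = Field(default_factory=default_panel)
    age_range: tuple[int, int] = (18, 90)
    level_range: tuple[float, float] = (0.1, 10000.0)
    date_window: tuple[date, date] = (date(2020, 3, 1), date(2020, 6, 30))
    seed: int = 0
    #: Fraction of patients in intensive care (the rest are on the ward).
    care_setting_mix: float = Field(default=0.5, ge=0.0, le=1.0)
    #: Per-cell probability that an analyte level is absent.
    missing_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("age_range")
    @classmethod
    def _age_range_valid(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[0] < 0 or v[0] > v[1]:
            raise ValueError(f"age_range must satisfy 0 <= min <= max, got {v}")
        return v

    @field_validator("level_range")
    @classmethod
    def _level_range_valid(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not (0.0 < v[0] < v[1]):
            raise ValueError(
                f"level_range must satisfy 0 < min < max for log-uniform sampling, got {v}"
            )
        return v

    @field_validator("date_window")
    @classmethod
    def _window_valid(cls, v: tuple[date, date]) -> tuple[date, date]:
        if v[0] > v[1]:
            raise ValueError(f"date_window start must not be after end, got {v}")
        return v

    @field_validator("analyte_panel")
    @classmethod
    def _panel_valid(cls, v: list[tuple[str, int]]) -> list[tuple[str, int]]:
        labels = [label for label, _ in v]
        if len(labels) != len(set(labels)):
            raise ValueError("analyte_panel contains duplicate analyte labels")
        panel_ids = sorted({pid for _, pid in v})
        if v and panel_ids != list(range(1, len(panel_ids) + 1)):
            raise ValueError(
                f"panel ids must form the contiguous set 1..k, got {panel_ids}"
            )
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "CohortConfig":
        if self.n_records > 0 and self.n_patients == 0:
            raise ValueError("n_patients must be >= 1 when n_records > 0")
        if self.n_patients > self.n_records:
            raise ValueError(
                f"n_patients ({self.n_patients}) must not exceed n_records ({self.n_records})"
            )
        return self

    @classmethod
    def create(cls, **kwargs) -> "CohortConfig":
        """Build a config, raising :class:`ConfigurationError` on bad fields."""
        try:
            return cls(**kwargs)
        except Exception as exc:  # pydantic.ValidationError names the field
            raise ConfigurationError(str(exc)) from exc

    @property
    def panel_of(self) -> dict[str, int]:
        return dict(self.analyte_panel)

    @property
    def n_panels(self) -> int:
        return len({pid for _, pid in self.analyte_panel})


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class MeasurementRecord:
    """One tabular row: a patient's panel measurements at one time point."""

    patient_id: str
    record_timestamp: datetime
    sampling_date: date
    measurement_date: date
    patient_age: int
    care_setting: str
    #: analyte label → concentration (pg/mL); missing analytes are absent keys.
    levels: dict[str, float] = field(default_factory=dict)
    #: analyte label → panel id (None for analytes of unknown provenance).
    panel_by_analyte: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.patient_age < 0:
            raise DataValidationError(
                f"patient_age must be >= 0, got {self.patient_age}"
            )
        if self.care_setting not in CARE_SETTINGS:
            raise DataValidationError(
                f"care_setting must be one of {CARE_SETTINGS}, got {self.care_setting!r}"
            )
        if not (self.sampling_date <= self.measurement_date
                <= self.record_timestamp.date()):
            raise DataValidationError(
                "temporal order violated: require sampling_date <= measurement_date "
                f"<= record date, got {self.sampling_date} / {self.measurement_date} "
                f"/ {self.record_timestamp.date()} for patient {self.patient_id}"
            )
        for analyte, value in self.levels.items():
            if value < 0:
                raise DataValidationError(
                    f"negative level {value} for analyte {analyte!r} "
                    f"(patient {self.patient_id})"
                )

    @property
    def panel_ids(self) -> tuple[int, ...]:
        """Sorted distinct panel ids covered by this record's measured analytes."""
        return tuple(sorted({
            pid for analyte, pid in self.panel_by_analyte.items()
            if pid is not None and analyte in self.levels
        }))


@dataclass
class SeverityDailyRow:
    """Daily clinical parameters feeding the severity score.

    Ward rows carry ``oxygen_flow`` (L/min) and no ``pf_ratio``/``fio2``;
    ICU rows carry ``pf_ratio`` (kPa) and ``fio2`` (%) and no ``oxygen_flow``.
    """

    patient_id: str
    date: date
    care_setting: str
    respiratory_rate: float  # breaths/min
    spo2: float              # %
    gcs: int                 # Glasgow Coma Scale, 3-15
    urea: float              # mmol/L
    crp: float               # mg/L
    oxygen_flow: Optional[float] = None  # L/min, ward only
    pf_ratio: Optional[float] = None     # kPa, ICU only
    fio2: Optional[float] = None         # %, ICU only

    def __post_init__(self) -> None:
        if self.care_setting not in CARE_SETTINGS:
            raise DataValidationError(
                f"care_setting must be one of {CARE_SETTINGS}, got {self.care_setting!r}"
            )
        if not 3 <= self.gcs <= 15:
            raise DataValidationError(f"gcs must be in 3..15, got {self.gcs}")
        if self.care_setting == "ward":
            if self.oxygen_flow is None:
                raise DataValidationError(
                    f"ward row ({self.patient_id}, {self.date}) requires oxygen_flow"
                )
            if self.pf_ratio is not None or self.fio2 is not None:
                raise DataValidationError(
                    f"ward row ({self.patient_id}, {self.date}) must not carry "
                    "pf_ratio or fio2"
                )
        else:
            if self.pf_ratio is None or self.fio2 is None:
                raise DataValidationError(
                    f"ICU row ({self.patient_id}, {self.date}) requires pf_ratio and fio2"
                )
            if self.oxygen_flow is not None:
                raise DataValidationError(
                    f"ICU row ({self.patient_id}, {self.date}) must not carry oxygen_flow"
                )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _patient_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> list[MeasurementRecord]:
    """Generate ``config.n_records`` measurement records over
    ``config.n_patients`` distinct patients, deterministically from
    ``config.seed``.

    Each patient keeps a fixed age and care setting across time points;
    per-analyte levels are log-uniform over ``config.level_range`` and
    dropped with probability ``config.missing_rate``.
    """
    if config.n_records == 0:
        return []
    rng = np.random.default_rng(config.seed)
    ids = _patient_ids(config.n_patients)
    lo_age, hi_age = config.age_range
    ages = {pid: int(rng.integers(lo_age, hi_age + 1)) for pid in ids}
    settings = {
        pid: ("ICU" if rng.random() < config.care_setting_mix else "ward")
        for pid in ids
    }

    # Every patient gets at least one record; the remainder are assigned
    # uniformly at random.
    assignment = list(range(config.n_patients))
    extra = config.n_records - config.n_patients
    if extra > 0:
        assignment.extend(int(i) for i in rng.integers(0, config.n_patients, extra))

    start, end = config.date_window
    window_days = (end - start).days
    log_lo, log_hi = np.log(config.level_range[0]), np.log(config.level_range[1])
    panel_map = config.panel_of

    records: list[MeasurementRecord] = []
    for patient_idx in assignment:
        pid = ids[patient_idx]
        sampling = start + timedelta(days=int(rng.integers(0, window_days + 1)))
        measurement = sampling + timedelta(days=int(rng.integers(0, 4)))
        ts = datetime.combine(
            measurement,
            time(hour=int(rng.integers(8, 18)), minute=int(rng.integers(0, 60))),
            tzinfo=timezone.utc,
        )
        levels: dict[str, float] = {}
        for analyte, _pid in config.analyte_panel:
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                continue
            levels[analyte] = float(np.exp(rng.uniform(log_lo, log_hi)))
        records.append(
            MeasurementRecord(
                patient_id=pid,
                record_timestamp=ts,
                sampling_date=sampling,
                measurement_date=measurement,
                patient_age=ages[pid],
                care_setting=settings[pid],
                levels=levels,
                panel_by_analyte=dict(panel_map),
            )
        )
    return records


def generate_severity_rows(config: CohortConfig) -> list[SeverityDailyRow]:
    """Generate one daily-parameter row per (patient, sampling date) implied
    by the cohort of *config*, deterministic given ``config.seed``.

    Values are drawn uniformly within common physiologic ranges (respiratory
    rate 12–40 /min, SpO2 85–100 %, GCS 3–15, urea 2–20 mmol/L, CRP 0–300
    mg/L; oxygen flow 0–15 L/min on the ward, p/f ratio 8–60 kPa and FiO2
    21–100 % in the ICU).
    """
    cohort = generate_cohort(config)
    keys = sorted({(r.patient_id, r.sampling_date, r.care_setting) for r in cohort})
    rng = np.random.default_rng([max(config.seed, 0), 1])
    rows: list[SeverityDailyRow] = []
    for pid, day, setting in keys:
        common = dict(
            patient_id=pid,
            date=day,
            care_setting=setting,
            respiratory_rate=float(np.round(rng.uniform(12, 40), 1)),
            spo2=float(np.round(rng.uniform(85, 100), 1)),
            gcs=int(rng.integers(3, 16)),
            urea=float(np.round(rng.uniform(2, 20), 1)),
            crp=float(np.round(rng.uniform(0, 300), 1)),
        )
        if setting == "ward":
            rows.append(SeverityDailyRow(
                **common, oxygen_flow=float(np.round(rng.uniform(0, 15), 1))
            ))
        else:
            rows.append(SeverityDailyRow(
                **common,
                pf_ratio=float(np.round(rng.uniform(8, 60), 1)),
                fio2=float(np.round(rng.uniform(21, 100), 1)),
            ))
    return rows


# ---------------------------------------------------------------------------
# CSV I/O (UTF-8, comma-separated, RFC 4180 quoting)
# ---------------------------------------------------------------------------


def _format_timestamp(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _parse_timestamp(text: str) -> datetime:
    return datetime.fromisoformat(text.replace("Z", "+00:00"))


def _analyte_columns(records: Sequence[MeasurementRecord],
                     panel: Sequence[tuple[str, int]]) -> list[str]:
    """Analyte columns in panel order, then any extra analytes alphabetically."""
    known = [label for label, _ in panel]
    extra = sorted({a for r in records for a in r.levels} - set(known))
    return known + extra


def write_table(records: Sequence[MeasurementRecord], path,
                panel: Optional[Sequence[tuple[str, int]]] = None) -> None:
    """Write records as CSV; byte-identical output for identical input."""
    if panel is None:
        panel = default_panel()
    analytes = _analyte_columns(records, panel)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(list(FIXED_COLUMNS) + analytes)
        for rec in records:
            row = [
                rec.patient_id,
                _format_timestamp(rec.record_timestamp),
                rec.sampling_date.isoformat(),
                rec.measurement_date.isoformat(),
                str(rec.patient_age),
                rec.care_setting,
                ";".join(str(p) for p in rec.panel_ids),
            ]
            for analyte in analytes:
                value = rec.levels.get(analyte)
                row.append("" if value is None else repr(value))
            writer.writerow(row)


def read_table(path, panel: Optional[Sequence[tuple[str, int]]] = None
               ) -> list[MeasurementRecord]:
    """Read a cohort CSV back into records (lossless round trip of
    :func:`write_table` when the same panel definition is supplied).

    Unknown analyte columns trigger a warning and are preserved with an
    undetermined panel. Rows violating the temporal-order invariant raise a
    :class:`DataValidationError` naming the offending data rows.
    """
    if panel is None:
        panel = default_panel()
    panel_map = dict(panel)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataValidationError(f"{path}: empty file, expected a header row")
        missing = [c for c in FIXED_COLUMNS if c not in header]
        if missing:
            raise DataValidationError(
                f"{path}: header missing required columns {missing}"
            )
        analyte_cols = [c for c in header if c not in FIXED_COLUMNS]
        unknown = [c for c in analyte_cols if c not in panel_map]
        if unknown:
            warnings.warn(
                f"{path}: unknown analyte columns preserved without a panel: {unknown}",
                stacklevel=2,
            )
        idx = {name: header.index(name) for name in header}
        records: list[MeasurementRecord] = []
        bad_rows: list[str] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise DataValidationError(
                    f"{path}: line {line_no}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            try:
                levels = {
                    a: float(row[idx[a]]) for a in analyte_cols if row[idx[a]] != ""
                }
                record = MeasurementRecord(
                    patient_id=row[idx["patient_id"]],
                    record_timestamp=_parse_timestamp(row[idx["record_timestamp"]]),
                    sampling_date=date.fromisoformat(row[idx["sampling_date"]]),
                    measurement_date=date.fromisoformat(row[idx["measurement_date"]]),
                    patient_age=int(row[idx["patient_age"]]),
                    care_setting=row[idx["care_setting"]],
                    levels=levels,
                    panel_by_analyte={a: panel_map.get(a) for a in analyte_cols},
                )
            except DataValidationError as exc:
                bad_rows.append(f"line {line_no}: {exc}")
                continue
            except ValueError as exc:
                raise DataValidationError(f"{path}: line {line_no}: {exc}") from exc
            records.append(record)
        if bad_rows:
            raise DataValidationError(
                f"{path}: {len(bad_rows)} invalid row(s):\n" + "\n".join(bad_rows)
            )
    return records


_SEVERITY_COLUMNS = (
    "patient_id", "date", "care_setting", "respiratory_rate", "spo2", "gcs",
    "urea", "crp", "oxygen_flow", "pf_ratio", "fio2",
)


def write_severity_table(rows: Sequence[SeverityDailyRow], path) -> None:
    """Write daily severity-parameter rows as CSV (absent fields are empty)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(_SEVERITY_COLUMNS)
        for r in rows:
            writer.writerow([
                r.patient_id, r.date.isoformat(), r.care_setting,
                repr(r.respiratory_rate), repr(r.spo2), str(r.gcs),
                repr(r.urea), repr(r.crp),
                "" if r.oxygen_flow is None else repr(r.oxygen_flow),
                "" if r.pf_ratio is None else repr(r.pf_ratio),
                "" if r.fio2 is None else repr(r.fio2),
            ])


def read_severity_table(path) -> list[SeverityDailyRow]:
    """Read daily severity-parameter rows (round trip of
    :func:`write_severity_table`)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataValidationError(f"{path}: empty file, expected a header row")
        missing = [c for c in _SEVERITY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise DataValidationError(
                f"{path}: header missing required columns {missing}"
            )
        rows = []
        for line_no, rec in enumerate(reader, start=2):
            try:
                rows.append(SeverityDailyRow(
                    patient_id=rec["patient_id"],
                    date=date.fromisoformat(rec["date"]),
                    care_setting=rec["care_setting"],
                    respiratory_rate=float(rec["respiratory_rate"]),
                    spo2=float(rec["spo2"]),
                    gcs=int(rec["gcs"]),
                    urea=float(rec["urea"]),
                    crp=float(rec["crp"]),
                    oxygen_flow=float(rec["oxygen_flow"]) if rec["oxygen_flow"] else None,
                    pf_ratio=float(rec["pf_ratio"]) if rec["pf_ratio"] else None,
                    fio2=float(rec["fio2"]) if rec["fio2"] else None,
                ))
            except (ValueError, DataValidationError) as exc:
                raise DataValidationError(f"{path}: line {line_no}: {exc}") from exc
    return rows
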