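"""Severity engine: band lookup vs a linear-scan oracle, monotonicity,
fixed-parameter exclusion, batch semantics."""

from __future__ import annotations

from datetime import date
from types import SimpleNamespace

import numpy as np
import pytest

from fairclin.cohort import CohortConfig, SeverityDailyRow, generate_severity_rows
from fairclin.errors import ConfigurationError, DataValidationError, SeverityError
from fairclin.severity import (
    Band,
    ParameterBands,
    ScoreBandConfig,
    daily_severity_score,
    default_bands,
    score_cohort,
)

PARAM_RANGES = {
    "respiratory_rate": (0.0, 80.0, "both"),
    "spo2": (0.0, 101.0, "both"),
    "gcs": (3.0, 16.0, "both"),
    "urea": (0.0, 200.0, "both"),
    "crp": (0.0, 1000.0, "both"),
    "oxygen_flow": (0.0, 80.0, "ward"),
    "pf_ratio": (0.0, 150.0, "ICU"),
    "fio2": (21.0, 101.0, "ICU"),
}


def random_band_config(rng: np.random.Generator) -> ScoreBandConfig:
    parameters = {}
    for name, (lo, hi, applicability) in PARAM_RANGES.items():
        n_bands = int(rng.integers(1, 5))
        cuts = sorted(c for c in set(np.round(rng.uniform(lo, hi, n_bands - 1), 3))
                      if lo < c < hi)
        edges = [lo, *cuts, hi]
        bands = tuple(
            Band(edges[i], edges[i + 1], int(rng.integers(0, 4)))
            for i in range(len(edges) - 1)
        )
        parameters[name] = ParameterBands(name, applicability, "", bands)
    return ScoreBandConfig(parameters=parameters)


def random_row(rng: np.random.Generator, care_setting=None) -> SeverityDailyRow:
    if care_setting is None:
        care_setting = "ward" if rng.random() < 0.5 else "ICU"
    kwargs = dict(
        patient_id="P0001",
        date=date(2020, 4, 1),
        care_setting=care_setting,
        respiratory_rate=float(rng.uniform(5, 60)),
        spo2=float(rng.uniform(60, 100)),
        gcs=int(rng.integers(3, 16)),
        urea=float(rng.uniform(1, 50)),
        crp=float(rng.uniform(0, 500)),
    )
    if care_setting == "ward":
        kwargs["oxygen_flow"] = float(rng.uniform(0, 40))
    else:
        kwargs["pf_ratio"] = float(rng.uniform(5, 80))
        kwargs["fio2"] = float(rng.uniform(21, 100))
    return SeverityDailyRow(**kwargs)


def linear_scan_oracle(row, config) -> int:
    """Independent evaluation: scan every band table linearly and sum."""
    total = 0
    for name, table in config.parameters.items():
        if table.applicability not in ("both", row.care_setting):
            continue
        value = float(getattr(row, name))
        matches = [b.points for b in table.bands if b.lo <= value < b.hi]
        assert len(matches) == 1  # exactly one band matches any in-range value
        total += matches[0]
    return total


class TestEngine:
    def test_all_lowest_bands_score_zero(self):
        row = SeverityDailyRow("P0001", date(2020, 4, 1), "ward",
                               respiratory_rate=16, spo2=97, gcs=15,
                               urea=5.0, crp=10.0, oxygen_flow=0.5)
        result = daily_severity_score(row, default_bands())
        assert result.value == 0
        assert all(points == 0 for points in result.breakdown.values())

    @pytest.mark.parametrize("case_seed", range(10))
    def test_matches_linear_scan_oracle_on_random_inputs(self, case_seed):
        rng = np.random.default_rng(case_seed)
        for _ in range(30):
            config = random_band_config(rng)
            row = random_row(rng)
            result = daily_severity_score(row, config)
            assert result.value == linear_scan_oracle(row, config)
            assert result.value == sum(result.breakdown.values())

    def test_breakdown_covers_exactly_applicable_parameters(self):
        bands = default_bands()
        rng = np.random.default_rng(1)
        ward = daily_severity_score(random_row(rng, "ward"), bands)
        icu = daily_severity_score(random_row(rng, "ICU"), bands)
        assert set(ward.breakdown) == {"respiratory_rate", "spo2", "gcs",
                                       "urea", "crp", "oxygen_flow"}
        assert set(icu.breakdown) == {"respiratory_rate", "spo2", "gcs",
                                      "urea", "crp", "pf_ratio", "fio2"}

    def test_ward_row_with_pf_ratio_rejected(self):
        with pytest.raises(DataValidationError, match="pf_ratio"):
            SeverityDailyRow("P0001", date(2020, 4, 1), "ward",
                             respiratory_rate=16, spo2=97, gcs=15, urea=5,
                             crp=10, oxygen_flow=1.0, pf_ratio=40.0)
        # the engine enforces applicability even for duck-typed rows
        row = SimpleNamespace(patient_id="P0001", date=date(2020, 4, 1),
                              care_setting="ward", respiratory_rate=16,
                              spo2=97, gcs=15, urea=5, crp=10,
                              oxygen_flow=1.0, pf_ratio=40.0, fio2=None)
        with pytest.raises(SeverityError, match="pf_ratio"):
            daily_severity_score(row, default_bands())

    def test_missing_applicable_parameter_rejected(self):
        row = SimpleNamespace(patient_id="P0001", date=date(2020, 4, 1),
                              care_setting="ward", respiratory_rate=16,
                              spo2=97, gcs=15, urea=5, crp=10)
        with pytest.raises(SeverityError, match="oxygen_flow"):
            daily_severity_score(row, default_bands())

    def test_out_of_range_value_names_parameter_and_value(self):
        row = SeverityDailyRow("P0001", date(2020, 4, 1), "ward",
                               respiratory_rate=16, spo2=97, gcs=15,
                               urea=5.0, crp=10.0, oxygen_flow=500.0)
        with pytest.raises(SeverityError, match=r"500.*oxygen_flow|oxygen_flow.*500"):
            daily_severity_score(row, default_bands())


class TestProperties:
    def test_monotonicity_over_randomized_bands(self):
        """Moving one parameter into a band with >= points never lowers the
        total score."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            config = random_band_config(rng)
            row = random_row(rng)
            base = daily_severity_score(row, config)
            name = str(rng.choice(config.applicable(row.care_setting)))
            table = config.parameters[name]
            current = table.points_for(float(getattr(row, name)))
            higher = [b for b in table.bands if b.points >= current]
            target = higher[int(rng.integers(0, len(higher)))]
            moved_value = (target.lo + target.hi) / 2
            moved = SimpleNamespace(**{**row.__dict__, name: moved_value})
            assert daily_severity_score(moved, config).value >= base.value

    def test_age_and_sex_never_contribute(self):
        """Perturbing fixed admission attributes leaves the score unchanged."""
        rng = np.random.default_rng(7)
        bands = default_bands()
        for _ in range(50):
            row = random_row(rng)
            base = daily_severity_score(row, bands).value
            perturbed = SimpleNamespace(**row.__dict__, age=int(rng.integers(0, 100)),
                                        sex=str(rng.choice(["female", "male"])))
            assert daily_severity_score(perturbed, bands).value == base

    def test_batch_equals_per_row_and_preserves_order(self):
        rows = generate_severity_rows(CohortConfig(seed=13))
        bands = default_bands()
        batch = score_cohort(rows, bands)
        singles = [daily_severity_score(r, bands) for r in rows]
        assert batch == singles

    def test_empty_batch(self):
        assert score_cohort([], default_bands()) == []

    def test_batch_error_reports_row_index(self):
        rows = [random_row(np.random.default_rng(0), "ward") for _ in range(3)]
        rows[2] = SeverityDailyRow("P0009", date(2020, 4, 1), "ward",
                                   respiratory_rate=16, spo2=97, gcs=15,
                                   urea=5.0, crp=10.0, oxygen_flow=500.0)
        with pytest.raises(SeverityError, match="row 2"):
            score_cohort(rows, default_bands())


class TestBandConfig:
    def test_default_table_structure(self):
        bands = default_bands()
        assert set(bands.parameters) == set(PARAM_RANGES)
        added = {"oxygen_flow", "pf_ratio", "fio2"}
        for name, table in bands.parameters.items():
            assert table.provisional == (name in added)

    def test_gap_between_bands_rejected(self):
        with pytest.raises(ConfigurationError, match="gap"):
            ParameterBands("x", "both", "", (Band(0, 10, 0), Band(20, 30, 1)))

    def test_negative_points_rejected(self):
        with pytest.raises(ConfigurationError, match="points"):
            Band(0, 10, -1)

    def test_empty_interval_rejected(self):
        with pytest.raises(ConfigurationError, match="empty"):
            Band(5, 5, 0)
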