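"""Core data types and tabular I/O for per-subject analyte measurements.

The canonical on-disk form is a long-format CSV (one row per subject ×
analyte) with columns ``subject_id, breed, sex, age_years, weight_kg,
analyte, value``; panels of claimed reference intervals are YAML/JSON
mappings ``analyte -> {low, high, units, decimals}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

MEASUREMENT_COLUMNS = [
    "subject_id",
    "breed",
    "sex",
    "age_years",
    "weight_kg",
    "analyte",
    "value",
]

VALID_SEXES = frozenset({"female", "male"})


@dataclass(frozen=True)
class AnalyteDefinition:
    """An analyte in the panel: display name, units, rounding decimals."""

    name: str
    units: str = ""
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.decimals < 0:
            raise ValueError(f"decimals must be >= 0, got {self.decimals}")


@dataclass(frozen=True)
class EligibilityCriteria:
    """Donor inclusion rules: age within [age_min, age_max] years (inclusive)
    and body weight strictly above ``weight_min`` kilograms."""

    age_min: float = 2.0
    age_max: float = 8.0
    weight_min: float = 25.0

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.weight_min <= 0:
            raise ValueError("weight_min must be > 0")


class ClaimedRIPanel:
    """Mapping of analyte name -> claimed reference interval (low, high).

    Optionally carries the analyte definitions (units/decimals) parsed from
    the same config file.
    """

    def __init__(
        self,
        entries: dict[str, tuple[float, float]],
        analytes: list[AnalyteDefinition] | None = None,
    ) -> None:
        for name, (low, high) in entries.items():
            if not low < high:
                raise ValueError(
                    f"claimed RI for {name!r} must satisfy low < high, got ({low}, {high})"
                )
        self.entries = {k: (float(v[0]), float(v[1])) for k, v in entries.items()}
        self.analytes = analytes or [AnalyteDefinition(n) for n in entries]

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.entries

    def __getitem__(self, analyte: str) -> tuple[float, float]:
        return self.entries[analyte]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def definition(self, analyte: str) -> AnalyteDefinition:
        for a in self.analytes:
            if a.name == analyte:
                return a
        raise KeyError(analyte)


@dataclass
class MeasurementTable:
    """Long-format measurement table plus its panel of analyte definitions.

    Invariants enforced at construction: at most one value per
    (subject_id, analyte); every value finite; every analyte known to the
    panel; sex one of female/male; age and weight positive.
    """

    data: pd.DataFrame
    analytes: list[AnalyteDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        df = df[MEASUREMENT_COLUMNS].reset_index(drop=True)
        dup = df.duplicated(subset=["subject_id", "analyte"], keep=False)
        if dup.any():
            first = df.loc[dup, ["subject_id", "analyte"]].iloc[0]
            raise ValueError(
                "duplicate (subject_id, analyte) pair: "
                f"({first['subject_id']!r}, {first['analyte']!r})"
            )
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = values.isna() | ~values.map(lambda v: abs(v) != float("inf"))
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"non-numeric or non-finite value in row {i}, column 'value': "
                f"{df['value'].iloc[i]!r}"
            )
        df["value"] = values.astype(float)
        if self.analytes:
            known = {a.name for a in self.analytes}
            unknown = set(df["analyte"]) - known
            if unknown:
                raise ValueError(f"unknown analyte label(s): {sorted(unknown)}")
        bad_sex = ~df["sex"].isin(VALID_SEXES)
        if bad_sex.any():
            raise ValueError(
                f"sex must be 'female' or 'male', got {df.loc[bad_sex, 'sex'].iloc[0]!r}"
            )
        for col in ("age_years", "weight_kg"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or (vals <= 0).any():
                raise ValueError(f"column {col!r} must be numeric and > 0")
            df[col] = vals.astype(float)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject with its metadata."""
        return (
            self.data[["subject_id", "breed", "sex", "age_years", "weight_kg"]]
            .drop_duplicates(subset="subject_id")
            .reset_index(drop=True)
        )

    def values_for(self, analyte: str) -> pd.Series:
        """All values of one analyte, indexed by subject_id."""
        sub = self.data[self.data["analyte"] == analyte]
        return pd.Series(sub["value"].to_numpy(), index=sub["subject_id"].to_numpy())


def read_measurements(
    path: str | Path, panel: list[AnalyteDefinition] | None = None
) -> MeasurementTable:
    """Read a long-format measurement CSV, validating rows against ``panel``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "breed": str, "sex": str})
    return MeasurementTable(df, analytes=panel or [])


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def apply_eligibility_filter(
    table: MeasurementTable, criteria: EligibilityCriteria | None = None
) -> MeasurementTable:
    """Drop every row of any subject outside the donor eligibility window.

    Age bounds are inclusive; the weight bound is strict (> weight_min).
    Filtering acts on whole subjects, never on individual analyte rows.
    """
    criteria = criteria or EligibilityCriteria()
    subj = table.subjects
    ok = (
        (subj["age_years"] >= criteria.age_min)
        & (subj["age_years"] <= criteria.age_max)
        & (subj["weight_kg"] > criteria.weight_min)
    )
    keep = set(subj.loc[ok, "subject_id"])
    kept = table.data[table.data["subject_id"].isin(keep)].reset_index(drop=True)
    return MeasurementTable(kept, analytes=table.analytes)


def read_claimed_panel(path: str | Path) -> ClaimedRIPanel:
    """Read a claimed-RI panel config (YAML or JSON): analyte -> {low, high, ...}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"panel config {path} must map analyte -> entry")
    entries: dict[str, tuple[float, float]] = {}
    analytes: list[AnalyteDefinition] = []
    for name, entry in raw.items():
        try:
            low, high = float(entry["low"]), float(entry["high"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed panel entry for {name!r}: {entry!r}") from exc
        entries[name] = (low, high)
        analytes.append(
            AnalyteDefinition(
                name=name,
                units=str(entry.get("units", "")),
                decimals=int(entry.get("decimals", 2)),
            )
        )
    return ClaimedRIPanel(entries, analytes)


def wide_to_long(df: pd.DataFrame, analyte_columns: list[str]) -> pd.DataFrame:
    """Convenience converter from wide (one column per analyte) to the
    canonical long format. Missing values are dropped, not imputed."""
    id_cols = ["subject_id", "breed", "sex", "age_years", "weight_kg"]
    long = df.melt(
        id_vars=id_cols, value_vars=analyte_columns, var_name="analyte", value_name="value"
    )
    return long.dropna(subset=["value"]).reset_index(drop=True)
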