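"""Packaged fixtures: the claimed 21-analyte canine panel, per-breed
round-wise outside-percentages, published breed RIs, and per-breed
summary statistics driving the synthetic cohort generator.

Breed codes: A Ariegeois (n=156), B Bleu de Gascogne (52), C Bracco
italiano (64), D Segugio italiano (123), E Briquet Griffon Vandeen (50).

Notes on transcription: the published summary table swaps the unit labels
of HCT and Hb (printed "g/dL" for HCT and "%" for Hb); the fixture stores
HCT in % and Hb in g/dL. The source reports RDW-SD in its methods but
RDW-CV in its tables; the fixture uses the single generic label "RDW".
Decimal-comma typos in published limits are transcribed as plain decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..io import ClaimedRIPanel, read_claimed_panel
from ..synthetic import CohortEntry, CohortSpec

BREED_NAMES = {
    "A": "Ariegeois",
    "B": "Bleu de Gascogne",
    "C": "Bracco italiano",
    "D": "Segugio italiano",
    "E": "Briquet Griffon Vandeen",
}

BREED_SIZES = {"A": 156, "B": 52, "C": 64, "D": 123, "E": 50}


def _path(name: str):
    return resources.files(__package__) / name


def load_claimed_panel() -> ClaimedRIPanel:
    """The laboratory's claimed RIs with units and display decimals."""
    return read_claimed_panel(str(_path("table1_claimed.yaml")))


def load_outside_percentages() -> pd.DataFrame:
    """Printed round-wise outside-percentages per breed and analyte.

    Columns: breed, analyte, pct1, pct2 (NaN when no second round was
    printed), reported_new_ri (1 when the source's results list a new
    breed RI for that analyte).
    """
    return pd.read_csv(_path("table1_outside_percent.csv"))


def load_breed_ris() -> pd.DataFrame:
    """Published new breed RIs (comparison fixture only — these derive from
    the unavailable raw donor data and are not recomputed here)."""
    return pd.read_csv(_path("table1_breed_ris.csv"))


def load_summaries() -> pd.DataFrame:
    """Per-breed, per-analyte mean/SD/median/min/max with generator family."""
    return pd.read_csv(_path("table3_summaries.csv"))


def load_cohort_specs() -> dict[str, CohortSpec]:
    """Synthetic-cohort specs for all five breeds, one entry per analyte."""
    df = load_summaries()
    specs: dict[str, CohortSpec] = {}
    for (breed, n), group in df.groupby(["breed", "n"]):
        entries = {
            row.analyte: CohortEntry(
                family=row.family,
                mean=float(row.mean_),
                sd=float(row.sd),
                lower=float(row.min),
                upper=float(row.max),
                units=row.units,
            )
            for row in group.rename(columns={"mean": "mean_"}).itertuples()
        }
        specs[breed] = CohortSpec(breed=breed, n=int(n), entries=entries)
    return specs
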