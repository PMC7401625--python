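"""Panel reports: per-breed validation tables, new-RI aggregation, and the
replay of published round-wise percentages through the decision rule.

A panel report pairs each analyte's validation outcome with the claimed RI
and, for rejected analytes, the freshly estimated breed RI. The replay
path re-derives validate/reject decisions from printed outside-percentage
cells alone (percent / 5 = count out of 20) and flags any analyte whose
rule-derived decision disagrees with the published new-RI list, rather
than silently matching the publication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ClaimedRIPanel
from .ri import ReferenceIntervalEstimate
from .transference import (
    DECISION_REJECTED,
    DECISION_VALIDATED,
    ValidationOutcome,
    two_round_decision,
)


def format_outside_string(c1: int, c2: int | None = None) -> str:
    """Render round counts as integer percentages of 20: "P1" or "P1 (P2)"."""
    if not 0 <= c1 <= 20:
        raise ValueError(f"c1 must be in 0..20, got {c1}")
    if c2 is None:
        return str(5 * c1)
    if not 0 <= c2 <= 20:
        raise ValueError(f"c2 must be in 0..20, got {c2}")
    return f"{5 * c1} ({5 * c2})"


@dataclass
class PanelReport:
    breed: str
    rows: list[dict] = field(default_factory=list)

    @property
    def new_ri_analytes(self) -> set[str]:
        return {r["analyte"] for r in self.rows if r["decision"] == DECISION_REJECTED}

    @property
    def new_ri_count(self) -> int:
        return len(self.new_ri_analytes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_markdown(self, decimals: dict[str, int] | None = None) -> str:
        decimals = decimals or {}
        lines = [
            f"## Breed {self.breed}: transference validation",
            "",
            "| Analyte | Outside RI (%) | Decision | Claimed RI | Breed RI |",
            "|---|---|---|---|---|",
        ]
        for r in self.rows:
            d = decimals.get(r["analyte"], 2)
            claimed = f"{r['claimed_low']:.{d}f}-{r['claimed_high']:.{d}f}"
            if r["decision"] == DECISION_REJECTED and r.get("new_lrl") is not None:
                new = f"**{r['new_lrl']:.{d}f}-{r['new_url']:.{d}f}**"
            else:
                new = "(claimed retained)"
            lines.append(
                f"| {r['analyte']} | {r['outside']} | {r['decision']} | {claimed} | {new} |"
            )
        lines += ["", f"New RIs established for {self.new_ri_count} analytes."]
        return "\n".join(lines)


def build_panel_report(
    outcomes: dict[str, ValidationOutcome],
    estimates: dict[str, ReferenceIntervalEstimate],
    panel: ClaimedRIPanel,
    breed: str,
) -> PanelReport:
    """Assemble a per-breed report; every rejected analyte must carry an
    estimate, and rows follow the panel's analyte order."""
    missing = [a for a in panel if a not in outcomes]
    if missing:
        raise ValueError(f"no validation outcome for panel analyte(s): {missing}")
    report = PanelReport(breed=breed)
    for analyte in panel:
        outcome = outcomes[analyte]
        low, high = panel[analyte]
        row = {
            "analyte": analyte,
            "outside": format_outside_string(outcome.c1, outcome.c2),
            "pct1": outcome.pct1,
            "pct2": outcome.pct2,
            "decision": outcome.decision,
            "claimed_low": low,
            "claimed_high": high,
            "new_lrl": None,
            "new_url": None,
            "method": None,
        }
        if outcome.decision == DECISION_REJECTED:
            if analyte not in estimates:
                raise ValueError(
                    f"rejected analyte {analyte!r} has no reference-interval estimate"
                )
            est = estimates[analyte]
            d = panel.definition(analyte).decimals
            row["new_lrl"] = round(est.lrl, d)
            row["new_url"] = round(est.url, d)
            row["method"] = est.method
        report.rows.append(row)
    return report


def union_new_ri_analytes(reports: list[PanelReport]) -> set[str]:
    """Analytes given a new RI in at least one breed."""
    if not reports:
        raise ValueError("need at least one report")
    out: set[str] = set()
    for r in reports:
        out |= r.new_ri_analytes
    return out


def decisions_from_printed_percentages(
    percent_rows: dict[str, tuple[float, float | None]],
) -> dict[str, str]:
    """Replay the two-round rule from printed percentage cells.

    ``percent_rows`` maps analyte -> (pct1, pct2 or None); percentages must
    be multiples of 5 in [0, 100] since each round holds 20 values.
    """
    decisions: dict[str, str] = {}
    for analyte, (pct1, pct2) in percent_rows.items():
        cs = []
        for pct in (pct1, pct2):
            if pct is None:
                cs.append(None)
                continue
            if pct % 5 or not 0 <= pct <= 100:
                raise ValueError(
                    f"{analyte}: percentage {pct} is not a multiple of 5 in [0, 100]"
                )
            cs.append(int(pct) // 5)
        decisions[analyte] = two_round_decision(cs[0], cs[1])
    return decisions


def replay_published_decisions(outside: pd.DataFrame) -> pd.DataFrame:
    """Replay every breed's printed percentage cells through the rule and
    compare with the published new-RI lists.

    Input columns: breed, analyte, pct1, pct2 (NaN allowed),
    reported_new_ri (0/1). Output adds ``rule_decision`` and
    ``discrepancy`` (True where the rule's decision disagrees with the
    published list — flagged, never suppressed).
    """
    rows = []
    for r in outside.itertuples():
        pct2 = None if pd.isna(r.pct2) else float(r.pct2)
        decision = decisions_from_printed_percentages(
            {r.analyte: (float(r.pct1), pct2)}
        )[r.analyte]
        reported = (
            DECISION_REJECTED if int(r.reported_new_ri) else DECISION_VALIDATED
        )
        rows.append(
            {
                "breed": r.breed,
                "analyte": r.analyte,
                "pct1": float(r.pct1),
                "pct2": pct2,
                "outside": format_outside_string(
                    int(r.pct1) // 5, None if pct2 is None else int(pct2) // 5
                ),
                "rule_decision": decision,
                "reported_decision": reported,
                "discrepancy": decision != reported,
            }
        )
    return pd.DataFrame(rows)


def rejected_counts(replay: pd.DataFrame) -> dict[str, int]:
    """Rule-rejected analyte count per breed from a replay frame."""
    rej = replay[replay["rule_decision"] == DECISION_REJECTED]
    counts = rej.groupby("breed")["analyte"].count().to_dict()
    return {b: int(counts.get(b, 0)) for b in sorted(replay["breed"].unique())}


def rejected_union(replay: pd.DataFrame) -> set[str]:
    """Union over breeds of rule-rejected analytes from a replay frame."""
    rej = replay[replay["rule_decision"] == DECISION_REJECTED]
    return set(rej["analyte"])
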