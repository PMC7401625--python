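"""Two-round, 20-sample transference validation of claimed reference
intervals.

The procedure tests whether an existing ("claimed") RI can be carried over
to a new population: shuffle the population's values for one analyte into
a random order, take the first 20, and count how many fall outside the
claimed interval (limits count as inside).

* 0-2 outside (<= 10%)  -> the claimed RI is validated;
* 6+ outside  (> 25%)   -> rejected outright;
* 3-5 outside (15-25%)  -> a second, disjoint batch of 20 is drawn and the
  10% threshold applied to it: 0-2 outside validates, 3+ rejects.

Counts are reported as percentages of 20 (5 percentage points per value),
formatted "P1" or "P1 (P2)". A rejected analyte gets a fresh breed RI from
the full, outlier-screened cohort.

``TransferenceValidator`` exposes the rule as a scikit-learn estimator:
construct with the claimed limits, ``fit`` on the cohort values, read
``decision_``, ``c1_``, ``c2_``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ClaimedRIPanel, MeasurementTable
from .ri import ReferenceIntervalEstimate, estimate_reference_interval

DECISION_VALIDATED = "validated"
DECISION_REJECTED = "rejected"

BATCH = 20
VALIDATE_MAX = 2   # counts <= this validate a round
REJECT_MIN = 6     # round-1 counts >= this reject outright


@dataclass(frozen=True)
class ValidationOutcome:
    analyte: str
    c1: int
    c2: int | None
    decision: str
    seed: int | None
    subset_ids_round1: tuple
    subset_ids_round2: tuple | None = None

    @property
    def pct1(self) -> int:
        return 5 * self.c1

    @property
    def pct2(self) -> int | None:
        return None if self.c2 is None else 5 * self.c2


def derive_seed(master_seed: int, analyte: str) -> int:
    """Deterministic per-analyte seed below 2**31, stable across platforms."""
    digest = hashlib.sha256(f"{master_seed}:{analyte}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def shuffle_order(values, seed: int | None = None):
    """Seeded uniform random permutation of a keyed collection.

    Accepts a pandas Series (keys = index) or any sequence; returns the
    same type, permuted. Sampling across validation rounds is without
    replacement by construction (rounds are slices of one permutation).
    """
    rng = np.random.default_rng(seed)
    if isinstance(values, pd.Series):
        if values.empty:
            raise ValueError("cannot shuffle an empty collection")
        perm = rng.permutation(len(values))
        return values.iloc[perm]
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("cannot shuffle an empty collection")
    return arr[rng.permutation(arr.shape[0])]


def count_outside(subset, claimed: tuple[float, float]) -> int:
    """Values strictly below the claimed low or strictly above the claimed
    high; values exactly on a limit count as inside."""
    x = np.asarray(subset, dtype=float)
    if x.size == 0:
        raise ValueError("subset must be non-empty")
    low, high = claimed
    return int(np.sum((x < low) | (x > high)))


def two_round_decision(c1: int, c2: int | None = None) -> str:
    """Apply the decision rule to the round counts.

    Round 2 is required exactly when 3 <= c1 <= 5 (the printed artifacts
    show a second round at 25%, so immediate rejection needs c1 >= 6).
    """
    if not 0 <= c1 <= BATCH:
        raise ValueError(f"c1 must be in 0..{BATCH}, got {c1}")
    needs_round2 = VALIDATE_MAX < c1 < REJECT_MIN
    if needs_round2 and c2 is None:
        raise ValueError(f"c1 = {c1} requires a second round, but c2 is missing")
    if not needs_round2 and c2 is not None:
        raise ValueError(f"c1 = {c1} does not allow a second round, but c2 was given")
    if c1 <= VALIDATE_MAX:
        return DECISION_VALIDATED
    if c1 >= REJECT_MIN:
        return DECISION_REJECTED
    if not 0 <= c2 <= BATCH:
        raise ValueError(f"c2 must be in 0..{BATCH}, got {c2}")
    return DECISION_VALIDATED if c2 <= VALIDATE_MAX else DECISION_REJECTED


def validate_against_claimed(
    values,
    claimed: tuple[float, float],
    seed: int | None = None,
    analyte: str = "",
) -> ValidationOutcome:
    """Run the full two-round procedure on one analyte's cohort values.

    ``values`` may be a pandas Series keyed by subject id (keys are
    recorded in the outcome) or a plain sequence. Requires >= 20 values,
    and >= 40 when a second round is triggered.
    """
    if not isinstance(values, pd.Series):
        arr = np.asarray(values, dtype=float).ravel()
        values = pd.Series(arr, index=pd.RangeIndex(arr.size))
    if len(values) < BATCH:
        raise ValueError(f"need at least {BATCH} values, got {len(values)}")
    shuffled = shuffle_order(values, seed=seed)
    round1 = shuffled.iloc[:BATCH]
    c1 = count_outside(round1.to_numpy(), claimed)
    if VALIDATE_MAX < c1 < REJECT_MIN:
        if len(shuffled) < 2 * BATCH:
            raise ValueError(
                f"round 2 triggered (c1 = {c1}) but only {len(shuffled)} values "
                f"are available; {2 * BATCH} are required — collect more data "
                "or reject manually"
            )
        round2 = shuffled.iloc[BATCH : 2 * BATCH]
        c2 = count_outside(round2.to_numpy(), claimed)
        decision = two_round_decision(c1, c2)
        return ValidationOutcome(
            analyte=analyte, c1=c1, c2=c2, decision=decision, seed=seed,
            subset_ids_round1=tuple(round1.index),
            subset_ids_round2=tuple(round2.index),
        )
    decision = two_round_decision(c1)
    return ValidationOutcome(
        analyte=analyte, c1=c1, c2=None, decision=decision, seed=seed,
        subset_ids_round1=tuple(round1.index),
    )


class TransferenceValidator(BaseEstimator):
    """The two-round rule as a scikit-learn estimator.

    Parameters
    ----------
    low, high : float
        Claimed reference limits being tested.
    random_state : int or None
        Seed for the shuffle.

    Attributes (after ``fit``)
    --------------------------
    c1_, c2_ : int / int or None
        Outside counts per round.
    decision_ : {"validated", "rejected"}
    outcome_ : ValidationOutcome
    """

    def __init__(self, low: float, high: float, random_state: int | None = None):
        self.low = low
        self.high = high
        self.random_state = random_state

    def fit(self, X, y=None, analyte: str = ""):
        if not self.low < self.high:
            raise ValueError("claimed limits must satisfy low < high")
        outcome = validate_against_claimed(
            X if isinstance(X, pd.Series) else np.asarray(X, dtype=float).ravel(),
            (self.low, self.high),
            seed=self.random_state,
            analyte=analyte,
        )
        self.c1_ = outcome.c1
        self.c2_ = outcome.c2
        self.decision_ = outcome.decision
        self.outcome_ = outcome
        return self

    def predict(self, X) -> np.ndarray:
        """+1 for values inside the claimed interval, -1 outside."""
        x = np.asarray(X, dtype=float).ravel()
        return np.where((x >= self.low) & (x <= self.high), 1, -1)


def validate_panel(
    table: MeasurementTable,
    panel: ClaimedRIPanel,
    seed: int,
    estimate_kwargs: dict | None = None,
) -> tuple[dict[str, ValidationOutcome], dict[str, ReferenceIntervalEstimate]]:
    """Validate every panel analyte against the cohort and re-estimate a
    breed RI for each rejected one.

    Per-analyte shuffle seeds are derived deterministically from the master
    seed and the analyte name. Returns (outcomes, new RI estimates keyed by
    rejected analyte).
    """
    estimate_kwargs = estimate_kwargs or {}
    present = set(table.data["analyte"])
    missing = [a for a in panel if a not in present]
    if missing:
        raise ValueError(f"cohort has no data for panel analyte(s): {missing}")
    outcomes: dict[str, ValidationOutcome] = {}
    estimates: dict[str, ReferenceIntervalEstimate] = {}
    for analyte in panel:
        sub_seed = derive_seed(seed, analyte)
        series = table.values_for(analyte)
        outcome = validate_against_claimed(
            series, panel[analyte], seed=sub_seed, analyte=analyte
        )
        outcomes[analyte] = outcome
        if outcome.decision == DECISION_REJECTED:
            estimates[analyte] = estimate_reference_interval(
                series.to_numpy(), seed=sub_seed, analyte=analyte, **estimate_kwargs
            )
    return outcomes, estimates
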