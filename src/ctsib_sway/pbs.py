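"""Pediatric Balance Scale (PBS) scoring.

The PBS is a 14-item functional balance scale for children, adapted
from the Berg Balance Scale. Each item scores 0–4; the scale maximum is
56. Attempt rules differ by item:

* items 1, 2, 3, 6, 7, 8 — up to three attempts, best attempt counts;
* items 9 and 14 — exactly three attempts, their mean counts (totals may
  therefore be fractional; no rounding is applied);
* items 4, 5, 10, 11, 12, 13 — a single attempt.

Only the scoring algebra is modeled, not item administration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError

BEST_OF_THREE_ITEMS = frozenset({1, 2, 3, 6, 7, 8})
MEAN_OF_THREE_ITEMS = frozenset({9, 14})
SINGLE_ATTEMPT_ITEMS = frozenset({4, 5, 10, 11, 12, 13})
N_ITEMS = 14
MAX_TOTAL = 56.0


@dataclass(frozen=True)
class PBSItemRecord:
    """Attempt scores for one PBS item."""

    item: int
    attempts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attempts", tuple(int(a) for a in self.attempts))
        if not 1 <= self.item <= N_ITEMS:
            raise InputError(f"item must be 1..{N_ITEMS}, got {self.item}")
        if any(not 0 <= a <= 4 for a in self.attempts):
            raise InputError(f"item {self.item}: attempt scores must be 0..4, got {self.attempts}")
        na = len(self.attempts)
        if self.item in BEST_OF_THREE_ITEMS and not 1 <= na <= 3:
            raise InputError(f"item {self.item}: 1..3 attempts allowed, got {na}")
        if self.item in MEAN_OF_THREE_ITEMS and na != 3:
            raise InputError(f"item {self.item}: exactly 3 attempts required, got {na}")
        if self.item in SINGLE_ATTEMPT_ITEMS and na != 1:
            raise InputError(f"item {self.item}: exactly 1 attempt allowed, got {na}")


@dataclass(frozen=True)
class PBSRecord:
    participant_id: str
    items: tuple[PBSItemRecord, ...]
    total: float


def score_item(rec: PBSItemRecord) -> float:
    """Score one item per its attempt rule; in [0, 4]."""
    if rec.item in BEST_OF_THREE_ITEMS:
        return float(max(rec.attempts))
    if rec.item in MEAN_OF_THREE_ITEMS:
        return float(sum(rec.attempts) / 3.0)
    return float(rec.attempts[0])


def score_pbs(items: Iterable[PBSItemRecord], participant_id: str = "") -> PBSRecord:
    """Total PBS score over all 14 items; in [0, 56]."""
    items = tuple(items)
    seen = [rec.item for rec in items]
    if sorted(seen) != list(range(1, N_ITEMS + 1)):
        raise InputError(f"need exactly one record per item 1..{N_ITEMS}, got items {sorted(seen)}")
    total = float(sum(score_item(rec) for rec in items))
    return PBSRecord(participant_id=participant_id, items=items, total=total)


def read_pbs_csv(path: str | Path) -> pd.DataFrame:
    """Score a PBS CSV into a table of totals.

    Input header: ``participant_id,item,attempt_1,attempt_2,attempt_3``
    with empty cells for unused attempts. Returns a DataFrame with
    columns ``participant_id, pbs_total``, one row per participant.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "item", "attempt_1"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        records = []
        for rec in grp.to_dict("records"):
            attempts = [
                int(rec[c])
                for c in ("attempt_1", "attempt_2", "attempt_3")
                if c in rec and pd.notna(rec[c])
            ]
            records.append(PBSItemRecord(item=int(rec["item"]), attempts=tuple(attempts)))
        rows.append({"participant_id": str(pid), "pbs_total": score_pbs(records, str(pid)).total})
    return pd.DataFrame(rows, columns=["participant_id", "pbs_total"])


def write_pbs_csv(path: str | Path, records: Sequence[tuple[str, Sequence[PBSItemRecord]]]) -> None:
    """Write participant item records in the PBS CSV interchange format."""
    rows = []
    for pid, items in records:
        for rec in items:
            att = list(rec.attempts) + [None] * (3 - len(rec.attempts))
            rows.append(
                {
                    "participant_id": pid,
                    "item": rec.item,
                    "attempt_1": att[0],
                    "attempt_2": att[1],
                    "attempt_3": att[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
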