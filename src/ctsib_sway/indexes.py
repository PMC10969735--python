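"""m-CTSIB sensory participation indexes.

Each participant × marker contributes one aggregated sway value per
condition C1..C6 (trial 1 is discarded as familiarization; trials 2 and
3 are averaged). Four indexes are then formed as sway ratios:

* somatosensory  SOM = C2 / C1
* visual         VIS = C4 / C1
* vestibular     VEST = C5 / C1
* visual preference  VP = (C3 + C6) / (C2 + C5)

Because greater sway means worse stability, higher index values mean
less effective use of that sensory channel. Indexes can be reported on
the ratio scale (default, matching typical published magnitudes of
order 1) or multiplied by 100 (``x100``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .conditions import ALL_CONDITIONS, Condition, Marker
from .errors import DegenerateProfileError, InputError, MissingTrialError, ParameterError
from .traces import SwayMethod, compute_sway, read_trace_csv, trim_trace

logger = logging.getLogger(__name__)

IndexScale = Literal["ratio", "x100"]
INDEX_NAMES: tuple[str, ...] = ("som", "vis", "vest", "vp")


@dataclass(frozen=True)
class ConditionSwayProfile:
    """Aggregated sway per m-CTSIB condition for one participant × marker."""

    participant_id: str
    marker: Marker
    sway: Mapping[Condition, float]

    def __post_init__(self) -> None:
        missing = [c.value for c in ALL_CONDITIONS if c not in self.sway]
        if missing:
            raise InputError(
                f"profile {self.participant_id}/{self.marker.value} missing condition(s) {missing}"
            )
        bad = {c.value: v for c, v in self.sway.items() if not (v >= 0)}
        if bad:
            raise InputError(f"negative or NaN sway values in profile: {bad}")


@dataclass(frozen=True)
class SensoryIndexSet:
    """SOM, VIS, VEST and VP indexes for one participant × marker."""

    participant_id: str
    marker: Marker
    som: float
    vis: float
    vest: float
    vp: float
    scale: IndexScale = "ratio"

    def as_dict(self) -> dict[str, float]:
        return {"som": self.som, "vis": self.vis, "vest": self.vest, "vp": self.vp}


def aggregate_trials(
    trials: Iterable[tuple[int, float]],
    expected_n: int = 3,
    *,
    allow_single_trial: bool = False,
) -> float:
    """Aggregate a condition's trial sway values into one scalar.

    The first trial is a familiarization trial and is discarded; the
    remaining trials (2 and 3 under the standard protocol) are averaged.
    With ``allow_single_trial`` a lone non-familiarization trial is used
    with a warning instead of raising :class:`MissingTrialError`.
    """
    trials = list(trials)
    numbers = [t for t, _ in trials]
    if len(set(numbers)) != len(numbers):
        raise InputError(f"duplicate trial numbers: {sorted(numbers)}")
    if any(not (1 <= t <= expected_n) for t in numbers):
        raise InputError(f"trial numbers must lie in 1..{expected_n}: {sorted(numbers)}")
    kept = [v for t, v in trials if t >= 2]
    expected_kept = expected_n - 1
    if len(kept) < expected_kept:
        if allow_single_trial and len(kept) >= 1:
            logger.warning(
                "only %d of %d non-familiarization trials present; averaging the available one(s)",
                len(kept), expected_kept,
            )
        else:
            raise MissingTrialError(
                f"need trials 2..{expected_n}, got trial numbers {sorted(numbers)}"
            )
    return float(sum(kept) / len(kept))


def compute_indexes(
    profile: ConditionSwayProfile,
    scale: IndexScale = "ratio",
    denom_epsilon: float = 1e-9,
) -> SensoryIndexSet:
    """Compute the four sensory participation indexes from a sway profile.

    Raises
    ------
    DegenerateProfileError
        If C1 or C2+C5 is at or below ``denom_epsilon``, naming the
        participant and the offending denominator.
    """
    if denom_epsilon <= 0:
        raise ParameterError("denom_epsilon must be positive")
    if scale not in ("ratio", "x100"):
        raise ParameterError(f"unknown index scale {scale!r}")
    s = {c: float(profile.sway[c]) for c in ALL_CONDITIONS}
    who = f"{profile.participant_id}/{profile.marker.value}"
    if s[Condition.C1] <= denom_epsilon:
        raise DegenerateProfileError(f"{who}: C1 sway ({s[Condition.C1]:g}) is numerically zero")
    pair = s[Condition.C2] + s[Condition.C5]
    if pair <= denom_epsilon:
        raise DegenerateProfileError(f"{who}: C2+C5 sway ({pair:g}) is numerically zero")
    factor = 100.0 if scale == "x100" else 1.0
    return SensoryIndexSet(
        participant_id=profile.participant_id,
        marker=profile.marker,
        som=factor * s[Condition.C2] / s[Condition.C1],
        vis=factor * s[Condition.C4] / s[Condition.C1],
        vest=factor * s[Condition.C5] / s[Condition.C1],
        vp=factor * (s[Condition.C3] + s[Condition.C6]) / pair,
        scale=scale,
    )


def build_cohort_index_table(
    manifest: pd.DataFrame,
    *,
    base_dir: str | Path | None = None,
    method: SwayMethod = "path_length",
    scale: IndexScale = "ratio",
    window_s: float = 20.0,
    cm_per_pixel: float | None = None,
    allow_single_trial: bool = False,
    denom_epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Run the full trace → sway → aggregation → index chain over a manifest.

    The manifest has columns ``participant_id, marker, condition,
    trial_number, file``. Participants with an incomplete or degenerate
    profile are excluded listwise *within marker*, with the reason
    logged. Returns a DataFrame with one row per retained participant ×
    marker and columns ``participant_id, marker, som, vis, vest, vp,
    scale, method``.
    """
    required = {"participant_id", "marker", "condition", "trial_number", "file"}
    if manifest is None or len(manifest) == 0:
        raise InputError("empty manifest")
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise InputError(f"manifest missing column(s) {sorted(missing_cols)}")
    base = Path(base_dir) if base_dir is not None else Path(".")

    rows: list[dict[str, object]] = []
    for (pid, marker_str), grp in manifest.groupby(["participant_id", "marker"], sort=True):
        marker = Marker(str(marker_str))
        try:
            sway: dict[Condition, float] = {}
            for cond_str, cgrp in grp.groupby("condition", sort=True):
                trials = []
                for rec in cgrp.to_dict("records"):
                    trace = read_trace_csv(base / str(rec["file"]), rec, cm_per_pixel=cm_per_pixel)
                    trace = trim_trace(trace, window_s=window_s)
                    trials.append((int(rec["trial_number"]), compute_sway(trace, method).value_cm))
                sway[Condition(str(cond_str))] = aggregate_trials(
                    trials, allow_single_trial=allow_single_trial
                )
            profile = ConditionSwayProfile(str(pid), marker, sway)
            idx = compute_indexes(profile, scale=scale, denom_epsilon=denom_epsilon)
        except (InputError, MissingTrialError, DegenerateProfileError) as exc:
            logger.warning("excluding %s/%s: %s", pid, marker.value, exc)
            continue
        rows.append(
            {
                "participant_id": str(pid),
                "marker": marker.value,
                **idx.as_dict(),
                "scale": scale,
                "method": method,
            }
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "marker", *INDEX_NAMES, "scale", "method"]
    )
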