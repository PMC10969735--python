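"""Synthetic m-CTSIB cohort generator.

Generates a fully synthetic study — per-trial sway traces for every
participant × marker × condition, plus Pediatric Balance Scale records —
with the statistical structure the analysis pipeline assumes, so every
stage is testable without access to recorded data.

Sway model
----------
Anteroposterior displacement follows a discrete mean-reverting
(Ornstein–Uhlenbeck-style) recursion

    x_{t+Δ} = x_t (1 − λΔ) + σ_c √Δ ε_t,   ε_t ~ N(0, 1),  x_0 = 0,

with reversion rate λ and condition-specific noise scale
σ_c = baseline_sigma × condition_multiplier × participant_scale. Every
sample path scales linearly in σ_c, so the expected path length is
proportional to the condition multiplier and the sensory-index ratios
recover multiplier ratios — a clean parameter-recovery surface. This is
a declared stand-in for recorded sway, not a model of postural
physiology.

Cohort structure
----------------
Participant overall sway magnitude is lognormal
(``participant_sd_log``). A pure per-marker scale factor would cancel in
every index ratio, so cross-marker agreement is instead created by
per-participant, per-condition lognormal effects (``condition_sd_log``)
shared between the two markers, on top of marker-specific per-condition
deviations (``marker_noise_sd_log``): the shared effects make the two
markers' indexes correlate, the marker-specific ones keep the agreement
imperfect. PBS totals are generated around the malleolus vestibular
index with a target population correlation (negative by default), then
decomposed into legal item attempt records.

Reproducibility: all randomness derives from a single root seed through
``numpy.random.SeedSequence`` with deterministic spawn keys — key
``(p,)`` for participant ``p`` (draw order: participant scale, mastoid
factor, then the (36, steps) innovation array in marker-major,
condition-major, trial-major order) and key ``(2**16,)`` for the PBS
noise stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .conditions import ALL_CONDITIONS, ALL_MARKERS, Condition, Marker
from .errors import InputError, ParameterError, StabilityError
from .indexes import (
    ConditionSwayProfile,
    SensoryIndexSet,
    aggregate_trials,
    compute_indexes,
)
from .pbs import (
    BEST_OF_THREE_ITEMS,
    MEAN_OF_THREE_ITEMS,
    N_ITEMS,
    PBSItemRecord,
    score_pbs,
    write_pbs_csv,
)
from .traces import MarkerTrace, SwayMethod, path_length_cm

logger = logging.getLogger(__name__)

#: Condition noise multipliers solved from published malleolus index
#: medians treated as ratio-scale targets: SOM≈0.7, VIS≈2.1, VEST≈2.0,
#: VP=(C3+C6)/(C2+C5)≈4.8.
DEFAULT_CONDITION_MULTIPLIERS: dict[Condition, float] = {
    Condition.C1: 1.0,
    Condition.C2: 0.7,
    Condition.C3: 3.5,
    Condition.C4: 2.1,
    Condition.C5: 2.0,
    Condition.C6: 9.5,
}

_PBS_STREAM_KEY = 2**16  # spawn key of the PBS noise stream


@dataclass(frozen=True)
class SwaySimConfig:
    """Parameters of the per-trial sway process."""

    baseline_sigma_cm: float = 0.05
    reversion_rate_per_s: float = 1.0
    condition_multipliers: Mapping[Condition, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_MULTIPLIERS)
    )
    sampling_rate_hz: float = 25.0
    duration_s: float = 20.0
    trials_per_condition: int = 3
    participant_sd_log: float = 0.15
    condition_sd_log: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sigma_cm < 0:
            raise ParameterError("baseline_sigma_cm must be >= 0")
        if self.reversion_rate_per_s <= 0 or self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ParameterError("rates and duration must be positive")
        if self.trials_per_condition < 1:
            raise ParameterError("trials_per_condition must be >= 1")
        if self.participant_sd_log < 0 or self.condition_sd_log < 0:
            raise ParameterError("participant_sd_log and condition_sd_log must be >= 0")
        missing = [c.value for c in ALL_CONDITIONS if c not in self.condition_multipliers]
        if missing:
            raise ParameterError(f"condition_multipliers missing {missing}")
        if any(m <= 0 for m in self.condition_multipliers.values()):
            raise ParameterError("condition multipliers must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative parameters."""

    n_participants: int = 27
    marker_noise_sd_log: float = 0.3
    pbs_mean: float = 50.44
    pbs_sd: float = 2.74
    pbs_vest_rho_target: float = -0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ParameterError("n_participants must be >= 2")
        if self.marker_noise_sd_log < 0:
            raise ParameterError("marker_noise_sd_log must be >= 0")
        if not abs(self.pbs_vest_rho_target) < 1:
            raise ParameterError("|pbs_vest_rho_target| must be < 1")
        if self.pbs_sd < 0:
            raise ParameterError("pbs_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """In-memory synthetic study.

    ``sway`` has one row per participant × marker × condition × trial
    with the trial's path length; ``traces`` maps the same key to the
    full :class:`MarkerTrace`; ``pbs_items`` holds the item records
    whose scored totals are in ``pbs``.
    """

    sway_cfg: SwaySimConfig
    cohort_cfg: CohortConfig
    sway: pd.DataFrame
    traces: dict[tuple[str, Marker, Condition, int], MarkerTrace]
    participant_scales: pd.DataFrame
    pbs: pd.DataFrame
    pbs_items: list[tuple[str, list[PBSItemRecord]]]

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.sway["participant_id"].unique())


def _check_stability(cfg: SwaySimConfig) -> tuple[float, float]:
    dt = 1.0 / cfg.sampling_rate_hz
    if cfg.reversion_rate_per_s * dt >= 1.0:
        raise StabilityError(
            f"reversion_rate × Δt = {cfg.reversion_rate_per_s * dt:.3f} >= 1; "
            "raise sampling_rate_hz or lower reversion_rate_per_s"
        )
    return dt, 1.0 - cfg.reversion_rate_per_s * dt


def _filter_paths(eps: np.ndarray, a: float, b: float) -> np.ndarray:
    """Run x_{i+1} = a x_i + b ε_i along the last axis; prepends x_0 = 0."""
    x = lfilter([b], [1.0, -a], eps, axis=-1)
    pad = np.zeros(eps.shape[:-1] + (1,))
    return np.concatenate([pad, x], axis=-1)


def simulate_trace(
    cfg: SwaySimConfig,
    condition: Condition,
    participant_scale: float,
    seed: int | np.random.SeedSequence,
    *,
    participant_id: str = "sim",
    marker: Marker = Marker.LATERAL_MALLEOLUS,
    trial_number: int = 1,
) -> MarkerTrace:
    """Simulate one trial's marker trace; identical seed → identical trace."""
    if participant_scale <= 0:
        raise ParameterError("participant_scale must be positive")
    dt, a = _check_stability(cfg)
    sigma = cfg.baseline_sigma_cm * float(cfg.condition_multipliers[condition]) * participant_scale
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    eps = rng.standard_normal(n - 1)
    ap = _filter_paths(eps, a, sigma * np.sqrt(dt))
    t = np.arange(n) * dt
    return MarkerTrace(
        participant_id=participant_id,
        marker=marker,
        condition=condition,
        trial_number=trial_number,
        sampling_rate_hz=cfg.sampling_rate_hz,
        time_s=t,
        ap_cm=ap,
        vert_cm=np.zeros(n),
    )


def simulate_condition_paths(
    cfg: SwaySimConfig,
    condition: Condition,
    n_trials: int,
    seed: int | np.random.SeedSequence,
    participant_scale: float = 1.0,
) -> np.ndarray:
    """Path lengths of ``n_trials`` independent trials of one condition.

    Vectorized over trials; used for Monte-Carlo parameter-recovery
    studies where the full :class:`MarkerTrace` objects are not needed.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    dt, a = _check_stability(cfg)
    sigma = cfg.baseline_sigma_cm * float(cfg.condition_multipliers[condition]) * participant_scale
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_trials, cfg.n_samples - 1))
    ap = _filter_paths(eps, a, sigma * np.sqrt(dt))
    return np.abs(np.diff(ap, axis=-1)).sum(axis=-1)


def _participant_seed(root_seed: int, p_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(p_index,))


def simulate_participant(
    sway_cfg: SwaySimConfig,
    cohort_cfg: CohortConfig,
    participant_id: str,
    p_index: int,
    root_seed: int,
    *,
    keep_traces: bool = True,
) -> tuple[dict[tuple[Marker, Condition, int], MarkerTrace], dict[Marker, float], pd.DataFrame]:
    """Simulate all trials of one participant.

    Returns the traces (2 markers × 6 conditions × trials; empty dict
    when ``keep_traces`` is false), the latent per-marker scale, and a
    tidy sway table (path length per trial).

    Latent draw order from the participant's stream: overall scale, the
    six shared condition effects, the 2 × 6 marker-specific condition
    deviations, then the innovation array.
    """
    dt, a = _check_stability(sway_cfg)
    rng = np.random.default_rng(_participant_seed(root_seed, p_index))
    base_scale = float(np.exp(sway_cfg.participant_sd_log * rng.standard_normal()))
    # condition response shared across markers; marker-specific deviation
    cond_eff = np.exp(sway_cfg.condition_sd_log * rng.standard_normal(len(ALL_CONDITIONS)))
    marker_dev = np.exp(
        cohort_cfg.marker_noise_sd_log
        * rng.standard_normal((len(ALL_MARKERS), len(ALL_CONDITIONS)))
    )
    scales = {marker: base_scale for marker in ALL_MARKERS}
    n = sway_cfg.n_samples
    n_trials = sway_cfg.trials_per_condition
    n_traces = len(ALL_MARKERS) * len(ALL_CONDITIONS) * n_trials
    eps = rng.standard_normal((n_traces, n - 1))

    sigmas = np.empty(n_traces)
    keys: list[tuple[Marker, Condition, int]] = []
    i = 0
    for mi, marker in enumerate(ALL_MARKERS):
        for ci, cond in enumerate(ALL_CONDITIONS):
            sig = (
                sway_cfg.baseline_sigma_cm
                * float(sway_cfg.condition_multipliers[cond])
                * scales[marker]
                * float(cond_eff[ci])
                * float(marker_dev[mi, ci])
            )
            for trial in range(1, n_trials + 1):
                sigmas[i] = sig
                keys.append((marker, cond, trial))
                i += 1
    ap = _filter_paths(eps, a, np.sqrt(dt)) * sigmas[:, None]
    path = np.abs(np.diff(ap, axis=-1)).sum(axis=-1)

    rows = [
        {
            "participant_id": participant_id,
            "marker": marker.value,
            "condition": cond.value,
            "trial_number": trial,
            "sway_cm": float(path[j]),
        }
        for j, (marker, cond, trial) in enumerate(keys)
    ]
    traces: dict[tuple[Marker, Condition, int], MarkerTrace] = {}
    if keep_traces:
        t = np.arange(n) * dt
        zeros = np.zeros(n)
        for j, (marker, cond, trial) in enumerate(keys):
            traces[(marker, cond, trial)] = MarkerTrace(
                participant_id=participant_id,
                marker=marker,
                condition=cond,
                trial_number=trial,
                sampling_rate_hz=sway_cfg.sampling_rate_hz,
                time_s=t,
                ap_cm=ap[j],
                vert_cm=zeros,
            )
    return traces, scales, pd.DataFrame(rows)


def cohort_index_table(sway: pd.DataFrame, scale: str = "ratio") -> pd.DataFrame:
    """Aggregate a tidy sway table into the per-participant index table.

    Applies the protocol's trial rule (discard trial 1, average the
    rest) and the index formulas; mirrors the file-based pipeline but
    operates on in-memory sway scalars.
    """
    rows = []
    for (pid, marker_str), grp in sway.groupby(["participant_id", "marker"], sort=True):
        sway_by_cond = {
            Condition(str(cond)): aggregate_trials(
                list(zip(cgrp["trial_number"].astype(int), cgrp["sway_cm"].astype(float)))
            )
            for cond, cgrp in grp.groupby("condition", sort=True)
        }
        profile = ConditionSwayProfile(str(pid), Marker(str(marker_str)), sway_by_cond)
        idx = compute_indexes(profile, scale=scale)  # type: ignore[arg-type]
        rows.append(
            {
                "participant_id": str(pid),
                "marker": str(marker_str),
                **idx.as_dict(),
                "scale": scale,
                "method": "path_length",
            }
        )
    return pd.DataFrame(rows)


def pbs_items_from_total(total: float) -> list[PBSItemRecord]:
    """Decompose a target total into legal item records.

    The total is quantized to the scale's native resolution (thirds,
    from the two mean-of-three items) and clipped to [0, 56]; the
    returned records score exactly to the quantized value.
    """
    thirds = int(round(np.clip(total, 0.0, 56.0) * 3))
    records: list[PBSItemRecord] = []
    remaining = thirds
    # integer-scored items first (4 points = 12 thirds each)
    for item in sorted(BEST_OF_THREE_ITEMS | {4, 5, 10, 11, 12, 13}):
        pts = min(4, remaining // 3)
        records.append(PBSItemRecord(item=item, attempts=(pts,)))
        remaining -= pts * 3
    # items 9 and 14 absorb the remainder in thirds (mean of 3 attempts)
    for item in sorted(MEAN_OF_THREE_ITEMS):
        s = min(12, remaining)  # attempt-sum for this item
        remaining -= s
        attempts = []
        for _ in range(3):
            a = min(4, s)
            attempts.append(a)
            s -= a
        records.append(PBSItemRecord(item=item, attempts=tuple(attempts)))
    assert remaining == 0, "decomposition must consume the whole total"
    return sorted(records, key=lambda r: r.item)


def simulate_pbs(
    cohort_cfg: CohortConfig,
    vest_indexes: np.ndarray,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Generate PBS totals correlated with the vestibular index.

    Totals are ``pbs_mean + slope·z(vest) + noise`` with the slope and
    noise variance solved so the population Pearson correlation with
    vest equals ``pbs_vest_rho_target`` and the total's sd equals
    ``pbs_sd``; values are clamped to [0, 56] (clamping is logged).
    """
    vest = np.asarray(vest_indexes, dtype=float)
    if not np.isfinite(vest).all():
        raise InputError("vest_indexes must be finite")
    rho = cohort_cfg.pbs_vest_rho_target
    rng = np.random.default_rng(seed)
    sd_v = vest.std()
    z = np.zeros_like(vest) if sd_v == 0 else (vest - vest.mean()) / sd_v
    slope = rho * cohort_cfg.pbs_sd
    noise_sd = cohort_cfg.pbs_sd * np.sqrt(1.0 - rho**2)
    totals = cohort_cfg.pbs_mean + slope * z + noise_sd * rng.standard_normal(vest.size)
    clamped = (totals < 0) | (totals > 56)
    if clamped.any():
        logger.warning("clamped %d PBS total(s) to [0, 56]", int(clamped.sum()))
    return np.clip(totals, 0.0, 56.0)


def simulate_cohort(
    sway_cfg: SwaySimConfig | None = None,
    cohort_cfg: CohortConfig | None = None,
    *,
    keep_traces: bool = False,
) -> SyntheticCohort:
    """Simulate the full study cohort from the cohort config's seed.

    With ``keep_traces`` the full 20 s trajectories are retained (needed
    for writing a file fixture); otherwise only per-trial path lengths
    are kept, which is what the analysis consumes.
    """
    sway_cfg = sway_cfg or SwaySimConfig()
    cohort_cfg = cohort_cfg or CohortConfig()
    root = cohort_cfg.seed
    width = max(2, len(str(cohort_cfg.n_participants)))
    sway_parts, scale_rows, all_traces = [], [], {}
    for p in range(cohort_cfg.n_participants):
        pid = f"P{p + 1:0{width}d}"
        traces, scales, sway_df = simulate_participant(
            sway_cfg, cohort_cfg, pid, p, root, keep_traces=keep_traces
        )
        sway_parts.append(sway_df)
        for marker, sc in scales.items():
            scale_rows.append({"participant_id": pid, "marker": marker.value, "scale": sc})
        for key, tr in traces.items():
            all_traces[(pid, *key)] = tr
    sway = pd.concat(sway_parts, ignore_index=True)

    idx = cohort_index_table(sway)
    mall = idx[idx["marker"] == Marker.LATERAL_MALLEOLUS.value].sort_values("participant_id")
    totals = simulate_pbs(
        cohort_cfg,
        mall["vest"].to_numpy(),
        np.random.SeedSequence(entropy=root, spawn_key=(_PBS_STREAM_KEY,)),
    )
    pbs_items = [
        (pid, pbs_items_from_total(t))
        for pid, t in zip(mall["participant_id"], totals)
    ]
    pbs = pd.DataFrame(
        {
            "participant_id": [pid for pid, _ in pbs_items],
            "pbs_total": [score_pbs(items, pid).total for pid, items in pbs_items],
        }
    )
    return SyntheticCohort(
        sway_cfg=sway_cfg,
        cohort_cfg=cohort_cfg,
        sway=sway,
        traces=all_traces,
        participant_scales=pd.DataFrame(scale_rows),
        pbs=pbs,
        pbs_items=pbs_items,
    )


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write a cohort to disk in the pipeline's interchange formats.

    Produces ``manifest.csv``, one trace CSV per trial under
    ``traces/``, and ``pbs.csv``. A round-trip through the file-based
    pipeline reproduces the in-memory sway scalars.
    """
    if not cohort.traces:
        raise InputError(
            "cohort holds no traces (simulate with keep_traces=True to write a fixture)"
        )
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for (pid, marker, cond, trial), tr in sorted(
        cohort.traces.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value, kv[0][3])
    ):
        rel = f"traces/{pid}_{marker.value}_{cond.value}_t{trial}.csv"
        pd.DataFrame(
            {"time_s": tr.time_s, "ap_cm": tr.ap_cm, "vert_cm": tr.vert_cm}
        ).to_csv(directory / rel, index=False, float_format="%.17g")
        manifest_rows.append(
            {
                "participant_id": pid,
                "marker": marker.value,
                "condition": cond.value,
                "trial_number": trial,
                "file": rel,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(directory / "manifest.csv", index=False)
    write_pbs_csv(directory / "pbs.csv", cohort.pbs_items)
    return directory
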