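"""Marker trajectory handling and per-trial sway quantification.

A trial is a sagittal-plane video tracking of a single anatomical marker
(lateral malleolus or mastoid process), exported as a CSV time series of
anteroposterior (AP) and vertical displacement in centimeters. Each
trial is reduced to one scalar sway magnitude over a 20 s window; the
default scalar is the AP path length, the cumulative absolute AP
displacement, which is ratio-scaled and therefore suitable for the
sensory-index ratios computed downstream. AP range and RMS deviation
from the mean are selectable alternatives. Only the AP coordinate enters
the sway scalar; the vertical coordinate is carried but unused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .conditions import Condition, Marker
from .errors import ParameterError, TraceFormatError, TraceValidationError

logger = logging.getLogger(__name__)

SwayMethod = Literal["path_length", "range", "rms_deviation"]
SWAY_METHODS: tuple[str, ...] = ("path_length", "range", "rms_deviation")

#: relative tolerance for "uniform" inter-sample spacing
_SPACING_RTOL = 0.01

TRACE_COLUMNS = ("time_s", "ap_cm", "vert_cm")


@dataclass(frozen=True)
class MarkerTrace:
    """One trial's tracked marker displacement time series.

    Attributes
    ----------
    participant_id : str
        Opaque participant label.
    marker : Marker
        Tracked landmark.
    condition : Condition
        m-CTSIB condition under which the trial was recorded.
    trial_number : int
        1-based trial index within the condition (trial 1 is the
        familiarization trial).
    sampling_rate_hz : float
        Frames per second of the underlying video.
    time_s, ap_cm, vert_cm : numpy arrays
        Sample times and planar displacements, centimeters.
    """

    participant_id: str
    marker: Marker
    condition: Condition
    trial_number: int
    sampling_rate_hz: float
    time_s: np.ndarray
    ap_cm: np.ndarray
    vert_cm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time_s", "ap_cm", "vert_cm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        t, ap, vert = self.time_s, self.ap_cm, self.vert_cm
        if t.ndim != 1 or t.size < 2:
            raise TraceValidationError(
                f"trace needs at least 2 samples, got {t.size} "
                f"({self.participant_id}/{self.marker.value}/{self.condition.value}/t{self.trial_number})"
            )
        if ap.shape != t.shape or vert.shape != t.shape:
            raise TraceValidationError("time, AP and vertical arrays must have equal length")
        if not (np.isfinite(ap).all() and np.isfinite(vert).all() and np.isfinite(t).all()):
            raise TraceValidationError("non-finite values in trace")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceValidationError("sample times must be strictly increasing (no duplicates)")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > _SPACING_RTOL * med):
            raise TraceValidationError("inter-sample spacing not uniform within 1% tolerance")
        if not (1 <= self.trial_number):
            raise TraceValidationError(f"trial_number must be >= 1, got {self.trial_number}")
        if not self.sampling_rate_hz > 0:
            raise TraceValidationError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class SwayMeasure:
    """Scalar sway magnitude of one trial."""

    value_cm: float
    method: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.value_cm < 0:
            raise TraceValidationError("sway magnitude cannot be negative")


def infer_sampling_rate(time_s: np.ndarray) -> float:
    """Sampling rate from the median inter-sample interval."""
    dt = np.median(np.diff(np.asarray(time_s, dtype=float)))
    if dt <= 0:
        raise TraceValidationError("cannot infer sampling rate from non-increasing times")
    return 1.0 / float(dt)


def read_trace_csv(
    path: str | Path,
    manifest_row: Mapping[str, object],
    *,
    cm_per_pixel: float | None = None,
    declared_rate_hz: float | None = None,
) -> MarkerTrace:
    """Read one trial's trajectory CSV into a validated :class:`MarkerTrace`.

    The file must have the header ``time_s,ap_cm,vert_cm``. Rows are
    sorted by time before validation, so row order in the file does not
    matter. If ``cm_per_pixel`` is given, displacement columns are
    interpreted as pixels and rescaled. A declared sampling rate
    overrides the inferred one, with a warning if they disagree by more
    than 1%.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}; expected header {','.join(TRACE_COLUMNS)}")
    if len(df) < 2:
        raise TraceValidationError(f"{path}: fewer than 2 rows")
    df = df.sort_values("time_s", kind="mergesort").reset_index(drop=True)

    scale = float(cm_per_pixel) if cm_per_pixel is not None else 1.0
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(time) == 0):
        raise TraceValidationError(f"{path}: duplicate timestamps")

    rate = infer_sampling_rate(time)
    if declared_rate_hz is not None:
        if abs(declared_rate_hz - rate) > 0.01 * rate:
            logger.warning(
                "%s: declared sampling rate %.3f Hz differs from inferred %.3f Hz by >1%%; using declared",
                path, declared_rate_hz, rate,
            )
        rate = float(declared_rate_hz)

    return MarkerTrace(
        participant_id=str(manifest_row["participant_id"]),
        marker=Marker(str(manifest_row["marker"])),
        condition=Condition(str(manifest_row["condition"])),
        trial_number=int(manifest_row["trial_number"]),  # type: ignore[arg-type]
        sampling_rate_hz=rate,
        time_s=time,
        ap_cm=df["ap_cm"].to_numpy(dtype=float) * scale,
        vert_cm=df["vert_cm"].to_numpy(dtype=float) * scale,
    )


def trim_trace(trace: MarkerTrace, window_s: float = 20.0) -> MarkerTrace:
    """Restrict a trace to the half-open window ``[t0, t0 + window_s)``.

    Traces shorter than the window are returned unchanged with a logged
    warning; the protocol's trials are 20 s, so a short trace usually
    indicates a truncated recording.
    """
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    t0 = trace.time_s[0]
    keep = trace.time_s < t0 + window_s
    if keep.all():
        if trace.duration_s < window_s:
            logger.warning(
                "trace %s/%s/%s/t%d is %.2f s, shorter than the %.0f s window; kept as is",
                trace.participant_id, trace.marker.value, trace.condition.value,
                trace.trial_number, trace.duration_s, window_s,
            )
        return trace
    return replace(
        trace,
        time_s=trace.time_s[keep],
        ap_cm=trace.ap_cm[keep],
        vert_cm=trace.vert_cm[keep],
    )


def path_length_cm(ap_cm: np.ndarray) -> float:
    """Cumulative absolute AP displacement Σ|ap[i+1] − ap[i]|."""
    return float(np.abs(np.diff(np.asarray(ap_cm, dtype=float))).sum())


def compute_sway(trace: MarkerTrace, method: SwayMethod = "path_length") -> SwayMeasure:
    """Reduce a (trimmed) trace to one scalar sway magnitude.

    Methods
    -------
    path_length
        Σ_i |ap_{i+1} − ap_i| over consecutive samples.
    range
        max(ap) − min(ap).
    rms_deviation
        Root-mean-square of ap about its mean.
    """
    ap = trace.ap_cm
    if method == "path_length":
        value = path_length_cm(ap)
    elif method == "range":
        value = float(ap.max() - ap.min())
    elif method == "rms_deviation":
        value = float(np.sqrt(np.mean((ap - ap.mean()) ** 2)))
    else:
        raise ParameterError(f"unknown sway method {method!r}; choose one of {SWAY_METHODS}")
    return SwayMeasure(value_cm=value, method=method, duration_s=trace.duration_s)
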