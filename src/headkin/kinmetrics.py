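"""Kinematic metric extraction: spike-screened peak angular velocity,
full-width-at-half-maximum duration, and 5%-rise time-to-peak.

Spike screening follows the head-sensor rejection rules: a candidate local
maximum is discarded if its value is below 100 rad/s, its width (at half
prominence) is under 0.4 ms, or it jumps by more than 0.3 rad/s from an
immediately adjacent sample beyond the local smooth slope.  The highest
surviving candidate is the peak angular velocity; every candidate's fate is
logged for audit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import (
    InvalidSpecError,
    NoPeakError,
    NoRiseError,
    UnboundedPulseError,
)
from .traces import AngularRateTrace, TriaxialTrace

log = logging.getLogger(__name__)


@dataclass
class SpikeRejectionParams:
    """Thresholds for the three spike-rejection rules.

    ``max_neighbor_jump`` is compared, by default, against the adjacent-sample
    jump *after subtracting* the median absolute sample-to-sample change in a
    ``neighborhood_ms`` window around the candidate; a raw comparison (no
    correction) is available as ``strict=True``.  The correction keeps the
    0.3 rad/s criterion from firing on the genuine pulse slope at moderate
    sampling rates.
    """

    min_peak: float = 100.0
    min_width_ms: float = 0.4
    max_neighbor_jump: float = 0.3
    neighborhood_ms: float = 1.0
    strict: bool = False

    def __post_init__(self):
        if min(self.min_peak, self.min_width_ms, self.max_neighbor_jump,
               self.neighborhood_ms) <= 0:
            raise InvalidSpecError("spike-rejection parameters must be positive")


@dataclass
class Candidate:
    index: int
    time: float
    value: float
    width_ms: float
    reason: str  # below_min | too_narrow | neighbor_jump | accepted


@dataclass
class PeakInfo:
    """Accepted peak plus the audit log of every candidate considered."""

    peak_value: float
    peak_time: float
    peak_index: int
    candidate_log: list[Candidate] = field(default_factory=list)

    def log_records(self) -> list[dict]:
        return [asdict(c) for c in self.candidate_log]


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Interior local maxima; the left edge of a plateau counts once.

    A sample qualifies when it strictly exceeds its left neighbour and is at
    least as large as its right neighbour.  Endpoints are excluded.
    """
    if v.size < 3:
        return np.array([], dtype=int)
    left = v[1:-1] > v[:-2]
    right = v[1:-1] >= v[2:]
    return np.nonzero(left & right)[0] + 1


def _half_prominence_width(v: np.ndarray, i: int, dt: float) -> float:
    """Width (seconds) of candidate ``i`` at half its topographic prominence.

    Prominence uses the standard definition: the drop from the candidate to
    the higher of the two key saddles, where each saddle is the minimum
    between the candidate and the nearest strictly higher sample on that side
    (or the trace end).  The half-prominence level is crossed with linear
    interpolation; the search is confined to the candidate's base.
    """
    n = v.size
    # left base: scan to previous strictly-higher sample (or start)
    jl = i
    left_min = v[i]
    j = i - 1
    while j >= 0 and v[j] <= v[i]:
        if v[j] < left_min:
            left_min = v[j]
            jl = j
        j -= 1
    left_base = j + 1 if j >= 0 else 0
    jr = i
    right_min = v[i]
    j = i + 1
    while j < n and v[j] <= v[i]:
        if v[j] < right_min:
            right_min = v[j]
            jr = j
        j += 1
    right_base = j - 1 if j < n else n - 1
    prominence = v[i] - max(left_min, right_min)
    level = v[i] - 0.5 * prominence
    # walk out to the crossing of `level`, staying within the base
    tl = float(i)
    j = i
    while j > left_base and v[j - 1] >= level:
        j -= 1
    if j > left_base or v[left_base] < level:
        # interpolate between j-1 (below) and j (above)
        if j - 1 >= 0 and v[j] != v[j - 1]:
            tl = (j - 1) + (level - v[j - 1]) / (v[j] - v[j - 1])
        else:
            tl = float(j)
    else:
        tl = float(left_base)
    j = i
    while j < right_base and v[j + 1] >= level:
        j += 1
    if j < right_base or v[right_base] < level:
        if j + 1 < n and v[j] != v[j + 1]:
            tr = j + (v[j] - level) / (v[j] - v[j + 1])
        else:
            tr = float(j)
    else:
        tr = float(right_base)
    return (tr - tl) * dt


def _neighbor_jump(v: np.ndarray, i: int) -> float:
    jumps = []
    if i > 0:
        jumps.append(abs(v[i] - v[i - 1]))
    if i + 1 < v.size:
        jumps.append(abs(v[i] - v[i + 1]))
    return max(jumps) if jumps else 0.0


def _local_median_step(v: np.ndarray, i: int, half_window: int) -> float:
    lo = max(0, i - half_window)
    hi = min(v.size - 1, i + half_window)
    steps = np.abs(np.diff(v[lo : hi + 1]))
    return float(np.median(steps)) if steps.size else 0.0


def detect_peak(
    trace: AngularRateTrace,
    params: SpikeRejectionParams | None = SpikeRejectionParams(),
) -> PeakInfo:
    """Select the peak angular velocity after spike screening.

    Candidates are the local maxima of the trace.  With ``params=None`` no
    screening is applied (used for the machine sensor, which the protocol
    does not spike-screen) and the global maximum among candidates — or the
    global maximum sample if the trace is monotone — is returned.

    Raises :class:`NoPeakError`, carrying the candidate log, when screening
    rejects every candidate.
    """
    v = trace.omega
    if v.size < 3:
        raise InvalidSpecError("need at least three samples to detect a peak")
    dt = trace.dt
    idx = _local_maxima(v)
    if params is None:
        if idx.size == 0:
            i = int(np.argmax(v))
        else:
            i = int(idx[np.argmax(v[idx])])
        return PeakInfo(float(v[i]), float(trace.time[i]), i,
                        [Candidate(i, float(trace.time[i]), float(v[i]),
                                   float("nan"), "accepted")])
    half_window = max(1, int(round(params.neighborhood_ms * 1e-3 / dt / 2.0)))
    candidates: list[Candidate] = []
    for i in idx:
        i = int(i)
        width_ms = _half_prominence_width(v, i, dt) * 1e3
        reason = "accepted"
        if v[i] < params.min_peak:
            reason = "below_min"
        elif width_ms < params.min_width_ms:
            reason = "too_narrow"
        else:
            jump = _neighbor_jump(v, i)
            if not params.strict:
                jump -= _local_median_step(v, i, half_window)
            if jump > params.max_neighbor_jump:
                reason = "neighbor_jump"
        candidates.append(Candidate(i, float(trace.time[i]), float(v[i]), width_ms, reason))
    accepted = [c for c in candidates if c.reason == "accepted"]
    if not accepted:
        raise NoPeakError(
            f"no candidate peak survived screening ({len(candidates)} rejected)",
            candidate_log=candidates,
        )
    best = max(accepted, key=lambda c: (c.value, -c.index))  # ties -> earlier
    if sum(1 for c in accepted if c.value == best.value) > 1:
        log.info("tied surviving peaks at %.6g rad/s; keeping the earlier one", best.value)
    return PeakInfo(best.value, best.time, best.index, candidates)


def _cross_before(t, v, i_peak, level):
    """Time of the last upward crossing of `level` before sample i_peak."""
    j = i_peak
    while j > 0 and v[j - 1] >= level:
        j -= 1
    if j == 0 and v[0] >= level:
        return None
    if v[j] == level:
        return float(t[j])
    return float(t[j - 1] + (level - v[j - 1]) / (v[j] - v[j - 1]) * (t[j] - t[j - 1]))


def _cross_after(t, v, i_peak, level):
    """Time of the first downward crossing of `level` after sample i_peak."""
    n = v.size
    j = i_peak
    while j < n - 1 and v[j + 1] >= level:
        j += 1
    if j == n - 1 and v[n - 1] >= level:
        return None
    return float(t[j] + (v[j] - level) / (v[j] - v[j + 1]) * (t[j + 1] - t[j]))


def fwhm(trace: AngularRateTrace, peak: PeakInfo) -> float:
    """Full width at half-maximum of the accepted peak, in milliseconds.

    Measured between the last up-crossing of half the peak value before the
    peak and the first down-crossing after it, with linear interpolation
    between the bracketing samples.
    """
    level = peak.peak_value / 2.0
    t, v = trace.time, trace.omega
    t_left = _cross_before(t, v, peak.peak_index, level)
    t_right = _cross_after(t, v, peak.peak_index, level)
    if t_left is None or t_right is None:
        raise UnboundedPulseError("trace never falls below half-maximum on one side of the peak")
    return (t_right - t_left) * 1e3


def rise_time(trace: AngularRateTrace, peak: PeakInfo, rise_fraction: float = 0.05) -> float:
    """Time (s) of the last crossing of ``rise_fraction * peak`` before the peak."""
    if not 0 < rise_fraction <= 1:
        raise InvalidSpecError("rise_fraction must be in (0, 1]")
    if rise_fraction == 1.0:
        return peak.peak_time
    level = rise_fraction * peak.peak_value
    t_cross = _cross_before(trace.time, trace.omega, peak.peak_index, level)
    if t_cross is None:
        raise NoRiseError("trace never falls below the rise threshold before the peak")
    return t_cross


def time_to_peak(trace: AngularRateTrace, peak: PeakInfo, rise_fraction: float = 0.05) -> float:
    """Interval (ms) from the rise-threshold crossing to the peak."""
    return (peak.peak_time - rise_time(trace, peak, rise_fraction)) * 1e3


@dataclass
class KinematicSummary:
    """Per-animal extracted metrics for one sensor stream (Table-style row)."""

    animal_id: str
    sensor: str  # machine | skull_resultant | skull_coronal
    peak_angular_velocity: float  # rad/s
    fwhm_ms: float
    time_to_peak_ms: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_animal(
    machine: AngularRateTrace,
    skull: TriaxialTrace,
    config=None,
    animal_id: str = "animal",
) -> list[KinematicSummary]:
    """Full per-animal extraction over the three reported sensor streams.

    Filters each channel with the channel-class filter, computes the skull
    resultant from the filtered axes, applies spike screening to the skull
    streams only, and extracts peak / FWHM / time-to-peak per stream.
    Returns summaries for ``machine``, ``skull_resultant``, ``skull_coronal``.
    """
    from .config import PipelineConfig
    from .sigproc import cfc_filter, resultant

    if machine is None:
        raise InvalidSpecError("machine trace is missing")
    if skull is None:
        raise InvalidSpecError("skull (triaxial) trace is missing")
    cfg = config or PipelineConfig()
    fspec = cfg.filter_spec()
    sparams = cfg.spike_params()

    streams: dict[str, tuple[AngularRateTrace, SpikeRejectionParams | None]] = {}
    try:
        streams["machine"] = (cfc_filter(machine, fspec), None if not cfg.screen_machine else sparams)
        filt = TriaxialTrace(
            cfc_filter(skull.coronal, fspec),
            cfc_filter(skull.sagittal, fspec),
            cfc_filter(skull.axial, fspec),
        )
    except Exception as exc:
        raise type(exc)(f"[filter] {exc}") from exc
    streams["skull_resultant"] = (resultant(filt), sparams)
    streams["skull_coronal"] = (filt.coronal, sparams)

    out = []
    for sensor, (tr, params) in streams.items():
        try:
            peak = detect_peak(tr, params)
            out.append(
                KinematicSummary(
                    animal_id=animal_id,
                    sensor=sensor,
                    peak_angular_velocity=peak.peak_value,
                    fwhm_ms=fwhm(tr, peak),
                    time_to_peak_ms=time_to_peak(tr, peak, cfg.rise_fraction),
                )
            )
        except Exception as exc:
            raise type(exc)(f"[{sensor}] {exc}") from exc
    return out
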