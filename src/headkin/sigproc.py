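"""Trace conditioning: SAE J211 channel-class filtering, resultant,
rise-time windowing, and angular excursion.

The channel frequency class (CFC) filter is the standard automotive-safety
low-pass: a two-pole Butterworth, designed from the published J211
difference-equation coefficients, applied forward then backward so the
composite four-pole response is phaseless.  For CFC 1000 the composite
(-3 dB) cutoff sits at 1.65 kHz.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from .errors import InvalidSpecError, NoRiseError, UnfilterableError
from .traces import AngularRateTrace, TriaxialTrace

log = logging.getLogger(__name__)

#: Analog prototype warp factor from the J211 coefficient formula: the
#: per-pass Butterworth corner is placed at 2.0775 x CFC so that the two-pass
#: (phaseless) response is -3 dB at 1.65 x CFC.
_J211_WARP = 2.0775

#: Composite -3 dB cutoff in units of CFC.
CUTOFF_PER_CFC = 1.65


@dataclass
class FilterSpec:
    """Channel-frequency-class filter settings.

    ``poles`` is the composite order: 4 means the canonical 2-pole forward +
    2-pole backward realization.  ``padding`` controls how the trace is
    extended before filtering (``reflect`` mirrors the ends, ``constant``
    repeats the edge value); ``pad_ms`` is the extension length.
    """

    cfc: float = 1000.0
    poles: int = 4
    padding: str = "reflect"
    pad_ms: float = 10.0

    def __post_init__(self):
        if self.cfc <= 0:
            raise InvalidSpecError("cfc must be positive")
        if self.poles != 4:
            raise InvalidSpecError("only the four-pole (2+2 phaseless) realization is supported")
        if self.padding not in ("reflect", "constant"):
            raise InvalidSpecError("padding must be 'reflect' or 'constant'")
        if self.pad_ms < 0:
            raise InvalidSpecError("pad_ms must be non-negative")


def j211_coefficients(cfc: float, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 2-pole Butterworth coefficients per the J211 formula.

    Returns ``(b, a)`` for use with :func:`scipy.signal.lfilter`; the
    difference equation is
    ``y[i] = a0*x[i] + a1*x[i-1] + a2*x[i-2] + b1*y[i-1] + b2*y[i-2]``
    with the prewarped analog corner at ``2.0775 * cfc``.
    """
    T = 1.0 / sampling_rate
    wd = 2.0 * np.pi * cfc * _J211_WARP
    wa = np.tan(wd * T / 2.0)
    denom = 1.0 + np.sqrt(2.0) * wa + wa * wa
    a0 = wa * wa / denom
    a1 = 2.0 * a0
    a2 = a0
    b1 = -2.0 * (wa * wa - 1.0) / denom
    b2 = (-1.0 + np.sqrt(2.0) * wa - wa * wa) / denom
    b = np.array([a0, a1, a2])
    a = np.array([1.0, -b1, -b2])
    return b, a


def filter_gain(cfc: float, sampling_rate: float, freq_hz) -> np.ndarray:
    """Predicted two-pass amplitude gain of the phaseless filter.

    The forward-backward cascade has magnitude ``|H(f)|**2`` where ``H`` is
    the single-pass response of the J211 coefficients.
    """
    b, a = j211_coefficients(cfc, sampling_rate)
    freq_hz = np.atleast_1d(np.asarray(freq_hz, dtype=float))
    _, h = signal.freqz(b, a, worN=2.0 * np.pi * freq_hz / sampling_rate)
    return np.abs(h) ** 2


def min_sampling_rate(cfc: float) -> float:
    """Minimum sampling rate (Hz) accepted for a channel class."""
    return 2.0 * CUTOFF_PER_CFC * cfc


def cfc_filter(trace: AngularRateTrace, spec: FilterSpec | None = None) -> AngularRateTrace:
    """Phaseless four-pole Butterworth channel-class filter.

    Applies the 2-pole J211 stage forward then backward over a padded copy of
    the trace, so the output has zero phase lag, unit DC gain, and the same
    length as the input.
    """
    spec = spec or FilterSpec()
    fs = trace.sampling_rate
    fmin = min_sampling_rate(spec.cfc)
    if fs <= fmin:
        raise UnfilterableError(
            f"sampling rate {fs:.0f} Hz too low for CFC {spec.cfc:.0f}; "
            f"need more than {fmin:.0f} Hz"
        )
    b, a = j211_coefficients(spec.cfc, fs)
    npad = int(round(spec.pad_ms * 1e-3 * fs))
    x = trace.omega
    if npad > 0:
        npad_eff = min(npad, x.size - 1)
        mode = "reflect" if spec.padding == "reflect" else "edge"
        x = np.pad(x, npad_eff, mode=mode)
    else:
        npad_eff = 0
    y = signal.lfilter(b, a, x)
    y = signal.lfilter(b, a, y[::-1])[::-1]
    if npad_eff:
        y = y[npad_eff:-npad_eff]
    return trace.with_omega(y)


def resultant(tri: TriaxialTrace) -> AngularRateTrace:
    """Sample-wise Euclidean magnitude across the three rotation planes.

    ``r(t) = sqrt(wc^2 + ws^2 + wa^2)``; dominates the absolute value of every
    individual channel at every sample.
    """
    r = np.sqrt(tri.coronal.omega**2 + tri.sagittal.omega**2 + tri.axial.omega**2)
    return AngularRateTrace(tri.time.copy(), r, "resultant")


def window_trace(
    trace: AngularRateTrace,
    rise_fraction: float = 0.05,
    pre_window_ms: float = 4.0,
) -> AngularRateTrace:
    """Clip a trace to start a fixed lead before the pulse rise time.

    The rise time is where the trace last crosses ``rise_fraction`` of its
    peak before the peak (the same convention used for time-to-peak).  If the
    requested lead extends past the start of the recording the window is
    clipped there and a warning is logged.
    """
    if pre_window_ms < 0:
        raise InvalidSpecError("pre_window_ms must be non-negative")
    from .kinmetrics import detect_peak, rise_time  # deferred: avoids import cycle

    peak = detect_peak(trace, params=None)
    t_rise = rise_time(trace, peak, rise_fraction)
    t_start = t_rise - pre_window_ms * 1e-3
    if t_start < trace.time[0]:
        log.warning(
            "window start %.4f s precedes trace start %.4f s; truncating",
            t_start, trace.time[0],
        )
        t_start = trace.time[0]
    i0 = int(np.searchsorted(trace.time, t_start - 1e-12))
    if trace.n - i0 < 2:
        raise NoRiseError("window leaves fewer than two samples")
    return AngularRateTrace(trace.time[i0:].copy(), trace.omega[i0:].copy(), trace.axis_label)


def angular_excursion(trace: AngularRateTrace) -> np.ndarray:
    """Cumulative rotation angle (rad) by trapezoidal integration of omega.

    Returns an array aligned with ``trace.time``; the first element is 0 and
    the series is non-decreasing wherever omega is non-negative.
    """
    return integrate.cumulative_trapezoid(trace.omega, trace.time, initial=0.0)
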