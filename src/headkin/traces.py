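"""Angular-velocity trace containers and their delimited-text round trip.

Internal units are seconds and rad/s throughout; report-facing code converts
to milliseconds.  A machine (actuator side-arm) sensor records a single axis;
the skull sensor records three orthogonal anatomical axes (coronal, sagittal,
axial) on one shared clock.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidSpecError

AXIS_LABELS = ("coronal", "sagittal", "axial", "machine", "resultant")

#: Maximum tolerated deviation of the time step from uniformity, in seconds.
UNIFORMITY_TOL = 1e-9


@dataclass
class AngularRateTrace:
    """Uniformly sampled angular velocity for one sensor axis.

    Parameters
    ----------
    time : ndarray
        Strictly increasing, uniformly spaced sample times in seconds.
    omega : ndarray
        Angular velocity in rad/s, same length as ``time``.
    axis_label : str
        One of ``coronal``, ``sagittal``, ``axial``, ``machine``,
        ``resultant``.
    """

    time: np.ndarray
    omega: np.ndarray
    axis_label: str = "machine"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.time.ndim != 1 or self.omega.ndim != 1:
            raise InvalidSpecError("time and omega must be one-dimensional")
        if self.time.size != self.omega.size:
            raise InvalidSpecError("time and omega must have equal length")
        if self.time.size < 2:
            raise InvalidSpecError("a trace needs at least two samples")
        if self.axis_label not in AXIS_LABELS:
            raise InvalidSpecError(f"unknown axis label {self.axis_label!r}")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.omega))):
            raise InvalidSpecError("trace contains non-finite values")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise InvalidSpecError("time must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > UNIFORMITY_TOL:
            raise InvalidSpecError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def n(self) -> int:
        return int(self.time.size)

    def with_omega(self, omega: np.ndarray, axis_label: str | None = None) -> "AngularRateTrace":
        """New trace on the same time grid with replaced samples."""
        return AngularRateTrace(
            self.time.copy(), np.asarray(omega, dtype=float),
            axis_label or self.axis_label,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "omega_rad_s": self.omega}).to_csv(
            path, index=False, float_format="%.9g"
        )

    @classmethod
    def from_csv(cls, path, axis_label: str = "machine") -> "AngularRateTrace":
        df = pd.read_csv(path)
        required = {"time_s", "omega_rad_s"}
        if not required.issubset(df.columns):
            raise InvalidSpecError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(df["time_s"].to_numpy(), df["omega_rad_s"].to_numpy(), axis_label)


@dataclass
class TriaxialTrace:
    """Three axis-aligned angular-rate traces sharing one clock."""

    coronal: AngularRateTrace
    sagittal: AngularRateTrace
    axial: AngularRateTrace

    def __post_init__(self):
        n = self.coronal.n
        for tr in (self.sagittal, self.axial):
            if tr.n != n:
                raise AlignmentError("triaxial channels differ in length")
            if abs(tr.dt - self.coronal.dt) > UNIFORMITY_TOL:
                raise AlignmentError("triaxial channels differ in sampling rate")
            if abs(tr.time[0] - self.coronal.time[0]) > UNIFORMITY_TOL:
                raise AlignmentError("triaxial channels differ in start time")

    @property
    def time(self) -> np.ndarray:
        return self.coronal.time

    @property
    def sampling_rate(self) -> float:
        return self.coronal.sampling_rate

    def channels(self) -> dict[str, AngularRateTrace]:
        return {"coronal": self.coronal, "sagittal": self.sagittal, "axial": self.axial}

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "omega_coronal": self.coronal.omega,
                "omega_sagittal": self.sagittal.omega,
                "omega_axial": self.axial.omega,
            }
        ).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "TriaxialTrace":
        df = pd.read_csv(path)
        required = {"time_s", "omega_coronal", "omega_sagittal", "omega_axial"}
        if not required.issubset(df.columns):
            raise InvalidSpecError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        t = df["time_s"].to_numpy()
        return cls(
            AngularRateTrace(t, df["omega_coronal"].to_numpy(), "coronal"),
            AngularRateTrace(t.copy(), df["omega_sagittal"].to_numpy(), "sagittal"),
            AngularRateTrace(t.copy(), df["omega_axial"].to_numpy(), "axial"),
        )
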