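"""Core in-memory containers for tachograms and blood-pressure sessions.

An :class:`RRSeries` is a beat-to-beat interval sequence (the tachogram) in
milliseconds, with cumulative beat times in seconds.  A :class:`BPSession`
holds the intradialytic blood-pressure readings of one hemodialysis session.
An :class:`EvenSeries` is an evenly resampled tachogram, the prerequisite of
FFT-based spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: physiological bounds on a plausible RR interval, ms
RR_MIN_MS = 200.0
RR_MAX_MS = 3000.0

#: physiological bounds on a plausible systolic pressure, mmHg
SBP_MIN = 40.0
SBP_MAX = 250.0


@dataclass
class RRSeries:
    """A tachogram: ordered RR intervals in ms with cumulative beat times.

    ``t_s`` defaults to the cumulative sum of the intervals (seconds), which
    is how beat-to-beat recorders timestamp their samples.  Derived series
    (e.g. detrended fluctuations) may carry the timestamps of the series they
    were computed from, in which case values are no longer positive
    intervals; :meth:`validate_physiological` is only meant for raw data.
    """

    intervals_ms: np.ndarray
    t_s: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.intervals_ms.ndim != 1:
            raise ValueError("intervals_ms must be one-dimensional")
        if self.t_s is None:
            self.t_s = np.cumsum(self.intervals_ms) / 1000.0
        else:
            self.t_s = np.asarray(self.t_s, dtype=float)
        if self.t_s.shape != self.intervals_ms.shape:
            raise ValueError("t_s and intervals_ms must have equal length")

    def __len__(self) -> int:
        return self.intervals_ms.size

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self) else 0.0

    def validate_physiological(self) -> None:
        """Raise if any interval falls outside (200, 3000) ms or times are
        not strictly increasing."""
        x = self.intervals_ms
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite RR intervals")
        bad = (x <= RR_MIN_MS) | (x >= RR_MAX_MS)
        if bad.any():
            idx = np.flatnonzero(bad)[:5]
            raise ValueError(
                f"RR intervals outside ({RR_MIN_MS:g}, {RR_MAX_MS:g}) ms "
                f"at positions {idx.tolist()}"
            )
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("beat times must be strictly increasing")


@dataclass
class BPSession:
    """Blood-pressure readings of one hemodialysis session.

    Eight readings at 0, 30, ..., 210 min under the default 4-hour protocol;
    fewer are tolerated for shorter sessions.  ``delta_sbp_mmhg`` is the
    session max(SBP) − min(SBP), the quantity hemodynamic stability is
    judged on.
    """

    subject: str
    t_min: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    label: str | None = None  # "HS", "HU" or None when not yet stratified

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.sbp_mmhg = np.asarray(self.sbp_mmhg, dtype=float)
        self.dbp_mmhg = np.asarray(self.dbp_mmhg, dtype=float)
        if not (self.t_min.shape == self.sbp_mmhg.shape == self.dbp_mmhg.shape):
            raise ValueError("t_min, sbp_mmhg, dbp_mmhg must have equal length")

    def __len__(self) -> int:
        return self.sbp_mmhg.size

    @property
    def delta_sbp_mmhg(self) -> float:
        if len(self) < 2:
            raise ValueError("SBP delta requires at least two readings")
        return float(self.sbp_mmhg.max() - self.sbp_mmhg.min())

    def validate_physiological(self) -> None:
        s = self.sbp_mmhg
        if np.any((s <= SBP_MIN) | (s >= SBP_MAX)):
            raise ValueError(f"SBP outside ({SBP_MIN:g}, {SBP_MAX:g}) mmHg")


@dataclass
class EvenSeries:
    """Evenly sampled RR series (ms) at ``fs_hz``, starting at ``t0_s``."""

    fs_hz: float
    values_ms: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.values_ms = np.asarray(self.values_ms, dtype=float)

    def __len__(self) -> int:
        return self.values_ms.size

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.fs_hz if len(self) else 0.0

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.fs_hz
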