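"""Hemodynamic stratification from intradialytic SBP deltas.

A session's delta is max(SBP) − min(SBP) over its readings.  Patients are
labelled hemodynamically stable (HS, delta < cutoff) or unstable (HU,
delta ≥ cutoff); the boundary belongs to HU.  The default cutoff is the
fixed 30 mmHg bound; a data-driven mode uses the cohort median delta
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import BPSession

__all__ = ["StratificationResult", "sbp_delta", "median_cutoff", "stratify",
           "stratify_sessions"]

DEFAULT_CUTOFF_MMHG = 30.0


@dataclass
class StratificationResult:
    deltas: dict[str, float]
    cutoff_mmhg: float
    labels: dict[str, str]

    @property
    def n_hs(self) -> int:
        return sum(1 for v in self.labels.values() if v == "HS")

    @property
    def n_hu(self) -> int:
        return sum(1 for v in self.labels.values() if v == "HU")


def sbp_delta(session: BPSession) -> float:
    """Session SBP delta: highest minus lowest reading (mmHg)."""
    return session.delta_sbp_mmhg


def median_cutoff(deltas: list[float] | np.ndarray) -> float:
    """Sample median of the deltas (mean of middle two for even n)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("need at least one delta")
    return float(np.median(deltas))


def stratify(
    deltas: dict[str, float], cutoff_mmhg: float = DEFAULT_CUTOFF_MMHG
) -> StratificationResult:
    """Assign HS (delta < cutoff) / HU (delta ≥ cutoff) labels."""
    if cutoff_mmhg <= 0:
        raise ValueError("cutoff must be positive")
    labels = {
        subject: ("HS" if delta < cutoff_mmhg else "HU")
        for subject, delta in deltas.items()
    }
    return StratificationResult(deltas=dict(deltas), cutoff_mmhg=cutoff_mmhg,
                                labels=labels)


def stratify_sessions(
    sessions: list[BPSession],
    cutoff_mmhg: float | None = DEFAULT_CUTOFF_MMHG,
) -> StratificationResult:
    """Stratify a list of sessions; ``cutoff_mmhg=None`` uses the cohort
    median delta as the cutoff."""
    deltas = {s.subject: sbp_delta(s) for s in sessions}
    cutoff = (median_cutoff(list(deltas.values()))
              if cutoff_mmhg is None else cutoff_mmhg)
    return stratify(deltas, cutoff)
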