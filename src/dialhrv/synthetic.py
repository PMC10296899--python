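"""Synthetic hemodialysis cohort generator.

Real intradialytic RR recordings of the kind this pipeline analyses are not
publicly deposited, so every downstream stage is exercised on a generator
that reproduces the statistical structure the analysis assumes:

* ~4-hour tachograms (≈14,000–20,000 beats at a mean RR of 800 ms) built as
  mean RR + a pink/white noise mixture + embedded LF (0.1 Hz) and HF
  (0.25 Hz) oscillations sampled at the running beat times;
* two complexity phenotypes controlled by the pink-noise mixing weight:
  stable-like subjects are pink-dominated (flat multiscale-entropy curve),
  unstable-like subjects are white-dominated (entropy decays with scale);
* 8-point intradialytic SBP series whose max−min delta is drawn from a
  group-specific range straddling the 30 mmHg stability cutoff, with the
  drawn delta imposed exactly;
* session covariates (filtered volume, uremic status) in ranges typical of
  chronic kidney disease cohorts.

Everything is a pure function of the cohort spec and seeds: a subject's
stream is seeded as ``(master_seed, subject_index)``, so single subjects are
reproducible without generating the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BPSession, RRSeries

GROUP_HS = "HS"
GROUP_HU = "HU"


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design this pipeline targets: 21 stable and 25
    unstable patients, 4-hour sessions, mean RR 800 ms, and SBP delta ranges
    of [5, 29] mmHg (stable) vs [30, 60] mmHg (unstable).
    """

    n_hs: int = 21
    n_hu: int = 25
    duration_s: float = 14400.0
    mean_rr_ms: float = 800.0
    rr_sd_ms: float = 50.0
    complexity_hs: float = 0.9  # pink-noise mixing weight, stable phenotype
    complexity_hu: float = 0.4  # pink-noise mixing weight, unstable phenotype
    lf_amp_ms: float = 15.0  # amplitude of the embedded 0.1 Hz oscillation
    hf_amp_ms: float = 10.0  # amplitude of the embedded 0.25 Hz oscillation
    sbp_base_mmhg: float = 150.0
    delta_hs_range: tuple[float, float] = (5.0, 29.0)
    delta_hu_range: tuple[float, float] = (30.0, 60.0)
    filtered_volume_mean_ml: float = 2600.0
    filtered_volume_sd_ml: float = 950.0
    urea_mean_mg_dl: float = 133.0
    urea_sd_mg_dl: float = 33.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hs < 1 or self.n_hu < 1:
            raise ValueError("n_hs and n_hu must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for w in (self.complexity_hs, self.complexity_hu):
            if not 0.0 <= w <= 1.0:
                raise ValueError("complexity mixing weights must lie in [0, 1]")
        if not self.delta_hs_range[0] <= self.delta_hs_range[1] < 30.0:
            raise ValueError("delta_hs_range must lie entirely below 30 mmHg")
        if not 30.0 <= self.delta_hu_range[0] <= self.delta_hu_range[1]:
            raise ValueError("delta_hu_range must lie entirely at/above 30 mmHg")

    def mixing_weight(self, group: str) -> float:
        if group == GROUP_HS:
            return self.complexity_hs
        if group == GROUP_HU:
            return self.complexity_hu
        raise ValueError(f"unknown group {group!r}")

    def delta_range(self, group: str) -> tuple[float, float]:
        return self.delta_hs_range if group == GROUP_HS else self.delta_hu_range


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f (pink) noise by spectral shaping of white Gaussian noise.

    The rFFT of a white draw is multiplied by a 1/sqrt(f) amplitude profile
    (power ∝ 1/f) with the DC bin zeroed, inverted, and rescaled to unit
    standard deviation.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    y = np.fft.irfft(spec * shape, n)
    return y / y.std()


def _subject_rng(spec: CohortSpec, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, subject_seed])


def generate_rr_series(
    spec: CohortSpec, group: str, subject_seed: int
) -> RRSeries:
    """Generate one subject's tachogram.

    Beat i gets interval ``mean_rr + mix*pink_i + (1-mix)*white_i + LF/HF
    sines evaluated at the previous beat time``, both noise components scaled
    to ``rr_sd_ms`` before mixing; beats accumulate until the session
    duration is reached.  Intervals are clipped to the physiological (200,
    3000) ms range.
    """
    mix = spec.mixing_weight(group)
    rng = _subject_rng(spec, subject_seed)
    # enough beats even if intervals run short
    n_max = int(spec.duration_s * 1000.0 / spec.mean_rr_ms * 1.6) + 16
    pink = pink_noise(n_max, rng) * spec.rr_sd_ms
    white = rng.standard_normal(n_max) * spec.rr_sd_ms
    noise = mix * pink + (1.0 - mix) * white

    intervals = np.empty(n_max)
    t = 0.0
    two_pi = 2.0 * np.pi
    n = 0
    for i in range(n_max):
        rr = (
            spec.mean_rr_ms
            + noise[i]
            + spec.lf_amp_ms * np.sin(two_pi * 0.1 * t)
            + spec.hf_amp_ms * np.sin(two_pi * 0.25 * t)
        )
        rr = min(max(rr, 200.5), 2999.5)
        intervals[n] = rr
        n += 1
        t += rr / 1000.0
        if t >= spec.duration_s:
            break
    intervals = intervals[:n]
    if n < 2000:
        raise ValueError(
            f"duration {spec.duration_s} s yields only {n} beats; "
            "at least 2000 are required for 20-scale entropy analysis"
        )
    rr = RRSeries(
        intervals_ms=intervals,
        meta={"subject": f"subj{subject_seed:03d}", "group_truth": group},
    )
    rr.validate_physiological()
    return rr


def generate_bp_session(
    spec: CohortSpec, group: str, subject_seed: int
) -> BPSession:
    """Generate one session's 8-point SBP/DBP series.

    The SBP delta is drawn uniformly from the group's range and imposed
    exactly: the session max and min are placed in two random reading slots,
    remaining readings fall strictly between them.
    """
    rng = _subject_rng(spec, subject_seed + 1_000_000)
    lo, hi = spec.delta_range(group)
    delta = float(rng.uniform(lo, hi))
    base = float(rng.normal(spec.sbp_base_mmhg, 8.0))
    sbp_max = base + delta / 2.0
    sbp_min = base - delta / 2.0

    t_min = np.arange(8) * 30.0
    sbp = rng.uniform(sbp_min, sbp_max, size=8)
    i_max, i_min = rng.choice(8, size=2, replace=False)
    sbp[i_max] = sbp_max
    sbp[i_min] = sbp_min
    dbp = sbp * 0.6 + rng.normal(0.0, 3.0, size=8)

    session = BPSession(
        subject=f"subj{subject_seed:03d}",
        t_min=t_min,
        sbp_mmhg=np.round(sbp, 1),
        dbp_mmhg=np.round(dbp, 1),
    )
    session.validate_physiological()
    return session


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[RRSeries], list[BPSession], pd.DataFrame]:
    """Generate the full cohort: tachograms, BP sessions and covariates.

    Subjects 0..n_hs-1 are stable-like, the rest unstable-like; the truth
    label is stored in each record for recovery tests.  Covariates (session
    filtered volume, uremic status) are drawn from normal ranges typical of
    hemodialysis cohorts, independent of group.
    """
    rr_list: list[RRSeries] = []
    bp_list: list[BPSession] = []
    rows = []
    groups = [GROUP_HS] * spec.n_hs + [GROUP_HU] * spec.n_hu
    for idx, group in enumerate(groups):
        rr_list.append(generate_rr_series(spec, group, idx))
        bp_list.append(generate_bp_session(spec, group, idx))
        crng = _subject_rng(spec, idx + 2_000_000)
        volume = max(float(crng.normal(spec.filtered_volume_mean_ml,
                                       spec.filtered_volume_sd_ml)), 300.0)
        urea = max(float(crng.normal(spec.urea_mean_mg_dl,
                                     spec.urea_sd_mg_dl)), 40.0)
        rows.append(
            {
                "subject": f"subj{idx:03d}",
                "filtered_volume_ml": round(volume, 1),
                "urea_mg_dl": round(urea, 1),
                "group_truth": group,
            }
        )
    covariates = pd.DataFrame(rows).set_index("subject")
    return rr_list, bp_list, covariates


# ---------------------------------------------------------------------------
# plain-text export

def write_cohort(
    outdir: str | Path,
    rr_list: list[RRSeries],
    bp_list: list[BPSession],
    covariates: pd.DataFrame,
) -> dict[str, Path]:
    """Write the cohort as plain-text artifacts.

    RR files: one interval (ms) per line, named ``rr_<subject>.txt`` under
    ``rr/``.  BP CSV: ``subject,t_min,sbp,dbp``.  Covariates CSV:
    ``subject,filtered_volume_ml,urea_mg_dl,group_truth``.
    """
    outdir = Path(outdir)
    rr_dir = outdir / "rr"
    rr_dir.mkdir(parents=True, exist_ok=True)
    for rr in rr_list:
        subject = rr.meta["subject"]
        path = rr_dir / f"rr_{subject}.txt"
        np.savetxt(path, rr.intervals_ms, fmt="%.3f")
    bp_rows = []
    for bp in bp_list:
        for t, s, d in zip(bp.t_min, bp.sbp_mmhg, bp.dbp_mmhg):
            bp_rows.append({"subject": bp.subject, "t_min": t, "sbp": s, "dbp": d})
    bp_path = outdir / "bp.csv"
    pd.DataFrame(bp_rows).to_csv(bp_path, index=False)
    cov_path = outdir / "covariates.csv"
    covariates.to_csv(cov_path)
    return {"rr_dir": rr_dir, "bp_csv": bp_path, "covariates_csv": cov_path}
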