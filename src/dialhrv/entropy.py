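"""Multiscale sample entropy and fuzzy entropy of RR tachograms.

The multiscale-entropy (MSE) procedure quantifies signal irregularity over
time scales τ = 1..20: the series is coarse-grained into non-overlapping
τ-point averages and the sample entropy (SampEn) of each coarse-grained
series is computed with tolerance r fixed from the original series.  Flat
MSE curves are the signature of long-range-correlated (1/f-like) dynamics —
a complex, adaptable system — whereas uncorrelated (white-like) dynamics
decay with scale because averaging shrinks their variance while r stays
fixed.

Summary complexity indices are trapezoidal areas under the MSE curve:
MSE_1-20 (global), MSE_1-5 (short scales, vagal range) and MSE_6-20 (long
scales, sympathetic range).  Fuzzy entropy (FuzzyEn) replaces SampEn's hard
match threshold with the graded membership exp(−0.6931·(d/r)^n) of the
template distance d, and is reported for the original (τ = 1) series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "EntropyConfig",
    "EntropyProfile",
    "coarse_grain",
    "sample_entropy",
    "fuzzy_membership",
    "fuzzy_entropy",
    "mse_curve",
    "mse_profile",
    "auc_mse",
]


@dataclass
class EntropyConfig:
    """Knobs of the entropy analysis.

    m=2 and r=0.2·SD are the universal short-term HRV defaults; the
    tolerance is computed once from the original series and reused at every
    scale (the canonical MSE choice) unless ``r_mode='per_scale_sd'``.
    """

    m: int = 2
    r_frac: float = 0.2
    max_scale: int = 20
    fuzzy_n: float = 2.0
    r_mode: str = "fixed_original_sd"  # or "per_scale_sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not 0.0 < self.r_frac < 1.0:
            raise ValueError("r_frac must lie in (0, 1)")
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")
        if self.fuzzy_n <= 0:
            raise ValueError("fuzzy_n must be positive")
        if self.r_mode not in ("fixed_original_sd", "per_scale_sd"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class EntropyProfile:
    """Per-scale SampEn values plus the derived complexity indices.

    ``sampen_by_scale[tau]`` maps scale to entropy; NaN marks scales where
    SampEn is undefined (no template matches), in which case the AUC indices
    are NaN too and ``defined`` is False.
    """

    sampen_by_scale: dict[int, float]
    auc_1_20: float
    auc_1_5: float
    auc_6_20: float
    fuzzyen: float
    config: EntropyConfig = field(default_factory=EntropyConfig)

    @property
    def defined(self) -> bool:
        return all(math.isfinite(v) for v in self.sampen_by_scale.values())

    def as_array(self) -> np.ndarray:
        scales = sorted(self.sampen_by_scale)
        return np.array([self.sampen_by_scale[t] for t in scales])


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping τ-point averages; trailing remainder dropped.

    y_j = mean(x[(j-1)τ .. jτ]) for j = 1..floor(N/τ); τ=1 returns the
    series unchanged.
    """
    if tau < 1:
        raise ValueError("scale tau must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size // tau
    if n < 1:
        raise ValueError("series shorter than one coarse-graining window")
    if tau == 1:
        return x.copy()
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy −ln(A/B) with tolerance ``r`` in the units of ``x``.

    B counts pairs of distinct m-point templates with Chebyshev distance
    ≤ r; A the same for (m+1)-point templates over the same start indices;
    self-matches are excluded.  Returns NaN (with a warning) when no
    template pair matches at either length.  ``r`` defaults to 0.2·SD(x).
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError("series too short for the requested embedding")
    if r is None:
        r = 0.2 * float(np.std(x))
    if not r > 0:
        raise ValueError("tolerance r must be positive (constant series?)")
    a, b = _kernels.sampen_counts(x, m, float(r))
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined: no template matches",
                      stacklevel=2)
        return float("nan")
    return float(-math.log(a / b))


def fuzzy_membership(d: float, r: float, n: float) -> float:
    """Graded similarity exp(−0.6931·(d/r)^n) of a template distance.

    The constant is ln 2, so d = r maps to membership 0.5 — the soft
    counterpart of SampEn's hard threshold at r.
    """
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if d < 0:
        raise ValueError("distance d must be non-negative")
    return float(np.exp(-_kernels.LN2 * (d / r) ** n))


def fuzzy_entropy(
    x: np.ndarray,
    m: int = 2,
    r: float | None = None,
    n: float = 2.0,
) -> float:
    """Fuzzy entropy −ln(φ_{m+1}/φ_m) of a series.

    φ_m is the mean fuzzy membership of the Chebyshev distance between all
    pairs of baseline-removed (own-mean-subtracted) m-point templates;
    template start positions 0..N−m−1 are shared between the m and m+1
    passes.  Scale-invariant: FuzzyEn(c·x, r=c·r0) = FuzzyEn(x, r0).
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError("series too short for the requested embedding")
    if r is None:
        r = 0.2 * float(np.std(x))
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    nt = x.size - m
    phi_m = _kernels.fuzzy_phi(x, m, nt, float(r), float(n))
    phi_m1 = _kernels.fuzzy_phi(x, m + 1, nt - 1, float(r), float(n))
    if phi_m <= 0 or phi_m1 <= 0:
        warnings.warn("fuzzy entropy undefined: zero mean membership",
                      stacklevel=2)
        return float("nan")
    return float(-math.log(phi_m1 / phi_m))


def auc_mse(profile: dict[int, float], lo: int, hi: int) -> float:
    """Trapezoidal area under the MSE curve between scales lo and hi.

    Unit scale spacing, so the area is Σ_{τ=lo..hi-1} (S_τ + S_{τ+1})/2.
    Linear in the profile, hence the area of a group-mean curve equals the
    group mean of per-subject areas.
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    vals = []
    for tau in range(lo, hi + 1):
        if tau not in profile:
            raise ValueError(f"scale {tau} missing from profile")
        vals.append(profile[tau])
    return float(np.trapezoid(np.asarray(vals, dtype=float)))


def mse_curve(x: np.ndarray, cfg: EntropyConfig | None = None) -> dict[int, float]:
    """Per-scale SampEn values only (no FuzzyEn, no AUC indices).

    The per-scale loop of :func:`mse_profile`, useful when only the shape
    of the MSE curve is needed.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    sd0 = float(np.std(x))
    if sd0 <= 0:
        raise ValueError("constant series: tolerance would be zero")
    r0 = cfg.r_frac * sd0
    by_scale: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tau in range(1, cfg.max_scale + 1):
            y = coarse_grain(x, tau)
            r = r0 if cfg.r_mode == "fixed_original_sd" \
                else cfg.r_frac * float(np.std(y))
            by_scale[tau] = sample_entropy(y, cfg.m, r)
    return by_scale


def mse_profile(x: np.ndarray, cfg: EntropyConfig | None = None) -> EntropyProfile:
    """MSE profile over τ = 1..max_scale plus AUC indices and FuzzyEn.

    The tolerance is ``r_frac``·SD of the original series and, under the
    default ``r_mode``, is held fixed across scales; τ = 1 equals the plain
    SampEn of the series.  Series shorter than 2000 points trigger a
    warning — the τ = 20 coarse series would be too short for stable
    estimates.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    if x.size < 2000:
        warnings.warn(
            f"series of {x.size} points is short for {cfg.max_scale}-scale "
            "entropy analysis; estimates at coarse scales will be noisy",
            stacklevel=2,
        )
    sd0 = float(np.std(x))
    if sd0 <= 0:
        raise ValueError("constant series: tolerance would be zero")
    r0 = cfg.r_frac * sd0

    by_scale = mse_curve(x, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fuz = fuzzy_entropy(x, cfg.m, r0, cfg.fuzzy_n)

    if all(math.isfinite(v) for v in by_scale.values()):
        auc_full = auc_mse(by_scale, 1, min(20, cfg.max_scale))
        auc_short = auc_mse(by_scale, 1, 5) if cfg.max_scale >= 5 else float("nan")
        auc_long = auc_mse(by_scale, 6, 20) if cfg.max_scale >= 20 else float("nan")
    else:
        warnings.warn("undefined SampEn at some scale; AUC indices flagged NaN",
                      stacklevel=2)
        auc_full = auc_short = auc_long = float("nan")
    return EntropyProfile(
        sampen_by_scale=by_scale,
        auc_1_20=auc_full,
        auc_1_5=auc_short,
        auc_6_20=auc_long,
        fuzzyen=fuz,
        config=cfg,
    )
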