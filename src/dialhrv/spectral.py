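"""Frequency-domain HRV: Welch periodogram and LF/HF band powers.

The evenly resampled, detrended tachogram is analysed with a
segment-averaged FFT periodogram (Hann taper, 256 s windows, 50% overlap).
Band powers are integrated over the standard short-term HRV bands — LF
0.04–0.15 Hz and HF 0.15–0.4 Hz — and normalized units are percentages of
their sum: LFnu = 100·LF/(LF+HF), so LFnu + HFnu = 100 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .series import EvenSeries

__all__ = ["SpectralConfig", "SpectralResult", "welch_psd", "band_powers",
           "spectral_features"]


@dataclass
class SpectralConfig:
    window_s: float = 256.0
    overlap_frac: float = 0.5
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        for lo, hi in (self.lf_band, self.hf_band):
            if not 0 < lo < hi:
                raise ValueError("band edges must be positive and ordered")


@dataclass
class SpectralResult:
    """Band powers (ms²) and normalized units (%) of one subject."""

    freqs_hz: np.ndarray
    psd_ms2_hz: np.ndarray
    lf_ms2: float
    hf_ms2: float
    lfnu: float
    hfnu: float
    lf_hf: float
    flags: list[str] = field(default_factory=list)


def welch_psd(
    series: EvenSeries, cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of the resampled tachogram.

    Hann taper, per-segment mean removal, density scaling (the integral of
    the PSD over [0, fs/2] approximates the series variance up to taper
    bias).  If the series is shorter than one window, a single full-length
    segment is used with a warning.
    """
    cfg = cfg or SpectralConfig()
    x = series.values_ms
    nper = int(round(cfg.window_s * series.fs_hz))
    if x.size < nper:
        warnings.warn(
            "series shorter than one analysis window; "
            "using a single full-length segment", stacklevel=2,
        )
        nper = x.size
    noverlap = int(nper * cfg.overlap_frac)
    freqs, psd = signal.welch(
        x,
        fs=series.fs_hz,
        window="hann",
        nperseg=nper,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal band power with interpolated band edges."""
    inside = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inside, [hi]))
    pw = np.interp(grid, freqs, psd)
    return float(np.trapezoid(pw, grid))


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig | None = None
) -> SpectralResult:
    """LF/HF band powers and normalized units from a PSD.

    Requires PSD coverage of the full HF band.  When LF+HF is zero the
    normalized units are undefined and flagged NaN.
    """
    cfg = cfg or SpectralConfig()
    if freqs[-1] < cfg.hf_band[1]:
        raise ValueError(
            f"PSD reaches only {freqs[-1]:.3f} Hz; need coverage to "
            f"{cfg.hf_band[1]:.2f} Hz"
        )
    lf = _band_power(freqs, psd, *cfg.lf_band)
    hf = _band_power(freqs, psd, *cfg.hf_band)
    flags: list[str] = []
    if lf + hf > 0:
        lfnu = 100.0 * lf / (lf + hf)
        hfnu = 100.0 * hf / (lf + hf)
    else:
        lfnu = hfnu = float("nan")
        flags.append("zero LF+HF power: normalized units undefined")
    lf_hf = lf / hf if hf > 0 else float("inf")
    return SpectralResult(
        freqs_hz=freqs, psd_ms2_hz=psd,
        lf_ms2=lf, hf_ms2=hf, lfnu=lfnu, hfnu=hfnu, lf_hf=lf_hf, flags=flags,
    )


def spectral_features(
    series: EvenSeries, cfg: SpectralConfig | None = None
) -> SpectralResult:
    """Convenience: Welch PSD followed by band integration."""
    freqs, psd = welch_psd(series, cfg)
    return band_powers(freqs, psd, cfg)
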