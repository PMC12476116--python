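"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF summarizes resting-state local activity per voxel as the fraction of
the BOLD signal's spectral content that lies in the low-frequency band
(default 0.01-0.1 Hz): the series is linearly detrended, transformed with an
FFT, and the sum of spectral amplitudes inside the band is divided by the
sum over all positive-frequency bins up to Nyquist (DC excluded from both
sums).  Raw fALFF is therefore a dimensionless ratio in [0, 1] under the
amplitude-sum convention.  For group analyses each subject's map is
standardized by its in-mask global mean, so the standardized map has mean 1.

The ratio may also be formed on power (squared amplitudes); both conventions
appear in the literature, so the choice is exposed as ``spectrum``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["compute_falff", "standardize_global_mean", "band_bins",
           "spectral_amplitudes"]

DEFAULT_BAND = (0.01, 0.1)


def spectral_amplitudes(series: np.ndarray, tr: float):
    """One-sided spectral amplitudes of a time course.

    Returns (freqs, amp) where amp[k] = |X_k| from the real FFT.  Under this
    convention sum(|X_k|^2) over the two-sided spectrum equals N * sum(x^2)
    (Parseval), which the test suite uses as a transform sanity invariant.
    """
    series = np.asarray(series, float)
    freqs = np.fft.rfftfreq(series.shape[-1], d=tr)
    return freqs, np.abs(np.fft.rfft(series, axis=-1))


def band_bins(n_timepoints: int, tr: float,
              band: tuple[float, float] = DEFAULT_BAND):
    """Return (in_band, positive) boolean masks over rfft frequency bins."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    positive = freqs > 0
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return in_band & positive, positive


def compute_falff(series: np.ndarray, tr: float,
                  band: tuple[float, float] = DEFAULT_BAND,
                  spectrum: str = "amplitude",
                  detrend: bool = False) -> np.ndarray:
    """Raw fALFF per voxel.

    Parameters
    ----------
    series : array, shape (..., T)
        Time courses along the last axis.
    tr : float
        Repetition time in seconds.
    band : (f_low, f_high)
        Low-frequency band in Hz, edges inclusive.
    spectrum : {"amplitude", "power"}
        Sum square-root-of-power (amplitude) or power over bins.
    detrend : bool
        Remove a linear trend before the FFT.  Off by default: slow drifts
        are normally removed during preprocessing, the DC bin is excluded
        from both sums anyway, and the least-squares trend of a finite
        oscillatory record is not exactly zero, so detrending smears a small
        broadband residual across bins and biases the amplitude-sum ratio of
        clean narrowband signals.

    Constant series (zero spectral mass) get fALFF 0 with a warning.
    """
    series = np.asarray(series, float)
    if not np.isfinite(series).all():
        raise ValueError("series must be finite")
    if spectrum not in ("amplitude", "power"):
        raise ValueError("spectrum must be 'amplitude' or 'power'")
    T = series.shape[-1]
    if T < 8:
        raise ValueError("series too short")
    in_band, positive = band_bins(T, tr, band)
    if not in_band.any():
        warnings.warn(f"band {band} Hz unresolvable at T={T}, tr={tr}",
                      stacklevel=2)
    x = series
    if detrend:
        t = np.arange(T) - (T - 1) / 2.0
        slope = (x * t).sum(-1, keepdims=True) / (t * t).sum()
        x = x - x.mean(-1, keepdims=True) - slope * t
    amp = np.abs(np.fft.rfft(x, axis=-1))
    if spectrum == "power":
        amp = amp ** 2
    num = amp[..., in_band].sum(-1)
    den = amp[..., positive].sum(-1)
    out = np.zeros_like(den)
    ok = den > 0
    if not ok.all():
        warnings.warn("constant series encountered; fALFF set to 0",
                      stacklevel=2)
    np.divide(num, den, out=out, where=ok)
    return out


def standardize_global_mean(raw: np.ndarray,
                            mask: np.ndarray | None = None) -> np.ndarray:
    """Divide each in-mask voxel by the in-mask mean (out-of-mask -> 0)."""
    raw = np.asarray(raw, float)
    if mask is None:
        mask = np.ones(raw.shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != raw.shape:
        raise ValueError("mask/map shape mismatch")
    g = raw[mask].mean()
    if g == 0:
        raise ValueError("global mean is zero; cannot standardize")
    out = np.zeros_like(raw)
    out[mask] = raw[mask] / g
    return out
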