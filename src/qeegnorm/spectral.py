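"""Windowing, power spectra, band areas, and Shannon spectral entropy.

The record is cut into 1-s moving windows with 10% overlap.  Each window is
tapered, zero-padded to twice its length (so a 1-s window at 128 Hz yields a
0.5 Hz frequency grid), and turned into a one-sided power spectral density in
µV²/Hz.  Every window's spectrum is then renormalized so that its integral
equals the window's time-domain mean square — Parseval's identity holds
exactly per window, for any taper, which keeps band areas physically
interpretable as signal power.

Band areas integrate the spectrum over the classical EEG bands
(delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30 Hz); a bin lying exactly on a
shared edge belongs to the lower band, so the four bands partition the
0.5-30 Hz area exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .montage import BipolarRecording, MonopolarRecording

#: Classical EEG band edges in Hz (lower, upper).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta")

#: Support of the spectral-entropy distribution (the filtered band).
DEFAULT_ENTROPY_SUPPORT: tuple[float, float] = (0.5, 30.0)

DEFAULT_WINDOW_LEN = 1.0
DEFAULT_OVERLAP = 0.1
DEFAULT_PAD_FACTOR = 2

_EPS = 1e-9  # guards the floor() in the window-count formula against fp error


@dataclass
class WindowSet:
    """Per-window views of a multichannel record.

    data has shape (n_windows, n_channels, window_samples); `starts` are the
    window start samples.
    """

    data: np.ndarray
    starts: np.ndarray
    channels: tuple[str, ...]
    fs: float
    window_len: float
    overlap_frac: float

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class WindowedSpectrum:
    """One-sided per-window power spectral density, µV²/Hz.

    S has shape (n_windows, n_channels, n_freqs); `freqs` is a uniform grid
    starting at 0 with spacing `df`.
    """

    S: np.ndarray
    freqs: np.ndarray
    channels: tuple[str, ...]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def mean_spectrum(self) -> np.ndarray:
        """Window-averaged spectrum, shape (n_channels, n_freqs)."""
        return self.S.mean(axis=0)

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not present") from None


@dataclass
class BandAreas:
    """Band-integrated power (µV²) per channel, window-averaged.

    `areas` is a DataFrame indexed by channel with one column per band.
    """

    areas: pd.DataFrame
    band_edges: dict[str, tuple[float, float]]


@dataclass
class EntropyValue:
    """Shannon spectral entropy in bits per channel, and the bin count that
    bounds it (SSE <= log2(n_bins))."""

    sse: pd.Series
    n_bins: int


def n_windows_expected(duration: float, window_len: float = DEFAULT_WINDOW_LEN,
                       overlap_frac: float = DEFAULT_OVERLAP) -> int:
    """Number of moving windows: floor((T - L) / step) + 1, step = L(1-overlap)."""
    step = window_len * (1.0 - overlap_frac)
    if duration < window_len:
        return 0
    return int(np.floor((duration - window_len) / step + _EPS)) + 1


def make_windows(rec: BipolarRecording | MonopolarRecording,
                 window_len: float = DEFAULT_WINDOW_LEN,
                 overlap_frac: float = DEFAULT_OVERLAP) -> WindowSet:
    """Cut a record into moving windows (default 1 s with 10% overlap)."""
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    labels = rec.channels if isinstance(rec, BipolarRecording) else rec.labels
    n_samp = int(round(window_len * rec.fs))
    if rec.n_times < n_samp:
        raise ValueError(
            f"record of {rec.duration:.2f} s shorter than one "
            f"{window_len:.2f} s window"
        )
    step = window_len * (1.0 - overlap_frac)
    n_win = n_windows_expected(rec.duration, window_len, overlap_frac)
    starts = np.array([int(round(i * step * rec.fs)) for i in range(n_win)])
    # floating-point rounding of the last start may spill past the record end
    starts = starts[starts + n_samp <= rec.n_times]
    data = np.stack([rec.samples[:, s:s + n_samp] for s in starts])
    return WindowSet(data, starts, tuple(labels), rec.fs, window_len, overlap_frac)


def _taper(n: int, kind: str) -> np.ndarray:
    if kind == "hann":
        return np.hanning(n)
    if kind == "rect":
        return np.ones(n)
    raise ValueError(f"unknown taper {kind!r}")


def window_fft(ws: WindowSet, taper: str = "hann",
               pad_factor: int = DEFAULT_PAD_FACTOR
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tapered, zero-padded rfft of every window.

    Returns (coeffs, freqs, taper_window); coeffs has shape
    (n_windows, n_channels, n_freqs).  Shared by the power-spectrum and
    coherence estimators so auto- and cross-spectra come from one estimator.
    """
    if not np.all(np.isfinite(ws.data)):
        raise ValueError("non-finite samples in windows")
    n = ws.n_samples
    w = _taper(n, taper)
    nfft = n * pad_factor
    coeffs = np.fft.rfft(ws.data * w, n=nfft, axis=2)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / ws.fs)
    return coeffs, freqs, w


def power_spectrum(ws: WindowSet, taper: str = "hann",
                   pad_factor: int = DEFAULT_PAD_FACTOR,
                   parseval: bool = True) -> WindowedSpectrum:
    """Per-window one-sided PSD in µV²/Hz.

    With `parseval` (default) each window's spectrum is rescaled so that
    sum(S)*df equals the window's raw mean-square voltage, making band areas
    sum exactly to time-domain power.
    """
    coeffs, freqs, w = window_fft(ws, taper, pad_factor)
    scale = 1.0 / (ws.fs * np.sum(w ** 2))
    S = (coeffs.real ** 2 + coeffs.imag ** 2) * scale
    S[..., 1:] *= 2.0
    if coeffs.shape[2] % 2 == 1:  # even nfft: last bin is the Nyquist bin
        S[..., -1] /= 2.0
    if parseval:
        df = freqs[1] - freqs[0]
        msq = np.mean(ws.data ** 2, axis=2)           # (n_win, n_ch)
        area = S.sum(axis=2) * df
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(area > 0, msq / np.where(area > 0, area, 1.0), 1.0)
        S *= factor[:, :, None]
    return WindowedSpectrum(S, freqs, ws.channels)


def _band_mask(freqs: np.ndarray, lo: float, hi: float,
               closed_lower: bool) -> np.ndarray:
    # shared edges belong to the lower band: intervals are (lo, hi], except
    # the lowest band which keeps its own lower edge
    if closed_lower:
        return (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    return (freqs > lo + 1e-12) & (freqs <= hi + 1e-12)


def band_areas(spec: WindowedSpectrum,
               bands: Mapping[str, tuple[float, float]] | None = None
               ) -> BandAreas:
    """Integrate the PSD over each EEG band, then average over windows."""
    bands = dict(bands or DEFAULT_BANDS)
    fmax = spec.freqs[-1]
    lowest = min(lo for lo, _ in bands.values())
    for name, (lo, hi) in bands.items():
        if lo < spec.freqs[0] - 1e-12 or hi > fmax + 1e-12:
            raise ValueError(
                f"band {name} ({lo}-{hi} Hz) outside the frequency grid "
                f"(0-{fmax} Hz)"
            )
    df = spec.df
    per_band = {}
    for name, (lo, hi) in sorted(bands.items(), key=lambda kv: kv[1][0]):
        mask = _band_mask(spec.freqs, lo, hi, closed_lower=(lo == lowest))
        # per-window area, then mean over windows (before any log transform)
        per_band[name] = (spec.S[:, :, mask].sum(axis=2) * df).mean(axis=0)
    areas = pd.DataFrame(per_band, index=list(spec.channels))
    return BandAreas(areas, {k: tuple(v) for k, v in bands.items()})


def log_transform(ba: BandAreas | pd.DataFrame, base: float = 10.0) -> pd.DataFrame:
    """logPS: logarithm (default base 10) of the band areas.

    Raw band powers vary by orders of magnitude between subjects; the log
    brings them to a comparable, approximately Gaussian scale.
    """
    areas = ba.areas if isinstance(ba, BandAreas) else ba
    values = areas.to_numpy()
    if np.any(values <= 0):
        raise ValueError("band areas must be strictly positive for log transform")
    return pd.DataFrame(np.log(values) / np.log(base),
                        index=areas.index, columns=areas.columns)


def spectral_entropy(spec: WindowedSpectrum,
                     support: tuple[float, float] = DEFAULT_ENTROPY_SUPPORT,
                     method: str = "per-window") -> EntropyValue:
    """Shannon spectral entropy (bits) over the analysis band.

    Each window's spectrum inside `support` is normalized to a probability
    distribution p_k over frequency bins; SSE = -sum p_k log2 p_k.  A flat
    spectrum over the default 60 bins gives log2(60) ~ 5.907 bits; a single
    spectral line gives 0.  `method` selects per-window entropies averaged
    over windows (default) or the entropy of the window-mean spectrum.
    """
    if method not in ("per-window", "mean-spectrum"):
        raise ValueError(f"unknown method {method!r}")
    lo, hi = support
    mask = (spec.freqs >= lo - 1e-12) & (spec.freqs <= hi + 1e-12)
    n_bins = int(mask.sum())
    if n_bins == 0:
        raise ValueError("entropy support contains no frequency bins")
    sub = spec.S[:, :, mask]
    if method == "mean-spectrum":
        sub = sub.mean(axis=0, keepdims=True)
    totals = sub.sum(axis=2, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("all-zero spectrum in entropy support")
    p = sub / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    sse = -plogp.sum(axis=2).mean(axis=0)
    return EntropyValue(pd.Series(sse, index=list(spec.channels)), n_bins)
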