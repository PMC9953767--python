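"""Monopolar 10-20 recordings, clinical preprocessing, and the double-banana montage.

The double-banana (longitudinal bipolar) montage chains adjacent 10-20
electrodes along the parasagittal and temporal lines of each hemisphere plus
the midline.  Every bipolar trace is the elementwise difference of its two
parent electrodes, which removes any signal common to the whole scalp
(reference, line noise picked up equally everywhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

#: The 19 classical 10-20 electrode positions.
ELECTRODES_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Double-banana channel order: left parasagittal, left temporal,
#: right parasagittal, right temporal, midline.
DOUBLE_BANANA: tuple[tuple[str, str], ...] = (
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)

MIDLINE_CHANNELS: tuple[str, ...] = ("Fz-Cz", "Cz-Pz")

#: Default analysis band and rate used throughout the package.
DEFAULT_BAND: tuple[float, float] = (0.5, 30.0)
DEFAULT_TARGET_FS: float = 128.0
DEFAULT_FILTER_ORDER: int = 6

#: Records shorter than this (seconds) trigger a warning after concatenation.
MIN_RECOMMENDED_DURATION: float = 120.0


class ShortRecordWarning(UserWarning):
    """Concatenated artifact-free record is shorter than recommended."""


def channel_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


BIPOLAR_LABELS: tuple[str, ...] = tuple(channel_label(p) for p in DOUBLE_BANANA)


@dataclass
class MonopolarRecording:
    """19-channel scalp EEG in µV referenced to the amplifier common.

    Parameters
    ----------
    labels : channel names; must contain each 10-20 electrode exactly once.
    samples : array (n_channels, n_times) in µV.
    fs : sampling rate in Hz; must exceed twice the 30 Hz analysis band edge.
    subject_age : age in years, optional (required for normative comparison).
    """

    labels: tuple[str, ...]
    samples: np.ndarray
    fs: float
    subject_age: float | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.labels):
            raise ValueError(
                f"samples must be (n_channels={len(self.labels)}, n_times); "
                f"got shape {self.samples.shape}"
            )
        missing = [e for e in ELECTRODES_1020 if self.labels.count(e) != 1]
        extra = [l for l in self.labels if l not in ELECTRODES_1020]
        if missing or extra:
            raise ValueError(
                "recording must contain each 10-20 electrode exactly once; "
                f"missing/duplicated: {missing}, unexpected: {extra}"
            )
        if not self.fs > 2 * 30.0:
            raise ValueError(f"sampling rate {self.fs} Hz below 2 x 30 Hz")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def get(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"electrode {label!r} not present") from None


@dataclass
class BipolarRecording:
    """Differential double-banana record derived from a MonopolarRecording."""

    channels: tuple[str, ...]
    samples: np.ndarray
    fs: float
    subject_age: float | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_times)")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def get(self, channel: str) -> np.ndarray:
        try:
            return self.samples[self.channels.index(channel)]
        except ValueError:
            raise KeyError(f"channel {channel!r} not present") from None


def butter_bandpass_sos(band: tuple[float, float], fs: float,
                        order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Order-`order` Butterworth bandpass as second-order sections.

    `order` is the overall filter order (an order-6 bandpass is scipy's
    N=3 design).
    """
    if order % 2:
        raise ValueError("bandpass order must be even")
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if fs <= 2 * high:
        raise ValueError(
            f"sampling rate {fs} Hz is at or below Nyquist for {high} Hz"
        )
    return signal.butter(order // 2, band, btype="bandpass", fs=fs, output="sos")


def preprocess(rec: MonopolarRecording,
               target_fs: float = DEFAULT_TARGET_FS,
               band: tuple[float, float] = DEFAULT_BAND,
               order: int = DEFAULT_FILTER_ORDER,
               edge_trim: float = 2.0) -> MonopolarRecording:
    """Band-limit and downsample a raw recording.

    Applies a zero-phase (forward-backward) Butterworth bandpass of overall
    order `order` between ``band[0]`` and ``band[1]`` Hz, then reduces the
    rate to `target_fs`.  With the default 0.5-30 Hz band the 30 Hz cut-off
    itself is the anti-alias guard for the 512 -> 128 Hz decimation.

    `edge_trim` seconds are dropped from each end afterwards (capped at 10%
    of the record per side): the high-pass settle-in at the record edges
    otherwise deposits a low-frequency transient of any strong in-band
    rhythm into the delta band.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("cannot preprocess a recording with NaN samples")
    sos = butter_bandpass_sos(band, rec.fs, order)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)

    ratio = Fraction(rec.fs / target_fs).limit_denominator(1000)
    if ratio.denominator == 1:
        out = filtered[:, :: ratio.numerator]
    else:
        out = signal.resample_poly(filtered, up=ratio.denominator,
                                   down=ratio.numerator, axis=1)
    trim = int(round(min(edge_trim, 0.1 * rec.duration) * target_fs))
    if trim > 0:
        out = out[:, trim:-trim]
    return MonopolarRecording(rec.labels, out, target_fs, rec.subject_age)


def concatenate_artifact_free(
    chunks: Sequence[MonopolarRecording],
    min_duration: float = MIN_RECOMMENDED_DURATION,
) -> MonopolarRecording:
    """Join visually selected artifact-free chunks end to end.

    All chunks must share electrode labels and sampling rate (channel order
    may differ; chunks are aligned to the first chunk's order).  A total
    below `min_duration` seconds is allowed but warned about, since short
    records inflate the variance of every spectral estimate.
    """
    chunks = list(chunks)
    if not chunks:
        raise ValueError("no chunks to concatenate")
    first = chunks[0]
    parts = [first.samples]
    for c in chunks[1:]:
        if c.fs != first.fs:
            raise ValueError(f"chunk sampling rates differ: {c.fs} vs {first.fs}")
        if set(c.labels) != set(first.labels):
            raise ValueError("chunk electrode labels differ")
        idx = [c.labels.index(l) for l in first.labels]
        parts.append(c.samples[idx])
    out = MonopolarRecording(first.labels, np.concatenate(parts, axis=1),
                             first.fs, first.subject_age)
    if out.duration < min_duration:
        warnings.warn(
            f"concatenated record is {out.duration:.1f} s, below the "
            f"recommended {min_duration:.0f} s",
            ShortRecordWarning,
            stacklevel=2,
        )
    return out


def reconstruct_double_banana(rec: MonopolarRecording) -> BipolarRecording:
    """Derive the 18 double-banana bipolar channels.

    Each output trace is first-parent minus second-parent; any signal common
    to all electrodes cancels exactly.
    """
    label_to_row = {l: i for i, l in enumerate(rec.labels)}
    for a, b in DOUBLE_BANANA:
        for e in (a, b):
            if e not in label_to_row:
                raise ValueError(f"missing electrode {e!r} for double-banana montage")
    out = np.empty((len(DOUBLE_BANANA), rec.n_times))
    for i, (a, b) in enumerate(DOUBLE_BANANA):
        out[i] = rec.samples[label_to_row[a]] - rec.samples[label_to_row[b]]
    return BipolarRecording(BIPOLAR_LABELS, out, rec.fs, rec.subject_age)
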