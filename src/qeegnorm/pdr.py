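"""Posterior dominant rhythm: alpha-peak frequency and RMS amplitude.

The PDR is the dominant occipital alpha oscillation of the awake eyes-closed
EEG, read from the parieto-occipital channels P3-O1 (left) and P4-O2 (right).
Frequency is the location of the maximum of the window-averaged spectrum
inside the alpha band on the 0.5 Hz grid; amplitude is the root mean square
of the band-limited (0.5-30 Hz) channel voltage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import BipolarRecording
from .spectral import WindowedSpectrum

PDR_CHANNELS = {"left": "P3-O1", "right": "P4-O2"}
DEFAULT_ALPHA_BAND: tuple[float, float] = (8.0, 13.0)


@dataclass
class PDRResult:
    """Peak alpha frequency (Hz, 0.5 Hz grid) and RMS amplitude (µV) per side."""

    freq_left: float
    freq_right: float
    amp_left: float
    amp_right: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pdr_freq_left": self.freq_left,
            "pdr_freq_right": self.freq_right,
            "pdr_amp_left": self.amp_left,
            "pdr_amp_right": self.amp_right,
        }


def pdr_frequency(spec: WindowedSpectrum, channel: str = "P3-O1",
                  band: tuple[float, float] = DEFAULT_ALPHA_BAND) -> float:
    """Frequency of the alpha-band maximum of the window-averaged spectrum.

    Exact ties break toward the lower frequency (argmax returns the first
    index of an ascending grid), which is deterministic and documented.
    """
    ch = spec.channel_index(channel)
    lo, hi = band
    mask = (spec.freqs >= lo - 1e-12) & (spec.freqs <= hi + 1e-12)
    if not mask.any():
        raise ValueError(f"no frequency bins inside the {lo}-{hi} Hz band")
    mean_spec = spec.S[:, ch, :].mean(axis=0)
    in_band = mean_spec[mask]
    return float(spec.freqs[mask][int(np.argmax(in_band))])


def rms_amplitude(rec: BipolarRecording, channel: str) -> float:
    """Root mean square of a channel's voltage over the full analyzed record."""
    x = rec.get(channel)
    if x.size == 0:
        raise ValueError(f"channel {channel!r} has no samples")
    return float(np.sqrt(np.mean(x ** 2)))


def measure_pdr(spec: WindowedSpectrum, rec: BipolarRecording,
                band: tuple[float, float] = DEFAULT_ALPHA_BAND) -> PDRResult:
    """PDR frequency and amplitude for both hemispheres."""
    return PDRResult(
        freq_left=pdr_frequency(spec, PDR_CHANNELS["left"], band),
        freq_right=pdr_frequency(spec, PDR_CHANNELS["right"], band),
        amp_left=rms_amplitude(rec, PDR_CHANNELS["left"]),
        amp_right=rms_amplitude(rec, PDR_CHANNELS["right"]),
    )
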