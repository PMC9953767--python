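"""Magnitude-squared coherence between bipolar channels.

Coh(w) = |<S_ij(w)>_n|^2 / (<S_ii(w)>_n <S_jj(w)>_n), where <.>_n averages
the cross-spectrum over windows *before* the magnitude is taken (averaging
after the magnitude would give 1 everywhere).  By Cauchy-Schwarz the result
is bounded in [0, 1]; for independent signals its expectation is ~1/n for n
averaged windows, a bias that vanishes as the record lengthens.

Band coherence is the unweighted mean of Coh(w) over a band's bins, and
lobe/hemisphere values average all channel pairs of the group
(Npairs = Nch(Nch-1)/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral import (DEFAULT_BANDS, DEFAULT_PAD_FACTOR, WindowSet,
                       _band_mask, window_fft)


@dataclass
class CoherenceSpectrum:
    """Frequency-resolved coherence per channel pair (dimensionless)."""

    coh: np.ndarray                      # (n_pairs, n_freqs) in [0, 1]
    pairs: tuple[tuple[str, str], ...]
    freqs: np.ndarray

    def pair_index(self, a: str, b: str) -> int:
        for i, (x, y) in enumerate(self.pairs):
            if {x, y} == {a, b}:
                return i
        raise KeyError(f"pair ({a}, {b}) not present")


def coherence_spectrum(ws: WindowSet,
                       pairs: Sequence[tuple[str, str]] | None = None,
                       taper: str = "hann",
                       pad_factor: int = DEFAULT_PAD_FACTOR) -> CoherenceSpectrum:
    """Window-averaged magnitude-squared coherence for the given channel pairs
    (default: all unordered pairs).

    Uses the same tapered, zero-padded window FFTs as the power spectrum, so
    auto- and cross-spectra come from a single estimator.  Requires at least
    two windows: a single window's coherence is identically 1.
    """
    if ws.n_windows < 2:
        raise ValueError("coherence requires at least 2 windows")
    coeffs, freqs, _ = window_fft(ws, taper, pad_factor)
    if pairs is None:
        pairs = list(combinations(ws.channels, 2))
    idx = {c: i for i, c in enumerate(ws.channels)}
    auto = (coeffs.real ** 2 + coeffs.imag ** 2).mean(axis=0)  # (n_ch, n_f)
    coh = np.empty((len(pairs), len(freqs)))
    for k, (a, b) in enumerate(pairs):
        if a not in idx or b not in idx:
            raise KeyError(f"unknown channel in pair ({a}, {b})")
        cross = (coeffs[:, idx[a]] * np.conj(coeffs[:, idx[b]])).mean(axis=0)
        denom = auto[idx[a]] * auto[idx[b]]
        bad = denom <= 0
        if np.any(bad):
            warnings.warn(
                f"zero auto-spectrum in pair ({a}, {b}); "
                f"{int(bad.sum())} bins masked as NaN",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (cross.real ** 2 + cross.imag ** 2) / np.where(bad, 1.0, denom)
        c[bad] = np.nan
        coh[k] = np.clip(c, 0.0, 1.0)
    return CoherenceSpectrum(coh, tuple((a, b) for a, b in pairs), freqs)


def band_coherence(cs: CoherenceSpectrum,
                   bands: Mapping[str, tuple[float, float]] | None = None
                   ) -> pd.DataFrame:
    """Mean coherence per band: DataFrame indexed by 'A-B|C-D' pair labels."""
    bands = dict(bands or DEFAULT_BANDS)
    lowest = min(lo for lo, _ in bands.values())
    out = {}
    for name, (lo, hi) in sorted(bands.items(), key=lambda kv: kv[1][0]):
        if hi > cs.freqs[-1] + 1e-12 or lo < cs.freqs[0] - 1e-12:
            raise ValueError(f"band {name} outside coherence frequency grid")
        mask = _band_mask(cs.freqs, lo, hi, closed_lower=(lo == lowest))
        if not mask.any():
            raise ValueError(f"band {name} has empty support on the grid")
        out[name] = cs.coh[:, mask].mean(axis=1)
    index = [f"{a}|{b}" for a, b in cs.pairs]
    return pd.DataFrame(out, index=index)


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}" if a <= b else f"{b}|{a}"


def group_coherence(bc: pd.DataFrame,
                    grouping: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Average pairwise band coherences over channel groups.

    `grouping` maps a region name to its channel slots (3 for a lobe, 9 for a
    hemisphere).  All slot pairs i<j are averaged; a slot list may legitimately
    repeat a channel (the hemisphere definition lists T5-O1/T6-O2 twice), in
    which case the repeated channel's pairings count twice and its pairing
    with itself is dropped as a self-pair.
    """
    lookup = {}
    for label in bc.index:
        a, b = label.split("|")
        lookup[_pair_key(a, b)] = label
    rows = {}
    for region, channels in grouping.items():
        vals = []
        for a, b in combinations(list(channels), 2):
            if a == b:
                continue  # self-pair of a duplicated slot
            key = _pair_key(a, b)
            if key not in lookup:
                raise KeyError(
                    f"grouping {region!r} references pair ({a}, {b}) "
                    "absent from the coherence table"
                )
            vals.append(bc.loc[lookup[key]])
        rows[region] = pd.concat(vals, axis=1).mean(axis=1)
    return pd.DataFrame(rows).T[list(bc.columns)]
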