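"""Age-parameterized synthetic 19-electrode resting-state EEG.

The generator emits eyes-closed-like monopolar recordings whose *bipolar*
double-banana derivations carry controlled per-band power, a posterior alpha
oscillation, and controlled within-lobe coherence, so that every pipeline
stage can be exercised against known ground truth.

Model
-----
Each hemisphere-lobe region r and band b has a shared band-limited Gaussian
source injected at the *scalp*: its electrode gains are solved so that the
region's three bipolar channels see the source with equal magnitude (a
within-lobe sign pattern), while the unavoidable boundary-electrode spill
into neighboring channels is spread where power headroom is largest —
a small, deterministic, volume-conduction-like effect.  Electrode-level
injection is automatically consistent with the montage's two-chain loop
(both chains of a hemisphere run from the prefrontal to the occipital
electrode, so only 7 of the 8 lateral bipolar signals are free).

Each channel additionally has a private band-limited source; the private
loop residual is least-squares spread over the hemisphere in proportion to
private power.  The shared-variance fraction c (``shared_fraction``) sets
the magnitude-squared coherence between lobe channels at ~c^2, so published
band-coherence targets map to c = sqrt(coherence).

Band powers are calibrated to the targets *as the package's own spectral
pipeline measures them*: the estimator's band transfer (own-band retention
and cross-band skirt leakage) is measured per source, the design solves
shared amplitudes and private powers against expected measured areas, and
two closure stages (raw periodogram, then the real pipeline) adjust the
private powers.  The posterior dominant rhythm is an O1/O2-localized
oscillator (RMS = ``pdr_amp``), which therefore appears on both P3-O1 and
T5-O1 (and the right homologues) exactly as a physical occipital source
would; ground truth accounts for its band footprint, including window
leakage into neighboring bands.

Private sources are mixtures of the lower and upper halves of each band with
mixing weight ``subband_lambda``; redistributing power *within* a band moves
spectral entropy without moving band areas, which is how cohort twins get
realistic, partly state-dependent SSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .montage import (DOUBLE_BANANA, ELECTRODES_1020, MonopolarRecording,
                      channel_label, preprocess, reconstruct_double_banana)
from .normative import (LOBE_CHANNELS, assign_age_group, load_normative_bundle,
                        load_reference_tables)
from .spectral import BAND_NAMES, DEFAULT_BANDS, band_areas, make_windows, power_spectrum

GEN_FS = 512.0
GEN_DURATION = 180.0

# chain structure per hemisphere: (parasagittal electrodes, temporal electrodes)
_CHAINS = {
    "L": (("Fp1", "F3", "C3", "P3", "O1"), ("Fp1", "F7", "T3", "T5", "O1")),
    "R": (("Fp2", "F4", "C4", "P4", "O2"), ("Fp2", "F8", "T4", "T6", "O2")),
}
_MIDLINE = ("Fz", "Cz", "Pz")

#: channel -> list of (side, lobe) regions it belongs to
CHANNEL_REGIONS: dict[str, list[tuple[str, str]]] = {}
for _side, _lobes in LOBE_CHANNELS.items():
    for _lobe, _chs in _lobes.items():
        for _ch in _chs:
            CHANNEL_REGIONS.setdefault(_ch, []).append((_side, _lobe))

#: +1 on parasagittal-chain channels, -1 on temporal-chain channels
_CHAIN_SIGN: dict[str, float] = {}
for _side, (_para, _temp) in _CHAINS.items():
    for _a, _b in zip(_para[:-1], _para[1:]):
        _CHAIN_SIGN[f"{_a}-{_b}"] = 1.0
    for _a, _b in zip(_temp[:-1], _temp[1:]):
        _CHAIN_SIGN[f"{_a}-{_b}"] = -1.0

_LATERAL = {side: tuple(f"{a}-{b}" for a, b in zip(chain[0][:-1], chain[0][1:]))
                  + tuple(f"{a}-{b}" for a, b in zip(chain[1][:-1], chain[1][1:]))
            for side, chain in _CHAINS.items()}
_POSTERIOR_ALPHA_CHANNELS = {"L": ("P3-O1", "T5-O1"), "R": ("P4-O2", "T6-O2")}


def default_band_power(age: float) -> dict[tuple[str, str], dict[str, float]]:
    """Per-region band-power targets (µV²) from the published per-age-group
    logPS means (10**logPS)."""
    group = assign_age_group(age)
    t2 = load_reference_tables()["group_logps"]
    out: dict[tuple[str, str], dict[str, float]] = {}
    for lobe, groups in t2.items():
        for band, sides in groups[group].items():
            for side in ("L", "R"):
                out.setdefault((side, lobe), {})[band] = 10.0 ** sides[side][0]
    return out


def default_shared_fraction(age: float) -> dict[tuple[str, str], dict[str, float]]:
    """Per-region shared-variance fractions from the published band-coherence
    group means (c = sqrt(coherence))."""
    group = assign_age_group(age)
    t3 = load_reference_tables()["group_coherence"]
    out: dict[tuple[str, str], dict[str, float]] = {}
    for lobe in ("F", "PO", "T"):
        for side in ("L", "R"):
            out[(side, lobe)] = {
                band: float(np.sqrt(coh))
                for band, coh in t3[lobe][group][side].items()
            }
    return out


def default_pdr(age: float) -> tuple[float, tuple[float, float]]:
    """(frequency, (left amp, right amp)) from the published age curves."""
    bundle = load_normative_bundle()
    freq = float(np.clip(bundle["pdr_frequency"].evaluate(age), 8.0, 13.0))
    return freq, (
        float(bundle["pdr_amplitude_left"].evaluate(age)),
        float(bundle["pdr_amplitude_right"].evaluate(age)),
    )


@dataclass
class SubjectSpec:
    """Ground-truth parameters of one synthetic subject.

    Leave the optional fields as None to use the published age-group defaults.
    ``pdr_amp`` may be a scalar (both sides) or a (left, right) pair.
    """

    age: float
    seed: int = 0
    band_power: dict[tuple[str, str], dict[str, float]] | None = None
    pdr_freq: float | None = None
    pdr_amp: float | tuple[float, float] | None = None
    shared_fraction: dict[tuple[str, str], dict[str, float]] | None = None
    subband_lambda: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.band_power is None:
            self.band_power = default_band_power(self.age)
        if self.shared_fraction is None:
            self.shared_fraction = default_shared_fraction(self.age)
        if self.pdr_freq is None or self.pdr_amp is None:
            freq, amps = default_pdr(self.age)
            if self.pdr_freq is None:
                self.pdr_freq = freq
            if self.pdr_amp is None:
                self.pdr_amp = amps
        if np.isscalar(self.pdr_amp):
            self.pdr_amp = (float(self.pdr_amp), float(self.pdr_amp))
        if self.subband_lambda is None:
            self.subband_lambda = {b: 0.5 for b in BAND_NAMES}
        for region, bands in self.band_power.items():
            for band, p in bands.items():
                if not p > 0:
                    raise ValueError(
                        f"infeasible band power {p} for {region}/{band}"
                    )
        for region, bands in self.shared_fraction.items():
            for band, c in bands.items():
                if not 0.0 <= c <= 1.0:
                    raise ValueError(
                        f"shared_fraction {c} outside [0, 1] for {region}/{band}"
                    )
        if not 8.0 <= self.pdr_freq <= 13.0:
            raise ValueError(f"pdr_freq {self.pdr_freq} outside [8, 13] Hz")
        if min(self.pdr_amp) <= 0:
            raise ValueError("pdr_amp must be positive")
        for band, lam in self.subband_lambda.items():
            if not 0.0 < lam < 1.0:
                raise ValueError(f"subband_lambda {lam} outside (0, 1)")


def _inband_normalize(x: np.ndarray, band: tuple[float, float],
                      fs: float) -> np.ndarray:
    """Scale so the periodogram power inside `band` is exactly 1 µV²
    (the filter skirts outside the band are excluded from the budget)."""
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    X = np.fft.rfft(x)[mask]
    p = 2.0 * np.sum(X.real ** 2 + X.imag ** 2) / x.size ** 2
    return x / np.sqrt(p) if p > 0 else x


def _bandlimited_noise(rng: np.random.Generator, band: tuple[float, float],
                       n: int, fs: float,
                       norm_band: tuple[float, float] | None = None
                       ) -> np.ndarray:
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return _inband_normalize(x, norm_band or band, fs)


def _private_source(rng: np.random.Generator, band: tuple[float, float],
                    lam: float, n: int, fs: float) -> np.ndarray:
    """Private noise with unit in-band power: lambda-weighted mix of the
    band's halves (redistributing power within the band moves spectral
    entropy without moving the band area)."""
    lo, hi = band
    mid = 0.5 * (lo + hi)
    low = _bandlimited_noise(rng, (lo, mid), n, fs, norm_band=(lo, hi))
    high = _bandlimited_noise(rng, (mid, hi), n, fs, norm_band=(lo, hi))
    x = np.sqrt(1.0 - lam) * low + np.sqrt(lam) * high
    return _inband_normalize(x, band, fs)


def _channel_band_target(spec: SubjectSpec, ch: str, band: str) -> float:
    regions = CHANNEL_REGIONS.get(ch)
    if regions:
        return float(np.mean([spec.band_power[r][band] for r in regions]))
    # midline channels: overall mean across regions
    return float(np.mean([v[band] for v in spec.band_power.values()]))


def _shared_weights(spec: SubjectSpec, ch: str, band: str
                    ) -> dict[tuple[str, str], float]:
    regions = CHANNEL_REGIONS.get(ch, [])
    cs = {r: spec.shared_fraction[r][band] for r in regions}
    total = sum(cs.values())
    norm = max(1.0, total)
    return {r: c / norm for r, c in cs.items()}


#: shared sources are injected at the scalp (electrode level), which keeps
#: them consistent with the montage's two-chain loop by construction; the
#: within-lobe sign pattern of the source across its three channels
_TEMPLATE_SIGNS = {"F": (1.0, -1.0, 1.0), "PO": (1.0, -1.0, -1.0),
                   "T": (1.0, -1.0, 1.0)}

_HEMI_ELECTRODES = {
    "L": ("Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5"),
    "R": ("Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6"),
}


def _region_channel_coeffs(side: str, lobe: str, amp: float,
                           headroom: pd.Series) -> dict[str, float]:
    """Channel coefficients of one region's scalp source.

    Solves the region's electrode gains so that its three lobe channels see
    exactly +-`amp` (the within-lobe sign pattern), while the unavoidable
    boundary-electrode spill into neighboring channels is spread in
    proportion to their power `headroom` (weighted least squares).  The
    spill behaves like volume conduction: small, deterministic, and placed
    where it perturbs band-power targets least.
    """
    electrodes = _HEMI_ELECTRODES[side]
    chans = _LATERAL[side]
    D = np.zeros((len(chans), len(electrodes)))
    for i, chlab in enumerate(chans):
        a, b = chlab.split("-")
        D[i, electrodes.index(a)] = 1.0
        D[i, electrodes.index(b)] = -1.0
    lobe_chs = LOBE_CHANNELS[side][lobe]
    y = np.zeros(len(chans))
    w = np.empty(len(chans))
    for i, chlab in enumerate(chans):
        if chlab in lobe_chs:
            y[i] = amp * _TEMPLATE_SIGNS[lobe][lobe_chs.index(chlab)]
            w[i] = 1e4  # effectively exact
        else:
            w[i] = 1.0 / np.sqrt(max(float(headroom[chlab]), 1e-9))
    gamma, *_ = np.linalg.lstsq(D * w[:, None], y * w, rcond=None)
    coeff = D @ gamma
    return {chlab: float(c) for chlab, c in zip(chans, coeff)
            if abs(c) > 1e-9 * max(abs(amp), 1.0)}


def _measure_band_areas(rec: MonopolarRecording) -> pd.DataFrame:
    """Band areas as the analysis pipeline itself would measure them."""
    bip = reconstruct_double_banana(preprocess(rec))
    spec = power_spectrum(make_windows(bip))
    return band_areas(spec).areas


def _waveform_band_areas(wave: np.ndarray, fs: float) -> pd.Series:
    """Pipeline band areas of a single waveform (filter, decimate, trim,
    window), mirroring the preprocessing applied to recordings."""
    from .montage import BipolarRecording, butter_bandpass_sos

    sos = butter_bandpass_sos((0.5, 30.0), fs)
    filtered = signal.sosfiltfilt(sos, wave)[:: int(fs / 128.0)]
    duration = wave.size / fs
    trim = int(round(min(2.0, 0.1 * duration) * 128.0))
    if trim > 0:
        filtered = filtered[trim:-trim]
    rec = BipolarRecording(("wave",), filtered[None, :], 128.0)
    spec = power_spectrum(make_windows(rec))
    return band_areas(spec).areas.loc["wave"]


def _loop_weights(priv_power: pd.DataFrame) -> pd.DataFrame:
    """Per-band distribution of the private-noise loop residual.

    Each hemisphere's chains share both end electrodes, so only 7 of its 8
    bipolar signals are free; the per-band residual of the private sources is
    spread over the channels in proportion to their *private* power targets.
    This keeps the relative perturbation of low-power channels (e.g. frontal
    alpha) small and sends none of the residual to fully shared channels, so
    the coherence limit of a fully shared lobe stays exact.
    """
    w = pd.DataFrame(0.0, index=priv_power.index, columns=priv_power.columns)
    for side in ("L", "R"):
        chs = list(_LATERAL[side])
        block = priv_power.loc[chs] + 1e-12
        w.loc[chs] = block / block.sum(axis=0)
    return w


def _assemble(shared_part: Mapping[str, Mapping[str, np.ndarray]],
              priv_part: Mapping[str, Mapping[str, np.ndarray]],
              weights: pd.DataFrame, n: int,
              osc: Mapping[str, np.ndarray] | None = None,
              common: np.ndarray | None = None) -> MonopolarRecording:
    """Electrode potentials from per-band designed bipolar signals.

    The shared contributions arrive already loop-balanced (see
    :func:`_balance_region_coeffs`); the private contributions' per-band loop
    residual is spread over each hemisphere's channels with `weights`.  The
    balanced signals are integrated along the chains into electrode
    potentials; occipital oscillators and a common-mode signal (which cancels
    in every bipolar derivation) are added on top.
    """
    bands = list(weights.columns)
    v = {e: np.zeros(n) for e in ELECTRODES_1020}
    for side, (para, temp) in _CHAINS.items():
        para_chs = [f"{a}-{b}" for a, b in zip(para[:-1], para[1:])]
        temp_chs = [f"{a}-{b}" for a, b in zip(temp[:-1], temp[1:])]
        adj = {c: sum(shared_part[c][b] for b in bands)
               + sum(priv_part[c][b] for b in bands)
               for c in para_chs + temp_chs}
        for b in bands:
            delta = (sum(priv_part[c][b] for c in para_chs)
                     - sum(priv_part[c][b] for c in temp_chs))
            for c in para_chs:
                adj[c] = adj[c] - weights.loc[c, b] * delta
            for c in temp_chs:
                adj[c] = adj[c] + weights.loc[c, b] * delta
        for chain in (para, temp):
            for a, b_ in zip(chain[:-1], chain[1:]):
                v[b_] = v[a] - adj[f"{a}-{b_}"]
        if osc is not None and side in osc:
            v[para[-1]] = v[para[-1]] - osc[side]  # O1/O2-localized source
    v["Cz"] = v["Fz"] - sum(priv_part["Fz-Cz"][b] for b in bands)
    v["Pz"] = v["Cz"] - sum(priv_part["Cz-Pz"][b] for b in bands)
    samples = np.stack([v[e] for e in ELECTRODES_1020])
    if common is not None:
        samples = samples + common
    return MonopolarRecording(ELECTRODES_1020, samples, GEN_FS)


def _loop_projection_matrix(channels: Sequence[str], weights: np.ndarray
                            ) -> np.ndarray:
    """Linear map designed -> loop-feasible bipolar signals for one band
    (midline rows are the identity): adj = d - side * w * sum(side * d).

    `weights` is aligned with `channels`.
    """
    n_ch = len(channels)
    P = np.eye(n_ch)
    for side, (para, temp) in _CHAINS.items():
        para_ix = [channels.index(f"{a}-{b}") for a, b in zip(para[:-1], para[1:])]
        temp_ix = [channels.index(f"{a}-{b}") for a, b in zip(temp[:-1], temp[1:])]
        for i in para_ix + temp_ix:
            s_i = 1.0 if i in para_ix else -1.0
            for j in para_ix + temp_ix:
                s_j = 1.0 if j in para_ix else -1.0
                P[i, j] -= s_i * weights[i] * s_j
    return P


def generate_subject(spec: SubjectSpec, duration: float = GEN_DURATION,
                     fs: float = GEN_FS, calibration_iters: int = 5,
                     common_mode_rms: float = 5.0
                     ) -> tuple[MonopolarRecording, dict]:
    """One synthetic subject: (recording, ground truth).

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    recordings.  Ground truth records the post-calibration per-channel band
    powers (including the posterior oscillator's alpha contribution), the
    oscillator frequency/amplitude, and the spec itself.
    """
    if fs != GEN_FS:
        raise ValueError("generator operates at 512 Hz")
    n = int(round(duration * fs))
    rng = np.random.default_rng(spec.seed)

    channels = [channel_label(p) for p in DOUBLE_BANANA]
    shared: dict[tuple[str, str, str], np.ndarray] = {}
    for side in ("L", "R"):
        for lobe in ("F", "PO", "T"):
            for band in BAND_NAMES:
                shared[(side, lobe, band)] = _bandlimited_noise(
                    rng, DEFAULT_BANDS[band], n, fs)
    private = {
        (ch, band): _private_source(rng, DEFAULT_BANDS[band],
                                    spec.subband_lambda[band], n, fs)
        for ch in channels for band in BAND_NAMES
    }
    phases = {side: rng.uniform(0, 2 * np.pi) for side in ("L", "R")}
    common = common_mode_rms * _bandlimited_noise(rng, (0.5, 30.0), n, fs) \
        if common_mode_rms > 0 else None

    targets = pd.DataFrame(
        {band: [_channel_band_target(spec, ch, band) for ch in channels]
         for band in BAND_NAMES}, index=channels)

    # band transfer of the windowed estimator, measured once per shared
    # source: a band-limited source keeps only part of its power in its own
    # band and spills the filter-skirt remainder into the neighbors.  The
    # design below solves shared amplitudes and private powers so that the
    # *expected measured* band areas land on the targets; without this, a
    # small band next to a dominant one (e.g. theta beside a strong
    # posterior alpha) would be unreachable from above, and coherence of
    # heavily shared bands would be diluted by private top-ups.
    transfer = {key: _waveform_band_areas(src, fs)
                for key, src in shared.items()}
    gen_transfer = {
        b: sum(transfer[(s, l, b)] for s in ("L", "R")
               for l in ("F", "PO", "T")) / 6.0
        for b in BAND_NAMES
    }

    floor = 0.02 * targets
    pv = targets.copy()
    shared_coeff: dict[tuple[str, str, str], dict[str, float]] = {}
    raw = targets.copy()
    for _ in range(6):
        shared_coeff = {}
        for (side, lobe) in spec.shared_fraction:
            chs = LOBE_CHANNELS[side][lobe]
            for band in BAND_NAMES:
                a = float(np.sqrt(np.mean([
                    _shared_weights(spec, ch, band).get((side, lobe), 0.0)
                    * raw.loc[ch, band] for ch in chs])))
                shared_coeff[(side, lobe, band)] = _region_channel_coeffs(
                    side, lobe, a, raw[band])
        expected = pd.DataFrame(0.0, index=channels, columns=list(BAND_NAMES))
        for (side, lobe, b_src), coeffs in shared_coeff.items():
            tr = transfer[(side, lobe, b_src)]
            for ch, c in coeffs.items():
                for b_dst in BAND_NAMES:
                    expected.loc[ch, b_dst] += c * c * float(tr[b_dst])
        for b_src in BAND_NAMES:
            tr = gen_transfer[b_src]
            for b_dst in BAND_NAMES:
                expected[b_dst] += pv[b_src] * float(tr[b_dst])
        own = pd.Series({b: float(gen_transfer[b][b]) for b in BAND_NAMES})
        pv = (pv + (targets - expected) / own).clip(lower=floor)
        shared_var = pd.DataFrame(0.0, index=channels,
                                  columns=list(BAND_NAMES))
        for (side, lobe, band), coeffs in shared_coeff.items():
            for ch, c in coeffs.items():
                shared_var.loc[ch, band] += c * c
        raw = shared_var + pv
    weights = _loop_weights(pv)

    def build(pv: pd.DataFrame, with_osc: bool,
              with_common: bool) -> MonopolarRecording:
        qv = pv ** 0.5
        shared_part = {ch: {band: np.zeros(n) for band in BAND_NAMES}
                       for ch in channels}
        for (side, lobe, band), coeffs in shared_coeff.items():
            src = shared[(side, lobe, band)]
            for ch, c in coeffs.items():
                shared_part[ch][band] = shared_part[ch][band] + c * src
        priv_part = {
            ch: {band: qv.loc[ch, band] * private[(ch, band)]
                 for band in BAND_NAMES}
            for ch in channels
        }
        osc = None
        if with_osc:
            t = np.arange(n) / fs
            osc = {
                side: np.sqrt(2.0) * amp
                * np.sin(2 * np.pi * spec.pdr_freq * t + phases[side])
                for side, amp in zip(("L", "R"), spec.pdr_amp)
            }
        return _assemble(shared_part, priv_part, weights, n,
                         osc=osc, common=common if with_common else None)

    # two-stage calibration of the private variances (the shared
    # coefficients are fixed by the coherence targets).  Stage 1 iterates an
    # additive update against raw-periodogram band powers of the designed
    # signals; stage 2 repeats it against the package's own spectral
    # pipeline to absorb what the raw periodogram cannot see (filter edges,
    # taper leakage).  Oscillator and common mode are excluded: the former
    # is accounted for analytically, the latter cancels in every bipolar
    # derivation.
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band_mask = {}
    proj = {}
    shared_rows = {}
    private_fft = {}
    for band in BAND_NAMES:
        lo, hi = DEFAULT_BANDS[band]
        mask = (freqs >= lo) & (freqs <= hi)
        band_mask[band] = mask
        proj[band] = _loop_projection_matrix(channels, weights[band].to_numpy())
        rows = np.zeros((len(channels), int(mask.sum())), dtype=complex)
        for (side, lobe, b2), coeffs in shared_coeff.items():
            if b2 != band:
                continue
            src = np.fft.rfft(shared[(side, lobe, band)])[mask]
            for ch, c in coeffs.items():
                rows[channels.index(ch)] += c * src
        shared_rows[band] = rows
        for ch in channels:
            private_fft[(ch, band)] = np.fft.rfft(private[(ch, band)])[mask]
    for _ in range(25):
        qv = pv ** 0.5
        meas = pd.DataFrame(0.0, index=channels, columns=list(BAND_NAMES))
        for band in BAND_NAMES:
            priv_rows = np.stack([qv.loc[ch, band] * private_fft[(ch, band)]
                                  for ch in channels])
            adj = proj[band] @ priv_rows + shared_rows[band]
            meas[band] = 2.0 * np.sum(adj.real ** 2 + adj.imag ** 2,
                                      axis=1) / n ** 2
        pv = (pv + (raw - meas)).clip(lower=floor)
    for _ in range(calibration_iters):
        measured = _measure_band_areas(build(pv, with_osc=False,
                                             with_common=False))
        pv = (pv + (targets - measured)).clip(lower=floor)

    rec = build(pv, with_osc=True, with_common=True)
    rec = replace(rec, subject_age=spec.age)

    # ground truth includes the oscillator's band footprint as the windowed
    # estimator sees it (a spectral line leaks into neighboring bands through
    # the 1-s window), measured once on the oscillator waveform alone
    truth_power = targets.copy()
    t = np.arange(n) / fs
    for side, amp in zip(("L", "R"), spec.pdr_amp):
        wave = np.sqrt(2.0) * amp * np.sin(
            2 * np.pi * spec.pdr_freq * t + phases[side])
        osc_areas = _waveform_band_areas(wave, fs)
        for ch in _POSTERIOR_ALPHA_CHANNELS[side]:
            truth_power.loc[ch] += osc_areas
    grid_freq = round(spec.pdr_freq * 2.0) / 2.0
    truth = {
        "age": spec.age,
        "band_power": truth_power,
        "pdr_freq": spec.pdr_freq,
        "pdr_freq_grid": grid_freq,
        "pdr_amp": tuple(spec.pdr_amp),
        "shared_fraction": spec.shared_fraction,
        "spec": spec,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """A synthetic cohort: ages, persistent subject traits, and session noise.

    Trait SDs give every subject stable individual deviations from the
    age-group defaults (log10 band-power offsets shared across hemispheres,
    PDR frequency scatter of 0.5 Hz around the normative cubic, relative
    amplitude scatter, shared-fraction jitter, within-band tilt).  Session
    SDs add state variability that differs between twin sessions of the same
    subject.
    """

    n: int
    seed: int = 0
    age_range: tuple[float, float] = (10.0, 74.0)
    ages: tuple[float, ...] | None = None
    duration: float = GEN_DURATION
    logps_trait_sd: float = 0.3
    session_logps_sd: float = 0.0375
    pdr_freq_sd: float = 0.5
    pdr_amp_rel_sd: float = 0.2
    shared_trait_sd: float = 0.05
    subband_trait_sd: float = 0.15
    session_subband_sd: float = 0.15
    calibration_iters: int = 5
    common_mode_rms: float = 5.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort needs n >= 1")
        if self.ages is not None:
            if len(self.ages) != self.n:
                raise ValueError("len(ages) must equal n")
            lo, hi = self.age_range
            if any(not lo <= a <= hi for a in self.ages):
                raise ValueError("explicit ages outside age_range")


def _cohort_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def subject_traits(cs: CohortSpec) -> list[dict]:
    """Persistent per-subject traits, independent of session."""
    rng = _cohort_rng(cs.seed, 0)
    if cs.ages is not None:
        ages = np.asarray(cs.ages, dtype=float)
    else:
        ages = rng.uniform(*cs.age_range, size=cs.n)
    traits = []
    for i, age in enumerate(ages):
        trng = _cohort_rng(cs.seed, 1, i)
        freq_default, amp_default = default_pdr(age)
        logps_off = {(lobe, band): trng.normal(0.0, cs.logps_trait_sd)
                     for lobe in ("F", "PO", "T") for band in BAND_NAMES}
        shared_off = {(lobe, band): trng.normal(0.0, cs.shared_trait_sd)
                      for lobe in ("F", "PO", "T") for band in BAND_NAMES}
        lam = {band: float(np.clip(0.5 + trng.normal(0.0, cs.subband_trait_sd),
                                   0.05, 0.95))
               for band in BAND_NAMES}
        traits.append({
            "age": float(age),
            "logps_offset": logps_off,
            "shared_offset": shared_off,
            "subband_lambda": lam,
            "pdr_freq": float(np.clip(
                freq_default + trng.normal(0.0, cs.pdr_freq_sd), 8.0, 13.0)),
            "pdr_amp": tuple(
                max(1.0, a * (1.0 + trng.normal(0.0, cs.pdr_amp_rel_sd)))
                for a in amp_default),
        })
    return traits


def realize_spec(traits: dict, cs: CohortSpec, subject: int,
                 session: int) -> SubjectSpec:
    """Session realization of a subject: traits plus session state noise."""
    srng = _cohort_rng(cs.seed, 2, subject, session)
    power = default_band_power(traits["age"])
    session_off = {(lobe, band): srng.normal(0.0, cs.session_logps_sd)
                   for lobe in ("F", "PO", "T") for band in BAND_NAMES}
    band_power = {
        (side, lobe): {
            band: p * 10.0 ** (traits["logps_offset"][(lobe, band)]
                               + session_off[(lobe, band)])
            for band, p in bands.items()
        }
        for (side, lobe), bands in power.items()
    }
    shared = {
        (side, lobe): {
            band: float(np.clip(c + traits["shared_offset"][(lobe, band)], 0.0, 1.0))
            for band, c in bands.items()
        }
        for (side, lobe), bands in default_shared_fraction(traits["age"]).items()
    }
    lam = {band: float(np.clip(
        traits["subband_lambda"][band] + srng.normal(0.0, cs.session_subband_sd),
        0.05, 0.95)) for band in BAND_NAMES}
    seed = int(np.random.SeedSequence(
        cs.seed, spawn_key=(3, subject, session)).generate_state(1)[0] % (2 ** 31))
    return SubjectSpec(
        age=traits["age"], seed=seed, band_power=band_power,
        pdr_freq=traits["pdr_freq"], pdr_amp=traits["pdr_amp"],
        shared_fraction=shared, subband_lambda=lam,
    )


def generate_cohort(cs: CohortSpec, session: int = 1
                    ) -> list[tuple[MonopolarRecording, dict]]:
    """Independent subjects with per-subject seeds derived from the master
    seed; the same (CohortSpec, session) is bit-reproducible."""
    traits = subject_traits(cs)
    out = []
    for i, tr in enumerate(traits):
        spec = realize_spec(tr, cs, i, session)
        out.append(generate_subject(
            spec, duration=cs.duration,
            calibration_iters=cs.calibration_iters,
            common_mode_rms=cs.common_mode_rms))
    return out


def twin_sessions(cs: CohortSpec) -> tuple[list, list]:
    """Two sessions of the same subjects: identical traits, fresh state noise
    and noise seeds — the test-retest design."""
    return generate_cohort(cs, session=1), generate_cohort(cs, session=2)


def generate_feature_cohort(n: int, seed: int = 0,
                            age_range: tuple[float, float] = (10.0, 74.0),
                            pdr_freq_sd: float = 0.5,
                            pdr_amp_rel_sd: float = 0.2,
                            logps_sd: float = 0.3,
                            sse_sd: float = 0.5,
                            coh_sd: float = 0.05) -> pd.DataFrame:
    """Feature-level cohort drawn directly from the published age curves.

    Each subject's PDR frequency is the normative cubic plus Gaussian noise
    (default SD 0.5 Hz), amplitudes follow the offset-exponentials with
    relative noise, SSE the printed cubics, and logPS / coherence the
    age-group table values.  Used for regression parameter-recovery studies
    where synthesizing full recordings would add nothing.
    """
    rng = np.random.default_rng(seed)
    bundle = load_normative_bundle()
    ages = rng.uniform(*age_range, size=n)
    rows = []
    for age in ages:
        row = {"age": float(age)}
        row["pdr_freq"] = float(bundle["pdr_frequency"].evaluate(age)
                                + rng.normal(0.0, pdr_freq_sd))
        for side, eq in (("left", "pdr_amplitude_left"),
                         ("right", "pdr_amplitude_right")):
            base = float(bundle[eq].evaluate(age))
            row[f"pdr_amp_{side}"] = max(1.0, base * (1 + rng.normal(0, pdr_amp_rel_sd)))
        for region in ("L_F", "R_F", "L_PO", "R_PO", "L_T", "R_T"):
            row[f"sse_{region}"] = float(bundle[f"sse_{region}"].evaluate(age)
                                         + rng.normal(0.0, sse_sd))
        power = default_band_power(age)
        for (side, lobe), bands in power.items():
            for band, p in bands.items():
                row[f"logps_{side}_{lobe}_{band}"] = float(
                    np.log10(p) + rng.normal(0.0, logps_sd))
        t3 = load_reference_tables()["group_coherence"]
        group = assign_age_group(age)
        for region in ("H", "F", "PO", "T"):
            for side in ("L", "R"):
                for band, coh in t3[region][group][side].items():
                    row[f"coh_{side}_{region}_{band}"] = float(
                        np.clip(coh + rng.normal(0.0, coh_sd), 0.0, 1.0))
        rows.append(row)
    return pd.DataFrame(rows)
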