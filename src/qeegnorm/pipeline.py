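"""End-to-end orchestration: raw monopolar record -> per-subject features.

Also houses the pipeline configuration (every tunable of the analysis in one
serializable object) and cohort-level summaries: whole-cohort and per-age-
group feature tables, symmetric-lobe comparisons, band-structure orderings,
and normative refits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as qstats
from .montage import (DEFAULT_BAND, DEFAULT_FILTER_ORDER, DEFAULT_TARGET_FS,
                      MonopolarRecording, preprocess, reconstruct_double_banana)
from .normative import (BANDS, REGIONS, assign_age_group, fit_normative,
                        fit_offset_exponential, load_normative_bundle,
                        region_grouping, region_table, structure_ordering,
                        ordering_label)
from .pdr import PDRResult, measure_pdr
from .spectral import (DEFAULT_BANDS, band_areas, log_transform, make_windows,
                       power_spectrum, spectral_entropy)
from .synchronization import band_coherence, coherence_spectrum, group_coherence


@dataclass
class PipelineConfig:
    """All analysis knobs with their clinical-pipeline defaults."""

    target_fs: float = DEFAULT_TARGET_FS
    filter_band: tuple[float, float] = DEFAULT_BAND
    filter_order: int = DEFAULT_FILTER_ORDER
    edge_trim: float = 2.0
    window_len: float = 1.0
    overlap_frac: float = 0.1
    taper: str = "hann"
    pad_factor: int = 2
    parseval: bool = True
    band_edges: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    log_base: float = 10.0
    entropy_method: str = "per-window"
    pdr_band: tuple[float, float] = (8.0, 13.0)
    age_boundaries: tuple[float, float] = (20.0, 50.0)
    hemisphere_policy: str = "slots"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("filter_band", "pdr_band", "age_boundaries"):
            if key in d:
                d[key] = tuple(d[key])
        if "band_edges" in d:
            d["band_edges"] = {k: tuple(v) for k, v in d["band_edges"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SubjectFeatures:
    """Per-subject qEEG feature set on the region grid.

    logps and coh are region x band DataFrames, sse a region Series; regions
    are L_F, L_PO, L_T, L_H and right homologues.  Channel-level logPS is
    kept for feature export.
    """

    age: float | None
    logps: pd.DataFrame
    sse: pd.Series
    coh: pd.DataFrame
    pdr: PDRResult
    channel_logps: pd.DataFrame | None = None

    def to_series(self) -> pd.Series:
        parts = {}
        for region in self.logps.index:
            for band in self.logps.columns:
                parts[f"logps_{region}_{band}"] = self.logps.loc[region, band]
        for region in self.sse.index:
            parts[f"sse_{region}"] = self.sse[region]
        for region in self.coh.index:
            for band in self.coh.columns:
                parts[f"coh_{region}_{band}"] = self.coh.loc[region, band]
        parts.update(self.pdr.as_dict())
        if self.age is not None:
            parts["age"] = self.age
        return pd.Series(parts)


def analyze_recording(rec: MonopolarRecording,
                      config: PipelineConfig | None = None) -> SubjectFeatures:
    """Full single-subject analysis.

    Filter and downsample, derive the double-banana montage, window, estimate
    per-window spectra, integrate band areas (log10), compute spectral
    entropy and pairwise band coherence, group everything by lobe and
    hemisphere, and read the posterior dominant rhythm.
    """
    cfg = config or PipelineConfig()
    pre = preprocess(rec, cfg.target_fs, cfg.filter_band, cfg.filter_order,
                     cfg.edge_trim)
    bip = reconstruct_double_banana(pre)
    ws = make_windows(bip, cfg.window_len, cfg.overlap_frac)
    spec = power_spectrum(ws, cfg.taper, cfg.pad_factor, cfg.parseval)

    areas = band_areas(spec, cfg.band_edges)
    channel_logps = log_transform(areas, cfg.log_base)
    entropy = spectral_entropy(
        spec, support=(min(lo for lo, _ in cfg.band_edges.values()),
                       max(hi for _, hi in cfg.band_edges.values())),
        method=cfg.entropy_method)

    grouping = region_grouping(cfg.hemisphere_policy)
    logps = region_table(channel_logps, cfg.hemisphere_policy)
    sse = region_table(entropy.sse, cfg.hemisphere_policy)

    cs = coherence_spectrum(ws, taper=cfg.taper, pad_factor=cfg.pad_factor)
    bc = band_coherence(cs, cfg.band_edges)
    coh = group_coherence(bc, grouping)

    pdr = measure_pdr(spec, bip, cfg.pdr_band)
    return SubjectFeatures(rec.subject_age, logps, sse, coh, pdr, channel_logps)


def features_frame(subjects: Sequence[SubjectFeatures]) -> pd.DataFrame:
    """Stack per-subject features into a subjects x features table."""
    return pd.DataFrame([s.to_series() for s in subjects]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort summaries


def cohort_band_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Whole-cohort logPS means/SEM per lobe, band and hemisphere with
    symmetric-lobe comparisons (the whole-cohort summary table)."""
    rows = []
    n = len(frame)
    for lobe in ("F", "PO", "T"):
        for band in BANDS:
            left = frame[f"logps_L_{lobe}_{band}"].to_numpy()
            right = frame[f"logps_R_{lobe}_{band}"].to_numpy()
            cmp = qstats.paired_compare(left, right) if n >= 5 else None
            rows.append({
                "lobe": lobe, "band": band,
                "left_mean": left.mean(), "left_sem": left.std(ddof=1) / np.sqrt(n),
                "right_mean": right.mean(), "right_sem": right.std(ddof=1) / np.sqrt(n),
                "test": cmp.test if cmp else None,
                "p": cmp.p if cmp else None,
            })
    return pd.DataFrame(rows)


def group_band_table(frame: pd.DataFrame,
                     boundaries: tuple[float, float] = (20.0, 50.0)
                     ) -> pd.DataFrame:
    """Per-age-group logPS means/SEM (the age-structure table) plus each
    group's band ordering per lobe and side."""
    groups = frame["age"].map(lambda a: assign_age_group(a, boundaries))
    rows = []
    for group, sub in frame.groupby(groups):
        for lobe in ("F", "PO", "T"):
            for side in ("L", "R"):
                means = {b: sub[f"logps_{side}_{lobe}_{b}"].mean() for b in BANDS}
                order = ordering_label(structure_ordering(means))
                for band in BANDS:
                    vals = sub[f"logps_{side}_{lobe}_{band}"]
                    rows.append({
                        "group": group, "lobe": lobe, "side": side, "band": band,
                        "n": len(sub), "mean": vals.mean(),
                        "sem": vals.std(ddof=1) / np.sqrt(len(sub)),
                        "ordering": order,
                    })
    return pd.DataFrame(rows)


def coherence_structure_table(frame: pd.DataFrame,
                              boundaries: tuple[float, float] = (20.0, 50.0)
                              ) -> pd.DataFrame:
    """Per-age-group band-coherence means and orderings per region."""
    groups = frame["age"].map(lambda a: assign_age_group(a, boundaries))
    rows = []
    for group, sub in frame.groupby(groups):
        for region in ("H", "F", "PO", "T"):
            for side in ("L", "R"):
                means = {b: sub[f"coh_{side}_{region}_{b}"].mean() for b in BANDS}
                order = ordering_label(structure_ordering(means))
                for band in BANDS:
                    rows.append({
                        "group": group, "region": region, "side": side,
                        "band": band, "n": len(sub), "mean": means[band],
                        "ordering": order,
                    })
    return pd.DataFrame(rows)


def fit_cohort_equations(frame: pd.DataFrame, degree: int = 3) -> dict:
    """Refit the normative age regressions on a cohort feature table:
    PDR cubic, amplitude offset-exponentials, SSE polynomials."""
    ages = frame["age"].to_numpy()
    fits = {
        "pdr_frequency": fit_normative(ages, frame["pdr_freq"].to_numpy()
                                       if "pdr_freq" in frame
                                       else frame[["pdr_freq_left", "pdr_freq_right"]]
                                       .mean(axis=1).to_numpy(),
                                       degree=degree, name="pdr_frequency",
                                       units="Hz"),
    }
    for side in ("left", "right"):
        col = f"pdr_amp_{side}"
        if col in frame:
            fits[f"pdr_amplitude_{side}"] = fit_offset_exponential(
                ages, frame[col].to_numpy(),
                name=f"pdr_amplitude_{side}", units="uV")
    for region in ("L_F", "R_F", "L_PO", "R_PO", "L_T", "R_T"):
        col = f"sse_{region}"
        if col in frame:
            fits[f"sse_{region}"] = fit_normative(
                ages, frame[col].to_numpy(), degree=degree,
                name=f"sse_{region}", units="bits")
    return fits


def deviation_report(features: SubjectFeatures,
                     bundle: dict | None = None) -> pd.DataFrame:
    """Observed features against the shipped normative equations.

    Residual = observed - predicted at the subject's age; useful as a
    screening distance from the physiological range.
    """
    if features.age is None:
        raise ValueError("deviation report requires the subject's age")
    bundle = bundle or load_normative_bundle()
    obs = {
        "pdr_frequency": np.mean([features.pdr.freq_left, features.pdr.freq_right]),
        "pdr_amplitude_left": features.pdr.amp_left,
        "pdr_amplitude_right": features.pdr.amp_right,
    }
    for region in ("L_F", "R_F", "L_PO", "R_PO", "L_T", "R_T"):
        obs[f"sse_{region}"] = features.sse[region]
    rows = []
    for name, eq in bundle.items():
        if name not in obs:
            continue
        pred = float(eq.evaluate(features.age))
        rows.append({
            "feature": name, "units": eq.units, "observed": obs[name],
            "predicted": pred, "residual": obs[name] - pred,
        })
    return pd.DataFrame(rows)
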