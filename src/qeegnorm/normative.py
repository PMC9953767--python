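"""Lobe/hemisphere grouping, age groups, band-structure orderings, and
normative age-regression equations.

Channel-level features are averaged over fixed channel triplets per lobe
(frontal F, parieto-occipital PO, temporal T) and over nine channel slots per
hemisphere.  The posterior channels T5-O1 / T6-O2 legitimately belong to both
the PO and T lobes, and the hemisphere slot list repeats them, so by default
they are double-counted in the hemisphere mean (a "unique" policy is
available).  Midline channels are never part of any grouping.

A normative equation regresses a feature on age in a healthy cohort; the
package ships the published bundle (PDR cubic, amplitude offset-exponentials,
SSE cubics) as versioned JSON and can refit analogous equations on any
cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as qstats

BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta")

#: Lobe channel triplets (bipolar double-banana labels).
LOBE_CHANNELS: dict[str, dict[str, tuple[str, str, str]]] = {
    "L": {
        "F": ("Fp1-F3", "F3-C3", "Fp1-F7"),
        "PO": ("C3-P3", "P3-O1", "T5-O1"),
        "T": ("F7-T3", "T3-T5", "T5-O1"),
    },
    "R": {
        "F": ("Fp2-F4", "F4-C4", "Fp2-F8"),
        "PO": ("C4-P4", "P4-O2", "T6-O2"),
        "T": ("F8-T4", "T4-T6", "T6-O2"),
    },
}

#: Hemisphere slot lists: the nine lobe slots as published, with the
#: posterior temporal-occipital channel appearing twice.
HEMISPHERE_SLOTS: dict[str, tuple[str, ...]] = {
    side: LOBE_CHANNELS[side]["F"] + LOBE_CHANNELS[side]["PO"] + LOBE_CHANNELS[side]["T"]
    for side in ("L", "R")
}

REGIONS: tuple[str, ...] = ("L_F", "L_PO", "L_T", "L_H", "R_F", "R_PO", "R_T", "R_H")

AGE_GROUPS: tuple[str, ...] = ("<20", "20-50", ">50")


def region_grouping(hemisphere_policy: str = "slots") -> dict[str, tuple[str, ...]]:
    """Region name -> channel slots, for lobes and hemispheres.

    hemisphere_policy 'slots' keeps the duplicated posterior slot (9 slots,
    36 formula pairs); 'unique' deduplicates to 8 channels.
    """
    if hemisphere_policy not in ("slots", "unique"):
        raise ValueError(f"unknown hemisphere policy {hemisphere_policy!r}")
    out: dict[str, tuple[str, ...]] = {}
    for side in ("L", "R"):
        for lobe in ("F", "PO", "T"):
            out[f"{side}_{lobe}"] = LOBE_CHANNELS[side][lobe]
        slots = HEMISPHERE_SLOTS[side]
        if hemisphere_policy == "unique":
            slots = tuple(dict.fromkeys(slots))
        out[f"{side}_H"] = slots
    return out


def group_features(values: Mapping[str, float] | pd.Series,
                   channels: Sequence[str]) -> float:
    """Arithmetic mean of a channel-level feature over grouping slots.

    Duplicated slots count twice, matching the published hemisphere formula.
    """
    vals = []
    for ch in channels:
        if ch not in values:
            raise KeyError(f"channel {ch!r} missing from feature values")
        vals.append(float(values[ch]))
    return float(np.mean(vals))


def region_table(per_channel: pd.DataFrame | pd.Series,
                 hemisphere_policy: str = "slots") -> pd.DataFrame | pd.Series:
    """Apply the full region grouping to a channel-indexed feature table."""
    grouping = region_grouping(hemisphere_policy)
    if isinstance(per_channel, pd.Series):
        return pd.Series(
            {r: group_features(per_channel, chs) for r, chs in grouping.items()}
        )[list(REGIONS)]
    rows = {
        r: {col: group_features(per_channel[col], chs)
            for col in per_channel.columns}
        for r, chs in grouping.items()
    }
    return pd.DataFrame(rows).T.loc[list(REGIONS), list(per_channel.columns)]


def assign_age_group(age: float,
                     boundaries: tuple[float, float] = (20.0, 50.0)) -> str:
    """Deterministic age partition: [0,20) -> '<20', [20,50] -> '20-50',
    (50, inf) -> '>50'."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    if not 10 <= age <= 74:
        warnings.warn(
            f"age {age} outside the 10-74 y normative range", stacklevel=2
        )
    lo, hi = boundaries
    if age < lo:
        return "<20"
    if age <= hi:
        return "20-50"
    return ">50"


def structure_ordering(means: Mapping[str, float],
                       tol: float = 0.0) -> tuple[tuple[str, ...], ...]:
    """Rank bands (or coherence measures) by descending group mean.

    Returns a tuple of tie groups, e.g. (('alpha',), ('delta',),
    ('beta', 'theta')) when beta and theta are exactly tied.  Values within
    `tol` of each other are treated as tied (default: exact ties only, which
    matches values printed to fixed precision).
    """
    items = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: list[list[str]] = []
    last = None
    for name, value in items:
        if last is not None and abs(last - value) <= tol:
            groups[-1].append(name)
        else:
            groups.append([name])
        last = value
    return tuple(tuple(g) for g in groups)


def ordering_label(ordering: tuple[tuple[str, ...], ...]) -> str:
    """Human-readable ordering, ties joined with '/': 'alpha, delta, beta/theta'."""
    return ", ".join("/".join(g) for g in ordering)


@dataclass
class NormativeEquation:
    """Age regression of a qEEG feature.

    kind 'polynomial': value = sum_i c_i * age**i (coefficients ascending).
    kind 'offset_exponential': value = c0 + c1 * exp(-c2 * age), the decaying
    form (amplitude falls steeply through adolescence toward an adult floor).
    """

    name: str
    kind: str
    coefficients: tuple[float, ...]
    r: float | None = None
    n: int | None = None
    age_range: tuple[float, float] = (10.0, 73.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.coefficients = tuple(float(c) for c in self.coefficients)
        if self.kind not in ("polynomial", "offset_exponential"):
            raise ValueError(f"unknown equation kind {self.kind!r}")
        if self.r is not None and not -1.0 <= self.r <= 1.0:
            raise ValueError(f"fit r {self.r} outside [-1, 1]")

    def evaluate(self, age) -> np.ndarray | float:
        age = np.asarray(age, dtype=float)
        if self.kind == "polynomial":
            out = np.polynomial.polynomial.polyval(age, self.coefficients)
        else:
            a, b, k = self.coefficients
            out = a + b * np.exp(-k * age)
        return float(out) if out.ndim == 0 else out


def evaluate_normative(eq: NormativeEquation, age: float) -> float:
    """Evaluate an equation at an age, warning outside its validity range."""
    lo, hi = eq.age_range
    if not lo <= age <= hi:
        warnings.warn(
            f"age {age} outside validity range [{lo}, {hi}] of {eq.name}",
            stacklevel=2,
        )
    return float(eq.evaluate(age))


@dataclass
class NormativeFit:
    """A fitted equation plus inference: fit correlation r with its one-tailed
    t-test, residual SD, and per-coefficient 95% confidence intervals."""

    equation: NormativeEquation
    regression: "qstats.RegressionResult"
    resid_sd: float
    conf_int: np.ndarray  # (n_coeff, 2)


def fit_normative(ages: Sequence[float], values: Sequence[float],
                  degree: int = 2, name: str = "feature",
                  units: str = "") -> NormativeFit:
    """Least-squares polynomial age regression (default quadratic).

    The fit correlation r is the Pearson correlation between observed and
    fitted values (= sqrt(R^2)); its significance uses the one-tailed t-test
    t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of freedom.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be equal-length 1-d arrays")
    n = ages.size
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} samples, got {n}")
    X = np.vander(ages, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design (too few distinct ages)")
    import statsmodels.api as sm

    model = sm.OLS(values, X).fit()
    coeffs = tuple(model.params)
    fitted = model.fittedvalues
    if degree == 0 or np.allclose(fitted, fitted[0]) or np.allclose(values, values[0]):
        r = 0.0
    else:
        r = float(np.corrcoef(values, fitted)[0, 1])
    eq = NormativeEquation(
        name=name, kind="polynomial", coefficients=coeffs, r=r, n=n,
        age_range=(float(ages.min()), float(ages.max())), units=units,
    )
    reg = qstats.correlation_t_test(r, n) if n >= 3 else None
    resid_sd = float(np.std(values - fitted, ddof=degree + 1)) if n > degree + 1 else 0.0
    return NormativeFit(eq, reg, resid_sd, np.asarray(model.conf_int(0.05)))


def fit_offset_exponential(ages: Sequence[float], values: Sequence[float],
                           name: str = "feature", units: str = "") -> NormativeFit:
    """Fit value = a + b*exp(-k*age) by nonlinear least squares."""
    from scipy.optimize import curve_fit

    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = ages.size
    if n < 5:
        raise ValueError("offset-exponential fit needs at least 5 samples")

    def f(y, a, b, k):
        return a + b * np.exp(-k * y)

    p0 = (float(values.min()), float(values.max() - values.min() + 1e-6), 0.1)
    popt, pcov = curve_fit(f, ages, values, p0=p0, maxfev=20000)
    fitted = f(ages, *popt)
    r = float(np.corrcoef(values, fitted)[0, 1]) if np.std(fitted) > 0 else 0.0
    eq = NormativeEquation(
        name=name, kind="offset_exponential", coefficients=tuple(popt), r=r,
        n=n, age_range=(float(ages.min()), float(ages.max())), units=units,
    )
    se = np.sqrt(np.diag(pcov))
    ci = np.column_stack([popt - 1.96 * se, popt + 1.96 * se])
    return NormativeFit(eq, qstats.correlation_t_test(r, n),
                        float(np.std(values - fitted, ddof=3)), ci)


# ---------------------------------------------------------------------------
# shipped bundle and printed reference tables


def _load_data(filename: str) -> dict:
    with resources.files("qeegnorm.data").joinpath(filename).open() as fh:
        return json.load(fh)


def load_normative_bundle() -> dict[str, NormativeEquation]:
    """The published normative equations as a name -> equation mapping."""
    raw = _load_data("normative_bundle.json")
    out = {}
    for name, spec in raw["equations"].items():
        out[name] = NormativeEquation(
            name=name, kind=spec["kind"],
            coefficients=tuple(spec["coefficients"]),
            r=spec.get("r"), n=raw["n"],
            age_range=tuple(raw["age_range"]), units=spec.get("units", ""),
        )
    return out


def load_reference_tables() -> dict:
    """Raw published reference tables (whole-cohort and per-age-group logPS
    means/SEM, band-coherence structure) plus the age-group sizes."""
    return _load_data("printed_tables.json")


def group_logps_means() -> pd.DataFrame:
    """Tidy per-age-group logPS means: columns lobe, group, band, side, mean, sem."""
    raw = load_reference_tables()["group_logps"]
    rows = []
    for lobe, groups in raw.items():
        for group, bands in groups.items():
            for band, sides in bands.items():
                for side in ("L", "R"):
                    rows.append({
                        "lobe": lobe, "group": group, "band": band,
                        "side": side, "mean": sides[side][0], "sem": sides[side][1],
                    })
    return pd.DataFrame(rows)


def cohort_means_from_group_means() -> pd.DataFrame:
    """Whole-cohort logPS means reconstructed as size-weighted averages of the
    per-age-group means (weights = group sizes 7/25/5).

    Returns columns lobe, band, side, reconstructed, printed.
    """
    tables = load_reference_tables()
    sizes = tables["age_group_n"]
    total = sum(sizes.values())
    t2 = group_logps_means()
    t1 = tables["cohort_logps"]
    rows = []
    for (lobe, band, side), sub in t2.groupby(["lobe", "band", "side"]):
        weighted = sum(
            sizes[row["group"]] * row["mean"] for _, row in sub.iterrows()
        ) / total
        rows.append({
            "lobe": lobe, "band": band, "side": side,
            "reconstructed": round(weighted, 2),
            "printed": t1[lobe][band][side][0],
        })
    return pd.DataFrame(rows)


def group_coherence_means() -> pd.DataFrame:
    """Tidy per-age-group band-coherence means: region, group, side, band, mean."""
    raw = load_reference_tables()["group_coherence"]
    rows = []
    for region, groups in raw.items():
        for group, sides in groups.items():
            for side, bands in sides.items():
                for band, mean in bands.items():
                    rows.append({
                        "region": region, "group": group, "side": side,
                        "band": band, "mean": mean,
                    })
    return pd.DataFrame(rows)
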