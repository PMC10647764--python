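"""Turn gel/blot/melt measurements into model observables.

Gel lanes give the assembly efficiency ``N/S`` as nucleosome-band over
total-lane Cy3 signal; Western-blot series give per-histone nucleosome
levels (max-standardized); thermal-shift curves give normalized fluorescence
``NF`` over 50-95 °C, per-stage dissociation metrics, and a comparative
disassembly decay rate at fixed temperature. Inputs are background-corrected
band intensities (densitometry itself is upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .reference import MELT_INTERVAL_I, MELT_INTERVAL_II, MELT_NORM_RANGE

__all__ = [
    "LaneQuant",
    "BlotQuant",
    "MeltCurve",
    "StageMetrics",
    "DecayFit",
    "UnusableLaneError",
    "DegenerateCurveError",
    "efficiency_from_bands",
    "standardize_blot",
    "blot_ratio",
    "normalize_melt",
    "melt_stage_metrics",
    "disassembly_rate_fit",
]


class UnusableLaneError(ValueError):
    """A lane carries no quantifiable signal."""


class DegenerateCurveError(ValueError):
    """A melt curve has no dynamic range within the normalization window."""


@dataclass(frozen=True)
class LaneQuant:
    """One gel lane: nucleosome-band and free-DNA-band intensities."""

    lane: str
    condition: str
    replicate: int
    nuc_intensity: float
    free_intensity: float

    def __post_init__(self) -> None:
        if self.nuc_intensity < 0 or self.free_intensity < 0:
            raise UnusableLaneError(f"lane {self.lane}: negative band intensity")


@dataclass(frozen=True)
class BlotQuant:
    """One Western-blot lane for one target histone."""

    lane: str
    target: str           # "H2A" | "H2A.Z" | "H4" | user-defined
    intensity: float
    standardized: float | None = None


@dataclass
class MeltCurve:
    """Temperature-fluorescence series, optionally with normalized NF."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    normalized: np.ndarray | None = None
    sample: str = ""


@dataclass(frozen=True)
class StageMetrics:
    """Per-interval dissociation metrics of a normalized melt curve."""

    interval: tuple[float, float]
    delta_nf: float             # NF rise over the interval
    mean_slope: float           # mean first-difference slope, per °C
    midpoint: float             # argmax of smoothed dNF/dT within interval, °C


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential disassembly fit N/S(t) = A * exp(-rate * t)."""

    rate: float                 # per hour, >= 0
    half_life: float            # ln 2 / rate (inf when rate == 0)
    amplitude: float
    increasing_flag: bool = False


def efficiency_from_bands(lane: LaneQuant) -> float:
    """Assembly efficiency N/S = nuc / (nuc + free) for one lane."""
    total = lane.nuc_intensity + lane.free_intensity
    if total <= 0:
        raise UnusableLaneError(f"lane {lane.lane}: zero total band intensity")
    return lane.nuc_intensity / total


def standardize_blot(raw: np.ndarray | list[float]) -> np.ndarray:
    """Rescale a blot intensity series so its maximum maps to 1.

    The series should span one assay's input range for one antibody; the
    brightest band is the unit. Scale-invariant: multiplying all raw
    intensities by c > 0 leaves the output unchanged.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0 or np.all(arr <= 0):
        raise UnusableLaneError("blot series has no positive intensity")
    if np.any(arr < 0):
        raise UnusableLaneError("blot series has negative intensities")
    return arr / arr.max()


def blot_ratio(NA_level: np.ndarray | list[float],
               NZ_level: np.ndarray | list[float]) -> np.ndarray:
    """Elementwise H2A / H2A.Z nucleosome-level ratio.

    Zero-denominator entries are returned as NaN (flagged missing, to be
    excluded from downstream fitting) rather than raising.
    """
    na = np.asarray(NA_level, dtype=float)
    nz = np.asarray(NZ_level, dtype=float)
    if na.shape != nz.shape:
        raise ValueError(f"shape mismatch: {na.shape} vs {nz.shape}")
    out = np.full(na.shape, np.nan)
    ok = nz > 0
    out[ok] = na[ok] / nz[ok]
    return out


def normalize_melt(
    temperatures: np.ndarray | list[float],
    fluorescence: np.ndarray | list[float],
    norm_range: tuple[float, float] = MELT_NORM_RANGE,
    sample: str = "",
) -> MeltCurve:
    """Normalize a melt curve: NF = (F - Fmin) / (Fmax - Fmin).

    Fmin and Fmax are taken within ``norm_range`` (default 50-95 °C);
    readings below the window (instrument warm-up) do not set the scale.
    The returned curve is restricted to the window. Invariant to affine
    transforms a*F + b (a > 0) of the raw signal.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.shape != f.shape:
        raise ValueError("temperature and fluorescence grids differ in length")
    lo, hi = norm_range
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise DegenerateCurveError(f"fewer than 2 readings within {norm_range} °C")
    fw = f[mask]
    fmin, fmax = fw.min(), fw.max()
    if fmax - fmin <= 0:
        raise DegenerateCurveError("constant fluorescence within the normalization window")
    nf = (fw - fmin) / (fmax - fmin)
    return MeltCurve(temperatures=t[mask], fluorescence=fw, normalized=nf, sample=sample)


def _smoothed_derivative(t: np.ndarray, nf: np.ndarray, window_c: float = 5.0) -> np.ndarray:
    """dNF/dT smoothed by a moving least-squares quadratic of ~window_c °C."""
    d = np.gradient(nf, t)
    if t.size < 5:
        return d
    step = np.median(np.diff(t))
    win = max(int(round(window_c / step)) | 1, 5)  # odd, >= 5 points
    win = min(win, t.size if t.size % 2 == 1 else t.size - 1)
    if win < 5:
        return d
    return savgol_filter(d, window_length=win, polyorder=2)


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic sub-grid refinement of the argmax at index i."""
    if i == 0 or i == len(t) - 1:
        return float(t[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(t[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(t[i] + shift * (t[i + 1] - t[i]))


def melt_stage_metrics(
    curve: MeltCurve,
    interval_I: tuple[float, float] = MELT_INTERVAL_I,
    interval_II: tuple[float, float] = MELT_INTERVAL_II,
) -> dict[str, StageMetrics]:
    """Per-stage dissociation metrics of a normalized melt curve.

    Stage I (default 55-75 °C) covers H2A/H2B- or H2A.Z/H2B-dimer release;
    stage II (76-87 °C) covers (H3-H4)2 tetramer release. For each interval
    the NF rise, the mean first-difference slope, and the transition
    midpoint (argmax of the smoothed derivative, parabolically refined)
    are returned.
    """
    if curve.normalized is None:
        raise ValueError("curve is not normalized; call normalize_melt first")
    t, nf = curve.temperatures, curve.normalized
    deriv = _smoothed_derivative(t, nf)
    out: dict[str, StageMetrics] = {}
    for name, (lo, hi) in (("I", interval_I), ("II", interval_II)):
        if lo < t.min() or hi > t.max():
            raise ValueError(f"interval {name} = ({lo}, {hi}) outside grid "
                             f"[{t.min()}, {t.max()}] °C")
        mask = (t >= lo) & (t <= hi)
        idx = np.flatnonzero(mask)
        tt, yy = t[idx], nf[idx]
        delta = float(yy[-1] - yy[0])
        mean_slope = float(np.mean(np.diff(yy) / np.diff(tt))) if idx.size > 1 else 0.0
        j = idx[np.argmax(deriv[idx])]
        out[name] = StageMetrics(
            interval=(lo, hi),
            delta_nf=delta,
            mean_slope=mean_slope,
            midpoint=_refine_peak(t, deriv, j),
        )
    return out


def disassembly_rate_fit(
    times: np.ndarray | list[float],
    efficiency: np.ndarray | list[float],
) -> DecayFit:
    """Fit N/S(t) = A * exp(-rate * t) to a fixed-temperature time course.

    Least squares on the log scale (exact for noiseless exponentials).
    A non-decaying (increasing) series yields ``rate = 0`` with
    ``increasing_flag`` set rather than a negative rate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(efficiency, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 time points, got {t.size}")
    if np.any(y <= 0) or np.any(y > 1):
        raise ValueError("efficiencies must lie in (0, 1]")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    # snap slopes indistinguishable from zero (rounding on constant series)
    tiny = 1e-12 / max(t.max() - t.min(), 1.0)
    if slope > tiny:
        return DecayFit(rate=0.0, half_life=np.inf,
                        amplitude=float(np.exp(np.mean(np.log(y)))), increasing_flag=True)
    rate = max(-float(slope), 0.0) if abs(slope) > tiny else 0.0
    half_life = np.log(2) / rate if rate > 0 else np.inf
    return DecayFit(rate=rate, half_life=half_life, amplitude=float(np.exp(intercept)))


# ---------------------------------------------------------------------------
# Tidy-table entry points (CSV schemas shared with synthetic_data / cli)

def lanes_to_efficiencies(lanes: pd.DataFrame) -> pd.DataFrame:
    """Compute N/S for a lanes table.

    Expects columns (lane, condition, replicate, nuc_intensity,
    free_intensity); returns the table with an ``efficiency`` column and a
    boolean ``usable`` flag (False where the lane total is zero).
    """
    required = {"lane", "condition", "replicate", "nuc_intensity", "free_intensity"}
    missing = required - set(lanes.columns)
    if missing:
        raise ValueError(f"lanes table missing columns: {sorted(missing)}")
    out = lanes.copy()
    total = out["nuc_intensity"] + out["free_intensity"]
    out["usable"] = total > 0
    out["efficiency"] = np.where(out["usable"], out["nuc_intensity"] / total.where(total > 0), np.nan)
    return out
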