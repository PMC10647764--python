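"""Synthetic experiments: band-intensity tables from the forward models.

No raw densitometry from the original reconstitution experiments is
deposited anywhere, so every input the pipeline consumes is generated here
from the forward models under the published experimental designs:

* octamer-concentration gradients 5-60 ug/mL on the 601 template at
  dialysis times of 10/12/14/16 h, five replicates per condition;
* constant-total-mass H2A vs H2A.Z competition series (2.4/3/3.6 ug total
  octamer on 3 ug DNA in 60 uL, six gradients);
* two-transition thermal-shift melt curves sampled at 1 °C from 25-95 °C.

Band intensities carry multiplicative log-normal noise (mean-1 corrected,
independent across bands) of configurable coefficient of variation;
intensities are positive and their errors scale with signal, which is the
regime gel/blot densitometry operates in. All generators are deterministic
under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference
from .assembly_simulator import RateSchedule, simulate_competitive
from .competition import CompetitionDesign, design_ratios
from .kinetics_core import InvalidParameterError, KineticParams, efficiency_explicit, theta

__all__ = [
    "MassMolarRegistry",
    "NoiseModel",
    "DEFAULT_REGISTRY",
    "mass_to_molar",
    "generate_gradient_experiment",
    "generate_competition_experiment",
    "generate_melt_curve",
]

#: Lane loading intensity, arbitrary fluorescence units. Cancels in every
#: downstream ratio (tested); it only sets the numeric scale of the tables.
DEFAULT_LANE_INTENSITY = 1000.0

#: Default replicate count per condition, matching the five independent
#: repeats of the gradient assays.
DEFAULT_REPLICATES = 5

#: Default band-noise coefficient of variation. Replicate scatter was not
#: numerically published; 10% is a realistic stand-in for gel densitometry.
DEFAULT_CV = 0.10

DEFAULT_Q_GRADIENT_UG_ML = tuple(float(q) for q in range(5, 61, 5))
DEFAULT_DIALYSIS_TIMES_H = (10.0, 12.0, 14.0, 16.0)


class MassMolarRegistry(dict):
    """Species -> molecular weight (g/mol) registry with molarity anchors.

    The default entries are back-derived from the published molarity
    anchors of the reaction components (60 ug/mL octamer = 5.52e-7 mol/L;
    3 ug / 60 uL of 147-bp 601 DNA = 5.09e-7 mol/L; of 156-bp CS DNA =
    4.62e-7 mol/L). Extend or override entries for other species.
    """

    def molar(self, mass_conc_ug_per_ml: float, species: str) -> float:
        """Convert ug/mL of ``species`` to mol/L."""
        if mass_conc_ug_per_ml < 0:
            raise InvalidParameterError(f"mass concentration must be >= 0, got {mass_conc_ug_per_ml}")
        if species not in self:
            raise KeyError(f"unknown species {species!r}; registry has {sorted(self)}")
        # ug/mL == mg/L; /1000 -> g/L
        return (mass_conc_ug_per_ml / 1000.0) / self[species]


DEFAULT_REGISTRY = MassMolarRegistry(reference.MOLECULAR_WEIGHTS_G_PER_MOL)


def mass_to_molar(
    mass_conc_ug_per_ml: float,
    species: str = "octamer",
    registry: MassMolarRegistry = DEFAULT_REGISTRY,
) -> float:
    """Module-level convenience wrapper around :meth:`MassMolarRegistry.molar`."""
    return registry.molar(mass_conc_ug_per_ml, species)


@dataclass(frozen=True)
class NoiseModel:
    """Mean-1 multiplicative log-normal band noise.

    Factors are ``exp(sigma*Z - sigma^2/2)`` with ``sigma^2 = ln(1 + cv^2)``
    so their expectation is exactly 1 at any coefficient of variation.
    """

    cv: float = DEFAULT_CV

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise InvalidParameterError(f"cv must be >= 0, got {self.cv}")

    def factors(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.cv == 0.0:
            return np.ones(size)
        sigma2 = np.log1p(self.cv**2)
        return np.exp(rng.normal(0.0, np.sqrt(sigma2), size=size) - 0.5 * sigma2)


def generate_gradient_experiment(
    params: KineticParams,
    q_gradient_ug_ml: tuple[float, ...] = DEFAULT_Q_GRADIENT_UG_ML,
    times_h: tuple[float, ...] = DEFAULT_DIALYSIS_TIMES_H,
    replicates: int = DEFAULT_REPLICATES,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    mode: str = "linear",
    dna_species: str = "601_147bp",
    dna_mass_conc_ug_per_ml: float = 50.0,
    registry: MassMolarRegistry = DEFAULT_REGISTRY,
    lane_intensity: float = DEFAULT_LANE_INTENSITY,
) -> pd.DataFrame:
    """Simulate a concentration-gradient gel assay as a lanes table.

    For each (Q, T, replicate) the true efficiency comes from the linear
    law (``mode="linear"``, Q in ug/mL with ``params`` carrying per-ug/mL
    units) or from the irreversible closed form on the molar scale
    (``mode="explicit"``); band intensities are
    ``nuc = I0 * (N/S) * eta1`` and ``free = I0 * (1 - N/S) * eta2`` with
    independent noise factors.

    Returns a tidy frame with columns (lane, condition, replicate,
    nuc_intensity, free_intensity, Q_ug_ml, time_h).
    """
    if mode not in ("linear", "explicit"):
        raise InvalidParameterError(f"mode must be 'linear' or 'explicit', got {mode!r}")
    if replicates < 1:
        raise InvalidParameterError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    s_molar = registry.molar(dna_mass_conc_ug_per_ml, dna_species)
    rows = []
    for T in times_h:
        th = theta(params, T)
        for q in q_gradient_ug_ml:
            if mode == "linear":
                eff = q * th
            else:
                eff = efficiency_explicit(registry.molar(q, "octamer"), s_molar, th)
            if not 0.0 <= eff < 1.0:
                raise InvalidParameterError(
                    f"true efficiency {eff:.4f} outside [0, 1) at Q={q}, T={T}; "
                    "parameters leave the physical regime"
                )
            for rep in range(1, replicates + 1):
                e1, e2 = noise.factors(rng, 2)
                rows.append({
                    "lane": f"T{T:g}h_Q{q:g}_r{rep}",
                    "condition": f"T{T:g}h_Q{q:g}",
                    "replicate": rep,
                    "nuc_intensity": lane_intensity * eff * e1,
                    "free_intensity": lane_intensity * (1.0 - eff) * e2,
                    "Q_ug_ml": q,
                    "time_h": T,
                })
    return pd.DataFrame(rows)


def _competition_truth(
    design: CompetitionDesign,
    params_A: KineticParams,
    params_Z: KineticParams,
    mode: str,
) -> list[dict]:
    """Noise-free per-gradient (N_A/S, N_Z/S) under the chosen forward model."""
    T = design.time
    s = design.dna_molar
    th_a = theta(params_A, T)
    th_z = theta(params_Z, T)
    out = []
    for i in range(1, len(design.gradients) + 1):
        qa, qz = design.species_concentrations(i)
        if mode == "linear":
            na_s, nz_s = qa * th_a, qz * th_z
        else:
            traj = simulate_competitive(
                qa, qz, s,
                RateSchedule.constant_with_theta(th_a, T),
                RateSchedule.constant_with_theta(th_z, T),
                T, n_out=2,
            )
            na_s = traj.endpoint("A") / s
            nz_s = traj.endpoint("Z") / s
        out.append({"gradient": i, "QA": qa, "QZ": qz, "NA_S": na_s, "NZ_S": nz_s})
    return out


def generate_competition_experiment(
    design: CompetitionDesign,
    params_A: KineticParams,
    params_Z: KineticParams,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    mode: str = "linear",
    lane_intensity: float = DEFAULT_LANE_INTENSITY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one competition series: a gel lanes table and a blot table.

    The gel lane of each gradient reports total nucleosome versus free DNA.
    The blot table reports the per-species nucleosome-band intensity of
    each gradient, on one shared intensity scale per assay so that H2A and
    H2A.Z levels remain mutually comparable after max-standardization
    (see methods on blot standardization).

    ``mode="linear"`` uses the per-species linear laws; ``mode="ode"`` runs
    the shared-DNA competitive simulator.
    """
    if mode not in ("linear", "ode"):
        raise InvalidParameterError(f"mode must be 'linear' or 'ode', got {mode!r}")
    rng = np.random.default_rng(seed)
    truth = _competition_truth(design, params_A, params_Z, mode)
    lane_rows, blot_rows = [], []
    for row in truth:
        i = row["gradient"]
        total_eff = row["NA_S"] + row["NZ_S"]
        if total_eff >= 1.0:
            raise InvalidParameterError(
                f"gradient {i}: total conversion {total_eff:.3f} >= 1; parameters unphysical"
            )
        e1, e2 = noise.factors(rng, 2)
        lane_rows.append({
            "lane": f"G{i}",
            "condition": f"gradient{i}",
            "replicate": 1,
            "nuc_intensity": lane_intensity * total_eff * e1,
            "free_intensity": lane_intensity * (1.0 - total_eff) * e2,
            "gradient": i,
        })
        for target, eff in (("H2A", row["NA_S"]), ("H2A.Z", row["NZ_S"])):
            (eta,) = noise.factors(rng, 1)
            blot_rows.append({
                "lane": f"G{i}",
                "gradient": i,
                "target": target,
                "intensity": lane_intensity * eff * eta,
            })
    return pd.DataFrame(lane_rows), pd.DataFrame(blot_rows)


def competition_ratio_table(
    design: CompetitionDesign,
    blots: pd.DataFrame,
) -> pd.DataFrame:
    """Pair blot intensities into (QA/QZ, NA/NZ) rows over usable gradients.

    The two target series share one intensity scale per assay, so the raw
    intensity ratio estimates N_A/N_Z directly; max-standardization (a
    shared per-assay rescale) would not change it. Endpoint gradients are
    excluded here exactly as :func:`nucleokinetics.competition.design_ratios`
    flags them.
    """
    ratios = {g.index: g.QA_over_QZ for g in design_ratios(design) if g.usable}
    pivot = blots.pivot_table(index="gradient", columns="target", values="intensity")
    rows = []
    for idx, x in ratios.items():
        if idx not in pivot.index:
            continue
        na = pivot.loc[idx].get("H2A", np.nan)
        nz = pivot.loc[idx].get("H2A.Z", np.nan)
        y = na / nz if nz and nz > 0 else np.nan
        rows.append({"gradient": idx, "QA_over_QZ": x, "NA_over_NZ": y})
    return pd.DataFrame(rows)


def generate_melt_curve(
    midpoints_c: tuple[float, float] = (71.0, 82.0),
    widths_c: tuple[float, float] = (2.0, 2.0),
    amplitudes: tuple[float, float] = (500.0, 500.0),
    baseline: float = 100.0,
    noise: NoiseModel = NoiseModel(cv=0.01),
    seed: int = 0,
    sample: str = "nucleosome",
    temp_range_c: tuple[float, float] = (25.0, 95.0),
) -> pd.DataFrame:
    """Simulate a two-transition thermal-shift melt curve.

    ``F(T) = baseline + sum_i amplitude_i * logistic((T - mid_i)/width_i)``
    sampled at 1 °C steps, multiplied by mean-1 log-normal noise. The first
    transition emulates H2A(Z)/H2B-dimer release, the second (H3-H4)2
    tetramer release. Returns columns (temperature_C, fluorescence, sample).
    """
    lo, hi = temp_range_c
    for mid, width in zip(midpoints_c, widths_c):
        if not lo <= mid <= hi:
            raise InvalidParameterError(f"midpoint {mid} °C outside sampled range {temp_range_c}")
        if width <= 0:
            raise InvalidParameterError(f"width must be > 0, got {width}")
    rng = np.random.default_rng(seed)
    t = np.arange(lo, hi + 0.5, 1.0)
    f = np.full_like(t, float(baseline))
    for mid, width, amp in zip(midpoints_c, widths_c, amplitudes):
        f = f + amp / (1.0 + np.exp(-(t - mid) / width))
    f = f * noise.factors(rng, t.size)
    return pd.DataFrame({"temperature_C": t, "fluorescence": f, "sample": sample})
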