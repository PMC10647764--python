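"""Competitive H2A-vs-H2A.Z assembly: per-species linear laws and the ratio law.

In the low-conversion regime each octamer species obeys its own linear law,
``N_A/S ≈ Q_A * kbar_A * (alpha + eps*T)`` and likewise for H2A.Z, with the
dialysis window ``(alpha + eps*T)`` shared. Dividing the two eliminates the
shared window and the DNA pool:

    N_A / N_Z ≈ (Q_A / Q_Z) * (kbar_A / kbar_Z)

so the zero-intercept slope of measured N_A/N_Z against the input Q_A/Q_Z
is a direct estimate of the rate-constant ratio — a single dimensionless
number quantifying which histone outcompetes the other. ``kbar_A/kbar_Z > 1``
means canonical H2A assembles faster than H2A.Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import yaml

from .kinetics_core import InvalidParameterError
from .reference import MOLECULAR_WEIGHTS_G_PER_MOL

__all__ = [
    "SpeciesParams",
    "CompetitionDesign",
    "GradientRatio",
    "RatioPrediction",
    "UndefinedRatioError",
    "predict_ratio",
    "design_ratios",
    "interpret_ratio",
    "load_design",
    "packaged_design",
]

#: Relative half-width of the "equal" verdict band around kbar_A/kbar_Z = 1.
EQUAL_BAND = 0.05


class UndefinedRatioError(ValueError):
    """A ratio with a zero denominator was requested (gradient endpoint)."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species rate constant; alpha/eps are shared across species."""

    label: str
    kbar: float
    alpha: float = 0.0
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.kbar < 0:
            raise InvalidParameterError(f"kbar must be >= 0, got {self.kbar}")


@dataclass(frozen=True)
class GradientRatio:
    """Input ratio of one design gradient, with endpoint flagging."""

    index: int
    mass_A: float
    mass_Z: float
    QA_over_QZ: float | None
    usable: bool
    note: str = ""


@dataclass(frozen=True)
class RatioPrediction:
    QA_over_QZ: float
    NA_over_NZ: float


@dataclass(frozen=True)
class CompetitionDesign:
    """A constant-total-mass competition series (the study's Table-1 layout).

    Attributes
    ----------
    total_protein_mass:
        Total octamer mass per reaction, ug; every gradient's masses sum
        to this.
    dna_mass:
        Template DNA mass, ug.
    volume:
        Reaction volume, uL.
    gradients:
        Ordered (mass_A, mass_Z) pairs in ug.
    time:
        First-step dialysis duration, h.
    mw_A, mw_Z:
        Octamer molecular weights, g/mol. Equal by default: the canonical
        vs H2A.Z octamer mass difference is < 1% of ~108.7 kDa, so Q_A/Q_Z
        equals the mass ratio.
    """

    total_protein_mass: float
    dna_mass: float
    volume: float
    gradients: tuple[tuple[float, float], ...]
    time: float = 16.0
    mw_A: float = MOLECULAR_WEIGHTS_G_PER_MOL["octamer"]
    mw_Z: float = MOLECULAR_WEIGHTS_G_PER_MOL["octamer_H2A.Z"]

    def __post_init__(self) -> None:
        if self.total_protein_mass <= 0 or self.dna_mass <= 0 or self.volume <= 0:
            raise InvalidParameterError("total_protein_mass, dna_mass and volume must be > 0")
        if self.mw_A <= 0 or self.mw_Z <= 0:
            raise InvalidParameterError("molecular weights must be > 0")
        for i, (ma, mz) in enumerate(self.gradients, start=1):
            if ma < 0 or mz < 0:
                raise InvalidParameterError(f"gradient {i}: masses must be >= 0")
            if abs(ma + mz - self.total_protein_mass) > 1e-9 * self.total_protein_mass:
                raise InvalidParameterError(
                    f"gradient {i}: masses ({ma}, {mz}) do not sum to "
                    f"total_protein_mass = {self.total_protein_mass}"
                )

    def molar(self, mass_ug: float, mw: float) -> float:
        """Convert a per-reaction mass (ug) to mol/L in this design's volume."""
        # ug / uL = g / L
        return (mass_ug / self.volume) / mw

    def species_concentrations(self, index: int) -> tuple[float, float]:
        """(Q_A, Q_Z) in mol/L for 1-based gradient ``index``."""
        ma, mz = self.gradients[index - 1]
        return self.molar(ma, self.mw_A), self.molar(mz, self.mw_Z)

    @property
    def dna_molar(self) -> float:
        return self.molar(self.dna_mass, MOLECULAR_WEIGHTS_G_PER_MOL["601_147bp"])


def predict_ratio(QA: float, QZ: float, kbar_A: float, kbar_Z: float) -> float:
    """Merged ratio law: N_A/N_Z = (Q_A/Q_Z) * (kbar_A/kbar_Z).

    Raises
    ------
    UndefinedRatioError
        If ``QZ == 0`` or ``kbar_Z == 0`` (single-species endpoints).
    """
    if QZ <= 0:
        raise UndefinedRatioError(f"QZ must be > 0 for a defined ratio, got {QZ}")
    if kbar_Z <= 0:
        raise UndefinedRatioError(f"kbar_Z must be > 0 for a defined ratio, got {kbar_Z}")
    if QA < 0 or kbar_A < 0:
        raise InvalidParameterError("QA and kbar_A must be >= 0")
    return (QA / QZ) * (kbar_A / kbar_Z)


def design_ratios(design: CompetitionDesign) -> list[GradientRatio]:
    """Input ratios Q_A/Q_Z per gradient; endpoints flagged, never dropped.

    Gradients with zero H2A or zero H2A.Z mass are single-species controls:
    their input ratio is undefined (or zero), so they are marked
    ``usable=False`` and excluded from ratio fitting downstream.
    """
    out: list[GradientRatio] = []
    for i in range(1, len(design.gradients) + 1):
        ma, mz = design.gradients[i - 1]
        qa, qz = design.species_concentrations(i)
        if mz == 0.0:
            out.append(GradientRatio(i, ma, mz, None, False, "zero H2A.Z mass (endpoint)"))
        elif ma == 0.0:
            out.append(GradientRatio(i, ma, mz, 0.0, False, "zero H2A mass (endpoint)"))
        else:
            out.append(GradientRatio(i, ma, mz, qa / qz, True))
    return out


def interpret_ratio(kbar_ratio: float, equal_band: float = EQUAL_BAND) -> str:
    """Qualitative verdict on kbar_A/kbar_Z.

    Returns ``"A-stronger"`` when the ratio exceeds 1 beyond the band,
    ``"Z-stronger"`` below it, and ``"equal"`` within ``1 ± equal_band``.
    """
    if not kbar_ratio > 0:
        raise InvalidParameterError(f"kbar ratio must be > 0, got {kbar_ratio}")
    if kbar_ratio > 1.0 + equal_band:
        return "A-stronger"
    if kbar_ratio < 1.0 - equal_band:
        return "Z-stronger"
    return "equal"


def load_design(path) -> CompetitionDesign:
    """Read a competition design from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _design_from_dict(raw)


def _design_from_dict(raw: dict) -> CompetitionDesign:
    try:
        gradients = tuple((float(a), float(z)) for a, z in raw["gradients"])
        return CompetitionDesign(
            total_protein_mass=float(raw["total_protein_mass"]),
            dna_mass=float(raw["dna_mass"]),
            volume=float(raw["volume"]),
            gradients=gradients,
            time=float(raw.get("time", 16.0)),
            mw_A=float(raw.get("mw_A", MOLECULAR_WEIGHTS_G_PER_MOL["octamer"])),
            mw_Z=float(raw.get("mw_Z", MOLECULAR_WEIGHTS_G_PER_MOL["octamer_H2A.Z"])),
        )
    except KeyError as exc:
        raise InvalidParameterError(f"design file missing key: {exc.args[0]}") from exc


def packaged_design(total_protein_mass: float = 3.0) -> CompetitionDesign:
    """One of the three packaged competition designs (2.4, 3 or 3.6 ug total)."""
    text = resources.files("nucleokinetics.data").joinpath("competition_designs.yaml").read_text()
    designs = yaml.safe_load(text)
    for raw in designs["designs"]:
        if abs(float(raw["total_protein_mass"]) - total_protein_mass) < 1e-9:
            return _design_from_dict(raw)
    known = [d["total_protein_mass"] for d in designs["designs"]]
    raise InvalidParameterError(
        f"no packaged design with total mass {total_protein_mass} ug; available: {known}"
    )
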