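"""Reference constants for the modelled in-vitro reconstitution system.

These are the published measurements the synthetic experiments are anchored
to: the fitted composite slopes ``kbar*(alpha + eps*T)`` of N/S versus
octamer concentration at four first-step dialysis durations, the fitted
H2A-to-H2A.Z mean-rate-constant ratios of the three competitive reaction
systems, the mass/molar anchors of the reaction components, and the
competitive-design mass gradients.

All slopes are per (ug/mL) of octamer; ratios are dimensionless.
"""

from __future__ import annotations

#: Fitted composite slope kbar*(alpha + eps*T) of N/S vs Q (per ug/mL),
#: keyed by first-step dialysis time in hours.
COMPOSITE_SLOPES_PER_UG_ML: dict[int, float] = {
    10: 0.01361,
    12: 0.01384,
    14: 0.01442,
    16: 0.01461,
}

#: Fitted kbar_A / kbar_Z of the competitive reaction systems, keyed by
#: total histone mass (ug) loaded onto 3 ug of 601 DNA in 60 uL.
KBAR_RATIO_BY_TOTAL_MASS_UG: dict[float, float] = {
    2.4: 1.38,
    3.0: 1.71,
    3.6: 1.59,
}

#: Reaction-volume and template amounts common to all designs.
REACTION_VOLUME_UL = 60.0
DNA_MASS_UG = 3.0

#: Molecular weights (g/mol) back-derived from the printed molarity anchors:
#: 60 ug/mL octamer <-> 5.52e-7 mol/L; 3 ug / 60 uL of 147-bp 601 DNA
#: <-> 5.09e-7 mol/L; same mass of 156-bp CS DNA <-> 4.62e-7 mol/L.
MOLECULAR_WEIGHTS_G_PER_MOL: dict[str, float] = {
    "octamer": 0.060 / 5.52e-7,        # 1.0870e5, canonical octamer
    "octamer_H2A.Z": 0.060 / 5.52e-7,  # mass difference to canonical < 1%
    "601_147bp": 0.050 / 5.09e-7,      # 9.8232e4
    "CS_156bp": 0.050 / 4.62e-7,       # 1.0823e5
}

#: Competitive-design mass gradients: per total-protein mass (ug), the
#: ordered (mass_H2A, mass_H2A.Z) pairs in ug. Gradients 1 and 6 are the
#: single-species endpoints.
COMPETITION_GRADIENTS_UG: dict[float, list[tuple[float, float]]] = {
    2.4: [(0.0, 2.4), (0.48, 1.92), (0.96, 1.44),
          (1.44, 0.96), (1.92, 0.48), (2.4, 0.0)],
    3.0: [(0.0, 3.0), (0.6, 2.4), (1.2, 1.8),
          (1.8, 1.2), (2.4, 0.6), (3.0, 0.0)],
    3.6: [(0.0, 3.6), (0.72, 2.88), (1.44, 2.16),
          (2.16, 1.44), (2.88, 0.72), (3.6, 0.0)],
}

#: Thermal-dissociation stage windows (deg C): dimer release and
#: (H3-H4)2 tetramer release.
MELT_INTERVAL_I = (55.0, 75.0)
MELT_INTERVAL_II = (76.0, 87.0)

#: Temperature window used for melt-curve normalization (deg C).
MELT_NORM_RANGE = (50.0, 95.0)
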