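"""Generators: registry anchors, determinism, pipeline closure."""

import numpy as np
import pytest

from nucleokinetics import (
    DEFAULT_REGISTRY,
    KineticParams,
    MassMolarRegistry,
    NoiseModel,
    competition_ratio_table,
    fit_competition_ratio,
    fit_efficiency_slope,
    generate_competition_experiment,
    generate_gradient_experiment,
    generate_melt_curve,
    mass_to_molar,
    packaged_design,
)
from nucleokinetics.quantify import lanes_to_efficiencies


class TestRegistry:
    def test_octamer_anchor_endpoints(self):
        # printed gradient endpoints: 5 ug/mL -> 0.46e-7 M, 60 ug/mL -> 5.52e-7 M
        assert mass_to_molar(60.0, "octamer") == pytest.approx(5.52e-7, rel=1e-3)
        assert mass_to_molar(5.0, "octamer") == pytest.approx(0.46e-7, rel=1e-2)

    def test_dna_anchors(self):
        # 3 ug / 60 uL = 50 ug/mL of each template
        assert mass_to_molar(50.0, "601_147bp") == pytest.approx(5.09e-7, rel=1e-3)
        assert mass_to_molar(50.0, "CS_156bp") == pytest.approx(4.62e-7, rel=1e-3)

    def test_zero_mass(self):
        assert mass_to_molar(0.0, "octamer") == 0.0

    def test_unknown_species_lists_registry(self):
        with pytest.raises(KeyError, match="octamer"):
            mass_to_molar(10.0, "hexasome")

    def test_custom_registry(self):
        reg = MassMolarRegistry({"widget": 1.0e5})
        assert reg.molar(100.0, "widget") == pytest.approx(1e-6)


class TestNoiseModel:
    def test_zero_cv_is_exact_ones(self, rng):
        assert np.all(NoiseModel(cv=0.0).factors(rng, 10) == 1.0)

    def test_mean_one_and_cv(self, rng):
        f = NoiseModel(cv=0.2).factors(rng, 200_000)
        assert f.mean() == pytest.approx(1.0, abs=5e-3)
        assert f.std() == pytest.approx(0.2, rel=0.02)
        assert np.all(f > 0)


class TestGradientExperiment:
    def test_cardinality(self):
        lanes = generate_gradient_experiment(
            KineticParams(kbar=0.01, alpha=0.0, eps=1.0 / 16.0), replicates=5,
        )
        assert len(lanes) == 12 * 4 * 5

    def test_determinism_under_fixed_seed(self):
        kwargs = dict(params=KineticParams(kbar=0.01, alpha=0.0, eps=1.0 / 16.0),
                      noise=NoiseModel(cv=0.1), seed=77)
        a = generate_gradient_experiment(**kwargs)
        b = generate_gradient_experiment(**kwargs)
        assert a.equals(b)

    def test_noiseless_inverse_composition(self):
        # quantify recovers the model N/S exactly at CV = 0
        slope = 0.01361
        lanes = generate_gradient_experiment(
            KineticParams(kbar=slope, alpha=0.0, eps=0.1), times_h=(10.0,),
            replicates=1, noise=NoiseModel(cv=0.0),
        )
        quant = lanes_to_efficiencies(lanes)
        np.testing.assert_allclose(quant["efficiency"], slope * quant["Q_ug_ml"], rtol=1e-12)

    def test_lane_intensity_cancels_downstream(self):
        base = dict(params=KineticParams(kbar=0.01, alpha=0.0, eps=1.0 / 16.0),
                    times_h=(16.0,), noise=NoiseModel(cv=0.05), seed=5)
        s1 = generate_gradient_experiment(**base, lane_intensity=1000.0)
        s2 = generate_gradient_experiment(**base, lane_intensity=123.0)
        f1 = fit_efficiency_slope(*_qy(s1))
        f2 = fit_efficiency_slope(*_qy(s2))
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)

    def test_unphysical_parameters_rejected(self):
        with pytest.raises(Exception, match="efficiency"):
            generate_gradient_experiment(KineticParams(kbar=0.1, alpha=0.0, eps=1.0))

    def test_explicit_mode_bends_below_linear(self):
        # the saturating closed form lies below the linear law at high Q
        p = KineticParams(kbar=3e4 * 16, alpha=0.0, eps=1.0 / 16.0)
        lanes = generate_gradient_experiment(
            p, times_h=(16.0,), replicates=1, noise=NoiseModel(cv=0.0), mode="explicit",
        )
        quant = lanes_to_efficiencies(lanes)
        molar = np.array([mass_to_molar(q) for q in quant["Q_ug_ml"]])
        linear = molar * 3e4 * 16 / 16 * 16  # theta at T=16 h
        assert np.all(quant["efficiency"] < linear)


def _qy(lanes):
    q = lanes_to_efficiencies(lanes)
    return q["Q_ug_ml"].to_numpy(), q["efficiency"].to_numpy()


class TestCompetitionExperiment:
    def _params(self, ratio, eps=1 / 16.0):
        kz = 0.0146
        return (KineticParams(kbar=kz * ratio, alpha=0.0, eps=eps),
                KineticParams(kbar=kz, alpha=0.0, eps=eps))

    def test_noiseless_linear_roundtrip(self):
        design = packaged_design(3.0)
        pa, pz = self._params(1.71)
        _, blots = generate_competition_experiment(design, pa, pz, noise=NoiseModel(cv=0.0))
        table = competition_ratio_table(design, blots)
        fit = fit_competition_ratio(table["QA_over_QZ"], table["NA_over_NZ"])
        assert fit.ratio == pytest.approx(1.71, rel=1e-12)
        assert fit.n == 4

    def test_symmetric_gradients_give_reciprocal_ratios(self):
        # equal species parameters: mirrored mass splits -> reciprocal ratios
        design = packaged_design(3.0)
        pa, pz = self._params(1.0)
        _, blots = generate_competition_experiment(design, pa, pz, noise=NoiseModel(cv=0.0))
        table = competition_ratio_table(design, blots).set_index("gradient")
        assert table.loc[2, "NA_over_NZ"] * table.loc[5, "NA_over_NZ"] == pytest.approx(1.0, rel=1e-10)
        assert table.loc[3, "NA_over_NZ"] * table.loc[4, "NA_over_NZ"] == pytest.approx(1.0, rel=1e-10)

    def test_endpoint_gradient_zero_signal(self):
        # gradient 1 carries no H2A mass -> zero H2A blot band
        design = packaged_design(2.4)
        pa, pz = self._params(1.38)
        _, blots = generate_competition_experiment(design, pa, pz, noise=NoiseModel(cv=0.0))
        g1 = blots[(blots["gradient"] == 1) & (blots["target"] == "H2A")]
        assert float(g1["intensity"].iloc[0]) == 0.0

    def test_gel_lanes_report_total_conversion(self):
        design = packaged_design(3.0)
        pa, pz = self._params(1.71)
        lanes, _ = generate_competition_experiment(design, pa, pz, noise=NoiseModel(cv=0.0))
        quant = lanes_to_efficiencies(lanes).set_index("gradient")
        th = pa.kbar  # theta at T = design.time since alpha=0, eps=1/T
        for i in (2, 5):
            qa, qz = design.species_concentrations(i)
            expected = qa * pa.kbar + qz * pz.kbar
            assert quant.loc[i, "efficiency"] == pytest.approx(expected, rel=1e-10)

    def test_ode_mode_matches_linear_in_low_conversion(self):
        design = packaged_design(3.6)
        # small composite rate -> conversion far below 5% of S
        pa = KineticParams(kbar=3e4 * 1.59, alpha=0.0, eps=1.0 / 16.0)
        pz = KineticParams(kbar=3e4, alpha=0.0, eps=1.0 / 16.0)
        _, blots = generate_competition_experiment(design, pa, pz,
                                                   noise=NoiseModel(cv=0.0), mode="ode")
        table = competition_ratio_table(design, blots)
        fit = fit_competition_ratio(table["QA_over_QZ"], table["NA_over_NZ"])
        assert fit.ratio == pytest.approx(1.59, rel=0.02)

    def test_determinism(self):
        design = packaged_design(3.0)
        pa, pz = self._params(1.71)
        out1 = generate_competition_experiment(design, pa, pz, noise=NoiseModel(cv=0.1), seed=9)
        out2 = generate_competition_experiment(design, pa, pz, noise=NoiseModel(cv=0.1), seed=9)
        assert out1[0].equals(out2[0]) and out1[1].equals(out2[1])


class TestMeltGenerator:
    def test_determinism(self):
        a = generate_melt_curve(seed=4, noise=NoiseModel(cv=0.02))
        b = generate_melt_curve(seed=4, noise=NoiseModel(cv=0.02))
        assert a.equals(b)

    def test_grid_covers_25_to_95(self):
        t = generate_melt_curve(noise=NoiseModel(cv=0.0))["temperature_C"]
        assert t.min() == 25.0 and t.max() == 95.0
        assert np.all(np.diff(t) == 1.0)

    def test_zero_amplitude_curve_is_degenerate_downstream(self):
        from nucleokinetics import DegenerateCurveError, normalize_melt

        flat = generate_melt_curve(amplitudes=(0.0, 0.0), noise=NoiseModel(cv=0.0))
        with pytest.raises(DegenerateCurveError):
            normalize_melt(flat["temperature_C"], flat["fluorescence"])

    def test_midpoint_outside_range_rejected(self):
        with pytest.raises(Exception, match="midpoint"):
            generate_melt_curve(midpoints_c=(10.0, 82.0))
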