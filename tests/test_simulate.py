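"""Synthetic plate generator: designs, noise, and the interaction surface."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combsyn.combination import MixtureRatio, synergy_profile
from combsyn.errors import InvalidInputError
from combsyn.median_effect import (
    dose_for_effect,
    effect_for_dose,
    fit_median_effect,
    points_from_wells,
)
from combsyn.simulate import (
    BC7_LIKE,
    CISPLATIN_LIKE,
    DrugGroundTruth,
    NoiseModel,
    PlateDesign,
    loewe_additive_effect,
    serial_dilution,
    simulate_combination_plate,
    simulate_single_drug_plate,
)


class TestSerialDilution:
    @pytest.mark.parametrize(
        "top,factor,n,expected",
        [
            (200, 2, 3, [200, 100, 50]),
            (10, 10, 2, [10, 1]),
        ],
    )
    def test_series(self, top, factor, n, expected):
        assert serial_dilution(top, factor, n) == expected

    def test_seven_point_combination_series(self):
        doses = serial_dilution(67.255, 2, 7)
        assert len(doses) == 7
        assert doses[-1] == pytest.approx(67.255 / 2**6)  # 1.0509
        assert all(a > b for a, b in zip(doses, doses[1:]))

    def test_invalid_factor(self):
        with pytest.raises(InvalidInputError):
            serial_dilution(10, 1.0, 3)


class TestSingleDrugPlate:
    def test_expectation_mode_matches_model_exactly(self):
        design = PlateDesign(top_dose=16 * 1.675, replicates=1)
        noise = NoiseModel(control_death_fraction=0.0, count_noise="expectation")
        wells = simulate_single_drug_plate(CISPLATIN_LIKE, design, noise)
        for w in wells:
            if w.is_control:
                continue
            fa = w.dead_cells / w.total_cells
            assert fa == pytest.approx(
                effect_for_dose(CISPLATIN_LIKE, w.total_dose), rel=1e-12
            )

    def test_background_adds_to_death_probability(self):
        design = PlateDesign(top_dose=16 * 1.675, replicates=2)
        noise = NoiseModel(control_death_fraction=0.08, count_noise="expectation")
        wells = simulate_single_drug_plate(CISPLATIN_LIKE, design, noise)
        controls = [w for w in wells if w.is_control]
        assert len(controls) == 2
        assert controls[0].dead_cells / controls[0].total_cells == pytest.approx(0.08)
        # background-corrected refit recovers the truth exactly
        fit = fit_median_effect(points_from_wells(wells))
        assert fit.m == pytest.approx(CISPLATIN_LIKE.m, rel=1e-9)
        assert fit.Dm == pytest.approx(CISPLATIN_LIKE.Dm, rel=1e-9)

    def test_seed_contract(self):
        design = PlateDesign(top_dose=30.0)
        a = simulate_single_drug_plate(CISPLATIN_LIKE, design, NoiseModel(seed=1))
        b = simulate_single_drug_plate(CISPLATIN_LIKE, design, NoiseModel(seed=1))
        c = simulate_single_drug_plate(CISPLATIN_LIKE, design, NoiseModel(seed=2))
        assert a == b
        assert a != c

    def test_beta_binomial_inflates_replicate_variance(self):
        design = PlateDesign(top_dose=1.675, n_doses=2, replicates=200,
                             cells_per_well=500)
        plain = simulate_single_drug_plate(
            CISPLATIN_LIKE, design, NoiseModel(count_noise="binomial", seed=3)
        )
        over = simulate_single_drug_plate(
            CISPLATIN_LIKE, design,
            NoiseModel(count_noise="beta-binomial", rho=0.05, seed=3),
        )

        def top_dose_var(wells):
            top = max(w.total_dose for w in wells)
            return np.var([w.dead_cells for w in wells if w.total_dose == top])

        assert top_dose_var(over) > 2 * top_dose_var(plain)


class TestLoeweSurface:
    def test_hyperbolic_additive_closed_form(self):
        # m = 1 for both drugs: D/2 * (1/10 + 1/20) = fa/fu has fa = 0.5 at
        # D_a = D_b = 20/3
        a = DrugGroundTruth("a", m=1.0, Dm=10.0)
        b = DrugGroundTruth("b", m=1.0, Dm=20.0)
        fa = loewe_additive_effect(a, b, 20.0 / 3, 20.0 / 3, psi=1.0)
        assert fa == pytest.approx(0.5, abs=1e-10)

    @given(
        m=st.floats(0.3, 4.0), dm=st.floats(0.01, 1000.0),
        fa_star=st.floats(0.05, 0.95), split=st.floats(0.01, 0.99),
    )
    @settings(derandomize=True, max_examples=60)
    def test_sham_consistency(self, m, dm, fa_star, split):
        """A drug 'combined' with itself returns the single-agent effect."""
        drug = DrugGroundTruth("x", m=m, Dm=dm)
        dx = dose_for_effect(drug, fa_star)
        fa = loewe_additive_effect(drug, drug, split * dx, (1 - split) * dx, psi=1.0)
        assert fa == pytest.approx(fa_star, abs=1e-9)

    def test_psi_scales_total_dose_linearly(self):
        a, b = CISPLATIN_LIKE, BC7_LIKE
        fa_full = loewe_additive_effect(a, b, 1.0, 30.0, psi=1.0)
        fa_half = loewe_additive_effect(a, b, 0.5, 15.0, psi=0.5)
        assert fa_half == pytest.approx(fa_full, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            loewe_additive_effect(CISPLATIN_LIKE, BC7_LIKE, 0.0, 0.0)
        with pytest.raises(InvalidInputError):
            loewe_additive_effect(CISPLATIN_LIKE, BC7_LIKE, 1.0, 1.0, psi=0.0)


def pipeline_ci(truth_a, truth_b, psi, k_a=1.0, k_b=1.0,
                fa_levels=(0.10, 0.25, 0.50, 0.75)):
    """Run the full noiseless simulate -> fit -> profile pipeline; return CIs."""
    ratio = MixtureRatio.from_ic50s(k_a, k_b, truth_a.Dm, truth_b.Dm)
    noise = NoiseModel(control_death_fraction=0.0, count_noise="expectation")
    single = {
        "a": PlateDesign(top_dose=16 * truth_a.Dm, n_doses=6, replicates=1),
        "b": PlateDesign(top_dose=16 * truth_b.Dm, n_doses=6, replicates=1),
    }
    fit_a = fit_median_effect(points_from_wells(
        simulate_single_drug_plate(truth_a, single["a"], noise)))
    fit_b = fit_median_effect(points_from_wells(
        simulate_single_drug_plate(truth_b, single["b"], noise, drug_slot="b")))
    unit = k_a * truth_a.Dm + k_b * truth_b.Dm
    design = PlateDesign(top_dose=4 * unit, n_doses=7, replicates=1)
    wells = simulate_combination_plate(truth_a, truth_b, ratio, psi, design, noise)
    fit_mix = fit_median_effect(points_from_wells(wells))
    profile = synergy_profile(fit_a, fit_b, fit_mix, ratio, fa_levels)
    return [row.ci for row in profile.rows]


class TestGeneratorAnalyzerDuality:
    @pytest.mark.parametrize("psi", [0.3, 0.55, 1.0, 1.5])
    def test_shared_shape_duality_is_exact(self, psi):
        """Noiseless pipeline CI equals psi when the components share m.

        With a common shape the constant-ratio mixture is itself a
        median-effect curve, so the fit is exact and the estimated CI
        reproduces the generating interaction to numerical precision.
        """
        a = DrugGroundTruth("a", m=1.2, Dm=1.675)
        b = DrugGroundTruth("b", m=1.2, Dm=65.58)
        for ci in pipeline_ci(a, b, psi):
            assert ci == pytest.approx(psi, abs=1e-6)

    def test_unequal_shapes_bounded_model_error(self):
        """With unequal shapes the mixture is only approximately median-effect.

        The linearized fit then carries systematic curvature error; the
        recovered CI still tracks psi within about 0.1 at mid effect levels
        but can drift by several tenths at the 10% tail.
        """
        cis = pipeline_ci(CISPLATIN_LIKE, BC7_LIKE, 0.55,
                          fa_levels=(0.10, 0.25, 0.50, 0.75))
        assert abs(cis[0] - 0.55) < 0.5
        assert all(abs(ci - 0.55) < 0.1 for ci in cis[1:])

    def test_stochastic_ci_tracks_psi_on_average(self):
        """Binomial noise, 3 replicates: mean CI over seeds within 0.1 of psi."""
        a = DrugGroundTruth("a", m=1.2, Dm=1.675)
        b = DrugGroundTruth("b", m=1.2, Dm=65.58)
        psi = 0.55
        ratio = MixtureRatio.from_ic50s(1, 1, a.Dm, b.Dm)
        unit = a.Dm + b.Dm
        cis = []
        for seed in range(10):
            noise = NoiseModel(control_death_fraction=0.05, seed=seed)
            fit_a = fit_median_effect(points_from_wells(simulate_single_drug_plate(
                a, PlateDesign(top_dose=16 * a.Dm), noise)))
            fit_b = fit_median_effect(points_from_wells(simulate_single_drug_plate(
                b, PlateDesign(top_dose=16 * b.Dm), noise, drug_slot="b")))
            wells = simulate_combination_plate(
                a, b, ratio, psi, PlateDesign(top_dose=4 * unit, n_doses=7), noise)
            fit_mix = fit_median_effect(points_from_wells(wells))
            profile = synergy_profile(fit_a, fit_b, fit_mix, ratio, [0.5])
            cis.append(profile.rows[0].ci)
        assert abs(np.mean(cis) - psi) < 0.1


class TestParameterRecovery:
    def test_recovery_improves_with_replicates(self):
        """Median |relative error| of (m, Dm) shrinks as replicates grow."""
        errors = {}
        for reps in (1, 3, 10):
            errs = []
            for seed in range(40):
                noise = NoiseModel(seed=seed)
                design = PlateDesign(top_dose=16 * CISPLATIN_LIKE.Dm,
                                     replicates=reps)
                wells = simulate_single_drug_plate(CISPLATIN_LIKE, design, noise)
                fit = fit_median_effect(points_from_wells(wells))
                errs.append(abs(fit.m - CISPLATIN_LIKE.m) / CISPLATIN_LIKE.m)
                errs.append(abs(fit.Dm - CISPLATIN_LIKE.Dm) / CISPLATIN_LIKE.Dm)
            errors[reps] = float(np.median(errs))
        assert errors[1] > errors[3] > errors[10]
        assert errors[3] < 0.10
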