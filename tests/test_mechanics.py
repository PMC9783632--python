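"""Closed-form uniaxial stress: invariants, pressure elimination, consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyromech import (
    Family,
    HyperelasticParams,
    PrincipalStretches,
    hydrostatic_pressure,
    invariants_from_stretches,
    small_strain_modulus,
    strain_energy,
    uniaxial_cauchy_stress,
    uniaxial_engineering_stress,
    uniaxial_stretches,
)
from thyromech.mechanics import stretch_stress_unconstrained


def eliminate_pressure(params, lam):
    """Independent oracle: axial stress via explicit lateral-stress elimination.

    Evaluates the unconstrained principal stresses λi ∂W/∂λi at the uniaxial
    state and subtracts the pressure that zeroes the lateral direction —
    never calling the closed-form expression under test.
    """
    s = uniaxial_stretches(lam)
    unconstrained = stretch_stress_unconstrained(params, s)
    pe = unconstrained[1]  # lateral σ2 = λ2 ∂W/∂λ2 − pe = 0
    return unconstrained[0] - pe


def random_params(rng, family):
    if family is Family.NEO_HOOKEAN:
        return HyperelasticParams.neo_hookean(rng.uniform(1e-4, 1e-1))
    if family is Family.MOONEY_RIVLIN:
        return HyperelasticParams.mooney_rivlin(
            rng.uniform(1e-4, 1e-1), rng.uniform(-1e-2, 1e-1)
        )
    if family is Family.YEOH:
        return HyperelasticParams.yeoh(
            rng.uniform(1e-4, 1e-1), rng.uniform(-1e-2, 1e-2), rng.uniform(0, 1e-1)
        )
    return HyperelasticParams.ogden(
        (rng.uniform(1e-3, 1e-1), rng.uniform(-1e-2, 0)),
        (rng.uniform(1, 10), rng.uniform(-6, -1)),
    )


class TestInvariants:
    @pytest.mark.parametrize(
        "stretches, expected",
        [((1, 1, 1), (3, 3, 1)), ((2, 1, 1), (6, 9, 4))],
    )
    def test_direct_evaluation(self, stretches, expected):
        inv = invariants_from_stretches(PrincipalStretches(*stretches))
        assert (inv.I1, inv.I2, inv.I3) == pytest.approx(expected)

    @given(lam=st.floats(0.2, 5.0))
    @settings(deadline=None)
    def test_uniaxial_state_is_isochoric(self, lam):
        inv = invariants_from_stretches(uniaxial_stretches(lam))
        assert inv.I3 == pytest.approx(1.0, abs=1e-12)
        # AM–GM: I1, I2 >= 3 on the incompressible manifold
        assert inv.I1 >= 3.0 - 1e-12
        assert inv.I2 >= 3.0 - 1e-12

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            PrincipalStretches(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            uniaxial_stretches(-1.0)


class TestClosedForm:
    def test_undeformed_state_is_stress_free(self, yeoh_reference):
        assert uniaxial_cauchy_stress(yeoh_reference, 1.0) == pytest.approx(0.0)
        assert uniaxial_engineering_stress(yeoh_reference, 0.0) == pytest.approx(0.0)

    def test_compression_stress_against_elimination_oracle(self, yeoh_reference):
        # frozen from the elimination oracle at λ = 0.75
        expected = eliminate_pressure(yeoh_reference, 0.75)
        assert expected == pytest.approx(-1.10197e-2, rel=1e-4)
        assert uniaxial_cauchy_stress(yeoh_reference, 0.75) == pytest.approx(
            expected, rel=1e-12
        )
        assert uniaxial_engineering_stress(yeoh_reference, -0.25) == pytest.approx(
            expected / 0.75, rel=1e-12
        )

    def test_sign_convention(self, yeoh_reference):
        assert uniaxial_cauchy_stress(yeoh_reference, 1.2) > 0.0
        assert uniaxial_cauchy_stress(yeoh_reference, 0.8) < 0.0

    @pytest.mark.parametrize("family", list(Family))
    def test_matches_pressure_elimination_on_random_draws(self, family):
        """Closed form equals explicit elimination over 1000 draws (rtol 1e-10)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            params = random_params(rng, family)
            lam = rng.uniform(0.5, 2.0)
            direct = eliminate_pressure(params, lam)
            closed = uniaxial_cauchy_stress(params, lam)
            assert closed == pytest.approx(direct, rel=1e-10, abs=1e-18)

    @pytest.mark.parametrize("family", list(Family))
    def test_stress_energy_consistency(self, family):
        """σ = λ ∂W/∂λ − p with the derivative from central finite differences."""
        rng = np.random.default_rng(7)
        h = 1e-6
        for _ in range(50):
            params = random_params(rng, family)
            lam = rng.uniform(0.6, 1.8)
            lat = lam**-0.5
            w_plus = strain_energy(params, PrincipalStretches(lam + h, lat, lat))
            w_minus = strain_energy(params, PrincipalStretches(lam - h, lat, lat))
            dw = (w_plus - w_minus) / (2.0 * h)
            sigma_fd = lam * dw - hydrostatic_pressure(params, lam)
            assert uniaxial_cauchy_stress(params, lam) == pytest.approx(
                sigma_fd, rel=1e-6, abs=1e-12
            )

    def test_family_degeneration_on_stretch_grid(self):
        """Yeoh(C10,0,0) ≡ NH(C10) ≡ MR(C10,0) ≡ Ogden((2C10, 2))."""
        c10 = 3.7e-3
        grid = np.linspace(0.5, 2.0, 61)
        reference = uniaxial_cauchy_stress(HyperelasticParams.neo_hookean(c10), grid)
        for params in (
            HyperelasticParams.yeoh(c10, 0.0, 0.0),
            HyperelasticParams.mooney_rivlin(c10, 0.0),
            HyperelasticParams.ogden((2.0 * c10,), (2.0,)),
        ):
            np.testing.assert_allclose(
                uniaxial_cauchy_stress(params, grid), reference, rtol=1e-12
            )

    def test_small_strain_slope_is_six_c10(self, yeoh_reference):
        h = 1e-7
        slope_fd = (
            uniaxial_engineering_stress(yeoh_reference, h)
            - uniaxial_engineering_stress(yeoh_reference, -h)
        ) / (2.0 * h)
        assert slope_fd == pytest.approx(6.0 * 1.9e-3, rel=1e-3)
        assert small_strain_modulus(yeoh_reference) == pytest.approx(6.0 * 1.9e-3)

    @given(c10=st.floats(1e-5, 1.0))
    @settings(deadline=None)
    def test_monotone_near_identity_when_c10_positive(self, c10):
        params = HyperelasticParams.yeoh(c10, 0.0, 0.0)
        h = 1e-6
        slope = (
            uniaxial_engineering_stress(params, h)
            - uniaxial_engineering_stress(params, -h)
        ) / (2.0 * h)
        assert slope > 0.0

    def test_domain_errors(self, yeoh_reference):
        with pytest.raises(ValueError):
            uniaxial_cauchy_stress(yeoh_reference, -0.1)
        with pytest.raises(ValueError):
            uniaxial_engineering_stress(yeoh_reference, -1.0)


class TestHydrostaticPressure:
    def test_identity_pressure_is_twice_c10(self, yeoh_reference):
        assert hydrostatic_pressure(yeoh_reference, 1.0) == pytest.approx(2 * 1.9e-3)
        assert hydrostatic_pressure(HyperelasticParams.yeoh(0, 0, 0), 1.0) == 0.0

    def test_pressure_zeroes_lateral_stress(self, yeoh_reference):
        for lam in (0.6, 0.9, 1.3, 1.9):
            s = uniaxial_stretches(lam)
            lateral = stretch_stress_unconstrained(yeoh_reference, s)[1]
            assert hydrostatic_pressure(yeoh_reference, lam) == pytest.approx(
                lateral, rel=1e-12
            )


class TestParamsValidation:
    def test_coefficient_count_enforced(self):
        with pytest.raises(ValueError):
            HyperelasticParams(Family.YEOH, (1.0, 2.0))

    def test_ogden_ground_state_must_be_positive(self):
        with pytest.raises(ValueError):
            HyperelasticParams.ogden((1.0,), (-2.0,))
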