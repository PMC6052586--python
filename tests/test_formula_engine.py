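"""Formula engines vs independent transcription oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iolmc import (
    AKREOS_AO,
    SOFTEC_HD,
    BracketError,
    DomainError,
    EyeBiometry,
    FormulaName,
    IOLModel,
    emmetropia_power,
    power_for_target,
    predict_refraction,
    round_to_grid,
    srkt_intermediates,
)
from iolmc.formula_engine import haigis_elp, haigis_refraction_at_elp

from conftest import AVERAGE_EYE, random_eyes
from oracles import (
    bisect_power,
    haigis_refraction_oracle,
    srkt_intermediates_oracle,
    srkt_refraction_oracle,
)


class TestSrktIntermediates:
    def test_average_eye_matches_oracle(self, average_eye):
        got = srkt_intermediates(average_eye, AKREOS_AO.a_constant)
        want = srkt_intermediates_oracle(average_eye.K, average_eye.AL, 118.24)
        for name in ("r", "lcor", "cw", "h", "offset", "acd_est", "lopt"):
            assert getattr(got, name) == pytest.approx(want[name], abs=1e-12)
        assert got.r == pytest.approx(337.5 / average_eye.K)

    def test_long_eye_correction_continuous_at_cutoff(self):
        below = srkt_intermediates(
            EyeBiometry("b", "OD", K=44.0, ACD=3.1, AL=24.2), 118.24
        )
        above = srkt_intermediates(
            EyeBiometry("a", "OD", K=44.0, ACD=3.1, AL=24.2000001), 118.24
        )
        assert below.lcor == 24.2
        # published coefficients leave a ~0.0015 mm step at the cutoff
        assert abs(above.lcor - below.lcor) < 2e-3

    def test_steep_small_cornea_clamps_height_to_radius(self):
        eye = EyeBiometry("s", "OD", K=60.0, ACD=3.0, AL=32.0)
        inter = srkt_intermediates(eye, 118.24)
        assert inter.h == pytest.approx(inter.r)  # sqrt argument clamped to 0
        assert math.isfinite(inter.acd_est)

    def test_rejects_axial_length_out_of_bounds(self):
        eye = EyeBiometry("z", "OD", K=44.0, ACD=3.0, AL=31.0)
        object.__setattr__(eye, "AL", 40.0)  # bypass dataclass guard
        with pytest.raises(DomainError):
            srkt_intermediates(eye, 118.24)


class TestOracleAgreement:
    """Both engines agree with the transcription oracles to 1e-9 D."""

    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_thousand_random_eyes(self, formula):
        rng = np.random.default_rng(42)
        for eye in random_eyes(1000, seed=7):
            power = float(rng.uniform(5.0, 35.0))
            got = predict_refraction(formula, eye, AKREOS_AO, power)
            if formula is FormulaName.SRKT:
                want = srkt_refraction_oracle(eye.K, eye.AL, 118.24, power)
            else:
                want = haigis_refraction_oracle(
                    eye.K, eye.ACD, eye.AL, 1.706, 0.279, 0.087, power
                )
            assert got == pytest.approx(want, abs=1e-9)


class TestPredictRefraction:
    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_emmetropia_round_trip(self, formula, average_eye):
        p0 = emmetropia_power(formula, average_eye, AKREOS_AO)
        assert predict_refraction(formula, average_eye, AKREOS_AO, p0) == pytest.approx(
            0.0, abs=1e-9
        )

    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_one_diopter_step_for_average_eye(self, formula, average_eye):
        """+1 D of IOL power shifts the spectacle plane by 0.55-0.75 D."""
        p0 = emmetropia_power(formula, average_eye, AKREOS_AO)
        drop = predict_refraction(
            formula, average_eye, AKREOS_AO, p0
        ) - predict_refraction(formula, average_eye, AKREOS_AO, p0 + 1.0)
        assert 0.55 <= drop <= 0.75

    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_strictly_decreasing_in_power(self, formula):
        for eye in random_eyes(20, seed=11):
            grid = np.linspace(5.0, 35.0, 61)
            refs = [predict_refraction(formula, eye, AKREOS_AO, p) for p in grid]
            assert all(a > b for a, b in zip(refs, refs[1:]))

    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_spectacle_sensitivity_within_physical_band(self, formula):
        """|dREF/dP| in (0.4, 1.0) for cohort-plausible eyes near emmetropia."""
        for eye in random_eyes(50, seed=13):
            p0 = emmetropia_power(formula, eye, AKREOS_AO)
            h = 0.05
            slope = (
                predict_refraction(formula, eye, AKREOS_AO, p0 + h)
                - predict_refraction(formula, eye, AKREOS_AO, p0 - h)
            ) / (2 * h)
            assert 0.4 < -slope < 1.0

    def test_haigis_elp_linear_in_a0_and_example_value(self, average_eye):
        assert haigis_elp(average_eye, AKREOS_AO) == pytest.approx(4.6196, abs=1e-4)
        shifted = IOLModel(
            name="shifted", interval=0.5, tolerance_sd=0.4,
            a_constant=118.24, haigis_a0=1.706 + 0.37, haigis_a1=0.279,
            haigis_a2=0.087, power_min=15.5, power_max=25.0,
        )
        assert haigis_elp(average_eye, shifted) - haigis_elp(
            average_eye, AKREOS_AO
        ) == pytest.approx(0.37, abs=1e-12)

    def test_singular_elp_reported(self, average_eye):
        with pytest.raises(DomainError):
            haigis_refraction_at_elp(average_eye.K, average_eye.AL, 24.0, 20.0)


class TestPowerForTarget:
    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_inverse_of_forward_map(self, formula, average_eye):
        ref = predict_refraction(formula, average_eye, AKREOS_AO, 21.0)
        assert power_for_target(formula, average_eye, AKREOS_AO, ref) == pytest.approx(
            21.0, abs=1e-8
        )

    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_agrees_with_bisection_oracle(self, formula):
        for eye in random_eyes(100, seed=17):
            if formula is FormulaName.SRKT:
                fn = lambda p: srkt_refraction_oracle(eye.K, eye.AL, 118.24, p)
            else:
                fn = lambda p: haigis_refraction_oracle(
                    eye.K, eye.ACD, eye.AL, 1.706, 0.279, 0.087, p
                )
            got = power_for_target(formula, eye, AKREOS_AO, -0.25)
            want = bisect_power(fn, -0.25)
            assert got == pytest.approx(want, abs=1e-7)

    @pytest.mark.parametrize("formula", list(FormulaName))
    def test_myopic_target_needs_more_power(self, formula, average_eye):
        p_myopic = power_for_target(formula, average_eye, AKREOS_AO, -0.50)
        p_plano = power_for_target(formula, average_eye, AKREOS_AO, 0.0)
        assert p_myopic > p_plano

    def test_unreachable_target_reports_bracket_failure(self, average_eye):
        with pytest.raises(BracketError):
            power_for_target(FormulaName.HAIGIS, average_eye, AKREOS_AO, -40.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        k=st.floats(41.0, 48.0),
        acd=st.floats(2.2, 4.2),
        al=st.floats(20.5, 26.5),
        target=st.floats(-3.0, 1.0),
        formula=st.sampled_from(list(FormulaName)),
    )
    def test_round_trip_property(self, k, acd, al, target, formula):
        """predict(power_for_target(t)) == t for any plausible eye."""
        eye = EyeBiometry("h", "OD", K=k, ACD=acd, AL=al)
        p = power_for_target(formula, eye, AKREOS_AO, target)
        assert predict_refraction(formula, eye, AKREOS_AO, p) == pytest.approx(
            target, abs=1e-7
        )


class TestRoundToGrid:
    @pytest.mark.parametrize(
        "power,lens,expected",
        [
            (20.60, AKREOS_AO, 20.50),   # nearest 0.50 grid point
            (20.60, SOFTEC_HD, 20.50),   # nearest 0.25 grid point
            (20.75, AKREOS_AO, 20.50),   # exact tie rounds to lower power
            (20.875, SOFTEC_HD, 20.75),  # 0.25-grid tie, same rule
            (20.90, AKREOS_AO, 21.00),
            (26.40, AKREOS_AO, 25.00),   # clamped to power_max
            (10.00, SOFTEC_HD, 15.50),   # clamped to power_min
        ],
    )
    def test_examples(self, power, lens, expected):
        assert round_to_grid(power, lens) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(power=st.floats(15.5, 25.0), step=st.sampled_from([0.25, 0.50]))
    def test_within_half_interval_property(self, power, step):
        lens = SOFTEC_HD if step == 0.25 else AKREOS_AO
        snapped = round_to_grid(power, lens)
        assert abs(snapped - power) <= step / 2 + 1e-12
        assert (snapped / step) == pytest.approx(round(snapped / step), abs=1e-9)
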