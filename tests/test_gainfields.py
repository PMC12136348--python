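"""Gain-field state, learning distributions, directed error, learning rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saccadapt import (
    FIG2_PARAMS,
    LearningParams,
    ModelParams,
    NegativeGainError,
    NegativeGainWarning,
    TABLE1_PARAMS,
    apply_adaptation_drop,
    build_learning_distribution,
    build_learning_distributions,
    directed_amplitude_error,
    init_gain_fields,
    update_gain_fields,
)


class TestInitGainFields:
    def test_flat_planes_at_constants(self, coarse_grid):
        gains = init_gain_fields((0.978, 0.962, 1.020), coarse_grid)
        assert np.all(gains.omega_v == 0.978)
        assert np.all(gains.omega_m == 0.962)
        assert np.all(gains.omega_cd == 1.020)

    def test_from_model_params(self, coarse_grid, table1):
        gains = init_gain_fields(table1, coarse_grid)
        assert gains.value_at((12.0, 0.0)) == {
            "omega_v": 0.978, "omega_m": 0.962, "omega_cd": 1.020,
        }


class TestLearningDistribution:
    def test_peak_rate_at_target(self, grid):
        # the rate at the adaptation target equals phi, at any resolution
        for phi in (0.008, -0.003):
            alpha = build_learning_distribution(
                phi, 0.48, 2.66, 1.06, (12.0, 0.0), grid
            )
            ax = grid.axis
            i = int(np.argmin(np.abs(ax - 12.0)))
            j = int(np.argmin(np.abs(ax)))
            assert alpha[i, j] == pytest.approx(phi, rel=1e-12)

    def test_outward_inward_ratio_matches_analytic_form(self, grid):
        lp = TABLE1_PARAMS.learning
        alpha = build_learning_distribution(
            lp.phi_m, lp.sigma_mF, lp.sigma_mP, lp.sigma_mO, (12.0, 0.0), grid
        )
        ax = grid.axis
        j = int(np.argmin(np.abs(ax)))
        out = alpha[int(np.argmin(np.abs(ax - 14.0))), j]
        inw = alpha[int(np.argmin(np.abs(ax - 10.0))), j]
        expected = np.exp(-4.0 / (2 * lp.sigma_mP**2)) / np.exp(
            -4.0 / (2 * lp.sigma_mF**2)
        )
        assert out / inw == pytest.approx(expected, rel=1e-9)
        assert out > inw  # sigma_P > sigma_F

    def test_rotation_equivariance_quarter_turn(self, grid):
        # 90-degree rotation maps grid cells onto grid cells, so the
        # analytically rotated construction must agree exactly
        a_right = build_learning_distribution(0.005, 0.55, 2.01, 1.04, (12.0, 0.0), grid)
        a_up = build_learning_distribution(0.005, 0.55, 2.01, 1.04, (0.0, 12.0), grid)
        ax = grid.axis

        def at(alpha, x, y):
            return alpha[int(np.argmin(np.abs(ax - x))), int(np.argmin(np.abs(ax - y)))]

        for (x, y) in [(14.0, 1.0), (10.5, -2.0), (13.0, 3.5)]:
            assert at(a_right, x, y) == pytest.approx(at(a_up, -y, x), rel=1e-12)

    def test_foveal_target_rejected(self, grid):
        with pytest.raises(ValueError):
            build_learning_distribution(0.005, 1.0, 2.0, 1.0, (0.0, 0.0), grid)

    def test_foveal_width_constraint_enforced(self, grid):
        lp = LearningParams(
            phi_v=0.005, phi_m=0.008, phi_cd=-0.003,
            sigma_vF=0.55, sigma_mF=4.5, sigma_cdF=1.10,  # 4.5 > 12/3
            sigma_vP=2.01, sigma_mP=2.66, sigma_cdP=1.18,
            sigma_vO=1.04, sigma_mO=1.06, sigma_cdO=1.13,
        )
        with pytest.raises(ValueError, match="foveal constraint"):
            build_learning_distributions(lp, (12.0, 0.0), grid)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        phi=st.floats(-0.05, 0.05),
        sf=st.floats(0.2, 3.0), sp=st.floats(0.2, 8.0), so=st.floats(0.2, 5.0),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_peak_invariant_over_parameterizations(self, phi, sf, sp, so, angle):
        from saccadapt import FieldGrid

        g = FieldGrid(16.0, 0.5)
        target = 10.0 * np.array([np.cos(angle), np.sin(angle)])
        alpha = build_learning_distribution(phi, sf, sp, so, target, g)
        # peak cannot exceed |phi| anywhere; it is attained near the target
        assert np.abs(alpha).max() <= abs(phi) + 1e-12


class TestDirectedAmplitudeError:
    @pytest.mark.parametrize(
        "E,P1,expected",
        [
            ((-1.2, 0.5), (12, 0), -1.3),   # inward error, right hemifield
            ((0.6, 0.8), (0, -10), -1.0),   # vertical-meridian branch
            ((0.0, 0.0), (12, 0), 0.0),
            ((1.2, -0.5), (-12, 0), -1.3),  # inward in the left hemifield
            ((0.0, 0.7), (12, 0), 0.0),     # tie-break: zero sign product
        ],
    )
    def test_examples(self, E, P1, expected):
        assert directed_amplitude_error(np.array(E), np.array(P1)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_foveal_target_rejected(self):
        with pytest.raises(ValueError):
            directed_amplitude_error(np.array([1.0, 0.0]), np.array([0.0, 0.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        ex=st.floats(-5, 5), ey=st.floats(-5, 5),
        px=st.floats(1, 20), py=st.floats(-20, 20),
    )
    def test_magnitude_and_antisymmetry(self, ex, ey, px, py):
        E = np.array([ex, ey])
        P1 = np.array([px, py])
        de = directed_amplitude_error(E, P1)
        assert abs(de) == pytest.approx(np.hypot(ex, ey), abs=1e-12) or de == 0.0
        assert directed_amplitude_error(-E, P1) == pytest.approx(-de, abs=1e-12)


class TestLearningUpdate:
    def test_zero_error_leaves_gains_unchanged(self, coarse_grid, table1):
        gains = init_gain_fields(table1, coarse_grid)
        alphas = build_learning_distributions(table1, (12.0, 0.0), coarse_grid)
        out = update_gain_fields(gains, alphas, 0.0)
        assert np.array_equal(out.omega_m, gains.omega_m)

    def test_update_signs_for_inward_error(self, coarse_grid, table1):
        # inward (negative) error: omega_v, omega_m dip, omega_cd rises
        gains = init_gain_fields(table1, coarse_grid)
        alphas = build_learning_distributions(table1, (12.0, 0.0), coarse_grid)
        out = update_gain_fields(gains, alphas, -2.0)
        at = out.value_at((12.0, 0.0))
        assert at["omega_v"] < 0.978
        assert at["omega_m"] < 0.962
        assert at["omega_cd"] > 1.020

    def test_update_signs_for_outward_error(self, coarse_grid, table1):
        gains = init_gain_fields(table1, coarse_grid)
        alphas = build_learning_distributions(table1, (12.0, 0.0), coarse_grid)
        out = update_gain_fields(gains, alphas, 2.0)
        at = out.value_at((12.0, 0.0))
        assert at["omega_v"] > 0.978
        assert at["omega_m"] > 0.962
        assert at["omega_cd"] < 1.020

    def test_additivity_over_repeated_steps(self, coarse_grid, table1):
        gains = init_gain_fields(table1, coarse_grid)
        alphas = build_learning_distributions(table1, (12.0, 0.0), coarse_grid)
        de = -0.7
        out = gains
        for _ in range(5):
            out = update_gain_fields(out, alphas, de)
        assert np.allclose(
            out.omega_v, gains.omega_v + 5 * de * alphas.alpha_v, atol=1e-12
        )

    def test_nonpositive_gain_is_flagged(self, coarse_grid, table1):
        gains = init_gain_fields(table1, coarse_grid)
        alphas = build_learning_distributions(table1, (12.0, 0.0), coarse_grid)
        with pytest.warns(NegativeGainWarning):
            update_gain_fields(gains, alphas, -150.0)
        with pytest.raises(NegativeGainError):
            update_gain_fields(gains, alphas, -150.0, on_nonpositive="raise")


class TestAdaptationDrop:
    def _pair(self, coarse_grid, table1):
        pre = init_gain_fields(table1, coarse_grid)
        alphas = build_learning_distributions(table1, (12.0, 0.0), coarse_grid)
        end = update_gain_fields(pre, alphas, -10.0)
        return pre, end

    def test_kappa_zero_keeps_end_state(self, coarse_grid, table1):
        pre, end = self._pair(coarse_grid, table1)
        out = apply_adaptation_drop(end, pre, 0.0)
        assert np.array_equal(out.omega_m, end.omega_m)

    def test_kappa_one_restores_pre_state(self, coarse_grid, table1):
        pre, end = self._pair(coarse_grid, table1)
        out = apply_adaptation_drop(end, pre, 1.0)
        assert np.allclose(out.omega_m, pre.omega_m, atol=1e-12)

    def test_fractional_drop_keeps_two_thirds(self, coarse_grid, table1):
        pre, end = self._pair(coarse_grid, table1)
        out = apply_adaptation_drop(end, pre, 0.334)
        remaining = out.omega_m - pre.omega_m
        acquired = end.omega_m - pre.omega_m
        assert np.allclose(remaining, 0.666 * acquired, atol=1e-12)

    def test_kappa_out_of_range(self, coarse_grid, table1):
        pre, end = self._pair(coarse_grid, table1)
        with pytest.raises(ValueError):
            apply_adaptation_drop(end, pre, 1.5)


class TestModelParams:
    def test_json_round_trip(self, tmp_path, table1):
        path = tmp_path / "params.json"
        table1.to_json(path)
        loaded = ModelParams.from_json(path)
        assert loaded == table1

    def test_flat_dict_uses_field_names(self, table1):
        d = table1.to_dict()
        assert d["omega_vC"] == 0.978
        assert d["phi_m"] == 0.008
        assert d["sigma_cdP"] == 1.18
        assert d["kappa"] == 0.334
        assert len(d) == 16

    def test_kappa_bounds_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(
                omega_vC=1.0, omega_mC=1.0, omega_cdC=1.0,
                learning=FIG2_PARAMS.learning, kappa=1.2,
            )

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            LearningParams(
                phi_v=0.005, phi_m=0.008, phi_cd=-0.003,
                sigma_vF=0.55, sigma_mF=-0.48, sigma_cdF=1.10,
                sigma_vP=2.01, sigma_mP=2.66, sigma_cdP=1.18,
                sigma_vO=1.04, sigma_mO=1.06, sigma_cdO=1.13,
            )
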