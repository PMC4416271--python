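import numpy as np
import pytest

from nasocond.airflow import partition_ratios, tidal_waveform
from nasocond.geometry import synthesize_geometry
from nasocond.psychro import AirProperties, saturation_vapour_density
from nasocond.transport import (
    AirState,
    PassageModel,
    SolverError,
    WallModel,
    run_breath_cycles,
    transfer_coefficients,
)

@pytest.fixture(scope="module")
def small_geometry():
    return synthesize_geometry(n_slices=12, slice_thickness=0.008)


class TestTransferCoefficients:
    def test_frozen_value(self):
        # oracle: Nu*k/Dh = 7.54*0.026/0.003 = 65.3 W/m²K
        props = AirProperties(
            density=1.15, dynamic_viscosity=1.86e-5, thermal_conductivity=0.026,
            specific_heat=1006.0, vapour_diffusivity=2.6e-5,
        )
        tc = transfer_coefficients(0.003, props)
        assert tc.h[0] == pytest.approx(65.3, abs=0.2)

    def test_ratio_constant_across_segments(self, air_props):
        tc = transfer_coefficients(np.array([0.002, 0.003, 0.005]), air_props)
        ratios = tc.h_m / tc.h
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_halving_dh_doubles_h(self, air_props):
        tc = transfer_coefficients(np.array([0.004, 0.002]), air_props)
        assert tc.h[1] == pytest.approx(2 * tc.h[0], rel=1e-12)

    def test_chilton_colburn_analogy(self, air_props):
        tc = transfer_coefficients(0.003, air_props)
        expected = tc.h[0] / (
            air_props.density * air_props.specific_heat
            * air_props.lewis_number ** (2 / 3)
        )
        assert tc.h_m[0] == pytest.approx(expected, rel=1e-12)

    def test_non_positive_dh(self, air_props):
        with pytest.raises(ValueError):
            transfer_coefficients(0.0, air_props)


class TestWallModel:
    def test_linear_profile(self):
        wall = WallModel(anterior_c=32.0, posterior_c=37.0)
        np.testing.assert_allclose(
            wall.temperatures(np.array([0.0, 0.5, 1.0])), [32.0, 34.5, 37.0]
        )

    def test_range_validation(self):
        with pytest.raises(ValueError):
            WallModel(anterior_c=15.0)
        with pytest.raises(ValueError):
            WallModel(posterior_c=45.0)


class TestAirState:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            AirState(t_air=np.array([30.0]), c_air=np.array([-1e-3]))


class TestPassagePhysics:
    def test_thermal_relaxation_oracle(self, small_geometry, ambient, default_asl,
                                       air_props):
        # zero flow, uniform wall, no moisture: T decays exponentially to the
        # wall with time constant rho*cp*Vol/(h*S)
        wall = WallModel(anterior_c=34.0, posterior_c=34.0)
        p = PassageModel(small_geometry, "left", wall, ambient, default_asl,
                         air_props=air_props, vapour_exchange=False)
        p.air.t_air = np.full_like(p.air.t_air, 23.0)
        tau = air_props.density * air_props.specific_heat * p.vol / (p.h * p.surf)
        t_end = 2.0 * float(tau.min())
        n_steps = 2000
        for _ in range(n_steps):
            p.advance(0.0, t_end / n_steps)
        expected = 34.0 + (23.0 - 34.0) * np.exp(-t_end / tau)
        np.testing.assert_allclose(p.air.t_air, expected, atol=0.02)

    def test_saturated_air_at_wall_temperature_is_equilibrium(
        self, small_geometry, ambient, default_asl, air_props
    ):
        wall = WallModel(anterior_c=34.0, posterior_c=34.0)
        p = PassageModel(small_geometry, "left", wall, ambient, default_asl,
                         air_props=air_props)
        p.air.t_air = p.wall_t.copy()
        p.air.c_air = p.csat_wall.copy()
        before = (p.air.t_air.copy(), p.air.c_air.copy(), p.he.copy())
        p.advance(0.0, 1.0)
        np.testing.assert_array_equal(p.air.t_air, before[0])
        np.testing.assert_array_equal(p.air.c_air, before[1])
        np.testing.assert_array_equal(p.he, before[2])

    def test_steady_inhalation_fully_conditions_air(
        self, small_geometry, ambient, default_asl, air_props
    ):
        # long constant inflow at high NTU: outlet saturates at the posterior
        # wall temperature (steady state of the ODE chain)
        p = PassageModel(small_geometry, "left", WallModel(), ambient, default_asl,
                         air_props=air_props)
        for _ in range(3000):
            p.advance(2e-5, 5e-3)
        c_target = saturation_vapour_density(p.wall_t[-1])
        assert p.air.c_air[-1] == pytest.approx(c_target, rel=0.02)
        assert p.air.t_air[-1] == pytest.approx(p.wall_t[-1], rel=0.02)

    def test_substep_limit_raises(self, small_geometry, ambient, default_asl,
                                  air_props):
        p = PassageModel(small_geometry, "left", WallModel(), ambient, default_asl,
                         air_props=air_props, max_substeps=2)
        with pytest.raises(SolverError, match="sub-steps"):
            p.advance(1e-3, 10.0)


class TestBreathCycles:
    def test_symmetric_geometry_identical_sides(self, small_geometry, ambient,
                                                default_asl, air_props):
        wf = tidal_waveform()
        res = run_breath_cycles(
            small_geometry, wf, partition_ratios(1.0, 1.0), WallModel(), ambient,
            default_asl, n_cycles=3, dt=5e-3, spin_up_cycles=2, output_stride=20,
            air_props=air_props,
        )
        for f in ("t_air", "c_air", "he"):
            a = getattr(res.sides["left"], f)
            b = getattr(res.sides["right"], f)
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-10)

    def test_water_conservation_audit(self, asym_result):
        for audit in asym_result.cycle_audits:
            for side in ("left", "right"):
                assert abs(audit[side]["air"]) <= 1e-8
                assert abs(audit[side]["asl"]) <= 1e-8

    def test_temperature_maximum_principle(self, asym_result, ambient):
        for side in ("left", "right"):
            t = asym_result.sides[side].t_air
            assert t.min() >= ambient.temperature_c - 1e-9
            assert t.max() <= 37.0 + 1e-9

    def test_monotone_conditioning_during_inhalation(self, asym_result):
        inh = asym_result.inhalation_mask
        for side in ("left", "right"):
            sr = asym_result.sides[side]
            assert np.all(np.diff(sr.t_air[inh], axis=1) >= -1e-9)
            assert np.all(np.diff(sr.c_air[inh], axis=1) >= -1e-12)

    def test_patent_side_dominates_dehydration(self, asym_result):
        # left is patent (congestion on the right): its minimum he must sit at
        # or below the congested side's at every station
        left = asym_result.metrics["left"].min_he
        right = asym_result.metrics["right"].min_he
        assert np.all(left <= right + 1e-12)
        assert left.min() < right.max()  # strict somewhere

    def test_exhalation_rehydrates_anterior(self, asym_result, waveform):
        # he at the end of exhalation exceeds he at the end of inhalation in
        # the anterior region of the patent side (condensation recovery)
        times = asym_result.times
        period = waveform.period
        last = times > times[-1] - period
        phase = np.mod(times[last], period)
        he = asym_result.sides["left"].he[last]
        i_end_inh = int(np.argmin(np.abs(phase - period / 2)))
        anterior = asym_result.positions["left"] < 0.3
        gain = he[-1][anterior] - he[i_end_inh][anterior]
        assert np.all(gain > 0)

    def test_periodic_steady_state(self, strong_supply_result, waveform):
        # with the printed supply cap the fields settle: cycle-to-cycle change
        # of every recorded field < 0.1% of its span after spin-up
        times = strong_supply_result.times
        period = waveform.period
        n_per = int(round(period / (times[1] - times[0])))
        for side in ("left", "right"):
            for f in ("t_air", "c_air", "he"):
                arr = getattr(strong_supply_result.sides[side], f)
                a, b = arr[-2 * n_per:-n_per], arr[-n_per:]
                span = max(arr.max() - arr.min(), 1e-12)
                assert np.abs(a - b).max() / span < 1e-3

    def test_partition_constant_over_breath(self, asym_result):
        # laminar resistance is flow independent, so the ratios are scalars
        assert asym_result.ratios.pr_left + asym_result.ratios.pr_right == \
            pytest.approx(1.0, abs=1e-12)
        assert asym_result.ratios.pr_left > 0.5  # patent side carries more

    def test_overhydration_logged_on_congested_side(self, asym_result):
        # exhaled saturated air condenses beyond the reabsorption cap
        # somewhere: the over-hydration diagnostic must fire
        assert sum(asym_result.overflow_events.values()) > 0

    def test_spin_up_validation(self, small_geometry, ambient, default_asl):
        wf = tidal_waveform()
        with pytest.raises(ValueError):
            run_breath_cycles(
                small_geometry, wf, partition_ratios(1.0, 1.0), WallModel(),
                ambient, default_asl, n_cycles=2, spin_up_cycles=2,
            )


class TestConvergence:
    def test_dt_halving(self, convergence_dt_pair):
        from conftest import span_normalised_rms

        r1, r2 = convergence_dt_pair
        for f in ("t_air", "c_air", "he"):
            a = getattr(r1.sides["left"], f)
            b = getattr(r2.sides["left"], f)
            assert span_normalised_rms(a, b) < 0.01
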