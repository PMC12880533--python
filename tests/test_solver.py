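"""Steady/transient heat transport: oracles, conservation, symmetry."""

import numpy as np
import pytest

from thermoflow import (
    ActuatorSpec,
    AmbientConditions,
    FlowCondition,
    PhantomGeometry,
    Scenario,
    default_materials,
    energy_balance_residual,
    probe_temperature,
    sensor_positions,
    sensor_readings,
    solve_steady,
    solve_transient,
    normalized_reading,
    power_density,
    CHANNEL_NAMES,
)
from thermoflow.grid import MATERIAL_CODES, SimulationGrid, build_scenario_grid
from thermoflow.solver import SingularSystemError, ThermalField


class TestHomogeneousAndBounds:
    def test_zero_power_uniform_boundaries_gives_uniform_field(self, small_scenario):
        grid = build_scenario_grid(small_scenario)
        field = solve_steady(grid, small_scenario.material_map,
                             small_scenario.ambient, actuator_power_mw=0.0)
        assert np.allclose(field.temperature, 25.0, atol=1e-8)

    def test_maximum_principle_and_hotspot_location(self, small_field, small_scenario):
        T = small_field.temperature
        assert T.min() >= 25.0 - 1e-8
        # the global maximum sits in/under the actuator footprint
        i, j, k = np.unravel_index(np.argmax(T), T.shape)
        x = small_field.grid.cell_centers(0)[i]
        y = small_field.grid.cell_centers(1)[j]
        assert np.hypot(x, y) <= small_scenario.actuator.diameter / 2 + 0.5

    def test_all_neumann_system_rejected(self, small_scenario):
        grid = build_scenario_grid(
            small_scenario.with_(flow=FlowCondition(mean_speed=0.0))
        )
        amb = AmbientConditions(bottom_surface_temperature=None,
                                convective_coefficient=0.0)
        with pytest.raises(SingularSystemError, match="bottom|convective"):
            solve_steady(grid, small_scenario.material_map, amb,
                         actuator_power_mw=10.0)


class TestZeroFlowSymmetry:
    def test_upstream_equals_downstream(self, small_field_zero_flow, small_scenario):
        r = sensor_readings(small_field_zero_flow, small_scenario.layout)
        d = dict(zip(CHANNEL_NAMES, r))
        assert d["t_top_up"] == pytest.approx(d["t_top_dn"], abs=1e-6)
        assert d["t_bot_up"] == pytest.approx(d["t_bot_dn"], abs=1e-6)

    def test_bottom_layer_warmer_than_top_at_zero_flow(
        self, small_field_zero_flow, small_scenario
    ):
        # recorded ordering on the reference configuration: heating from the
        # surface plane makes the on-skin layer warmer than the elevated one
        r = dict(zip(CHANNEL_NAMES,
                     sensor_readings(small_field_zero_flow, small_scenario.layout)))
        assert r["t_bot_up"] > r["t_top_up"]
        assert r["t_bot_ref"] > r["t_top_ref"]


class TestAdvection:
    def test_downstream_skew_with_flow(self, small_field, small_scenario):
        r = dict(zip(CHANNEL_NAMES, sensor_readings(small_field, small_scenario.layout)))
        assert r["t_bot_dn"] > r["t_bot_up"]
        assert r["t_top_dn"] > r["t_top_up"]

    def test_recorded_layer_ordering_with_flow(self, small_field, small_scenario):
        # regression fixture: at f = 1 mm/s the incoming 25 degC water cools
        # the upstream skin probe below the elevated one, while downstream
        # and reference probes stay warmer in the bottom layer
        r = dict(zip(CHANNEL_NAMES, sensor_readings(small_field, small_scenario.layout)))
        assert r["t_top_up"] > r["t_bot_up"]
        assert r["t_bot_dn"] > r["t_top_dn"]
        assert r["t_bot_ref"] > r["t_top_ref"]

    def test_peak_temperature_decreases_with_flow(self, small_scenario):
        grid = build_scenario_grid(small_scenario)
        peaks = []
        for f in (1.0, 4.0, 8.0):
            fld = solve_steady(grid, small_scenario.material_map,
                               small_scenario.ambient, flow=FlowCondition(f),
                               actuator_power_mw=small_scenario.actuator.power_mw)
            peaks.append(fld.temperature.max())
        assert peaks[0] > peaks[1] > peaks[2]


class TestAnalyticConductionOracle:
    def test_composite_slab_with_robin_top(self, small_scenario):
        """1D conduction through PDMS + air with convective top: the solved
        vertical profile must match the closed-form series-resistance
        solution to <0.5%."""
        grid = build_scenario_grid(
            small_scenario.with_(flow=FlowCondition(mean_speed=0.0))
        )
        # strip the channel and actuator: pure PDMS below, air above
        mat = grid.material.copy()
        zc = grid.cell_centers(2)
        mat[:, :, zc < 0] = MATERIAL_CODES["pdms"]
        mat[:, :, zc > 0] = MATERIAL_CODES["air"]
        slab = SimulationGrid(grid.spacing, grid.origin.copy(), mat,
                              np.zeros_like(grid.velocity_x))
        mats = small_scenario.material_map
        amb = AmbientConditions(ambient_temperature=40.0,
                                convective_coefficient=15.0,
                                bottom_surface_temperature=25.0)
        field = solve_steady(slab, mats, amb, actuator_power_mw=0.0)

        t1 = -grid.origin[2] * 1e-3  # PDMS thickness, m
        t2 = (zc[-1] + grid.spacing / 2) * 1e-3  # air thickness, m
        k1 = mats["pdms"].thermal_conductivity
        k2 = mats["air"].thermal_conductivity
        h = amb.convective_coefficient
        q = (amb.ambient_temperature - 25.0) / (t1 / k1 + t2 / k2 + 1 / h)

        def analytic(z_mm):
            z = z_mm * 1e-3
            if z_mm <= 0:
                return 25.0 + q * (z + t1) / k1
            return 25.0 + q * t1 / k1 + q * z / k2

        i, j = slab.shape[0] // 2, slab.shape[1] // 2
        for k in range(slab.shape[2]):
            got = field.temperature[i, j, k]
            want = analytic(zc[k])
            assert abs(got - want) / abs(want) < 0.005


class TestEnergyBalance:
    def test_residual_below_tolerance(self, small_field, small_scenario):
        res = energy_balance_residual(small_field, small_scenario.material_map,
                                      small_scenario.ambient,
                                      small_scenario.actuator.power_mw)
        assert res < 0.02

    def test_zero_power_absolute_residual(self, small_scenario):
        grid = build_scenario_grid(small_scenario)
        field = solve_steady(grid, small_scenario.material_map,
                             small_scenario.ambient, actuator_power_mw=0.0)
        res_mw = energy_balance_residual(field, small_scenario.material_map,
                                         small_scenario.ambient, 0.0)
        assert res_mw < 1e-6

    def test_residual_stable_under_refinement(self, small_scenario):
        fine = small_scenario.with_(spacing=0.25)
        grid = build_scenario_grid(fine)
        field = solve_steady(grid, fine.material_map, fine.ambient,
                             actuator_power_mw=fine.actuator.power_mw)
        res = energy_balance_residual(field, fine.material_map, fine.ambient,
                                      fine.actuator.power_mw)
        assert res < 0.02


class TestGridConvergence:
    def test_probe_temperatures_change_under_one_percent_when_halved(
        self, small_scenario, small_field
    ):
        fine = small_scenario.with_(spacing=0.25)
        grid = build_scenario_grid(fine)
        fld = solve_steady(grid, fine.material_map, fine.ambient,
                           actuator_power_mw=fine.actuator.power_mw)
        coarse = sensor_readings(small_field, small_scenario.layout)
        refined = sensor_readings(fld, fine.layout)
        assert np.all(np.abs(refined - coarse) / np.abs(coarse) < 0.01)


class TestProbe:
    def test_probe_at_node_returns_node_value(self, small_field):
        g = small_field.grid
        i, j, k = 4, 5, 3
        pos = (g.cell_centers(0)[i], g.cell_centers(1)[j], g.cell_centers(2)[k])
        assert probe_temperature(small_field, pos) == pytest.approx(
            small_field.temperature[i, j, k]
        )

    def test_linear_field_interpolated_exactly(self, small_field):
        g = small_field.grid
        lin = ThermalField(
            np.broadcast_to(2.0 * g.cell_centers(2), g.shape).copy() + 30.0, g
        )
        assert probe_temperature(lin, (0.3, -0.7, 0.8)) == pytest.approx(31.6)

    def test_out_of_domain_rejected(self, small_field):
        with pytest.raises(ValueError):
            probe_temperature(small_field, (100.0, 0.0, 0.0))

    def test_six_positions_fixed_order(self, small_scenario):
        pos = sensor_positions(small_scenario.layout)
        assert tuple(pos) == CHANNEL_NAMES
        L = small_scenario.layout.lateral_offset
        H = small_scenario.layout.interlayer_spacing
        assert pos["t_top_up"] == (-L, 0.0, H)
        assert pos["t_bot_ref"] == (0.0, L, 0.0)


class TestTransient:
    def test_zero_power_stays_at_initial(self, small_scenario):
        grid = build_scenario_grid(small_scenario)
        fields = solve_transient(
            grid, small_scenario.material_map, small_scenario.ambient,
            [(0.0, FlowCondition(1.0))], actuator_power_mw=0.0,
            duration=10.0, dt=2.0,
        )
        for f in fields:
            assert np.allclose(f.temperature, 25.0, atol=1e-8)

    def test_long_run_approaches_steady(self, small_scenario, small_field):
        grid = build_scenario_grid(small_scenario)
        fields = solve_transient(
            grid, small_scenario.material_map, small_scenario.ambient,
            [(0.0, FlowCondition(1.0))],
            actuator_power_mw=small_scenario.actuator.power_mw,
            duration=600.0, dt=5.0, record_every=40,
        )
        final = sensor_readings(fields[-1], small_scenario.layout)
        steady = sensor_readings(small_field, small_scenario.layout)
        assert np.max(np.abs(final - steady)) < 0.05

    def test_settling_slower_at_larger_depth(self, small_scenario):
        def rise_time(depth):
            sc = small_scenario.with_(
                geometry=PhantomGeometry(block_mm=(16.0, 11.0, 6.0),
                                         vessel_depth=depth)
            )
            grid = build_scenario_grid(sc)
            fields = solve_transient(
                grid, sc.material_map, sc.ambient,
                [(0.0, FlowCondition(3.0)), (60.0, FlowCondition(6.0))],
                actuator_power_mw=sc.actuator.power_mw,
                duration=120.0, dt=1.0,
            )
            pos = sensor_positions(sc.layout)["t_bot_dn"]
            t = np.array([f.time for f in fields])
            v = np.array([probe_temperature(f, pos) for f in fields])
            seg = t > 60.0
            v0, v1 = v[seg][0], v[seg][-1]
            frac = (v[seg] - v0) / (v1 - v0)
            return t[seg][np.argmax(frac >= 0.9)] - 60.0

        assert rise_time(2.0) >= rise_time(1.0)


class TestScalars:
    def test_power_density_printed_value(self):
        assert power_density(56.7, 3.5) == pytest.approx(5.89, abs=0.005)

    def test_power_density_unit_area(self):
        assert power_density(1.0, 2.0 / np.sqrt(np.pi)) == pytest.approx(1.0)

    def test_power_density_quarter_on_doubled_diameter(self):
        assert power_density(56.7, 7.0) == pytest.approx(power_density(56.7, 3.5) / 4)

    def test_power_density_domain_error(self):
        with pytest.raises(ValueError):
            power_density(10.0, 0.0)

    @pytest.mark.parametrize("T,expected", [(20.0, 0.0), (30.0, 1.0), (25.0, 0.5)])
    def test_normalized_reading_endpoints_and_midpoint(self, T, expected):
        assert normalized_reading(T, 20.0, 30.0) == pytest.approx(expected)

    def test_normalized_reading_degenerate_range(self):
        with pytest.raises(ValueError):
            normalized_reading(25.0, 30.0, 30.0)
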