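"""Shared fixtures: a reduced, fast phantom scenario and cached solves.

The small scenario keeps the full physics (channel, actuator, air gap, all
boundary conditions) in a 16 x 11 x 6 mm block at 0.5 mm spacing, which
solves in well under a second.  Session-scoped fixtures cache solved fields
so independent tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermoflow import (
    Scenario,
    PhantomGeometry,
    FlowCondition,
    build_grid,
    solve_steady,
)
from thermoflow.datasets import SteadySolveCache
from thermoflow.grid import build_scenario_grid


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    return Scenario(
        geometry=PhantomGeometry(block_mm=(16.0, 11.0, 6.0)),
        flow=FlowCondition(mean_speed=1.0),
        spacing=0.5,
    )


@pytest.fixture(scope="session")
def solve_cache() -> SteadySolveCache:
    return SteadySolveCache()


def _solve(scenario):
    grid = build_scenario_grid(scenario)
    return solve_steady(
        grid,
        scenario.material_map,
        scenario.ambient,
        actuator_power_mw=scenario.actuator.power_mw,
    )


@pytest.fixture(scope="session")
def small_field(small_scenario):
    """Steady field of the small scenario at f = 1 mm/s, d = 1 mm."""
    return _solve(small_scenario)


@pytest.fixture(scope="session")
def small_field_zero_flow(small_scenario):
    return _solve(small_scenario.with_(flow=FlowCondition(mean_speed=0.0)))


@pytest.fixture(scope="session")
def analytic_stack_scenario(small_scenario):
    """Small scenario with zero actuator power, used for closure checks."""
    from thermoflow import ActuatorSpec

    return small_scenario.with_(actuator=ActuatorSpec(power_mw=0.0))


class AnalyticReadingsCache(SteadySolveCache):
    """Solver-free stand-in: smooth synthetic readings as a function of the
    scenario's (depth, flow).  Used where tests exercise dataset/inversion
    bookkeeping rather than the thermal physics."""

    def readings(self, scenario) -> np.ndarray:
        key = scenario.cache_key()
        if key not in self._store:
            self._store[key] = self._evaluate(scenario)
            self.n_solves += 1
        return self._store[key]

    def _evaluate(self, scenario) -> np.ndarray:
        d = scenario.geometry.vessel_depth
        f = scenario.flow.mean_speed
        amb = scenario.ambient.ambient_temperature
        base = amb + 3.0 + 1.2 * d
        dn_up = 2.2 / (0.8 + 0.35 * f) * (1.6 - 0.4 * d)
        return np.array([
            base - 0.5 - 0.12 * f + 0.25 * d,       # top up
            base - 0.5 - 0.12 * f + 0.25 * d + 0.6 * dn_up,  # top dn
            base - 0.3 - 0.08 * f + 0.35 * d,       # top ref
            base - 1.1 - 0.18 * f + 0.55 * d,       # bot up
            base - 1.1 - 0.18 * f + 0.55 * d + dn_up,  # bot dn
            base - 0.6 - 0.10 * f + 0.70 * d,       # bot ref
        ])


@pytest.fixture()
def analytic_cache() -> AnalyticReadingsCache:
    return AnalyticReadingsCache()
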