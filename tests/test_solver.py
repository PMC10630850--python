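"""Coupled conduction-diffusion solver: limits, conservation, monotonicity."""

from dataclasses import replace

import numpy as np
import pytest

from foamdry.kinetics import crank_mr
from foamdry.solver import (
    Domain,
    SimulationConfig,
    concentration_to_moisture,
    config_from_manifest,
    dirichlet_limit_config,
    grid_time_convergence,
    moisture_to_concentration,
    simulate,
)
from foamdry.transfer import AirStream


@pytest.fixture(scope="module")
def run70():
    """Default-resolution production run at 70 degC (experimental duration)."""
    return simulate(SimulationConfig(air=AirStream(temperature=70.0)))


class TestConcentrationConversion:
    def test_zero_and_unit_cases(self):
        assert moisture_to_concentration(0.0, 30.0) == 0.0
        assert moisture_to_concentration(1.0, 0.018, 0.018) == pytest.approx(1.0)

    def test_initial_state_hand_multiplication(self):
        cfg = SimulationConfig(air=AirStream(temperature=50.0))
        c0 = moisture_to_concentration(
            3.5657, cfg.dry_solid_density, cfg.water_molar_mass
        )
        assert c0 == pytest.approx(3.5657 * cfg.dry_solid_density / 0.018)

    def test_round_trip_exact(self):
        x = np.array([0.0, 0.5, 3.5657])
        back = concentration_to_moisture(
            moisture_to_concentration(x, 30.175), 30.175
        )
        assert back == pytest.approx(x, rel=1e-15)

    def test_rejects_nonpositive_constants(self):
        with pytest.raises(ValueError):
            moisture_to_concentration(1.0, 0.0)


class TestLimits:
    def test_equilibrium_fixed_point(self):
        """A foam already at the air temperature and at equilibrium moisture
        (with ambient concentration matched) stays constant for all time."""
        x0 = 0.01 + 1e-9  # at equilibrium up to the X0 > X_e invariant
        rho_s = SimulationConfig(air=AirStream(temperature=70.0)).dry_solid_density
        cfg = SimulationConfig(
            air=AirStream(
                temperature=70.0,
                ambient_moisture_concentration=moisture_to_concentration(x0, rho_s),
            ),
            initial_temperature=70.0,
            initial_moisture=x0,
            duration=600.0,
            time_step=60.0,
        )
        res = simulate(cfg)
        # constant up to the 1e-9 equilibrium offset leaking through the
        # evaporative term
        assert res.temperature == pytest.approx(
            np.full_like(res.temperature, 70.0), abs=1e-3
        )
        assert res.moisture == pytest.approx(
            np.full_like(res.moisture, x0), rel=1e-6
        )

    def test_zero_diffusivity_freezes_moisture_while_heat_relaxes(self):
        """With internal diffusion and surface mass exchange both off, the
        moisture field is frozen at X0 while conduction pulls the layer to
        the air temperature."""
        cfg = SimulationConfig(
            air=AirStream(temperature=70.0),
            deff=0.0,
            h_m_override=0.0,
            duration=600.0,
            time_step=10.0,
        )
        res = simulate(cfg)
        assert np.all(res.moisture == res.moisture[0, 0])
        assert res.average_temperature[-1] == pytest.approx(70.0, abs=0.5)

    def test_dirichlet_limit_tracks_crank_series(self):
        """With an effectively pinned surface the volume-average MR follows
        the analytic slab series once the first Fourier modes dominate."""
        deff, duration = 5.218e-9, 6900.0
        cfg = dirichlet_limit_config(50.0, deff=deff, duration=duration)
        res = simulate(cfg)
        L = cfg.domain.thickness
        fo = deff * res.times / L**2
        mask = fo > 0.05
        oracle = crank_mr(deff, L, res.times[mask], n_terms=50)
        assert res.moisture_ratio()[mask] == pytest.approx(oracle, rel=0.01)


class TestConservationAndBounds:
    def test_mass_balance_closes(self, run70):
        assert run70.mass_balance_residual < 1e-5

    def test_deterministic_and_manifest_reproducible(self, run70):
        rebuilt = simulate(config_from_manifest(run70.manifest()))
        assert np.array_equal(rebuilt.moisture, run70.moisture)
        assert np.array_equal(rebuilt.temperature, run70.temperature)
        assert rebuilt.evaporated_mass == run70.evaporated_mass

    def test_moisture_maximum_principle(self, run70):
        assert run70.moisture.min() >= -1e-12
        assert run70.moisture.max() <= 3.5657 * (1 + 1e-12)

    def test_temperature_within_physical_bounds(self, run70):
        cfg = run70.config
        lo = min(cfg.initial_temperature, 70.0) - cfg.cooling_margin
        assert run70.temperature.min() >= lo
        assert run70.temperature.max() <= 70.0 + 1e-6

    def test_spatial_monotonicity_bottom_to_surface(self, run70):
        assert np.all(np.diff(run70.moisture[1:], axis=1) <= 1e-12)
        assert np.all(
            run70.surface_moisture[1:] <= run70.bottom_moisture[1:] + 1e-12
        )

    def test_average_temperature_reaches_air_temperature(self, run70):
        assert run70.average_temperature[-1] == pytest.approx(70.0, abs=0.5)

    def test_uniform_field_average_is_that_value(self, run70):
        assert run70.average_temperature[0] == pytest.approx(20.0)
        assert run70.average_moisture[0] == pytest.approx(3.5657)


class TestVariants:
    def test_literal_bottom_hold_pins_bottom_moisture(self):
        cfg = SimulationConfig(
            air=AirStream(temperature=70.0),
            literal_bottom_hold=True,
            duration=1800.0,
        )
        res = simulate(cfg)
        assert res.bottom_moisture == pytest.approx(
            np.full_like(res.bottom_moisture, 3.5657), rel=1e-9
        )
        assert np.isnan(res.mass_balance_residual)

    def test_as_printed_evaporative_form_runs_bounded(self):
        cfg = SimulationConfig(
            air=AirStream(temperature=70.0),
            evaporative_flux_form="as_printed",
            duration=1800.0,
        )
        res = simulate(cfg)
        assert res.mass_balance_residual < 1e-5
        assert res.temperature.min() >= 20.0 - cfg.cooling_margin

    def test_more_uniform_moisture_at_higher_temperature(self):
        """The bottom-vs-surface moisture gap at the experimental end time
        shrinks as the air temperature rises."""
        gaps = {}
        for T in (50.0, 70.0):
            res = simulate(
                SimulationConfig(air=AirStream(temperature=T), snapshot_every=10**9)
            )
            gaps[T] = res.bottom_moisture[-1] - res.surface_moisture[-1]
        assert gaps[70.0] < gaps[50.0]

    def test_termination_rule_stops_early(self):
        cfg = SimulationConfig(
            air=AirStream(temperature=70.0),
            termination_moisture=1.0,
            duration=5100.0,
        )
        res = simulate(cfg)
        assert res.termination_reason == "target_moisture"
        assert res.termination_time < 5100.0
        assert res.average_moisture[-1] <= 1.0


class TestConvergence:
    def test_refinement_moves_toward_oracle(self):
        """Halving the mesh on the pinned-surface case shrinks the distance
        to the analytic series."""
        deff, duration = 8.689e-9, 1800.0
        dists = []
        for n in (20, 40, 80):
            cfg = dirichlet_limit_config(
                70.0, deff=deff, duration=duration, n_nodes=n, time_step=1.0
            )
            res = simulate(cfg)
            oracle = crank_mr(deff, 0.005, float(res.times[-1]), n_terms=50)
            dists.append(abs(res.moisture_ratio()[-1] - oracle))
        assert dists[2] < dists[0]

    def test_successive_levels_converge(self):
        cfg = SimulationConfig(
            air=AirStream(temperature=70.0), duration=1800.0
        )
        table = grid_time_convergence(cfg, refinement_levels=3)
        changes = table["relative_change"].to_numpy()[1:]
        assert np.all(np.diff(changes) < 0)

    def test_identical_configs_give_identical_results(self):
        cfg = SimulationConfig(
            air=AirStream(temperature=60.0), duration=900.0, snapshot_every=10**9
        )
        a, b = simulate(cfg), simulate(cfg)
        assert np.array_equal(a.average_moisture, b.average_moisture)


@pytest.fixture(scope="module")
def run2d():
    cfg = SimulationConfig(
        air=AirStream(temperature=70.0),
        domain=Domain(
            geometry="cylinder_2d_axisymmetric", n_nodes=15, n_radial=10
        ),
        time_step=60.0,
        duration=1800.0,
    )
    return simulate(cfg)


class TestAxisymmetric:
    def test_mass_balance_closes(self, run2d):
        assert run2d.mass_balance_residual < 1e-5

    def test_bounds_and_monotonicity(self, run2d):
        assert run2d.moisture.min() >= -1e-12
        assert run2d.moisture.max() <= 3.5657 * (1 + 1e-12)
        assert np.all(
            run2d.surface_moisture[1:] <= run2d.bottom_moisture[1:] + 1e-12
        )

    def test_average_temperature_approaches_air(self, run2d):
        assert run2d.average_temperature[-1] == pytest.approx(70.0, abs=0.5)

    def test_field_shapes(self, run2d):
        nt = len(run2d.times)
        assert run2d.moisture.shape == (nt, 10, 15)
        assert run2d.radii is not None and len(run2d.radii) == 10


class TestValidation:
    def test_config_invariants(self):
        with pytest.raises(ValueError, match="X0 > X_e"):
            SimulationConfig(
                air=AirStream(temperature=50.0),
                initial_moisture=0.01,
                equilibrium_moisture=0.01,
            )
        with pytest.raises(ValueError, match="time_step"):
            SimulationConfig(air=AirStream(temperature=50.0), time_step=0.0)

    def test_domain_invariants(self):
        with pytest.raises(ValueError, match="at least 10"):
            Domain(n_nodes=5)
        with pytest.raises(ValueError, match="geometry"):
            Domain(geometry="sphere")

    def test_unknown_temperature_needs_explicit_inputs(self):
        cfg = SimulationConfig(air=AirStream(temperature=55.0))
        with pytest.raises(ValueError, match="deff"):
            cfg.resolved_deff()
        with pytest.raises(KeyError, match="duration"):
            cfg.resolved_duration()
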