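"""Stiff-solver correctness: closed forms, reference integrator, conservation."""

import numpy as np
import pytest

from pefros import make_scenario
from pefros.network import StateError
from pefros.pulse_driver import default_channels
from pefros.simulate import (
    IntegrationError,
    KineticsEngine,
    assemble_rhs,
    integrate_network,
    simulate,
)

from conftest import rk4_integrate

TIGHT = {"rtol": 1e-10, "atol": 1e-22}


@pytest.fixture(scope="module")
def short_scenario():
    """Reduced protocol (3 pulses) for fast end-to-end checks."""
    scn = make_scenario("bsa_h2o2", h2o2=1e-3)
    return scn.replace(
        protocol=scn.protocol.__class__(n_pulses=3, pulse_width=100e-6,
                                        period=1.0, amplitude=1470.0),
        pulse_start=2.0, t_end=8.0)


@pytest.fixture(scope="module")
def short_trajectory(network, short_scenario):
    return simulate(network, short_scenario)


class TestClosedForms:
    def test_singlet_oxygen_decay_matches_exponential(self, network):
        k = network.reaction("8").rate_constant
        t = np.linspace(0.0, 2e-5, 21)
        res = integrate_network(network.subnetwork(["8"]), {"1O2": 1e-6}, t,
                                **TIGHT)
        exact = 1e-6 * np.exp(-k * t)
        assert np.max(np.abs(res["1O2"] - exact) / exact) < 1e-6

    def test_hydroxyl_recombination_matches_second_order_law(self, network):
        k = network.reaction("5b").rate_constant
        c0 = 1e-6
        t = np.linspace(0.0, 1e-3, 11)
        res = integrate_network(network.subnetwork(["5b"]), {"HO.": c0}, t,
                                **TIGHT)
        exact = 1.0 / (1.0 / c0 + 2.0 * k * t)
        assert np.max(np.abs(res["HO."] - exact) / exact) < 1e-6

    def test_singlet_oxygen_decay_default_tolerances(self, network):
        # the shipped solver contract alone is good to ~1e-4
        t = np.linspace(0.0, 2e-5, 5)
        res = integrate_network(network.subnetwork(["8"]), {"1O2": 1e-6}, t)
        exact = 1e-6 * np.exp(-2.9e5 * t)
        assert np.max(np.abs(res["1O2"] - exact) / exact) < 1e-3


class TestReferenceIntegrator:
    @pytest.mark.parametrize("rids, initial, t_end, n_steps", [
        (["19", "20"], {"Fe2+": 2e-6, "Fe3+": 2e-6, "H2O2": 1e-3}, 5.0, 2000),
        (["5a", "5b", "13"],
         {"HO.": 1e-6, "HO2.": 1e-7, "H2O2": 1e-4}, 1e-3, 4000),
        (["8", "9"], {"1O2": 1e-6}, 1e-5, 2000),
    ])
    def test_stiff_solver_agrees_with_rk4(self, network, rids, initial,
                                          t_end, n_steps):
        sub = network.subnetwork(rids)
        engine = KineticsEngine(sub, compartments=["bulk"], volumes_l=[1.0],
                                visible=("bulk",))
        y0 = engine.initial_state(initial)
        t = np.linspace(0.0, t_end, n_steps + 1)
        ref = rk4_integrate(lambda tt, yy: engine.rhs(tt, yy, False), y0, t)
        res = integrate_network(sub, initial, t[::200])
        for sid in initial:
            j = engine.species.index(sid)
            ref_c = ref[::200, j]
            got = res[sid]
            scale = np.max(ref_c)
            assert np.max(np.abs(got - ref_c)) / scale < 1e-3

    def test_sources_consistent_with_reference_partition(self, network):
        """Fast source path reproduces the public current-partition rates."""
        from pefros.pulse_driver import partition_current

        channels = default_channels(network)
        engine = KineticsEngine(network, compartments=["anode", "bulk",
                                                       "cathode"],
                                volumes_l=[1e-3, 1.0, 1e-3],
                                channels=channels, current_amplitude=10.0)
        y = engine.initial_state({"H2O2": 1e-3, "BSA": 6e-4, "3O2": 3e-4})
        dy_on = engine.rhs(0.0, y, True)
        dy_off = engine.rhs(0.0, y, False)
        src = (dy_on - dy_off)[: engine.n_c * engine.n_s].reshape(
            engine.n_c, engine.n_s)
        state = {sid: 0.0 for sid in engine.species}
        state.update({"H2O2": 1e-3, "BSA": 6e-4, "3O2": 3e-4})
        rates = partition_current(10.0, state, channels, "anode")
        ho_expected = rates["water_ros"] / 1e-3  # product HO., anode layer, M/s
        j = engine.species.index("HO.")
        assert src[0, j] == pytest.approx(ho_expected, rel=1e-9)


class TestConservation:
    def test_zero_ros_state_has_zero_derivatives(self, network):
        rhs, engine = assemble_rhs(network, compartments=["bulk"],
                                   volumes_l=[1.0], visible=("bulk",))
        y = engine.initial_state({})
        dy = rhs(0.0, y)
        assert np.allclose(dy, 0.0)

    def test_single_species_decay_rhs_is_linear(self, network):
        sub = network.subnetwork(["8"])
        rhs, engine = assemble_rhs(sub, compartments=["bulk"],
                                   volumes_l=[1.0], visible=("bulk",))
        k = sub.reaction("8").rate_constant
        y = engine.initial_state({"1O2": 2e-6})
        j = engine.species.index("1O2")
        assert rhs(0.0, y)[j] == pytest.approx(-k * 2e-6)

    def test_iron_is_conserved_by_rhs_at_random_state(self, network):
        rhs, engine = assemble_rhs(network, compartments=["bulk"],
                                   volumes_l=[1.0], visible=("bulk",))
        rng = np.random.default_rng(7)
        y = engine.initial_state({})
        y[: engine.n_s] = rng.uniform(1e-9, 1e-4, engine.n_s)
        dy = rhs(0.0, y)
        i2 = engine.species.index("Fe2+")
        i3 = engine.species.index("Fe3+")
        scale = max(abs(dy[i2]), abs(dy[i3]), 1e-30)
        assert abs(dy[i2] + dy[i3]) / scale < 1e-12

    def test_iron_and_enzymes_conserved_along_trajectory(self,
                                                         short_trajectory):
        # iron cycles between oxidation states and exchanges between boxes;
        # the volume-weighted chamber total must stay fixed
        traj = short_trajectory
        vols = np.array(traj.meta["volumes_l"])
        iron = sum(traj.concentration(s, comp) * vols[i]
                   for s in ("Fe2+", "Fe3+")
                   for i, comp in enumerate(traj.compartments))
        assert np.allclose(iron, iron[0], rtol=1e-6)
        for enzyme in ("SOD", "CAT"):
            c = traj.concentration(enzyme, "bulk")
            assert np.allclose(c, c[0], atol=1e-15)

    def test_no_emitters_without_ros_or_sources(self, network):
        scn = make_scenario("pb", h2o2=0.0)
        scn = scn.replace(protocol=scn.protocol.__class__(
            n_pulses=0, pulse_width=1e-4, period=1.0, amplitude=0.0),
            t_end=5.0)
        traj = simulate(network, scn)
        assert np.all(traj.emission_flux == 0.0)
        assert np.all(traj.cumulative_emission == 0.0)


class TestTrajectoryContract:
    def test_time_strictly_increasing(self, short_trajectory):
        assert np.all(np.diff(short_trajectory.time) > 0)

    def test_concentrations_nonnegative(self, short_trajectory):
        assert short_trajectory.concentrations.min() >= 0.0

    def test_emission_flux_nonnegative_and_counters_monotone(
            self, short_trajectory):
        assert short_trajectory.emission_flux.min() >= 0.0
        for k in range(short_trajectory.cumulative_emission.shape[1]):
            assert np.all(np.diff(
                short_trajectory.cumulative_emission[:, k]) >= 0.0)

    def test_charge_matches_protocol(self, short_trajectory):
        meta = short_trajectory.meta
        assert short_trajectory.charge[-1] == pytest.approx(
            meta["total_charge_C"], rel=1e-4)

    def test_pulses_deposit_protein_at_anode(self, short_trajectory):
        c_bsa = short_trajectory.concentration("BSA", "anode")
        assert c_bsa[-1] > c_bsa[0]
        assert short_trajectory.meta["delivered_mol_m2"] > 0.0

    def test_negative_initial_concentration_rejected(self, network):
        engine = KineticsEngine(network, compartments=["bulk"],
                                volumes_l=[1.0])
        with pytest.raises(StateError):
            engine.initial_state({"H2O2": -1e-3})

    def test_trajectory_tsv_round_trip(self, short_trajectory, tmp_path):
        path = tmp_path / "traj.tsv"
        short_trajectory.to_tsv(path)
        data = np.loadtxt(path, skiprows=1)
        assert data.shape[0] == len(short_trajectory.time)
        np.testing.assert_allclose(data[:, 0], short_trajectory.time)
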