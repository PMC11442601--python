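"""Desk calculators: field, current, migration, heating, coulometry."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import pefros.electrophysics as ep
from pefros.constants import water_viscosity
from pefros.electrophysics import (
    ChamberGeometry,
    GeometryError,
    PulseProtocol,
    SampleProperties,
)


class TestDomainTypes:
    def test_default_geometry_matches_machined_dimensions(self, geometry):
        # 26 mm discs, 2.00 mm gap -> 5.31 cm^2 and 1.06 mL
        assert geometry.cross_section_area * 1e4 == pytest.approx(5.31, rel=5e-3)
        assert geometry.volume * 1e6 == pytest.approx(1.06, rel=5e-3)

    def test_inconsistent_area_rejected(self):
        with pytest.raises(GeometryError):
            ChamberGeometry(electrode_gap=2e-3, electrode_diameter=26e-3,
                            cross_section_area=6e-4)

    def test_inconsistent_volume_rejected(self):
        with pytest.raises(GeometryError):
            ChamberGeometry(electrode_gap=2e-3, electrode_diameter=26e-3,
                            volume=2e-6)

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(GeometryError):
            ChamberGeometry(electrode_gap=0.0, electrode_diameter=26e-3)

    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError):
            PulseProtocol(n_pulses=10, pulse_width=2.0, period=1.0,
                          amplitude=100.0)

    def test_total_on_time(self, protocol):
        assert protocol.total_on_time == pytest.approx(30 * 100e-6)

    def test_sample_positivity_enforced(self):
        with pytest.raises(ValueError):
            SampleProperties(conductivity=-1.0)


class TestFieldAndCurrent:
    @pytest.mark.parametrize("amplitude, gap, expected", [
        (1470.0, 2.00e-3, 7.35e5),   # treatment protocol
        (0.0, 2.00e-3, 0.0),
        (100.0, 1.0e-3, 1.0e5),
    ])
    def test_field_strength(self, amplitude, gap, expected):
        prot = PulseProtocol(1, 100e-6, 1.0, amplitude)
        geom = ChamberGeometry(electrode_gap=gap, electrode_diameter=26e-3)
        assert ep.field_strength(prot, geom) == pytest.approx(expected)

    def test_theoretical_current_treatment_conditions(
            self, sample, geometry, protocol):
        i = ep.theoretical_current(sample, geometry, protocol)
        assert round(i, 1) == pytest.approx(12.9, abs=0.05)

    def test_theoretical_current_zero_conductivity(self, geometry, protocol):
        s = SampleProperties(conductivity=1e-30)
        assert ep.theoretical_current(s, geometry, protocol) < 1e-20

    def test_theoretical_current_hand_arithmetic(self):
        s = SampleProperties(conductivity=0.01)
        g = ChamberGeometry(electrode_gap=1e-3,
                            electrode_diameter=2 * math.sqrt(1e-4 / math.pi))
        p = PulseProtocol(1, 100e-6, 1.0, 100.0)
        assert ep.theoretical_current(s, g, p) == pytest.approx(0.1, rel=1e-6)

    @given(st.floats(min_value=10.0, max_value=3000.0))
    @settings(max_examples=25, deadline=None)
    def test_field_linear_in_voltage(self, geometry, amplitude):
        p1 = PulseProtocol(1, 100e-6, 1.0, amplitude)
        p2 = PulseProtocol(1, 100e-6, 1.0, 2 * amplitude)
        assert ep.field_strength(p2, geometry) == pytest.approx(
            2 * ep.field_strength(p1, geometry))


class TestMigrationAndAccumulation:
    def test_displacement_treatment_conditions(self, sample, protocol,
                                               geometry):
        d = ep.electromigration_displacement(sample, protocol, geometry)
        assert d == pytest.approx(31e-6, rel=0.02)

    def test_displacement_zero_field(self, sample, geometry):
        p = PulseProtocol(30, 100e-6, 1.0, 0.0)
        assert ep.electromigration_displacement(sample, p, geometry) == 0.0

    def test_displacement_hand_arithmetic(self, geometry):
        s = SampleProperties(bsa_mobility=1e-8)
        p = PulseProtocol(10, 100e-6, 1.0, 1e6 * geometry.electrode_gap)
        assert ep.electromigration_displacement(s, p, geometry) == \
            pytest.approx(1e-5, rel=1e-9)

    def test_displacement_capped_at_gap(self, geometry):
        s = SampleProperties(bsa_mobility=1.0)
        p = PulseProtocol(30, 100e-6, 1.0, 1470.0)
        assert ep.electromigration_displacement(s, p, geometry) == \
            geometry.electrode_gap

    @pytest.mark.parametrize("conc, disp, expected", [
        (0.6, 3.09e-5, 1.85e-5),   # 0.6 mol m^-3 protein, full pulse train
        (0.0, 1e-5, 0.0),
        (1.0, 1e-6, 1e-6),
    ])
    def test_accumulated_surface_amount(self, conc, disp, expected):
        assert ep.accumulated_surface_amount(conc, disp) == \
            pytest.approx(expected, rel=0.02)

    def test_accumulation_never_exceeds_depletion_bound(self, sample,
                                                        protocol, geometry):
        d = ep.electromigration_displacement(sample, protocol, geometry)
        gamma = ep.accumulated_surface_amount(sample.bsa_concentration, d)
        assert gamma <= sample.bsa_concentration * geometry.electrode_gap

    def test_monolayer_coverage_7nm_protein(self):
        assert ep.monolayer_coverage(7.0e-9) == pytest.approx(4.0e-8, rel=0.03)

    def test_monolayer_coverage_scaling(self):
        assert ep.monolayer_coverage(2e-9) == pytest.approx(
            ep.monolayer_coverage(1e-9) / 4)

    def test_monolayer_coverage_1nm(self):
        assert ep.monolayer_coverage(1.0e-9) == pytest.approx(1.918e-6,
                                                             rel=1e-3)

    def test_layer_count_hundreds(self):
        n = ep.layer_count(1.8e-5, 4.0e-8)
        assert n == pytest.approx(450, rel=1e-6)
        assert 100 <= n <= 1000

    def test_layer_count_edge_cases(self):
        assert ep.layer_count(4.0e-8, 4.0e-8) == 1.0
        assert ep.layer_count(0.0, 4.0e-8) == 0.0
        with pytest.raises(ZeroDivisionError):
            ep.layer_count(1e-5, 0.0)


class TestThermal:
    def test_joule_heating_treatment_conditions(self, geometry, protocol,
                                                sample):
        dt = ep.joule_heating_adiabatic(protocol, 12.5, geometry, sample)
        assert dt == pytest.approx(12.4, abs=0.3)

    def test_joule_heating_zero_current(self, geometry, protocol, sample):
        assert ep.joule_heating_adiabatic(protocol, 0.0, geometry, sample) == 0

    def test_joule_heating_litre_of_water(self):
        g = ChamberGeometry(electrode_gap=0.1,
                            electrode_diameter=2 * math.sqrt(1e-2 / math.pi))
        p = PulseProtocol(1, 0.5, 1.0, 200.0)  # 100 J into 1 kg of water
        s = SampleProperties(density=1.0 / g.volume, heat_capacity=4180.0)
        dt = ep.joule_heating_adiabatic(p, 1.0, g, s)
        assert dt == pytest.approx(100.0 / 4180.0, rel=1e-9)

    def test_joule_heating_is_energy_over_heat_capacity(self, geometry,
                                                        protocol, sample):
        dt = ep.joule_heating_adiabatic(protocol, 12.5, geometry, sample)
        energy = protocol.amplitude * 12.5 * protocol.total_on_time
        mass = sample.density * geometry.volume
        assert dt * mass * sample.heat_capacity == pytest.approx(energy)

    def test_current_rise_thermometry_observed_rise(self):
        # a 7.5 % current rise from 22 degC indicates ~3 K of warming
        dt = ep.temperature_from_current_rise(1.075, 22.0)
        assert dt == pytest.approx(3.0, abs=0.5)
        assert 22.0 + dt == pytest.approx(25.0, abs=0.5)

    def test_current_rise_identity(self):
        assert ep.temperature_from_current_rise(1.0, 22.0) == 0.0

    def test_current_rise_inverts_forward_map(self):
        ratio = water_viscosity(22.0) / water_viscosity(30.0)
        dt = ep.temperature_from_current_rise(ratio, 22.0)
        assert dt == pytest.approx(8.0, abs=0.01)

    @pytest.mark.parametrize("t_final", [25.0, 35.0, 50.0])
    def test_current_rise_round_trip(self, t_final):
        t0 = 20.0
        ratio = ep.current_ratio_from_temperature(t0, t_final)
        assert ep.temperature_from_current_rise(ratio, t0) == \
            pytest.approx(t_final - t0, abs=0.01)

    def test_current_rise_out_of_range(self):
        with pytest.raises(ValueError):
            ep.temperature_from_current_rise(water_viscosity(22.0)
                                             / water_viscosity(59.0), 58.0)
        with pytest.raises(ValueError):
            ep.temperature_from_current_rise(0.9, 22.0)


class TestCoulometryAndTransport:
    def test_faraday_amount_pulse_train_charge(self):
        q = 12.5 * 3e-3
        assert ep.faraday_amount(q, 2) == pytest.approx(1.94e-7, rel=1e-2)

    def test_faraday_amount_edges(self):
        assert ep.faraday_amount(0.0, 3) == 0.0
        assert ep.faraday_amount(96485.0, 1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ep.faraday_amount(1.0, 0)

    def test_faraday_ratio(self):
        predicted = ep.faraday_amount(0.0375, 2)
        assert ep.faraday_ratio(predicted / 2, 0.0375, 2) == \
            pytest.approx(0.5)

    @pytest.mark.parametrize("d, tau, expected", [
        (2.3e-9, 1e-6, 4.8e-8),    # hydroxyl radical, microsecond lifetime
        (1e-5, 0.0, 0.0),
        (1e-8, 1e-4, 1e-6),
    ])
    def test_diffusion_length(self, d, tau, expected):
        assert ep.diffusion_length(d, tau) == pytest.approx(expected, rel=0.01)

    def test_hydroxyl_range_is_tens_to_hundreds_of_nm(self):
        for tau in (1e-6, 4e-6):
            assert 1e-8 < ep.diffusion_length(2.3e-9, tau) < 3e-7

    def test_iron_content_of_protein_stock(self):
        # 6 ppm iron in the solid, dissolved at 40 mg/mL -> ~4 uM
        c = ep.iron_content_molar(6.0, 40.0)
        assert c * 1e6 == pytest.approx(4.3, abs=0.4)
        assert 2.0 <= c * 1e6 <= 6.0

    def test_physics_report_structure(self):
        rows = ep.physics_report()
        names = {r["quantity"] for r in rows}
        assert {"field strength", "theoretical current",
                "monolayer coverage"} <= names
        assert all({"value", "units", "formula"} <= set(r) for r in rows)
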