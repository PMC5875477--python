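import numpy as np
import pytest
from scipy import integrate, stats

from cbctdose.geometry import VoxelPhantom
from cbctdose.materials import attenuation, get_material, table_for
from cbctdose.spectrum import EnergySpectrum
from cbctdose.transport import (
    MEC2_KEV,
    BowtieFilter,
    GeometryError,
    ProtocolError,
    ScanProtocol,
    bowtie_transmission,
    compton_scattered_energy,
    make_bowtie,
    run_simulation,
    sample_compton,
    sample_interaction,
    sample_source_photon,
)

from conftest import hole_doses


def mono_spectrum(energy):
    return EnergySpectrum(np.array([float(energy)]), np.array([1.0]), float(energy))


def pencil_protocol(**kw):
    kw.setdefault("tube_potential_kvp", 60)
    kw.setdefault("detector_width_cm", 1e-3)
    kw.setdefault("detector_height_cm", 1e-3)
    kw.setdefault("rotation_deg", 1e-9)
    kw.setdefault("n_batches", 2)
    return ScanProtocol(fan_mode="full", **kw)


def water_cube(n=20, pitch_mm=5.0):
    labels = np.ones((n, n, n), np.uint16)
    return VoxelPhantom(labels, (pitch_mm,) * 3,
                        {1: get_material("water")}).centered()


class TestProtocol:
    def test_standard_and_low_dose_modes(self):
        std = ScanProtocol.standard()
        low = ScanProtocol.low_dose()
        assert (std.tube_potential_kvp, std.tube_current_ma, std.pulse_time_ms) == (125, 80, 25)
        assert (low.tube_potential_kvp, low.tube_current_ma, low.pulse_time_ms) == (125, 40, 10)
        assert low.mAs / std.mAs == pytest.approx(0.2, rel=1e-12)

    @pytest.mark.parametrize("kw", [dict(sad_cm=200), dict(rotation_deg=0),
                                    dict(rotation_deg=400), dict(tube_current_ma=0),
                                    dict(fan_mode="third")])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ProtocolError):
            ScanProtocol(**kw)


class TestSource:
    def test_gantry_angles_uniform_over_rotation(self):
        rng = np.random.default_rng(1)
        src = sample_source_photon(ScanProtocol.standard(),
                                   mono_spectrum(60), rng, size=100_000)
        stat = stats.kstest(src["gantry_deg"] / 360.0, "uniform")
        assert stat.pvalue > 0.01

    def test_half_fan_mean_lateral_angle_positive(self):
        rng = np.random.default_rng(2)
        src = sample_source_photon(ScanProtocol.standard(fan_mode="half"),
                                   mono_spectrum(60), rng, size=50_000)
        assert src["fan_deg"].mean() > 1.0

    def test_no_bowtie_gives_unit_weights(self):
        proto = ScanProtocol.standard()
        proto.bowtie = make_bowtie("none", proto.fan_angle_min_deg,
                                   proto.fan_angle_max_deg)
        rng = np.random.default_rng(3)
        src = sample_source_photon(proto, mono_spectrum(60), rng, size=1000)
        assert np.all(src["weight"] == 1.0)

    def test_directions_are_unit_vectors_on_source_circle(self):
        rng = np.random.default_rng(4)
        proto = ScanProtocol.standard()
        src = sample_source_photon(proto, mono_spectrum(60), rng, size=5000)
        assert np.allclose(np.linalg.norm(src["position"][:, :2], axis=1), 100.0)
        assert np.allclose(np.linalg.norm(src["direction"], axis=1), 1.0)


class TestBowtie:
    def test_zero_thickness_transmits_fully(self):
        b = make_bowtie("none", -8, 8)
        assert bowtie_transmission(b, 0.0, 60.0) == 1.0

    def test_full_fan_center_transmits_most_at_every_energy(self):
        proto = ScanProtocol.standard(fan_mode="full")
        b = proto.bowtie
        for e in (20, 60, 100, 125):
            t0 = bowtie_transmission(b, 0.0, e)
            tmax = bowtie_transmission(b, proto.fan_angle_max_deg, e)
            assert t0 >= tmax

    def test_transmission_matches_direct_attenuation_call(self):
        b = BowtieFilter("custom", get_material("aluminum"),
                         np.array([-10.0, 10.0]), np.array([2.0, 2.0]))
        expected = np.exp(-0.2 * float(attenuation(get_material("aluminum"), 60.0)))
        assert bowtie_transmission(b, 0.0, 60.0) == pytest.approx(expected, rel=1e-12)

    def test_angle_outside_profile_is_range_error(self):
        b = make_bowtie("full_fan", -8, 8)
        with pytest.raises(ProtocolError, match="outside"):
            b.thickness(30.0)

    def test_csv_profile_round_trip(self, tmp_path):
        p = tmp_path / "bow.csv"
        p.write_text("fan_angle_deg,thickness_mm\n-10,5.0\n0,0.5\n10,5.0\n")
        b = BowtieFilter.from_csv(p)
        assert b.thickness(0.0) == 0.5
        assert b.thickness(5.0) == pytest.approx(2.75)


class TestCompton:
    def test_scattered_energy_bounded_by_backscatter_closed_form(self):
        rng = np.random.default_rng(5)
        for e0 in (30.0, 80.0, 125.0):
            e_sc, theta = sample_compton(e0, rng, size=20_000)
            e_min = e0 / (1 + 2 * e0 / MEC2_KEV)
            assert np.all(e_sc >= e_min - 1e-9)
            assert np.all(e_sc <= e0 + 1e-9)
            assert compton_scattered_energy(e0, -1.0) == pytest.approx(e_min)

    def test_mean_cosine_matches_numerical_klein_nishina(self):
        e0 = 125.0
        a = e0 / MEC2_KEV
        emin = 1 / (1 + 2 * a)

        def p(eps):
            cos = 1 - (1 / eps - 1) / a
            return eps + 1 / eps - (1 - cos**2)

        def cos_of(eps):
            return 1 - (1 / eps - 1) / a

        num, _ = integrate.quad(lambda x: cos_of(x) * p(x), emin, 1)
        den, _ = integrate.quad(p, emin, 1)
        expected = num / den

        rng = np.random.default_rng(6)
        _, theta = sample_compton(e0, rng, size=1_000_000)
        cos = np.cos(theta)
        assert abs(cos.mean() - expected) < 3 * cos.std() / np.sqrt(cos.size)


class TestComptonProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(10.0, 150.0), st.integers(0, 2**31 - 1))
    def test_samples_respect_kinematic_bounds_for_any_energy(self, e0, seed):
        rng = np.random.default_rng(seed)
        e_sc, theta = sample_compton(e0, rng, size=200)
        e_min = e0 / (1 + 2 * e0 / MEC2_KEV)
        assert np.all(e_sc >= e_min - 1e-9)
        assert np.all(e_sc <= e0 + 1e-9)
        assert np.all((theta >= 0) & (theta <= np.pi))


class TestInteractionSampling:
    def test_compton_frequency_in_water_matches_partial_fraction(self):
        tab = table_for(get_material("water"))
        idx = int(np.searchsorted(tab.energy_grid, 80.0))
        frac = tab.mu_over_rho["incoherent"][idx] / tab.total[idx]
        rng = np.random.default_rng(7)
        draws = sample_interaction(get_material("water"), 80.0, rng, size=100_000)
        observed = np.mean(draws == "incoherent")
        sigma = np.sqrt(frac * (1 - frac) / draws.size)
        assert abs(observed - frac) < 3 * sigma

    def test_rayleigh_never_drawn_when_disabled(self):
        rng = np.random.default_rng(8)
        draws = sample_interaction(get_material("water"), 60.0, rng,
                                   size=20_000, include_coherent=False)
        assert not np.any(draws == "coherent")


class TestTransport:
    def test_vacuum_phantom_deposits_nothing(self):
        labels = np.zeros((8, 8, 8), np.uint16)
        ph = VoxelPhantom(labels, (10.0,) * 3,
                          {0: get_material("vacuum")}).centered()
        dm = run_simulation(ph, pencil_protocol(n_histories=5000, seed=1),
                            mono_spectrum(60))
        assert dm.edep_kev.sum() == 0.0
        assert dm.escaped_kev == pytest.approx(dm.emitted_kev)

    def test_beer_lambert_transmission_through_water_slab(self):
        ph = water_cube()
        n = 1_000_000
        dm = run_simulation(ph, pencil_protocol(n_histories=n, seed=11),
                            mono_spectrum(60))
        mu = float(attenuation(get_material("water"), 60.0))
        expected = np.exp(-mu * 10.0)
        observed = dm.unscattered_escaped_weight / dm.total_weight
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * sigma

    def test_energy_ledger_balances_to_one_part_per_million(self):
        ph = water_cube(10)
        dm = run_simulation(ph, pencil_protocol(n_histories=50_000, seed=12),
                            mono_spectrum(60))
        balance = dm.emitted_kev - dm.deposited_kev - dm.escaped_kev
        assert abs(balance) < 1e-6 * dm.emitted_kev

    def test_dose_variance_scales_inversely_with_histories(self, spectrum125):
        from conftest import run_ctdi

        _, _, small = run_ctdi("head", "full", spectrum125, 100_000, seed=13)
        _, _, large = run_ctdi("head", "full", spectrum125, 400_000, seed=13)
        m_s, s_s = small.region_dose("A", "kerma")
        m_l, s_l = large.region_dose("A", "kerma")
        assert m_l == pytest.approx(m_s, abs=3 * np.hypot(s_s, s_l))
        assert 1.2 < s_s / s_l < 3.5  # expect ~2 from the 4x history ratio

    def test_cutoff_halving_changes_dose_below_1pct(self, spectrum125):
        ph = water_cube(16, pitch_mm=10.0)
        doses = []
        for cutoff in (10.0, 5.0):
            proto = pencil_protocol(tube_potential_kvp=125,
                                    n_histories=150_000, seed=14)
            proto.cutoff_kev = cutoff
            dm = run_simulation(ph, proto, spectrum125)
            doses.append(dm.deposited_kev / dm.emitted_kev)
        assert abs(doses[1] - doses[0]) / doses[0] < 0.01

    def test_empty_phantom_is_geometry_error(self):
        ph = water_cube(4)
        ph.labels = ph.labels[:0]
        with pytest.raises((GeometryError, ValueError)):
            run_simulation(ph, pencil_protocol(n_histories=10, seed=1),
                           mono_spectrum(60))


class TestRotationalSymmetry:
    def test_peripheral_holes_statistically_equal_under_full_rotation(self, body_run):
        _, _, dm = body_run
        doses = hole_doses(dm)
        vals = {k: v for k, v in doses.items() if k != "center"}
        for a in vals:
            for b in vals:
                if a < b:
                    da, sa = vals[a]
                    db, sb = vals[b]
                    assert abs(da - db) < 3 * np.hypot(sa, sb), (a, b)
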