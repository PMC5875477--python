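import math

import numpy as np
import pytest

from cbctdose.dosimetry import (
    CalibrationFactor,
    DosimetryError,
    DosimetryReport,
    UNIT_CALIBRATION,
    avg_periphery,
    batch_uncertainty,
    calibrate,
    compare_reference,
    ctdiw,
    organ_dose,
    point_dose,
)
from cbctdose.geometry import VoxelPhantom
from cbctdose.materials import get_material
from cbctdose.spectrum import EnergySpectrum
from cbctdose.transport import DoseMap, ScanProtocol, run_simulation


class TestArithmetic:
    def test_avg_periphery_reproduces_printed_body_columns(self):
        assert round(avg_periphery([5.54, 5.34, 5.36, 5.43]), 2) == 5.42
        assert round(avg_periphery([1.25, 1.26, 1.21, 1.30]), 2) == 1.25

    def test_avg_periphery_of_equal_doses_is_identity(self):
        assert avg_periphery([2.5] * 4) == 2.5

    def test_avg_periphery_requires_exactly_four(self):
        with pytest.raises(DosimetryError):
            avg_periphery([1, 2, 3])

    def test_ctdiw_weighted_combination(self):
        assert round(ctdiw(3.50, 5.42), 2) == 4.78
        assert ctdiw(0.0, 3.0) == pytest.approx(2.0)
        assert ctdiw(4.0, 4.0) == pytest.approx(4.0)

    def test_ctdiw_rejects_negative(self):
        with pytest.raises(DosimetryError):
            ctdiw(-1.0, 2.0)

    def test_compare_reference_signed_difference(self):
        assert compare_reference(4.78, 4.65) == pytest.approx(0.13)
        assert compare_reference(1.09, 1.16) == pytest.approx(-0.07)
        assert compare_reference(3.0, 3.0) == 0.0


class TestCalibration:
    def test_anchor_is_a_fixed_point(self):
        proto = ScanProtocol.standard()
        cal = calibrate(0.123, 8.90, proto)
        assert cal.to_cgy(0.123, proto) == pytest.approx(8.90, rel=1e-12)

    def test_low_dose_is_exactly_20pct_of_standard(self):
        cal = calibrate(0.1, 8.90, ScanProtocol.standard())
        std = cal.to_cgy(0.1, ScanProtocol.standard(fan_mode="half"))
        low = cal.to_cgy(0.1, ScanProtocol.low_dose(fan_mode="half"))
        assert low / std == pytest.approx(400 / 2000, rel=1e-12)

    def test_doubling_ma_doubles_dose_exactly(self):
        cal = calibrate(0.1, 8.90, ScanProtocol.standard())
        p1 = ScanProtocol.standard()
        p2 = ScanProtocol(tube_current_ma=160, pulse_time_ms=25)
        assert cal.to_cgy(0.5, p2) == pytest.approx(2 * cal.to_cgy(0.5, p1))

    def test_zero_tally_rejected(self):
        with pytest.raises(DosimetryError):
            calibrate(0.0, 8.9, ScanProtocol.standard())
        with pytest.raises(DosimetryError):
            CalibrationFactor(-1.0)


def uniform_dosemap(shape=(4, 4, 4), value=2.0, n_histories=1, n_batches=1):
    dm = DoseMap(shape, 1.0, n_histories, n_batches)
    dm.kerma_kev_per_g[:] = value
    dm.edep_kev[:] = value  # with unit density/volume, dose == edep
    return dm


class TestPointDose:
    def test_uniform_field_gives_same_dose_for_any_mask(self):
        dm = uniform_dosemap(value=2.0)
        proto = ScanProtocol.standard()
        scale = proto.beam_solid_angle_sr * proto.mAs
        for mask_spec in [np.s_[:1], np.s_[1:3]]:
            mask = np.zeros(dm.shape, bool)
            mask[mask_spec] = True
            d, _ = point_dose(dm, mask, UNIT_CALIBRATION, proto)
            assert d == pytest.approx(2.0 * scale, rel=1e-12)

    def test_doubling_calibration_doubles_dose(self):
        dm = uniform_dosemap()
        proto = ScanProtocol.standard()
        mask = np.ones(dm.shape, bool)
        d1, _ = point_dose(dm, mask, CalibrationFactor(1.0), proto)
        d2, _ = point_dose(dm, mask, CalibrationFactor(2.0), proto)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_sigma_shrinks_as_inverse_sqrt_batches(self):
        # closed-form batch variance oracle on synthetic region tallies
        rng = np.random.default_rng(0)
        proto = ScanProtocol.standard()
        sigmas = {}
        for b in (4, 16):
            dm = DoseMap((2, 2, 2), 1.0, n_histories=b, n_batches=b)
            tallies = 1.0 + 0.1 * rng.standard_normal(b)
            dm.region_tallies["hole"] = {"kerma": tallies, "analog": tallies}
            expected = tallies.std(ddof=1) / math.sqrt(b)
            _, s = point_dose(dm, None, UNIT_CALIBRATION, proto, region_name="hole")
            assert s == pytest.approx(
                expected * proto.beam_solid_angle_sr * proto.mAs, rel=1e-12)
            sigmas[b] = s / (tallies.std(ddof=1) + 1e-300)
        assert sigmas[16] < sigmas[4]

    def test_empty_mask_rejected(self):
        dm = uniform_dosemap()
        with pytest.raises(DosimetryError):
            point_dose(dm, np.zeros(dm.shape, bool), UNIT_CALIBRATION,
                       ScanProtocol.standard())


class TestBatchUncertainty:
    def make_map(self, value):
        dm = DoseMap((2, 2, 2), 1.0, n_histories=1, n_batches=1)
        dm.edep_kev[:] = value
        return dm

    def test_identical_batches_have_zero_sigma(self):
        maps = [self.make_map(3.0) for _ in range(5)]
        assert np.all(batch_uncertainty(maps) == 0.0)

    def test_two_batches_closed_form(self):
        maps = [self.make_map(1.0 - 0.25), self.make_map(1.0 + 0.25)]
        assert np.allclose(batch_uncertainty(maps), 0.25)

    def test_poisson_batches_match_analytic_standard_error(self):
        rng = np.random.default_rng(3)
        lam = 400.0
        b = 10
        maps = [self.make_map(rng.poisson(lam)) for _ in range(b)]
        sigma = batch_uncertainty(maps)[0, 0, 0]
        analytic = math.sqrt(lam / b)
        # sigma of the sigma estimate ~ analytic / sqrt(2(b-1))
        assert abs(sigma - analytic) < 3 * analytic / math.sqrt(2 * (b - 1))

    def test_single_batch_rejected(self):
        with pytest.raises(DosimetryError, match="2"):
            batch_uncertainty([self.make_map(1.0)])


def two_organ_phantom():
    labels = np.ones((6, 6, 12), np.uint16)
    organs = np.zeros_like(labels)
    organs[:, :, 2:4] = 1  # anterior organ (+y is source side; here use x split)
    organs[:, :, 8:10] = 2
    return VoxelPhantom(labels, (10.0, 10.0, 10.0),
                        {1: get_material("soft_tissue")},
                        organ_labels=organs,
                        organ_names={1: "near", 2: "far"}).centered()


class TestOrganDose:
    def test_uniform_field_gives_equal_organ_doses(self):
        ph = two_organ_phantom()
        dm = DoseMap(ph.labels.shape, ph.voxel_volume_cm3, 1, 1)
        dm.edep_kev[:] = 5.0
        doses = organ_dose(dm, ph, UNIT_CALIBRATION, ScanProtocol.standard())
        assert doses["near"][0] == pytest.approx(doses["far"][0], rel=1e-12)

    def test_merged_organs_give_mass_weighted_mean(self):
        ph = two_organ_phantom()
        dm = DoseMap(ph.labels.shape, ph.voxel_volume_cm3, 1, 1)
        dm.edep_kev[:, :, 2:4] = 2.0
        dm.edep_kev[:, :, 8:10] = 6.0
        proto = ScanProtocol.standard()
        doses = organ_dose(dm, ph, UNIT_CALIBRATION, proto)
        merged = VoxelPhantom(ph.labels, ph.pitch_mm, ph.materials,
                              ph.origin_mm,
                              np.where(ph.organ_labels > 0, 1, 0).astype(np.uint16),
                              {1: "both"})
        both = organ_dose(dm, merged, UNIT_CALIBRATION, proto)["both"][0]
        assert both == pytest.approx((doses["near"][0] + doses["far"][0]) / 2,
                                     rel=1e-12)

    def test_stationary_beam_depth_ordering(self):
        # anterior organ (toward the stationary source at +y) must receive
        # more dose than the posterior organ: depth attenuation ordering
        labels = np.ones((6, 20, 6), np.uint16)
        organs = np.zeros_like(labels)
        organs[:, 15:18, :] = 1  # +y side, shallow
        organs[:, 2:5, :] = 2    # -y side, deep
        ph = VoxelPhantom(labels, (10.0, 10.0, 10.0),
                          {1: get_material("soft_tissue")},
                          organ_labels=organs,
                          organ_names={1: "anterior", 2: "posterior"}).centered()
        proto = ScanProtocol(rotation_deg=1e-9, fan_mode="full",
                             detector_width_cm=4, detector_height_cm=4,
                             n_histories=40_000, n_batches=2, seed=5)
        proto.bowtie.thickness_mm[:] = 0.0
        spec = EnergySpectrum(np.array([60.0]), np.array([1.0]), 60.0)
        dm = run_simulation(ph, proto, spec)
        doses = organ_dose(dm, ph, UNIT_CALIBRATION, proto)
        assert doses["anterior"][0] > doses["posterior"][0]

    def test_phantom_without_organs_rejected(self):
        ph = two_organ_phantom()
        ph.organ_names = {}
        dm = DoseMap(ph.labels.shape, ph.voxel_volume_cm3, 1, 1)
        with pytest.raises(DosimetryError):
            organ_dose(dm, ph, UNIT_CALIBRATION, ScanProtocol.standard())


class TestReport:
    def test_internal_consistency_validation(self):
        rep = DosimetryReport(
            point_doses={"center": (3.50, 0.1), "A": (5.54, 0.1), "B": (5.34, 0.1),
                         "C": (5.36, 0.1), "D": (5.43, 0.1)},
            avg_periphery=avg_periphery([5.54, 5.34, 5.36, 5.43]))
        rep.ctdiw = ctdiw(3.50, rep.avg_periphery)
        rep.validate()
        rep.ctdiw += 0.01
        with pytest.raises(DosimetryError):
            rep.validate()

    def test_csv_and_json_outputs(self, tmp_path):
        rep = DosimetryReport(point_doses={"center": (1.0, 0.1)},
                              organ_doses={"liver": (2.0, 0.2)})
        rep.to_csv(tmp_path / "r.csv")
        payload = rep.to_json(tmp_path / "r.json")
        assert "dose_cGy" in (tmp_path / "r.csv").read_text()
        assert payload["organ_doses"]["liver"] == [2.0, 0.2]
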