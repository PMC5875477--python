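"""Dose reporting: point doses, weighted CTDI, organ doses, calibration.

Raw transport tallies are mean doses per history in keV/g. Absolute doses in
cGy follow from a single-point calibration: the factor is anchored so that one
reference quantity (by default the simulated head-phantom standard-mode CTDIw)
reproduces a known value, and thereafter dose scales exactly linearly with
mA x ms and with the beam's angular acceptance. The weighted CTDI combines the
central hole with the mean of the four peripheral holes as
CTDIw = (1/3) center + (2/3) mean(periphery).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .geometry import VoxelPhantom, organ_mask
from .transport import DoseMap, ScanProtocol


class DosimetryError(ValueError):
    """Invalid dosimetry inputs."""


@dataclass
class CalibrationFactor:
    """Scale from tally units (keV/g per history per sr per mAs) to cGy."""

    cgy_per_tally_unit: float
    anchor: str = "unit"
    mAs_reference: float = 1.0

    def __post_init__(self):
        if not self.cgy_per_tally_unit > 0:
            raise DosimetryError("calibration factor must be strictly positive")

    def to_cgy(self, tally_kev_per_g_per_history: float,
               protocol: ScanProtocol) -> float:
        """Absolute dose: tally x beam solid angle x mAs x factor."""
        return (tally_kev_per_g_per_history
                * protocol.beam_solid_angle_sr
                * protocol.mAs
                * self.cgy_per_tally_unit)


UNIT_CALIBRATION = CalibrationFactor(1.0, anchor="unit", mAs_reference=1.0)


def calibrate(sim_tally_per_history: float, reference_cgy: float,
              protocol: ScanProtocol, anchor: str = "") -> CalibrationFactor:
    """Anchor the absolute output so the simulated quantity equals ``reference_cgy``."""
    if sim_tally_per_history <= 0:
        raise DosimetryError("simulated tally must be positive to calibrate")
    if reference_cgy <= 0:
        raise DosimetryError("reference dose must be positive")
    factor = reference_cgy / (sim_tally_per_history
                              * protocol.beam_solid_angle_sr * protocol.mAs)
    return CalibrationFactor(factor, anchor or "user anchor", protocol.mAs)


def point_dose(dosemap: DoseMap, scoring_mask: Optional[np.ndarray],
               calibration: CalibrationFactor, protocol: ScanProtocol,
               phantom: Optional[VoxelPhantom] = None,
               region_name: Optional[str] = None,
               estimator: str = "kerma") -> Tuple[float, float]:
    """Mass-weighted mean dose over a scoring volume, in cGy with sigma.

    When ``region_name`` was registered at simulation time the uncertainty
    comes from exact batch statistics; otherwise it is estimated from the
    per-voxel squared accumulators (which neglects inter-voxel covariance).
    """
    if region_name is not None and region_name in dosemap.region_tallies:
        mean, sigma = dosemap.region_dose(region_name, estimator)
        return (calibration.to_cgy(mean, protocol),
                calibration.to_cgy(sigma, protocol))

    if scoring_mask is None or not np.asarray(scoring_mask).any():
        raise DosimetryError("scoring mask is empty")
    mask = np.asarray(scoring_mask, bool)
    if phantom is not None:
        mass = phantom.densities * phantom.voxel_volume_cm3
    else:
        mass = np.ones(dosemap.shape)
    msum = float(mass[mask].sum())
    if msum <= 0:
        raise DosimetryError("scoring volume has zero mass")
    if estimator == "kerma":
        x_tot, x_sq = dosemap.kerma_kev_per_g[mask], dosemap.kerma_sq[mask]
        coeff = mass[mask] / msum  # mass-weighted mean of per-mass kerma
    elif estimator == "analog":
        x_tot, x_sq = dosemap.edep_kev[mask], dosemap.edep_sq[mask]
        coeff = np.full(int(mask.sum()), 1.0 / msum)  # sum of edep over mass
    else:
        raise DosimetryError(f"unknown estimator {estimator!r}")
    per_hist = float((coeff * x_tot).sum()) / dosemap.n_histories
    b = dosemap.n_batches
    if b >= 2:
        # per-voxel batch variance; neglects inter-voxel covariance
        var_v = np.maximum((x_sq - x_tot**2 / b) / (b - 1), 0.0)
        var_region = float((coeff**2 * var_v).sum())
        n_per_batch = dosemap.n_histories / b
        sigma = math.sqrt(var_region / b) / n_per_batch
    else:
        sigma = float("nan")
    return (calibration.to_cgy(per_hist, protocol),
            calibration.to_cgy(sigma, protocol))


def avg_periphery(peripheral_doses: Sequence[float]) -> float:
    """Arithmetic mean of the four peripheral hole doses."""
    doses = list(peripheral_doses)
    if len(doses) != 4:
        raise DosimetryError(f"expected exactly 4 peripheral doses, got {len(doses)}")
    return sum(doses) / 4.0


def ctdiw(center: float, avg_periphery_dose: float) -> float:
    """Weighted CTDI: one third center plus two thirds mean periphery."""
    if center < 0 or avg_periphery_dose < 0:
        raise DosimetryError("point doses must be non-negative")
    return center / 3.0 + 2.0 * avg_periphery_dose / 3.0


def compare_reference(computed_cgy: float, reference_cgy: float) -> float:
    """Signed difference computed - reference, cGy."""
    return computed_cgy - reference_cgy


def batch_uncertainty(dosemaps: Sequence[DoseMap]) -> np.ndarray:
    """Per-voxel standard error of the mean over independent batch dose maps."""
    if len(dosemaps) < 2:
        raise DosimetryError("need at least 2 independent batches")
    stack = np.stack([m.edep_kev / m.n_histories for m in dosemaps])
    return stack.std(axis=0, ddof=1) / math.sqrt(len(dosemaps))


def organ_dose(dosemap: DoseMap, phantom: VoxelPhantom,
               calibration: CalibrationFactor, protocol: ScanProtocol,
               estimator: str = "analog") -> Dict[str, Tuple[float, float]]:
    """Mass-weighted mean absorbed dose per organ, cGy with sigma.

    Organs with zero mass are skipped with a warning. If the phantom labels
    tissue voxels that belong to no organ, they are reported as ``soft tissue``
    (merged with an existing soft-tissue organ when present, so the skin shell
    and remainder tissue count as soft tissue together).
    """
    import warnings

    if phantom.organ_labels is None or not phantom.organ_names:
        raise DosimetryError("phantom has no organ dictionary")
    out: Dict[str, Tuple[float, float]] = {}
    for name in phantom.organ_names.values():
        key = f"organ:{name}"
        if key in dosemap.region_tallies:
            out[name] = point_dose(dosemap, None, calibration, protocol,
                                   region_name=key, estimator=estimator)
            continue
        mask, mass = organ_mask(phantom, name)
        if mass <= 0:
            warnings.warn(f"organ {name!r} has zero mass; skipped", stacklevel=2)
            continue
        out[name] = point_dose(dosemap, mask, calibration, protocol,
                               phantom=phantom, estimator=estimator)
    return out


@dataclass
class DosimetryReport:
    """Point doses, CTDIw, organ doses and their uncertainties for one scan."""

    point_doses: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    avg_periphery: Optional[float] = None
    ctdiw: Optional[float] = None
    organ_doses: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    protocol_echo: Dict[str, object] = field(default_factory=dict)
    calibration_anchor: str = ""
    seed: Optional[int] = None
    reference_cgy: Optional[float] = None
    difference_cgy: Optional[float] = None

    def validate(self) -> None:
        """Check internal consistency of the stored summary quantities."""
        labels = {"A", "B", "C", "D"}
        if labels <= set(self.point_doses) and self.avg_periphery is not None:
            recomputed = avg_periphery([self.point_doses[l][0] for l in "ABCD"])
            if abs(recomputed - self.avg_periphery) > 1e-9:
                raise DosimetryError("avg_periphery inconsistent with point doses")
        if (self.ctdiw is not None and "center" in self.point_doses
                and self.avg_periphery is not None):
            if abs(ctdiw(self.point_doses["center"][0], self.avg_periphery)
                   - self.ctdiw) > 1e-9:
                raise DosimetryError("ctdiw inconsistent with its own fields")

    def to_rows(self):
        rows = []
        for label, (d, s) in self.point_doses.items():
            rows.append(("point", label, d, s))
        if self.avg_periphery is not None:
            rows.append(("summary", "avg_periphery", self.avg_periphery, float("nan")))
        if self.ctdiw is not None:
            rows.append(("summary", "ctdiw", self.ctdiw, float("nan")))
        if self.difference_cgy is not None:
            rows.append(("summary", "difference_vs_reference",
                         self.difference_cgy, float("nan")))
        for organ, (d, s) in self.organ_doses.items():
            rows.append(("organ", organ, d, s))
        return rows

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["quantity", "label", "dose_cGy", "sigma_cGy"])
            for row in self.to_rows():
                w.writerow(row)

    def to_json(self, path=None):
        payload = {
            "point_doses": {k: list(v) for k, v in self.point_doses.items()},
            "avg_periphery_cGy": self.avg_periphery,
            "ctdiw_cGy": self.ctdiw,
            "organ_doses": {k: list(v) for k, v in self.organ_doses.items()},
            "protocol": self.protocol_echo,
            "calibration_anchor": self.calibration_anchor,
            "seed": self.seed,
            "reference_cGy": self.reference_cgy,
            "difference_cGy": self.difference_cgy,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload
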