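"""kV x-ray source spectra: generation, CSV I/O, and beam-quality metrics.

The default source model is a filtered Kramers bremsstrahlung continuum,
fluence(E) ~ (E_max - E)/E attenuated by exp(-mu_Al(E) * t), plus tungsten
characteristic K lines below the tube potential. Exact tabulated spectra
(e.g. from standard report data) can be substituted through ``load_spectrum``.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
from scipy.optimize import brentq

from .materials import Material, attenuation, get_material, mass_energy_absorption

#: tungsten K-line energies (keV) and default relative intensities within the
#: characteristic component (Ka2, Ka1, Kb1, Kb2)
TUNGSTEN_K_LINES: Dict[float, float] = {57.98: 0.30, 59.32: 0.50, 67.24: 0.15, 69.07: 0.05}
DEFAULT_CHARACTERISTIC_FRACTION = 0.05
DEFAULT_INHERENT_FILTRATION_MM_AL = 2.5


class SpectrumError(ValueError):
    """Invalid spectrum parameters or malformed spectrum file."""


@dataclass
class EnergySpectrum:
    """Binned photon fluence vs energy.

    ``energy_bins`` are bin-center energies in keV, strictly increasing, with the
    last bin at the tube potential; ``relative_fluence`` is dimensionless and is
    normalized to unit sum by :meth:`normalize`.
    """

    energy_bins: np.ndarray
    relative_fluence: np.ndarray
    tube_potential: float  # kVp
    filtration_mm_al: float = 0.0

    def __post_init__(self):
        self.energy_bins = np.asarray(self.energy_bins, float)
        self.relative_fluence = np.asarray(self.relative_fluence, float)
        if self.energy_bins.size == 0:
            raise SpectrumError("empty spectrum")
        if self.energy_bins.size != self.relative_fluence.size:
            raise SpectrumError("energy and fluence arrays differ in length")
        if np.any(np.diff(self.energy_bins) <= 0):
            raise SpectrumError("energies must be strictly increasing")
        if np.any(self.relative_fluence < 0):
            raise SpectrumError("fluence values must be non-negative")
        if self.relative_fluence.sum() <= 0:
            raise SpectrumError("spectrum has zero total fluence")
        if self.energy_bins[-1] > self.tube_potential + 1e-9:
            raise SpectrumError("bin energy exceeds tube potential")

    def normalize(self) -> "EnergySpectrum":
        f = self.relative_fluence / self.relative_fluence.sum()
        return EnergySpectrum(self.energy_bins.copy(), f,
                              self.tube_potential, self.filtration_mm_al)

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy, keV."""
        w = self.relative_fluence
        return float(np.sum(self.energy_bins * w) / np.sum(w))


def generate_spectrum(tube_potential: float = 125.0,
                      added_filtration_mm_al: float = 0.0,
                      inherent_filtration_mm_al: float = DEFAULT_INHERENT_FILTRATION_MM_AL,
                      characteristic_fraction: float = DEFAULT_CHARACTERISTIC_FRACTION,
                      bin_width_kev: float = 1.0,
                      min_energy_kev: float = 10.0) -> EnergySpectrum:
    """Filtered-Kramers continuum plus tungsten K lines, 1 keV bins by default.

    The continuum follows fluence(E) ~ (E_max - E)/E with aluminium filtration
    applied as exp(-mu_Al(E) * t_total); K lines are added below the tube
    potential carrying ``characteristic_fraction`` of the total filtered fluence.
    """
    if tube_potential <= 0:
        raise SpectrumError(f"tube potential must be positive, got {tube_potential}")
    if not (40.0 <= tube_potential <= 150.0):
        raise SpectrumError("tube potential must lie in [40, 150] kVp")
    if added_filtration_mm_al < 0 or inherent_filtration_mm_al < 0:
        raise SpectrumError("filtration thicknesses must be >= 0")

    energies = np.arange(min_energy_kev, tube_potential + bin_width_kev / 2,
                         bin_width_kev)
    if abs(energies[-1] - tube_potential) > 1e-9:
        energies = np.append(energies, tube_potential)
    continuum = (tube_potential - energies) / energies
    t_cm = (added_filtration_mm_al + inherent_filtration_mm_al) / 10.0
    if t_cm > 0:
        al = get_material("aluminum")
        continuum = continuum * np.exp(-attenuation(al, energies) * t_cm)
    fluence = continuum.copy()

    if characteristic_fraction > 0:
        line_total = continuum.sum() * characteristic_fraction / (1 - characteristic_fraction)
        weights = {e: w for e, w in TUNGSTEN_K_LINES.items() if e < tube_potential}
        wsum = sum(weights.values())
        for e_line, w in weights.items():
            idx = int(np.argmin(np.abs(energies - e_line)))
            fluence[idx] += line_total * w / wsum

    spec = EnergySpectrum(energies, fluence, tube_potential,
                          added_filtration_mm_al + inherent_filtration_mm_al)
    return spec.normalize()


def write_spectrum(spectrum: EnergySpectrum, path) -> None:
    """Write the two-column spectrum CSV (header ``energy_keV,relative_fluence``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["energy_keV", "relative_fluence"])
        for e, f in zip(spectrum.energy_bins, spectrum.relative_fluence):
            writer.writerow([repr(float(e)), repr(float(f))])


def load_spectrum(path) -> EnergySpectrum:
    """Load and normalize a two-column (keV, relative fluence) CSV spectrum."""
    path = Path(path)
    energies, fluences = [], []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0] and rows[0][0].strip().lower().startswith("energy"):
        rows = rows[1:]
    for i, row in enumerate(rows, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            e, f = float(row[0]), float(row[1])
        except (ValueError, IndexError):
            raise SpectrumError(f"{path}: row {i} is not two numbers: {row}") from None
        if f < 0:
            raise SpectrumError(f"{path}: row {i} has negative fluence {f}")
        if energies and e <= energies[-1]:
            raise SpectrumError(f"{path}: row {i} energy {e} not strictly increasing")
        energies.append(e)
        fluences.append(f)
    if not energies:
        raise SpectrumError(f"{path}: no spectrum rows found")
    spec = EnergySpectrum(np.array(energies), np.array(fluences),
                          tube_potential=energies[-1])
    return spec.normalize()


def air_kerma_transmission(spectrum: EnergySpectrum, absorber: Material,
                           thickness_mm: float) -> float:
    """Relative air kerma behind ``thickness_mm`` of absorber (polychromatic)."""
    e = spectrum.energy_bins
    w = spectrum.relative_fluence * e * mass_energy_absorption(get_material("air"), e)
    mu = attenuation(absorber, e)
    return float(np.sum(w * np.exp(-mu * thickness_mm / 10.0)) / np.sum(w))


def half_value_layer(spectrum: EnergySpectrum, absorber: str | Material = "aluminum",
                     tol_mm: float = 1e-3) -> float:
    """Absorber thickness (mm) halving the air kerma, by bracketing + bisection."""
    if isinstance(absorber, str):
        absorber = get_material(absorber)
    if spectrum.energy_bins.size == 0 or spectrum.relative_fluence.sum() <= 0:
        raise SpectrumError("cannot compute HVL of an empty spectrum")

    def f(t):
        return air_kerma_transmission(spectrum, absorber, t) - 0.5

    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover
            raise SpectrumError("HVL bracket exceeded 10 m; check absorber data")
    return float(brentq(f, 0.0, hi, xtol=tol_mm))
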