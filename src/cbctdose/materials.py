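"""Photon interaction data and CT-number -> material/density conversion.

Materials are element mixtures; per-process mass attenuation coefficients
(photoelectric, incoherent/Compton, coherent/Rayleigh) and mass energy-absorption
coefficients come from compact embedded elemental tables on a 10-150 keV grid,
combined by the mixture rule and interpolated log-log. The CT conversion map
implements the piecewise-linear HU -> (material, density) binning used to turn
labeled CT volumes into transport media.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import _xsdata

E_MIN_KEV = 10.0
E_MAX_KEV = 150.0

PROCESSES = ("photoelectric", "incoherent", "coherent")


class MaterialError(ValueError):
    """Unknown element/material or invalid composition."""


class EnergyRangeError(ValueError):
    """Requested energy outside the tabulated 10-150 keV range."""


@dataclass(frozen=True)
class Material:
    """A homogeneous medium: name, bulk density, elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: Dict[str, float]  # element symbol -> mass fraction

    def __post_init__(self):
        if self.density <= 0:
            raise MaterialError(f"density must be positive, got {self.density}")
        tot = sum(self.composition.values())
        if abs(tot - 1.0) > 1e-6:
            raise MaterialError(
                f"mass fractions of {self.name!r} sum to {tot}, expected 1"
            )
        for el in self.composition:
            if el not in _xsdata.ELEMENTS:
                raise MaterialError(f"no tabulated data for element {el!r}")

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, dict(self.composition))


@dataclass
class CrossSectionTable:
    """Per-process mass attenuation data for one material on the common grid."""

    material: Material
    energy_grid: np.ndarray  # keV
    mu_over_rho: Dict[str, np.ndarray]  # process -> cm^2/g
    mu_en_over_rho: np.ndarray  # cm^2/g

    @property
    def total(self) -> np.ndarray:
        return sum(self.mu_over_rho[p] for p in PROCESSES)


def _loglog_interp(energy, grid, values):
    energy = np.asarray(energy, float)
    return np.exp(
        np.interp(np.log(energy), np.log(grid), np.log(np.maximum(values, 1e-300)))
    )


def mixture_table(composition: Dict[str, float], density: float,
                  name: str = "mixture") -> CrossSectionTable:
    """Build a cross-section table by mass-fraction-weighted sums of element data."""
    mat = Material(name, density, dict(composition))
    grid = _xsdata.ENERGY_GRID_KEV
    mor = {p: np.zeros_like(grid) for p in PROCESSES}
    muen = np.zeros_like(grid)
    for el, frac in composition.items():
        tab = _xsdata.ELEMENTS[el]
        for p in PROCESSES:
            mor[p] = mor[p] + frac * tab[p]
        muen = muen + frac * tab["mu_en"]
    if name in _xsdata.MUEN_OVERRIDES:
        muen = _xsdata.MUEN_OVERRIDES[name].copy()
    return CrossSectionTable(mat, grid.copy(), mor, muen)


def table_for(material: Material) -> CrossSectionTable:
    return mixture_table(material.composition, material.density, material.name)


def _check_range(energy) -> np.ndarray:
    energy = np.asarray(energy, float)
    if np.any(energy < E_MIN_KEV) or np.any(energy > E_MAX_KEV):
        raise EnergyRangeError(
            f"energy {energy} keV outside tabulated range "
            f"[{E_MIN_KEV}, {E_MAX_KEV}] keV"
        )
    return energy


def mass_attenuation(material: Material, energy, include_coherent: bool = True):
    """Total mass attenuation coefficient mu/rho (cm^2/g), log-log interpolated."""
    energy = _check_range(energy)
    tab = table_for(material)
    total = tab.mu_over_rho["photoelectric"] + tab.mu_over_rho["incoherent"]
    if include_coherent:
        total = total + tab.mu_over_rho["coherent"]
    return _loglog_interp(energy, tab.energy_grid, total)


def attenuation(material: Material, energy, include_coherent: bool = True):
    """Linear attenuation coefficient mu (1/cm) = (mu/rho)(E) * density."""
    return mass_attenuation(material, energy, include_coherent) * material.density


def mass_energy_absorption(material: Material, energy):
    """Mass energy-absorption coefficient mu_en/rho (cm^2/g)."""
    energy = _check_range(energy)
    tab = table_for(material)
    return _loglog_interp(energy, tab.energy_grid, tab.mu_en_over_rho)


# --------------------------------------------------------------------------
# bundled materials
# --------------------------------------------------------------------------

_AIR = {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828}
_TISSUE = {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
           "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}
_BONE = {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
         "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}
_ADIPOSE = {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
            "Na": 0.001, "S": 0.001, "Cl": 0.001}

PREDEFINED: Dict[str, Material] = {
    "vacuum": Material("vacuum", 1e-20, {"H": 1.0}),
    "air": Material("air", 0.0012041, _AIR),
    "water": Material("water", 1.0, {"H": 0.111894, "O": 0.888106}),
    "pmma": Material("pmma", 1.19, {"H": 0.080538, "C": 0.599848, "O": 0.319614}),
    "lung": Material("lung", 0.26, _TISSUE),
    "adipose": Material("adipose", 0.95, _ADIPOSE),
    "soft_tissue": Material("soft_tissue", 1.06, _TISSUE),
    "bone": Material("bone", 1.92, _BONE),
    "spongiosa": Material("spongiosa", 1.18, _BONE),
    "aluminum": Material("aluminum", 2.699, {"Al": 1.0}),
}


def get_material(name: str) -> Material:
    try:
        return PREDEFINED[name]
    except KeyError:
        raise MaterialError(
            f"unknown material {name!r}; available: {sorted(PREDEFINED)}"
        ) from None


# --------------------------------------------------------------------------
# CT-number conversion
# --------------------------------------------------------------------------

DEFAULT_CT_ANCHORS: List[Tuple[float, str, float]] = [
    (-1000.0, "air", 0.00121),
    (-700.0, "lung", 0.26),
    (-100.0, "adipose", 0.95),
    (0.0, "water", 1.0),
    (40.0, "soft_tissue", 1.06),
    (1300.0, "bone", 1.92),
]


@dataclass
class CTConversionMap:
    """Piecewise-linear HU -> mass-density map quantized into material bins.

    Each anchor segment is split into density bins no wider than
    ``density_tolerance``; every bin is a (Material, density) pair reusable for
    converting whole CT volumes. Ties at a breakpoint go to the higher segment;
    HU outside the anchored range is clamped.
    """

    anchors: List[Tuple[float, Material, float]]
    density_tolerance: float
    bins: List[Tuple[float, float, Material, float]] = field(default_factory=list)
    # (hu_lo, hu_hi, material-with-bin-density, bin density)

    def interpolated_density(self, ct_number: float) -> float:
        hu = np.array([a[0] for a in self.anchors])
        rho = np.array([a[2] for a in self.anchors])
        return float(np.interp(ct_number, hu, rho))

    def lookup(self, ct_number: float) -> Tuple[Material, float]:
        ct = min(max(ct_number, self.anchors[0][0]), self.anchors[-1][0])
        for lo, hi, mat, dens in self.bins:
            # half-open bins [lo, hi); final bin closed
            if lo <= ct < hi or (ct == hi == self.bins[-1][1]):
                return mat, dens
        raise AssertionError("bins do not cover anchored range")  # pragma: no cover

    def lookup_volume(self, hu_volume: np.ndarray):
        """Vectorized per-voxel conversion: label volume + bin dictionary."""
        edges = np.array([b[0] for b in self.bins] + [self.bins[-1][1]])
        clipped = np.clip(hu_volume, edges[0], edges[-1])
        idx = np.clip(np.searchsorted(edges, clipped, side="right") - 1,
                      0, len(self.bins) - 1)
        return idx.astype(np.int32), [(b[2], b[3]) for b in self.bins]


def build_ct_conversion(anchors: Sequence[Tuple[float, object, float]] | None = None,
                        density_tolerance: float = 0.05) -> CTConversionMap:
    """Quantize a piecewise-linear HU->density curve into material/density bins."""
    if anchors is None:
        anchors = DEFAULT_CT_ANCHORS
    if len(anchors) < 2:
        raise MaterialError("need at least 2 anchors")
    resolved = []
    for hu, mat, dens in anchors:
        if isinstance(mat, str):
            mat = get_material(mat)
        resolved.append((float(hu), mat, float(dens)))
    hus = [a[0] for a in resolved]
    if any(b <= a for a, b in zip(hus, hus[1:])):
        raise MaterialError(f"anchor CT numbers must be strictly increasing: {hus}")
    if density_tolerance <= 0:
        raise MaterialError("density_tolerance must be positive")

    cmap = CTConversionMap(resolved, density_tolerance)
    for (hu0, mat0, d0), (hu1, _mat1, d1) in zip(resolved, resolved[1:]):
        span = abs(d1 - d0)
        n_bins = max(1, math.ceil(span / density_tolerance - 1e-12))
        for k in range(n_bins):
            f_lo, f_hi = k / n_bins, (k + 1) / n_bins
            lo = hu0 + f_lo * (hu1 - hu0)
            hi = hu0 + f_hi * (hu1 - hu0)
            dens = d0 + f_lo * (d1 - d0)  # lower-edge density: anchors map to themselves
            cmap.bins.append((lo, hi, mat0.with_density(dens), dens))
    return cmap
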