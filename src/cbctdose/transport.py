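"""Monte Carlo photon transport of a rotating, bowtie-filtered cone beam.

The engine is an analog photon tracker on a voxel grid using Woodcock (delta)
tracking with an energy-dependent, grid-wide majorant attenuation coefficient.
Physics at 10-150 keV: photoelectric absorption (full local deposition),
incoherent scattering sampled from the free-electron Klein-Nishina cross
section with local deposition of the electron energy (collision-kerma
approximation; secondary-electron ranges are sub-millimetre at these
energies), and coherent scattering as a Thomson-like deflection without
deposition. Photons below the 10 keV cutoff deposit locally and terminate.

Continuous gantry rotation is modeled by drawing an independent uniform gantry
angle per photon; the bowtie filter enters as a multiplicative photon weight,
which keeps the transport itself analog. Alongside the analog energy
deposition map, a collision-kerma track estimator is tallied at every Woodcock
vertex (real or fictitious); it is the low-variance estimator used for the
air-filled scoring holes of CTDI phantoms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import VoxelPhantom
from .materials import (
    Material,
    PROCESSES,
    _loglog_interp,
    get_material,
    table_for,
)
from .spectrum import EnergySpectrum

MEC2_KEV = 510.99895
DEFAULT_CUTOFF_KEV = 10.0


class ProtocolError(ValueError):
    """Invalid scan-protocol parameters."""


class GeometryError(ValueError):
    """Degenerate transport geometry (empty phantom, zero majorant)."""


class PhysicsLedgerError(RuntimeError):
    """Per-run energy bookkeeping failed to balance."""


# --------------------------------------------------------------------------
# bowtie filter
# --------------------------------------------------------------------------


@dataclass
class BowtieFilter:
    """Aluminum compensator profile: fan angle (deg) -> thickness (mm).

    The default profiles equalize the attenuation of bowtie plus a water
    cylinder across the fan (16 cm equivalent for full-fan, 30 cm for
    half-fan) at a 60 keV design energy, clipped to [0.2, 30] mm. The
    half-fan profile is asymmetric following the lateral detector offset.
    """

    kind: str  # full_fan | half_fan | none
    material: Material
    fan_angles_deg: np.ndarray
    thickness_mm: np.ndarray
    lateral_offset_cm: float = 0.0

    def thickness(self, fan_angle_deg):
        ang = np.asarray(fan_angle_deg, float)
        lo, hi = self.fan_angles_deg[0], self.fan_angles_deg[-1]
        if np.any(ang < lo - 1e-9) or np.any(ang > hi + 1e-9):
            raise ProtocolError(
                f"fan angle {ang} deg outside bowtie profile [{lo:.3f}, {hi:.3f}]"
            )
        return np.interp(ang, self.fan_angles_deg, self.thickness_mm)

    @classmethod
    def from_csv(cls, path, kind: str = "custom") -> "BowtieFilter":
        """Load a profile CSV with header ``fan_angle_deg,thickness_mm``."""
        import csv as _csv

        angles, thick = [], []
        with open(path, newline="") as fh:
            for i, row in enumerate(_csv.reader(fh)):
                if i == 0 and row and not row[0].lstrip("-").replace(".", "").isdigit():
                    continue
                if not row:
                    continue
                angles.append(float(row[0]))
                thick.append(float(row[1]))
        return cls(kind, get_material("aluminum"), np.array(angles), np.array(thick))


def make_bowtie(kind: str, fan_angle_min_deg: float, fan_angle_max_deg: float,
                sad_cm: float = 100.0, design_energy_kev: float = 60.0,
                t_min_mm: float = 0.2, t_max_mm: float = 30.0,
                lateral_offset_cm: float = 0.0,
                design_radius_cm: Optional[float] = None) -> BowtieFilter:
    """Parametric water-cylinder compensator for the given fan acceptance.

    The full-fan profile flattens the attenuation of a water cylinder filling
    the imaged field of view (radius = SAD * tan(max fan angle)); the half-fan
    profile compensates a 30 cm water cylinder, asymmetrically because of the
    offset fan.
    """
    from .materials import attenuation

    al = get_material("aluminum")
    angles = np.linspace(fan_angle_min_deg - 0.2, fan_angle_max_deg + 0.2, 801)
    if kind == "none":
        return BowtieFilter("none", al, angles, np.zeros_like(angles))
    if design_radius_cm is not None:
        radius = design_radius_cm
    elif kind == "full_fan":
        radius = sad_cm * math.tan(math.radians(fan_angle_max_deg))
    elif kind == "half_fan":
        radius = 15.0
    else:
        raise ProtocolError(f"unknown bowtie kind {kind!r}")
    d = sad_cm * np.sin(np.radians(angles))  # lateral ray distance at isocenter
    chord = 2.0 * np.sqrt(np.maximum(radius**2 - d**2, 0.0))
    mu_w = float(attenuation(get_material("water"), design_energy_kev))
    mu_al = float(attenuation(al, design_energy_kev))
    t_mm = 10.0 * mu_w * (2 * radius - chord) / mu_al
    t_mm = np.clip(t_mm, t_min_mm, t_max_mm)
    return BowtieFilter(kind, al, angles, t_mm, lateral_offset_cm)


def bowtie_transmission(bowtie: BowtieFilter, fan_angle_deg, energy_kev):
    """exp(-mu_Al(E) * t(fan angle) / 10); deterministic."""
    from .materials import attenuation

    t_mm = bowtie.thickness(fan_angle_deg)
    mu = attenuation(bowtie.material, energy_kev)
    return np.exp(-mu * t_mm / 10.0)


# --------------------------------------------------------------------------
# scan protocol
# --------------------------------------------------------------------------


@dataclass
class ScanProtocol:
    """CBCT acquisition parameters: tube settings, geometry, fan mode, sampling.

    The standard mode is (125 kVp, 80 mA, 25 ms) and the low-dose mode
    (125 kVp, 40 mA, 10 ms), both a full clockwise 360-degree rotation with
    source-isocenter distance 100 cm and source-detector distance 150 cm.
    Dose scales exactly linearly with mA x ms at fixed geometry.
    """

    tube_potential_kvp: float = 125.0
    tube_current_ma: float = 80.0
    pulse_time_ms: float = 25.0
    rotation_deg: float = 360.0
    direction: str = "clockwise"
    fan_mode: str = "full"  # full | half
    bowtie: Optional[BowtieFilter] = None
    sad_cm: float = 100.0
    sdd_cm: float = 150.0
    detector_width_cm: float = 40.0
    detector_height_cm: float = 30.0
    half_fan_offset_cm: float = 14.8  # lateral detector shift, half-fan only
    n_histories: int = 2_000_000
    n_batches: int = 10
    seed: int = 0
    cutoff_kev: float = DEFAULT_CUTOFF_KEV
    include_coherent: bool = True
    pulses_per_rotation: int = 1

    def __post_init__(self):
        if self.tube_potential_kvp <= 0:
            raise ProtocolError("tube potential must be positive")
        if not self.sad_cm < self.sdd_cm:
            raise ProtocolError("SAD must be smaller than SDD")
        if not 0 < self.rotation_deg <= 360:
            raise ProtocolError("rotation must lie in (0, 360] degrees")
        if self.mAs <= 0:
            raise ProtocolError("mA x ms x pulses must be positive")
        if self.fan_mode not in ("full", "half"):
            raise ProtocolError(f"unknown fan mode {self.fan_mode!r}")
        if self.bowtie is None:
            self.bowtie = make_bowtie(
                {"full": "full_fan", "half": "half_fan"}[self.fan_mode],
                self.fan_angle_min_deg, self.fan_angle_max_deg,
                sad_cm=self.sad_cm,
                lateral_offset_cm=self.lateral_offset_cm,
            )

    @property
    def lateral_offset_cm(self) -> float:
        return self.half_fan_offset_cm if self.fan_mode == "half" else 0.0

    @property
    def fan_angle_min_deg(self) -> float:
        off = self.lateral_offset_cm
        return math.degrees(math.atan((off - self.detector_width_cm / 2) / self.sdd_cm))

    @property
    def fan_angle_max_deg(self) -> float:
        off = self.lateral_offset_cm
        return math.degrees(math.atan((off + self.detector_width_cm / 2) / self.sdd_cm))

    @property
    def cone_half_angle_deg(self) -> float:
        return math.degrees(math.atan(self.detector_height_cm / 2 / self.sdd_cm))

    @property
    def mAs(self) -> float:
        """Tube charge per rotation, mA x ms x pulses / 1000."""
        return self.tube_current_ma * self.pulse_time_ms * self.pulses_per_rotation / 1e3

    @property
    def beam_solid_angle_sr(self) -> float:
        """Angular acceptance of the collimated fan/cone (small-angle product)."""
        dphi = math.radians(self.fan_angle_max_deg - self.fan_angle_min_deg)
        dpsi = 2 * math.radians(self.cone_half_angle_deg)
        return dphi * dpsi

    @classmethod
    def standard(cls, fan_mode: str = "full", **kw) -> "ScanProtocol":
        return cls(tube_potential_kvp=125, tube_current_ma=80, pulse_time_ms=25,
                   fan_mode=fan_mode, **kw)

    @classmethod
    def low_dose(cls, fan_mode: str = "full", **kw) -> "ScanProtocol":
        return cls(tube_potential_kvp=125, tube_current_ma=40, pulse_time_ms=10,
                   fan_mode=fan_mode, **kw)

    def with_mode(self, standard: bool) -> "ScanProtocol":
        ma, ms = (80, 25) if standard else (40, 10)
        return replace(self, tube_current_ma=ma, pulse_time_ms=ms)


# --------------------------------------------------------------------------
# dose map
# --------------------------------------------------------------------------


@dataclass
class DoseMap:
    """Per-voxel tallies of one simulation: analog deposition and kerma estimate.

    ``edep_kev`` is the analog deposited energy (keV, weight-multiplied) summed
    over all histories; ``kerma_kev_per_g`` is the Woodcock collision-kerma
    estimate. The squared accumulators hold per-batch sums of squares for
    uncertainty estimation, and ``region_tallies`` per-batch mass-weighted mean
    doses (keV/g per history) for any scoring regions registered at run time.
    """

    shape: Tuple[int, int, int]
    voxel_volume_cm3: float
    n_histories: int
    n_batches: int
    per_history: bool = True
    edep_kev: np.ndarray = None
    edep_sq: np.ndarray = None
    kerma_kev_per_g: np.ndarray = None
    kerma_sq: np.ndarray = None
    region_tallies: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    emitted_kev: float = 0.0
    deposited_kev: float = 0.0
    escaped_kev: float = 0.0
    #: summed weight of photons leaving the grid without any real interaction
    unscattered_escaped_weight: float = 0.0
    #: summed weight of all source photons
    total_weight: float = 0.0

    def __post_init__(self):
        for name in ("edep_kev", "edep_sq", "kerma_kev_per_g", "kerma_sq"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.shape))

    def dose_kev_per_g(self, densities: np.ndarray) -> np.ndarray:
        """Analog absorbed dose per history, keV/g per voxel."""
        mass = np.maximum(densities * self.voxel_volume_cm3, 1e-300)
        return self.edep_kev / mass / self.n_histories

    def region_dose(self, name: str, estimator: str = "kerma") -> Tuple[float, float]:
        """Mean and standard error of a registered region tally (keV/g/history)."""
        batches = self.region_tallies[name][estimator]
        mean = float(batches.mean())
        if batches.size < 2:
            return mean, float("nan")
        sigma = float(batches.std(ddof=1) / math.sqrt(batches.size))
        return mean, sigma


# --------------------------------------------------------------------------
# sampling primitives
# --------------------------------------------------------------------------


def compton_scattered_energy(energy_kev, cos_theta):
    """Compton kinematics: E' = E / (1 + (E/mec2)(1 - cos theta))."""
    e = np.asarray(energy_kev, float)
    return e / (1.0 + e / MEC2_KEV * (1.0 - np.asarray(cos_theta, float)))


def _sample_kn_eps_cos(energy_kev: np.ndarray, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Rejection-sample eps = E'/E from the Klein-Nishina distribution.

    p(eps) ~ eps + 1/eps - sin^2(theta(eps)) on [1/(1+2a), 1], bounded by
    eps_min + 1/eps_min; exact for free electrons at rest.
    """
    e = np.asarray(energy_kev, float)
    a = e / MEC2_KEV
    emin = 1.0 / (1.0 + 2.0 * a)
    bound = emin + 1.0 / emin
    eps = np.empty_like(e)
    todo = np.ones(e.shape, bool)
    while todo.any():
        n = int(todo.sum())
        cand = emin[todo] + rng.random(n) * (1.0 - emin[todo])
        cos = 1.0 - (1.0 / cand - 1.0) / a[todo]
        p = cand + 1.0 / cand - (1.0 - cos**2)
        acc = rng.random(n) * bound[todo] <= p
        idx = np.flatnonzero(todo)[acc]
        eps[idx] = cand[acc]
        todo[idx] = False
    cos = 1.0 - (1.0 / eps - 1.0) / a
    return eps, np.clip(cos, -1.0, 1.0)


def sample_compton(energy_kev, rng, size: Optional[int] = None):
    """Sample (scattered energy keV, scatter angle rad) from Klein-Nishina."""
    e = np.asarray(energy_kev, float)
    scalar = e.ndim == 0 and size is None
    if e.ndim == 0:
        e = np.full(size if size else 1, float(e))
    eps, cos = _sample_kn_eps_cos(e, rng)
    e_out, theta = e * eps, np.arccos(cos)
    if scalar:
        return float(e_out[0]), float(theta[0])
    return e_out, theta


def _sample_thomson_cos(n: int, rng) -> np.ndarray:
    """Sample cos(theta) from the Thomson angular law ~ (1 + cos^2)."""
    out = np.empty(n)
    todo = np.ones(n, bool)
    while todo.any():
        m = int(todo.sum())
        c = rng.random(m) * 2.0 - 1.0
        acc = rng.random(m) * 2.0 <= 1.0 + c**2
        idx = np.flatnonzero(todo)[acc]
        out[idx] = c[acc]
        todo[idx] = False
    return out


def sample_interaction(material: Material, energy_kev: float, rng,
                       size: Optional[int] = None,
                       include_coherent: bool = True):
    """Draw interaction process(es) proportional to partial attenuation."""
    tab = table_for(material)
    parts = []
    for p in PROCESSES:
        if p == "coherent" and not include_coherent:
            parts.append(0.0)
        else:
            parts.append(float(_loglog_interp(energy_kev, tab.energy_grid,
                                              tab.mu_over_rho[p])))
    parts = np.array(parts)
    probs = parts / parts.sum()
    names = np.array(PROCESSES)
    draw = rng.choice(len(names), size=size, p=probs)
    if size is None:
        return str(names[draw])
    return names[draw]


def _rotate_directions(d: np.ndarray, cos_t: np.ndarray, rng) -> np.ndarray:
    """Rotate unit vectors by polar angle acos(cos_t) and uniform azimuth."""
    n = d.shape[0]
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    phi = rng.random(n) * 2.0 * np.pi
    # orthonormal frame around each direction
    helper = np.zeros_like(d)
    use_z = np.abs(d[:, 2]) < 0.9
    helper[use_z, 2] = 1.0
    helper[~use_z, 0] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    new = (cos_t[:, None] * d
           + (sin_t * np.cos(phi))[:, None] * u
           + (sin_t * np.sin(phi))[:, None] * v)
    return new / np.linalg.norm(new, axis=1, keepdims=True)


# --------------------------------------------------------------------------
# source sampling
# --------------------------------------------------------------------------


def sample_source_photon(protocol: ScanProtocol, spectrum: EnergySpectrum, rng,
                         size: int = 1):
    """Sample source photons: position on the SAD circle at a uniform gantry
    angle over the rotation arc, direction uniform over the fan/cone
    acceptance, energy from the spectrum, weight from the bowtie transmission.

    Returns a dict with ``position`` (cm), ``direction`` (unit), ``energy``
    (keV), ``weight`` and ``gantry_deg``/``fan_deg`` diagnostics.
    """
    n = int(size)
    gantry = rng.random(n) * protocol.rotation_deg
    sign = -1.0 if protocol.direction == "clockwise" else 1.0
    th = np.radians(gantry)
    pos = np.column_stack([
        sign * protocol.sad_cm * np.sin(th),
        protocol.sad_cm * np.cos(th),
        np.zeros(n),
    ])
    d0 = -pos / protocol.sad_cm
    u = np.column_stack([-d0[:, 1], d0[:, 0], np.zeros(n)])  # cross(z, d0)

    phi = np.radians(protocol.fan_angle_min_deg
                     + rng.random(n) * (protocol.fan_angle_max_deg
                                        - protocol.fan_angle_min_deg))
    psi_max = math.radians(protocol.cone_half_angle_deg)
    psi = (rng.random(n) * 2.0 - 1.0) * psi_max
    direction = (np.cos(psi)[:, None] * (np.cos(phi)[:, None] * d0
                                         + np.sin(phi)[:, None] * u))
    direction[:, 2] += np.sin(psi)

    cdf = np.cumsum(spectrum.relative_fluence)
    cdf /= cdf[-1]
    energy = spectrum.energy_bins[np.searchsorted(cdf, rng.random(n))]

    weight = np.asarray(bowtie_transmission(protocol.bowtie, np.degrees(phi), energy),
                        float)
    return {"position": pos, "direction": direction, "energy": energy,
            "weight": weight, "gantry_deg": gantry, "fan_deg": np.degrees(phi)}


# --------------------------------------------------------------------------
# transport tables and the main loop
# --------------------------------------------------------------------------


class _TransportTables:
    """Per-label linear attenuation on a 1 keV grid, plus majorant and kerma
    coefficients. Process partials are rescaled so they sum exactly to the
    log-log-interpolated total (keeps Woodcock attenuation consistent with
    :func:`cbctdose.materials.attenuation`)."""

    def __init__(self, phantom: VoxelPhantom, e_max_kev: float,
                 include_coherent: bool = True):
        self.e_fine = np.arange(10.0, math.floor(e_max_kev) + 1.0)
        n_e = self.e_fine.size
        max_lbl = max(phantom.materials)
        self.mu_tot = np.zeros((max_lbl + 1, n_e))
        self.frac_pe = np.zeros((max_lbl + 1, n_e))
        self.frac_pe_inc = np.ones((max_lbl + 1, n_e))
        self.muen_mass = np.zeros((max_lbl + 1, n_e))
        for lbl, mat in phantom.materials.items():
            tab = table_for(mat)
            total_coarse = tab.mu_over_rho["photoelectric"] + tab.mu_over_rho["incoherent"]
            if include_coherent:
                total_coarse = total_coarse + tab.mu_over_rho["coherent"]
            total = _loglog_interp(self.e_fine, tab.energy_grid, total_coarse)
            parts = {p: _loglog_interp(self.e_fine, tab.energy_grid, tab.mu_over_rho[p])
                     for p in PROCESSES}
            if not include_coherent:
                parts["coherent"] = np.zeros(n_e)
            psum = parts["photoelectric"] + parts["incoherent"] + parts["coherent"]
            scale = np.where(psum > 0, total / np.maximum(psum, 1e-300), 0.0)
            for p in PROCESSES:
                parts[p] = parts[p] * scale
            self.mu_tot[lbl] = total * mat.density
            self.frac_pe[lbl] = parts["photoelectric"] / np.maximum(total, 1e-300)
            self.frac_pe_inc[lbl] = ((parts["photoelectric"] + parts["incoherent"])
                                     / np.maximum(total, 1e-300))
            self.muen_mass[lbl] = _loglog_interp(self.e_fine, tab.energy_grid,
                                                 tab.mu_en_over_rho)
        self.majorant = self.mu_tot.max(axis=0)
        if not np.all(self.majorant > 0):
            raise GeometryError("zero majorant attenuation on the energy grid")

    def ebin(self, energy: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(energy - 10.0), 0, self.e_fine.size - 1).astype(np.intp)


def _ray_box_entry(pos, direction, lo, hi):
    """Distance to entry of an axis-aligned box; inf when the ray misses."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / direction
        t1 = (lo[None, :] - pos) * inv
        t2 = (hi[None, :] - pos) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = (tmax > np.maximum(tmin, 0.0))
    entry = np.maximum(tmin, 0.0)
    return np.where(hit, entry, np.inf), hit


def run_simulation(phantom: VoxelPhantom, protocol: ScanProtocol,
                   spectrum: EnergySpectrum,
                   regions: Optional[Dict[str, np.ndarray]] = None,
                   chunk_size: int = 250_000,
                   max_steps: int = 200_000) -> DoseMap:
    """Run the batched Woodcock transport and return the filled :class:`DoseMap`.

    ``regions`` maps scoring-region names to boolean voxel masks; for each, the
    per-batch mass-weighted mean dose (keV/g per history) is recorded for both
    the analog-deposition and the collision-kerma estimator. The per-run energy
    ledger (emitted = deposited + escaped) is verified to 1e-6 relative.
    """
    if protocol.n_histories < 1:
        raise ProtocolError("n_histories must be >= 1")
    nz, ny, nx = phantom.labels.shape
    if phantom.labels.size == 0:
        raise GeometryError("empty phantom")
    tables = _TransportTables(phantom, protocol.tube_potential_kvp,
                              protocol.include_coherent)
    spec = spectrum.normalize()

    pitch_cm = np.array(phantom.pitch_mm, float) / 10.0
    lo = np.array(phantom.origin_mm, float) / 10.0
    hi = lo + pitch_cm * np.array([nx, ny, nz], float)
    vvox = phantom.voxel_volume_cm3
    labels_flat = phantom.labels.ravel().astype(np.intp)

    densities = phantom.label_densities()
    mass_flat = densities[labels_flat] * vvox

    regions = regions or {}
    region_flat = {name: np.flatnonzero(np.asarray(mask).ravel())
                   for name, mask in regions.items()}
    region_mass = {name: float(mass_flat[idx].sum())
                   for name, idx in region_flat.items()}

    n_batches = max(1, protocol.n_batches)
    batch_sizes = [protocol.n_histories // n_batches] * n_batches
    batch_sizes[-1] += protocol.n_histories - sum(batch_sizes)

    dosemap = DoseMap((nz, ny, nx), vvox, protocol.n_histories, n_batches)
    for name in region_flat:
        dosemap.region_tallies[name] = {
            "analog": np.zeros(n_batches), "kerma": np.zeros(n_batches)}

    ss = np.random.SeedSequence(protocol.seed)
    child_seeds = ss.spawn(n_batches)

    cutoff = protocol.cutoff_kev
    nvox = labels_flat.size

    for b, (n_b, cs) in enumerate(zip(batch_sizes, child_seeds)):
        rng = np.random.default_rng(cs)
        edep = np.zeros(nvox)
        kerma = np.zeros(nvox)
        emitted = deposited = escaped = 0.0
        virgin_escaped = total_w = 0.0

        done = 0
        while done < n_b:
            n = min(chunk_size, n_b - done)
            done += n
            src = sample_source_photon(protocol, spec, rng, size=n)
            pos, direction = src["position"], src["direction"]
            energy, weight = src["energy"].astype(float), src["weight"]
            emitted += float(np.sum(energy * weight))
            total_w += float(np.sum(weight))

            entry, hit = _ray_box_entry(pos, direction, lo, hi)
            escaped += float(np.sum(energy[~hit] * weight[~hit]))
            virgin_escaped += float(np.sum(weight[~hit]))
            pos = pos[hit] + direction[hit] * (entry[hit, None] + 1e-9)
            direction = direction[hit]
            energy, weight = energy[hit], weight[hit]
            virgin = np.ones(energy.size, bool)
            ebin = tables.ebin(energy)

            for _ in range(max_steps):
                if energy.size == 0:
                    break
                maj = tables.majorant[ebin]
                # cap steps so near-vacuum majorants cannot overflow positions
                step = np.minimum(-np.log(rng.random(energy.size)) / maj, 1e9)
                pos = pos + direction * step[:, None]

                ijk = np.floor((pos - lo[None, :]) / pitch_cm[None, :]).astype(np.intp)
                inside = ((ijk[:, 0] >= 0) & (ijk[:, 0] < nx)
                          & (ijk[:, 1] >= 0) & (ijk[:, 1] < ny)
                          & (ijk[:, 2] >= 0) & (ijk[:, 2] < nz))
                if not inside.all():
                    out = ~inside
                    escaped += float(np.sum(energy[out] * weight[out]))
                    virgin_escaped += float(np.sum(weight[out & virgin]))
                    pos, direction = pos[inside], direction[inside]
                    energy, weight, ebin = energy[inside], weight[inside], ebin[inside]
                    maj = maj[inside]
                    virgin = virgin[inside]
                    ijk = ijk[inside]
                    if energy.size == 0:
                        break
                flat = (ijk[:, 2] * ny + ijk[:, 1]) * nx + ijk[:, 0]
                lbl = labels_flat[flat]

                # collision-kerma estimator at every Woodcock vertex
                np.add.at(kerma, flat,
                          weight * energy * tables.muen_mass[lbl, ebin] / (maj * vvox))

                mu_loc = tables.mu_tot[lbl, ebin]
                real = rng.random(energy.size) < mu_loc / maj
                if not real.any():
                    continue
                r_idx = np.flatnonzero(real)
                r_lbl, r_ebin = lbl[r_idx], ebin[r_idx]
                r_flat = flat[r_idx]
                r_e, r_w = energy[r_idx], weight[r_idx]

                u = rng.random(r_idx.size)
                is_pe = u < tables.frac_pe[r_lbl, r_ebin]
                is_ray = u >= tables.frac_pe_inc[r_lbl, r_ebin]
                is_co = ~is_pe & ~is_ray

                if is_pe.any():
                    np.add.at(edep, r_flat[is_pe], r_e[is_pe] * r_w[is_pe])
                    deposited += float(np.sum(r_e[is_pe] * r_w[is_pe]))

                virgin[r_idx] = False
                kill = np.zeros(energy.size, bool)
                kill[r_idx[is_pe]] = True

                if is_co.any():
                    ci = r_idx[is_co]
                    eps, cos_t = _sample_kn_eps_cos(energy[ci], rng)
                    e_new = energy[ci] * eps
                    de = (energy[ci] - e_new) * weight[ci]
                    np.add.at(edep, flat[ci], de)
                    deposited += float(np.sum(de))
                    direction[ci] = _rotate_directions(direction[ci], cos_t, rng)
                    energy[ci] = e_new
                    below = e_new < cutoff
                    if below.any():
                        bi = ci[below]
                        np.add.at(edep, flat[bi], energy[bi] * weight[bi])
                        deposited += float(np.sum(energy[bi] * weight[bi]))
                        kill[bi] = True
                    ebin[ci] = tables.ebin(energy[ci])

                if is_ray.any():
                    ri = r_idx[is_ray]
                    cos_t = _sample_thomson_cos(ri.size, rng)
                    direction[ri] = _rotate_directions(direction[ri], cos_t, rng)

                if kill.any():
                    keep = ~kill
                    pos, direction = pos[keep], direction[keep]
                    energy, weight, ebin = energy[keep], weight[keep], ebin[keep]
                    virgin = virgin[keep]
            else:  # pragma: no cover
                escaped += float(np.sum(energy * weight))

        balance = emitted - deposited - escaped
        if abs(balance) > 1e-6 * max(emitted, 1e-300):
            raise PhysicsLedgerError(
                f"batch {b}: energy ledger off by {balance:.3e} keV "
                f"of {emitted:.3e} emitted"
            )

        dosemap.edep_kev += edep.reshape(nz, ny, nx)
        dosemap.edep_sq += (edep**2).reshape(nz, ny, nx)
        dosemap.kerma_kev_per_g += kerma.reshape(nz, ny, nx)
        dosemap.kerma_sq += (kerma**2).reshape(nz, ny, nx)
        dosemap.emitted_kev += emitted
        dosemap.deposited_kev += deposited
        dosemap.escaped_kev += escaped
        dosemap.unscattered_escaped_weight += virgin_escaped
        dosemap.total_weight += total_w

        for name, idx in region_flat.items():
            mass = region_mass[name]
            if mass <= 0:
                continue
            dosemap.region_tallies[name]["analog"][b] = (
                float(edep[idx].sum()) / mass / n_b)
            dosemap.region_tallies[name]["kerma"][b] = (
                float((kerma[idx] * mass_flat[idx]).sum()) / mass / n_b)

    return dosemap
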