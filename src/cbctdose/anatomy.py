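"""Synthetic anthropomorphic voxel phantoms for the four scan sites.

These are parametric stand-ins for a licensed labeled-anatomy phantom: an
elliptical soft-tissue trunk (or head + neck) with a 3 mm skin shell, a
posterior vertebral column with the spinal cord inside, and site-specific
ellipsoidal/tubular organs at anatomically ordered positions with small
seeded placement jitter. They reproduce the acquisition grid of the study
anatomy (512 x 512 in-plane at 0.84 x 0.84 mm^2, 2.5 mm slices; 120/95/160/65
slices for head-and-neck/chest/abdomen/pelvis) but make no claim of
subject-level anatomical fidelity: their role is to exercise the organ-dose
pipeline with physically consistent masses and positions.

Orientation: +y is anterior, +x is the patient's left, z increases toward
the head; the volume is centered on the isocenter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import PhantomError, VoxelPhantom
from .materials import get_material

SITE_SLICES = {"head_neck": 120, "chest": 95, "abdomen": 160, "pelvis": 65}

SITE_ORGANS = {
    "head_neck": ["eyeball", "brain", "cord", "soft tissue"],
    "chest": ["lung-right", "lung-left", "heart", "cord", "soft tissue"],
    "abdomen": ["liver", "intestine", "kidney-right", "kidney-left", "soft tissue"],
    "pelvis_male": ["bladder", "prostate", "rectum", "soft tissue"],
    "pelvis_female": ["bladder", "rectum", "ovary", "uterus", "soft tissue"],
}

_LABEL_AIR, _LABEL_TISSUE, _LABEL_LUNG, _LABEL_BONE = 0, 1, 2, 3


@dataclass
class SitePhantomSpec:
    """Parameters of one synthetic site phantom."""

    site: str
    n_slices: Optional[int] = None  # defaults per site: 120/95/160/65
    array: int = 512
    pixel_mm: float = 0.84
    slice_mm: float = 2.5
    downsample: int = 4
    sex: str = "male"  # selects the pelvic organ set
    seed: int = 0
    jitter_mm: float = 3.0

    def __post_init__(self):
        if self.site not in SITE_SLICES:
            raise PhantomError(f"unknown site {self.site!r}; {sorted(SITE_SLICES)}")
        if self.n_slices is None:
            self.n_slices = SITE_SLICES[self.site]
        if self.sex not in ("male", "female"):
            raise PhantomError("sex must be 'male' or 'female'")
        if self.array % self.downsample:
            raise PhantomError("downsample must divide the array size")

    @property
    def organ_set(self) -> List[str]:
        key = f"pelvis_{self.sex}" if self.site == "pelvis" else self.site
        return list(SITE_ORGANS[key])


def _ellipsoid(X, Y, Z, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2
            + ((Z - cz) / rz) ** 2) <= 1.0


def _tube(X, Y, Z, center_xy, radius, z_lo, z_hi) -> np.ndarray:
    cx, cy = center_xy
    return (((X - cx) ** 2 + (Y - cy) ** 2) <= radius**2) & (Z >= z_lo) & (Z <= z_hi)


def _body_masks(spec: SitePhantomSpec, X, Y, Z, skin_mm=3.0):
    """(body, interior) masks; skin shell = body & ~interior."""
    z_lo, z_hi = float(Z.min()), float(Z.max())

    def ellipse(a, b, shrink=0.0):
        return ((X / (a - shrink)) ** 2 + (Y / (b - shrink)) ** 2) <= 1.0

    if spec.site == "head_neck":
        neck_top = z_lo + (z_hi - z_lo) / 3.0
        head = ellipse(75, 90) & (Z > neck_top)
        head_in = ellipse(75, 90, skin_mm) & (Z > neck_top)
        neck = (((X - 0) ** 2 + (Y + 20) ** 2) <= 50.0**2) & (Z <= neck_top)
        neck_in = (((X - 0) ** 2 + (Y + 20) ** 2) <= (50.0 - skin_mm) ** 2) & (Z <= neck_top)
        return head | neck, head_in | neck_in
    half_axes = {"chest": (165, 110), "abdomen": (160, 105), "pelvis": (165, 100)}
    a, b = half_axes[spec.site]
    return ellipse(a, b), ellipse(a, b, skin_mm)


def _structures(spec: SitePhantomSpec, X, Y, Z, rng, jitter_scale: float):
    """Organ masks (ordered) + bone mask. Positions are canonical fractions of
    the body span with seeded jitter; sizes are fixed."""
    z_lo, z_hi = float(Z.min()), float(Z.max())

    def jit():
        return rng.uniform(-1, 1, 3) * spec.jitter_mm * jitter_scale

    organs: Dict[str, np.ndarray] = {}
    bone = np.zeros(np.broadcast_shapes(X.shape, Y.shape, Z.shape), bool)

    if spec.site == "head_neck":
        neck_top = z_lo + (z_hi - z_lo) / 3.0
        hc = (neck_top + z_hi) / 2.0
        brain_c = np.array([0, -5, hc + 25]) + jit()
        organs["brain"] = _ellipsoid(X, Y, Z, brain_c, (55, 60, 65))
        eye = jit()
        organs["eyeball"] = (
            _ellipsoid(X, Y, Z, np.array([28, 62, hc + 5]) + eye, (11, 11, 11))
            | _ellipsoid(X, Y, Z, np.array([-28, 62, hc + 5]) + eye, (11, 11, 11)))
        cord_top = brain_c[2] - 70
        bone |= _tube(X, Y, Z, (0, -45), 13, z_lo, cord_top)
        organs["cord"] = _tube(X, Y, Z, (0, -45), 5, z_lo, cord_top)
        bone &= ~organs["cord"]
    elif spec.site == "chest":
        for name, sx in (("lung-right", -1), ("lung-left", 1)):
            c = np.array([sx * 88, -5, 5]) + jit()
            organs[name] = _ellipsoid(X, Y, Z, c, (45, 65, 90))
        organs["heart"] = _ellipsoid(X, Y, Z, np.array([10, 45, -25]) + jit(),
                                     (38, 38, 45))
        bone |= _tube(X, Y, Z, (0, -85), 13, z_lo, z_hi)
        organs["cord"] = _tube(X, Y, Z, (0, -85), 5, z_lo, z_hi)
        bone &= ~organs["cord"]
    elif spec.site == "abdomen":
        organs["liver"] = _ellipsoid(X, Y, Z, np.array([-55, 20, 60]) + jit(),
                                     (70, 60, 55))
        organs["intestine"] = _ellipsoid(X, Y, Z, np.array([0, 25, -90]) + jit(),
                                         (90, 55, 80))
        for name, sx in (("kidney-right", -1), ("kidney-left", 1)):
            c = np.array([sx * 60, -55, -10]) + jit()
            organs[name] = _ellipsoid(X, Y, Z, c, (25, 22, 45))
        bone |= _tube(X, Y, Z, (0, -80), 13, z_lo, z_hi)
    else:  # pelvis
        organs["bladder"] = _ellipsoid(X, Y, Z, np.array([0, 30, 0]) + jit(),
                                       (35, 30, 30))
        if spec.sex == "male":
            organs["prostate"] = _ellipsoid(X, Y, Z, np.array([0, 10, -45]) + jit(),
                                            (20, 18, 18))
        else:
            organs["uterus"] = _ellipsoid(X, Y, Z, np.array([0, -20, -10]) + jit(),
                                          (25, 16, 35))
            ov = jit()
            organs["ovary"] = (
                _ellipsoid(X, Y, Z, np.array([45, -10, 0]) + ov, (12, 12, 12))
                | _ellipsoid(X, Y, Z, np.array([-45, -10, 0]) + ov, (12, 12, 12)))
        organs["rectum"] = _tube(X, Y, Z, tuple(np.array([0, -58]) + jit()[:2]),
                                 11, z_lo, z_hi)
        bone |= _tube(X, Y, Z, (0, -82), 11, z_lo, z_hi)
    return organs, bone


def make_site_phantom(spec: SitePhantomSpec) -> VoxelPhantom:
    """Generate a deterministic-for-seed site phantom with labeled organs."""
    rng = np.random.default_rng(spec.seed)
    n_xy = spec.array // spec.downsample
    pitch_xy = spec.pixel_mm * spec.downsample
    nz = spec.n_slices

    x = (np.arange(n_xy) + 0.5) * pitch_xy - n_xy * pitch_xy / 2
    z = (np.arange(nz) + 0.5) * spec.slice_mm - nz * spec.slice_mm / 2
    X = x[None, None, :]
    Y = x[None, :, None]
    Z = z[:, None, None]

    full_shape = (nz, n_xy, n_xy)
    body, interior = _body_masks(spec, X, Y, Z)
    body = np.broadcast_to(body, full_shape)
    interior = np.broadcast_to(interior, full_shape)

    organs = bone = None
    for attempt in range(10):
        jitter_scale = 0.5**attempt
        cand_organs, cand_bone = _structures(spec, X, Y, Z, rng, jitter_scale)
        claimed = cand_bone.copy()
        ok = True
        for name, mask in cand_organs.items():
            mask &= interior  # organs stay strictly inside the skin shell
            cand_organs[name] = mask
            if not mask.any():
                ok = False
                break
            if (mask & claimed).any():
                ok = False
                break
            claimed |= mask
        if ok:
            organs, bone = cand_organs, cand_bone
            break
    if organs is None:
        raise PhantomError(
            f"organ placement failed after 10 jitter-shrink attempts ({spec.site})")

    labels = np.zeros(body.shape, np.uint16)
    labels[body] = _LABEL_TISSUE
    labels[bone & interior] = _LABEL_BONE
    organ_names: Dict[int, str] = {}
    organ_labels = np.zeros(body.shape, np.uint16)
    next_lbl = 1
    for name in spec.organ_set:
        if name == "soft tissue":
            continue
        organ_labels[organs[name]] = next_lbl
        organ_names[next_lbl] = name
        if name.startswith("lung"):
            labels[organs[name]] = _LABEL_LUNG
        next_lbl += 1
    if "soft tissue" in spec.organ_set:
        remainder = body & (organ_labels == 0) & (labels != _LABEL_BONE)
        organ_labels[remainder] = next_lbl
        organ_names[next_lbl] = "soft tissue"

    phantom = VoxelPhantom(
        labels=labels,
        pitch_mm=(pitch_xy, pitch_xy, spec.slice_mm),
        materials={
            _LABEL_AIR: get_material("air"),
            _LABEL_TISSUE: get_material("soft_tissue"),
            _LABEL_LUNG: get_material("lung"),
            _LABEL_BONE: get_material("spongiosa"),
        },
        organ_labels=organ_labels,
        organ_names=organ_names,
    ).centered()

    for name in spec.organ_set:
        inv = {v: k for k, v in organ_names.items()}
        if not (organ_labels == inv[name]).any():  # pragma: no cover
            raise PhantomError(f"organ {name!r} is empty after voxelization")
    return phantom


def phantom_summary(phantom: VoxelPhantom) -> pd.DataFrame:
    """One row per organ: name, voxel count, mass in grams."""
    if not phantom.organ_names:
        raise PhantomError("phantom has no organ dictionary")
    dens = phantom.densities
    vv = phantom.voxel_volume_cm3
    rows = []
    for lbl, name in sorted(phantom.organ_names.items()):
        mask = phantom.organ_labels == lbl
        rows.append({"organ": name, "voxels": int(mask.sum()),
                     "mass_g": float(dens[mask].sum() * vv)})
    return pd.DataFrame(rows)
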