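"""Voxel phantoms: CTDI PMMA cylinders with scoring holes, and interfile-style I/O.

Coordinate convention (used throughout the package): right-handed, origin at the
scanner isocenter, z along the rotation axis. Voxel indices are 0-based with
x-fastest raw ordering; in-memory arrays are indexed ``[z, y, x]`` (C order), so
the flattened array matches the raw file layout. Gantry angle 0 puts the source
on +y; rotation is clockwise when viewed from the source end.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .materials import Material, get_material


class PhantomError(ValueError):
    """Invalid phantom construction or file integrity failure."""


@dataclass
class VoxelPhantom:
    """A labeled voxel volume with per-label materials and optional organ labels.

    ``labels[z, y, x]`` indexes ``materials``; each label carries its own density
    through its :class:`~cbctdose.materials.Material`. ``origin_mm`` is the
    position of the corner of voxel (0, 0, 0) relative to the isocenter.
    """

    labels: np.ndarray  # (nz, ny, nx) integer material labels
    pitch_mm: Tuple[float, float, float]  # (dx, dy, dz)
    materials: Dict[int, Material]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_labels: Optional[np.ndarray] = None  # same shape, 0 = unassigned
    organ_names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        present = np.unique(self.labels)
        missing = [int(l) for l in present if int(l) not in self.materials]
        if missing:
            raise PhantomError(f"labels {missing} have no material dictionary entry")
        if self.organ_labels is not None:
            self.organ_labels = np.ascontiguousarray(self.organ_labels)
            if self.organ_labels.shape != self.labels.shape:
                raise PhantomError("organ label volume shape mismatch")
        names = list(self.organ_names.values())
        if len(names) != len(set(names)):
            raise PhantomError("organ names must be unique")

    @property
    def dims(self) -> Tuple[int, int, int]:
        """(nx, ny, nz)"""
        nz, ny, nx = self.labels.shape
        return nx, ny, nz

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.pitch_mm
        return dx * dy * dz * 1e-3

    def label_densities(self) -> np.ndarray:
        """Density per label index, g/cm^3 (dense array over max label)."""
        out = np.zeros(max(self.materials) + 1)
        for lbl, mat in self.materials.items():
            out[lbl] = mat.density
        return out

    @property
    def densities(self) -> np.ndarray:
        """Per-voxel mass density, g/cm^3."""
        return self.label_densities()[self.labels]

    def centered(self) -> "VoxelPhantom":
        """Return a copy whose volume center sits at the isocenter."""
        nx, ny, nz = self.dims
        dx, dy, dz = self.pitch_mm
        self.origin_mm = (-nx * dx / 2, -ny * dy / 2, -nz * dz / 2)
        return self

    def voxel_centers(self, axis: str) -> np.ndarray:
        """Voxel-center coordinates (mm from isocenter) along 'x', 'y' or 'z'."""
        i = "xyz".index(axis)
        n = self.dims[i]
        return self.origin_mm[i] + (np.arange(n) + 0.5) * self.pitch_mm[i]

    def total_mass_g(self) -> float:
        return float(self.densities.sum() * self.voxel_volume_cm3)


def organ_mask(phantom: VoxelPhantom, organ_name: str) -> Tuple[np.ndarray, float]:
    """Boolean voxel mask of one organ and its total mass in grams."""
    if phantom.organ_labels is None or not phantom.organ_names:
        raise PhantomError("phantom has no organ dictionary")
    inv = {v: k for k, v in phantom.organ_names.items()}
    if organ_name not in inv:
        raise PhantomError(
            f"unknown organ {organ_name!r}; available: {sorted(inv)}"
        )
    mask = phantom.organ_labels == inv[organ_name]
    mass = float(phantom.densities[mask].sum() * phantom.voxel_volume_cm3)
    if not mask.any():
        warnings.warn(f"organ {organ_name!r} has an empty mask", stacklevel=2)
    return mask, mass


# --------------------------------------------------------------------------
# CTDI phantoms
# --------------------------------------------------------------------------

#: radial offset of the peripheral holes, cm
CTDI_HOLE_OFFSET_CM = {"head": 7.0, "body": 15.0}
CTDI_DIAMETER_CM = {"head": 16.0, "body": 32.0}
CTDI_HEIGHT_CM = 15.0
DEFAULT_HOLE_DIAMETER_CM = 1.31  # standard ion-chamber bore


@dataclass
class CTDIPhantom:
    """Voxelized PMMA CTDI cylinder with air holes and per-hole scoring masks.

    Peripheral holes A, B, C, D sit at gantry angles 0/90/180/270 degrees
    (A on +y); scoring masks cover the full air column by default, or a
    centered chamber length when ``chamber_length_cm`` was given.
    """

    kind: str
    diameter_cm: float
    height_cm: float
    hole_offset_cm: float
    hole_diameter_cm: float
    hole_positions: Dict[str, Tuple[float, float]]  # label -> (x, y) cm
    phantom: VoxelPhantom
    scoring_masks: Dict[str, np.ndarray]


def build_ctdi_phantom(kind: str, voxel_pitch_mm: float = 2.0,
                       hole_diameter_cm: float = DEFAULT_HOLE_DIAMETER_CM,
                       chamber_length_cm: Optional[float] = None) -> CTDIPhantom:
    """Voxelize a standard PMMA CTDI phantom (16 cm head / 32 cm body)."""
    if kind not in CTDI_DIAMETER_CM:
        raise PhantomError(f"unknown CTDI phantom kind {kind!r}; use 'head' or 'body'")
    if voxel_pitch_mm > 2.0 + 1e-9:
        raise PhantomError("voxel pitch above 2 mm degrades the hole geometry")

    radius_cm = CTDI_DIAMETER_CM[kind] / 2
    offset = CTDI_HOLE_OFFSET_CM[kind]
    p_cm = voxel_pitch_mm / 10.0
    # even in-plane dims centered on the axis keep the grid 90-degree symmetric
    n_xy = int(np.ceil(radius_cm * 2 / p_cm / 2) * 2 + 2)
    n_z = int(round(CTDI_HEIGHT_CM / p_cm))

    xc = (np.arange(n_xy) + 0.5) * p_cm - n_xy * p_cm / 2
    X, Y = np.meshgrid(xc, xc, indexing="xy")  # X[y, x]
    in_cyl = X**2 + Y**2 <= radius_cm**2

    hole_positions = {"center": (0.0, 0.0), "A": (0.0, offset),
                      "B": (offset, 0.0), "C": (0.0, -offset), "D": (-offset, 0.0)}
    hole_r = hole_diameter_cm / 2
    hole_2d = {}
    any_hole = np.zeros_like(in_cyl)
    for name, (hx, hy) in hole_positions.items():
        if np.hypot(hx, hy) + hole_r > radius_cm:
            raise PhantomError(f"hole {name} does not fit inside the cylinder")
        m = (X - hx) ** 2 + (Y - hy) ** 2 <= hole_r**2
        hole_2d[name] = m
        any_hole |= m

    labels = np.zeros((n_z, n_xy, n_xy), dtype=np.uint16)
    labels[:, in_cyl & ~any_hole] = 1

    zc = (np.arange(n_z) + 0.5) * p_cm - n_z * p_cm / 2
    if chamber_length_cm is None:
        z_in = np.ones(n_z, bool)
    else:
        z_in = np.abs(zc) <= chamber_length_cm / 2
    masks = {}
    for name, m2d in hole_2d.items():
        m = np.zeros_like(labels, dtype=bool)
        m[z_in] = m2d
        masks[name] = m

    phantom = VoxelPhantom(
        labels=labels,
        pitch_mm=(voxel_pitch_mm,) * 3,
        materials={0: get_material("air"), 1: get_material("pmma")},
    ).centered()
    return CTDIPhantom(kind, 2 * radius_cm, CTDI_HEIGHT_CM, offset,
                       hole_diameter_cm, hole_positions, phantom, masks)


# --------------------------------------------------------------------------
# interfile-style I/O (minimal key-value dialect)
# --------------------------------------------------------------------------

_NUMBER_FORMATS = {"unsigned integer": "u", "signed integer": "i"}


def write_voxel_phantom(phantom: VoxelPhantom, header_path, raw_path=None,
                        byte_order: str = "LITTLEENDIAN") -> None:
    """Write ASCII header + raw little/big-endian label volume (x-fastest).

    Organ labels, when present, go to a sibling raw file recorded under the
    dialect-extension key ``name of organ data file``.
    """
    header_path = Path(header_path)
    if raw_path is None:
        raw_path = header_path.with_suffix(".raw")
    raw_path = Path(raw_path)
    byte_order = byte_order.upper()
    if byte_order not in ("LITTLEENDIAN", "BIGENDIAN"):
        raise PhantomError(f"unsupported byte order {byte_order!r}")
    endian = "<" if byte_order == "LITTLEENDIAN" else ">"
    arr = np.ascontiguousarray(phantom.labels, dtype=f"{endian}u2")
    raw_path.write_bytes(arr.tobytes())

    nx, ny, nz = phantom.dims
    lines = ["!INTERFILE :="]
    lines += [f"name of data file := {raw_path.name}",
              "number format := unsigned integer",
              "number of bytes per pixel := 2",
              f"imagedata byte order := {byte_order}",
              f"matrix size [1] := {nx}",
              f"matrix size [2] := {ny}",
              f"matrix size [3] := {nz}",
              f"scaling factor (mm/pixel) [1] := {phantom.pitch_mm[0]!r}",
              f"scaling factor (mm/pixel) [2] := {phantom.pitch_mm[1]!r}",
              f"scaling factor (mm/pixel) [3] := {phantom.pitch_mm[2]!r}",
              f"origin (mm) [1] := {phantom.origin_mm[0]!r}",
              f"origin (mm) [2] := {phantom.origin_mm[1]!r}",
              f"origin (mm) [3] := {phantom.origin_mm[2]!r}"]
    mat_entries = ";".join(
        f"{lbl}={mat.name}:{mat.density!r}" for lbl, mat in sorted(phantom.materials.items())
    )
    lines.append(f"material map := {mat_entries}")
    organ_entries = ";".join(
        f"{lbl}={name}" for lbl, name in sorted(phantom.organ_names.items())
    )
    lines.append(f"organ map := {organ_entries}")
    if phantom.organ_labels is not None:
        organ_raw = raw_path.with_name(raw_path.stem + "_organs.raw")
        np.ascontiguousarray(phantom.organ_labels, dtype=f"{endian}u2").tofile(organ_raw)
        lines.append(f"name of organ data file := {organ_raw.name}")
    lines.append("!END OF INTERFILE :=")
    header_path.write_text("\n".join(lines) + "\n")


def _parse_header(header_path: Path) -> Dict[str, str]:
    fields = {}
    for line in header_path.read_text().splitlines():
        line = line.strip()
        if not line or ":=" not in line:
            continue
        key, _, value = line.partition(":=")
        fields[key.strip().lstrip("!").lower()] = value.strip()
    return fields


def read_voxel_phantom(header_path, raw_path=None) -> VoxelPhantom:
    """Inverse of :func:`write_voxel_phantom`; validates header/raw consistency."""
    header_path = Path(header_path)
    fields = _parse_header(header_path)
    try:
        dims = tuple(int(fields[f"matrix size [{i}]"]) for i in (1, 2, 3))
        pitch = tuple(float(fields[f"scaling factor (mm/pixel) [{i}]"]) for i in (1, 2, 3))
        nfmt = fields["number format"]
        nbytes = int(fields.get("number of bytes per pixel", "2"))
        order = fields["imagedata byte order"].upper()
    except KeyError as exc:
        raise PhantomError(f"{header_path}: missing header key {exc}") from None
    origin = tuple(float(fields.get(f"origin (mm) [{i}]", "0")) for i in (1, 2, 3))
    if nfmt not in _NUMBER_FORMATS:
        raise PhantomError(f"{header_path}: unsupported number format {nfmt!r}")
    endian = {"LITTLEENDIAN": "<", "BIGENDIAN": ">"}.get(order)
    if endian is None:
        raise PhantomError(f"{header_path}: unsupported byte order {order!r}")
    dtype = np.dtype(f"{endian}{_NUMBER_FORMATS[nfmt]}{nbytes}")

    if raw_path is None:
        raw_path = header_path.parent / fields["name of data file"]
    raw_path = Path(raw_path)
    raw = raw_path.read_bytes()
    expected = dims[0] * dims[1] * dims[2] * nbytes
    if len(raw) != expected:
        raise PhantomError(
            f"{raw_path}: raw size {len(raw)} bytes does not match header "
            f"{dims[0]}x{dims[1]}x{dims[2]}x{nbytes} = {expected} bytes"
        )
    labels = np.frombuffer(raw, dtype=dtype).reshape(dims[2], dims[1], dims[0])
    labels = labels.astype(np.uint16)

    materials = {}
    for entry in filter(None, fields.get("material map", "").split(";")):
        lbl, _, spec = entry.partition("=")
        name, _, dens = spec.partition(":")
        mat = get_material(name)
        if dens:
            mat = mat.with_density(float(dens))
        materials[int(lbl)] = mat
    if not materials:
        raise PhantomError(f"{header_path}: empty material map")
    for lbl in np.unique(labels):
        if int(lbl) not in materials:
            raise PhantomError(f"{header_path}: label {int(lbl)} missing from material map")

    organ_names = {}
    for entry in filter(None, fields.get("organ map", "").split(";")):
        lbl, _, name = entry.partition("=")
        organ_names[int(lbl)] = name
    organ_labels = None
    if "name of organ data file" in fields:
        organ_raw = header_path.parent / fields["name of organ data file"]
        organ_labels = np.fromfile(organ_raw, dtype=f"{endian}u2").reshape(
            dims[2], dims[1], dims[0]).astype(np.uint16)

    return VoxelPhantom(labels, pitch, materials, origin, organ_labels, organ_names)


def write_mhd(volume: np.ndarray, pitch_mm, origin_mm, path) -> None:
    """Export a volume as MetaImage (.mhd + .raw), 32-bit float."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(volume, np.float32))
    img.SetSpacing(tuple(float(p) for p in pitch_mm))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    sitk.WriteImage(img, str(path))
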