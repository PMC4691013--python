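"""Volume, mesh and curve I/O plus the global-threshold segmentation baseline.

Grid convention
---------------
All 3D arrays are stored in ``(i, j, k) == (z, y, x)`` order, with ``z`` the
axial (section, usually thinnest) axis of a tomogram.  Voxel centers sit at
``origin + spacing * (i, j, k)`` in physical space; ``spacing`` is the
isotropic voxel edge length in nanometres.  All radii and distances anywhere
in this package are in nm.

Supported volume formats are MRC (mode 0/1/2/6, CELLA voxel size in
angstroms by cryo-EM convention), NRRD (raw little-endian encoding) and
multi-page TIFF (spacing carried in ImageJ metadata).  The MRC and NRRD
codecs here are deliberately minimal, covering the single-volume isotropic
case this package produces and consumes.
"""

from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BIOMASS",
    "VOID",
    "LUMEN",
    "ScalarVolume",
    "SegmentationMask",
    "BinaryVolume",
    "SpacingError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "threshold_segment",
    "write_mesh",
    "read_mesh",
    "write_curve",
    "read_curve",
]

# Label codes of a segmentation.  LUMEN is void space that has been marked as
# cell lumen; it counts as void for every distance computation.
VOID = 0
BIOMASS = 1
LUMEN = 2

_ROLES = ("intensity", "edt", "crt", "aedt", "acrt")

# relative tolerance for the isotropic-spacing requirement
_SPACING_RTOL = 1e-3


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be parsed in the stated format."""


class SpacingError(ValueError):
    """Raised when voxel spacing is missing, non-positive or anisotropic."""


def _check_isotropic(spacings) -> float:
    s = np.asarray(spacings, dtype=float)
    if s.size == 1:
        s = np.repeat(s, 3)
    if np.any(s <= 0):
        raise SpacingError(f"non-positive voxel spacing: {tuple(s)}")
    if (s.max() - s.min()) > _SPACING_RTOL * s.min():
        raise SpacingError(
            f"anisotropic voxel spacing not supported: {tuple(round(v, 6) for v in s)}"
        )
    return float(s.mean())


@dataclass
class ScalarVolume:
    """A 3D scalar field on an isotropic voxel grid.

    Parameters
    ----------
    values : (nz, ny, nx) ndarray
        Scalar values, one per voxel.
    spacing : float
        Isotropic voxel edge length, nm.
    origin : (3,) array-like
        Physical coordinate (nm) of the center of voxel (0, 0, 0).
    role : str
        One of ``intensity``, ``edt``, ``crt``, ``aedt``, ``acrt``.
        Distance-like roles require values >= 0.
    """

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    role: str = "intensity"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = _check_isotropic(self.spacing)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")
        if self.role != "intensity" and self.values.size and self.values.min() < 0:
            raise ValueError(f"role={self.role!r} requires nonnegative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class SegmentationMask:
    """Biomass / void / lumen label grid (codes 1 / 0 / 2)."""

    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        bad = set(np.unique(self.labels)) - {VOID, BIOMASS, LUMEN}
        if bad:
            raise ValueError(f"labels must be in {{0, 1, 2}}; found {sorted(bad)}")
        self.spacing = _check_isotropic(self.spacing)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def biomass(self) -> np.ndarray:
        return self.labels == BIOMASS

    @property
    def void(self) -> np.ndarray:
        """Non-biomass voxels (plain void plus lumen)."""
        return self.labels != BIOMASS

    @property
    def lumen(self) -> np.ndarray:
        return self.labels == LUMEN


@dataclass
class BinaryVolume:
    """Boolean field on the same grid as its source volume (e.g. Void(r))."""

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = _check_isotropic(self.spacing)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _write_mrc(path: str, values: np.ndarray, spacing_nm: float) -> None:
    arr = np.ascontiguousarray(values)
    if arr.dtype not in _MRC_MODE_OF:
        arr = arr.astype(np.float32)
    mode = _MRC_MODE_OF[arr.dtype]
    nz, ny, nx = arr.shape
    header = bytearray(1024)
    # NX NY NZ MODE; NXSTART..; MX MY MZ; CELLA (angstrom); CELLB; MAPC/R/S
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    cella = (nx * spacing_nm * 10.0, ny * spacing_nm * 10.0, nz * spacing_nm * 10.0)
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()),
                     float(arr.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())


def _read_mrc(path: str, units: str) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise VolumeFormatError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        if mode not in _MRC_MODES:
            raise VolumeFormatError(f"{path}: unsupported MRC mode {mode}")
        data = np.fromfile(fh, dtype=_MRC_MODES[mode], count=nx * ny * nz)
    if data.size != nx * ny * nz:
        raise VolumeFormatError(f"{path}: MRC payload shorter than header promises")
    values = data.reshape(nz, ny, nx)
    grid = (mx or nx, my or ny, mz or nz)
    vox = [c / g for c, g in zip(cella, grid)] if all(cella) else None
    if vox is None:
        raise SpacingError(f"{path}: MRC header carries no voxel size (CELLA is zero)")
    spacing = _check_isotropic(vox)
    if units in ("angstrom", "A", "Å"):
        spacing /= 10.0
    elif units != "nm":
        raise ValueError(f"unknown units {units!r}; expected 'angstrom' or 'nm'")
    return values, spacing


# ---------------------------------------------------------------------------
# NRRD (raw little-endian encoding only)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "signed char": np.int8, "int8": np.int8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32, "uint32": np.uint32,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAME_OF = {
    np.dtype(np.int8): "int8", np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16", np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32", np.dtype(np.uint32): "uint32",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


def _write_nrrd(path: str, values: np.ndarray, spacing_nm: float,
                origin: np.ndarray, role: str | None) -> None:
    arr = np.ascontiguousarray(values)
    if arr.dtype not in _NRRD_NAME_OF:
        arr = arr.astype(np.float64)
    nz, ny, nx = arr.shape
    s = spacing_nm
    lines = [
        "NRRD0004",
        "# generated by tomoaccess",
        f"type: {_NRRD_NAME_OF[arr.dtype]}",
        "dimension: 3",
        # fastest axis first in NRRD sizes; our memory order is (z, y, x)
        f"sizes: {nx} {ny} {nz}",
        "encoding: raw",
        "endian: little",
        "space: right-anterior-superior",
        f"space directions: ({s},0,0) (0,{s},0) (0,0,{s})",
        f"space origin: ({origin[2]},{origin[1]},{origin[0]})",
    ]
    if role is not None:
        lines.append(f"tomoaccess_role:={role}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode())
        fh.write(arr.astype(arr.dtype.newbyteorder("<")).tobytes())


def _read_nrrd(path: str) -> tuple[np.ndarray, float, np.ndarray, str | None]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise VolumeFormatError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        keyvals: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode().rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                k, v = text.split(":=", 1)
                keyvals[k.strip()] = v.strip()
            elif ": " in text or text.endswith(":"):
                k, _, v = text.partition(":")
                fields[k.strip().lower()] = v.strip()
        payload = fh.read()

    try:
        dtype = np.dtype(_NRRD_TYPES[fields["type"]])
        sizes = [int(t) for t in fields["sizes"].split()]
        encoding = fields["encoding"]
    except KeyError as exc:
        raise VolumeFormatError(f"{path}: NRRD header missing field {exc}") from exc
    if encoding != "raw":
        raise VolumeFormatError(f"{path}: only raw NRRD encoding supported")
    if fields.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    nx, ny, nz = sizes
    data = np.frombuffer(payload, dtype=dtype, count=nx * ny * nz)
    if data.size != nx * ny * nz:
        raise VolumeFormatError(f"{path}: NRRD payload shorter than header promises")
    values = np.asarray(data, dtype=dtype.newbyteorder("=")).reshape(nz, ny, nx)

    if "space directions" in fields:
        vecs = [v for v in fields["space directions"].split(")") if "(" in v]
        spacings = []
        for vec in vecs:
            comps = [float(c) for c in vec.split("(")[1].split(",")]
            spacings.append(float(np.linalg.norm(comps)))
    elif "spacings" in fields:
        spacings = [float(t) for t in fields["spacings"].split()]
    else:
        raise SpacingError(f"{path}: NRRD header carries no voxel spacing")
    spacing = _check_isotropic(spacings)

    origin = np.zeros(3)
    if "space origin" in fields:
        comps = [float(c) for c in
                 fields["space origin"].strip("()").split(",")]
        origin = np.array(comps[::-1], dtype=float)  # (x,y,z) -> (z,y,x)
    return values, spacing, origin, keyvals.get("tomoaccess_role")


# ---------------------------------------------------------------------------
# TIFF stack
# ---------------------------------------------------------------------------

def _write_tiff(path: str, values: np.ndarray, spacing_nm: float) -> None:
    import tifffile

    arr = np.ascontiguousarray(values)
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)  # ImageJ TIFF has no float64
    tifffile.imwrite(
        path, arr, imagej=True,
        resolution=(1.0 / spacing_nm, 1.0 / spacing_nm),
        metadata={"spacing": spacing_nm, "unit": "nm", "axes": "ZYX"},
    )


def _read_tiff(path: str, spacing_override: float | None) -> tuple[np.ndarray, float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta = tif.imagej_metadata or {}
    if values.ndim == 2:
        values = values[None]
    if spacing_override is not None:
        return values, float(spacing_override)
    if "spacing" in meta:
        return values, float(meta["spacing"])
    raise SpacingError(
        f"{path}: TIFF carries no spacing metadata; pass spacing= explicitly"
    )


# ---------------------------------------------------------------------------
# public volume API
# ---------------------------------------------------------------------------

_EXT_FORMAT = {".mrc": "mrc", ".rec": "mrc", ".map": "mrc",
               ".nrrd": "nrrd", ".tif": "tiff", ".tiff": "tiff"}


def _infer_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(path)[1].lower()
    try:
        return _EXT_FORMAT[ext]
    except KeyError:
        raise VolumeFormatError(
            f"cannot infer format from extension {ext!r}; pass format= explicitly"
        ) from None


def read_volume(path: str, format: str = "auto", *, spacing: float | None = None,
                units: str = "angstrom", role: str = "intensity") -> ScalarVolume:
    """Read a 3D volume from MRC, NRRD or a multi-page TIFF stack.

    Parameters
    ----------
    path, format : str
        ``format`` is one of ``mrc``, ``nrrd``, ``tiff``, ``auto`` (by
        extension).
    spacing : float, optional
        Override the voxel spacing (nm) from file metadata; required for
        TIFFs without ImageJ spacing metadata.
    units : str
        Units of the MRC header voxel size: ``"angstrom"`` (default,
        cryo-EM convention, divided by 10 to get nm) or ``"nm"``.
    role : str
        Role assigned to the returned volume when the file stores none.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    stored_role = None
    if fmt == "mrc":
        values, file_spacing = _read_mrc(path, units)
        origin = np.zeros(3)
    elif fmt == "nrrd":
        values, file_spacing, origin, stored_role = _read_nrrd(path)
    elif fmt == "tiff":
        values, file_spacing = _read_tiff(path, spacing)
        origin = np.zeros(3)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    if spacing is not None:
        file_spacing = float(spacing)
    return ScalarVolume(values, file_spacing, origin, stored_role or role)


def write_volume(volume: ScalarVolume, path: str, format: str = "auto") -> None:
    """Write a volume so that :func:`read_volume` recovers values and spacing."""
    fmt = _infer_format(path, format)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    if fmt == "mrc":
        _write_mrc(path, volume.values, volume.spacing)
    elif fmt == "nrrd":
        _write_nrrd(path, volume.values, volume.spacing, volume.origin, volume.role)
    elif fmt == "tiff":
        _write_tiff(path, volume.values, volume.spacing)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")


def read_mask(path: str, format: str = "auto", *,
              spacing: float | None = None) -> SegmentationMask:
    """Read a label volume (codes 0/1/2) as a :class:`SegmentationMask`."""
    vol = read_volume(path, format, spacing=spacing, units="nm")
    return SegmentationMask(np.rint(vol.values).astype(np.int8), vol.spacing,
                            vol.origin)


def write_mask(mask: SegmentationMask, path: str, format: str = "auto") -> None:
    vol = ScalarVolume(mask.labels.astype(np.int8), mask.spacing, mask.origin,
                       role="intensity")
    write_volume(vol, path, format)


# ---------------------------------------------------------------------------
# segmentation baseline
# ---------------------------------------------------------------------------

def threshold_segment(volume: ScalarVolume, cutoff: float,
                      invert: bool = False) -> SegmentationMask:
    """Global-threshold segmentation: dark voxels become biomass.

    Voxels with intensity strictly below ``cutoff`` are labeled BIOMASS
    (biomass is electron-dense, hence dark, in stained TEM tomograms);
    ``invert=True`` labels bright voxels instead.  No lumen labels are
    assigned.  A cutoff outside the data range produces an all-void or
    all-biomass mask and a warning, since downstream transforms reject
    single-phase masks.
    """
    if volume.role != "intensity":
        raise ValueError(f"threshold_segment expects an intensity volume, "
                         f"got role={volume.role!r}")
    dark = volume.values >= cutoff if invert else volume.values < cutoff
    labels = np.where(dark, BIOMASS, VOID).astype(np.int8)
    n_bio = int(labels.sum())
    if n_bio == 0:
        warnings.warn(f"cutoff {cutoff} yields an all-void mask", stacklevel=2)
    elif n_bio == labels.size:
        warnings.warn(f"cutoff {cutoff} yields an all-biomass mask", stacklevel=2)
    return SegmentationMask(labels, volume.spacing, volume.origin)


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def write_mesh(mesh, path: str, format: str = "auto") -> None:
    """Write a surface mesh to PLY (ASCII), OBJ or legacy VTK.

    PLY and VTK carry the per-vertex accessibility scalar (PLY property
    ``accessibility``, VTK POINT_DATA field of the same name); OBJ stores
    geometry only.
    """
    if format == "auto":
        format = os.path.splitext(path)[1].lstrip(".").lower()
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    v, f = np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.triangles)
    scal = getattr(mesh, "accessibility", None)
    if format == "ply":
        _write_ply(path, v, f, scal)
    elif format == "obj":
        with open(path, "w") as fh:
            for p in v:
                fh.write(f"v {p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
            for t in f:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    elif format == "vtk":
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ntomoaccess surface\nASCII\n"
                     "DATASET POLYDATA\n")
            fh.write(f"POINTS {len(v)} double\n")
            for p in v:
                fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
            fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
            for t in f:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
            if scal is not None:
                fh.write(f"POINT_DATA {len(v)}\n"
                         "SCALARS accessibility double 1\nLOOKUP_TABLE default\n")
                for s in np.asarray(scal, dtype=float):
                    fh.write(f"{s:.8g}\n")
    else:
        raise ValueError(f"unknown mesh format {format!r}")


def _write_ply(path, v, f, scal):
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if scal is not None:
            fh.write("property double accessibility\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        if scal is not None:
            for p, s in zip(v, np.asarray(scal, dtype=float)):
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {s:.17g}\n")
        else:
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for t in f:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh(path: str):
    """Read back an ASCII PLY written by :func:`write_mesh`.

    Returns ``(vertices, triangles, accessibility-or-None)``.
    """
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_v = n_f = 0
        props: list[str] = []
        element = None
        for line in fh:
            tok = line.split()
            if tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_v = int(tok[2])
                elif element == "face":
                    n_f = int(tok[2])
            elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        rows = [fh.readline().split() for _ in range(n_v)]
        data = np.array(rows, dtype=float)
        verts = data[:, :3]
        scal = data[:, props.index("accessibility")] \
            if "accessibility" in props else None
        faces = np.array([fh.readline().split()[1:4] for _ in range(n_f)],
                         dtype=int)
    return verts, faces, scal


# ---------------------------------------------------------------------------
# curve I/O
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["radius_nm", "area_nm2", "frac_total_area",
                  "area_per_biomass_vol"]


def write_curve(curve, path: str, format: str = "csv") -> None:
    """Write an accessible-area curve as CSV/TSV.

    Columns: radius_nm, area_nm2, frac_total_area, area_per_biomass_vol
    (the last in 1/µm, accessible area over total biomass volume).
    """
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.DataFrame({
        "radius_nm": curve.radii,
        "area_nm2": curve.area,
        "frac_total_area": curve.frac_total_area,
        "area_per_biomass_vol": curve.area_per_biomass_vol,
    })
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    df.to_csv(path, sep=sep, index=False)


def read_curve(path: str, format: str = "csv") -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.read_csv(path, sep=sep)
    missing = set(_CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: curve file missing columns {sorted(missing)}")
    return df
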