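"""On-disk artifacts: MRC2014 volumes, particle coordinate tables, grid bundles.

The in-memory convention everywhere in this package is a canonical ``(z, y, x)``
axis order with 0-based voxel indices.  The MRC header's column/row/section
axis mapping (``mapc``/``mapr``/``maps``) is applied only at this I/O boundary:
:func:`read_volume` permutes the stored array into canonical order and records
the mapping so :func:`write_volume` can restore the original file layout.

Particle tables are plain CSV with header ``class_id,x,y,z``; coordinates are
0-based floating-point voxel positions in ``(x, y, z)`` column order.
"""

from __future__ import annotations

import dataclasses
import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "GridBundle",
    "MRCFormatError",
    "ParticleParseError",
    "BundleFormatError",
    "read_volume",
    "write_volume",
    "read_particles",
    "write_particles",
    "particle_table",
    "save_bundle",
    "load_bundle",
]

PARTICLE_COLUMNS = ["class_id", "x", "y", "z"]

# MRC2014 data modes supported for reading; writing picks from {0, 1, 2}.
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


class MRCFormatError(ValueError):
    """Raised for corrupt, truncated, or unsupported MRC files."""


class ParticleParseError(ValueError):
    """Raised for malformed coordinate tables; names the offending line."""


class BundleFormatError(ValueError):
    """Raised when a grid-bundle archive is missing a required field."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with its spatial metadata.

    ``data`` is indexed ``[z, y, x]``.  ``voxel_size`` and ``origin`` are
    ``(x, y, z)`` triples in Angstrom.  ``axis_map`` is the MRC
    ``(mapc, mapr, maps)`` triple describing how file axes map to world axes.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_map: tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D with positive dims, got {self.data.shape}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if sorted(self.axis_map) != [1, 2, 3]:
            raise ValueError(f"axis_map must be a permutation of (1,2,3), got {self.axis_map}")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_map = tuple(int(a) for a in self.axis_map)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume sharing this volume's metadata."""
        return Volume(data, self.voxel_size, self.origin, self.axis_map)


@dataclasses.dataclass
class GridBundle:
    """One context-padded window cut from a volume, plus placement metadata.

    ``grid`` is ``(w, w, w)`` or ``(C, w, w, w)``; the core region of size
    ``extents`` starts ``pad`` voxels into the window and sits at voxel offset
    ``placement`` (``(i, j, k)`` in canonical z, y, x order) in the source.
    """

    grid: np.ndarray
    placement: tuple[int, int, int]
    extents: tuple[int, int, int]
    pad: int
    source_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_map: tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self):
        spatial = self.spatial_shape
        if len(set(spatial)) != 1:
            raise ValueError(f"window must be cubic, got {spatial}")
        w = spatial[0]
        for off, ext, src in zip(self.placement, self.extents, self.source_shape):
            if off < 0 or ext < 1 or off + ext > src:
                raise ValueError(
                    f"placement {self.placement} + extents {self.extents} exceed "
                    f"source shape {self.source_shape}"
                )
            if self.pad + ext > w:
                raise ValueError(f"pad {self.pad} + extent {ext} exceed window {w}")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.grid.shape[-3:]

    def core(self) -> np.ndarray:
        """The central non-padded region (what stitching writes back)."""
        p = self.pad
        di, dj, dk = self.extents
        return self.grid[..., p : p + di, p : p + dj, p : p + dk]


# ---------------------------------------------------------------------------
# MRC2014 volumes
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read an MRC2014 file into canonical (z, y, x) order."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MRCFormatError(f"{path}: truncated MRC header ({len(raw)} bytes)")
    (nx, ny, nz, mode) = struct.unpack_from("<4i", raw, 0)
    (mx, my, mz) = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    mapc, mapr, maps = struct.unpack_from("<3i", raw, 64)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    ox, oy, oz = struct.unpack_from("<3f", raw, 196)
    if min(nx, ny, nz) < 1 or mode not in _MODE_DTYPES:
        raise MRCFormatError(f"{path}: unsupported or corrupt header (mode={mode})")
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise MRCFormatError(f"{path}: invalid axis mapping {(mapc, mapr, maps)}")
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    n_vox = nx * ny * nz
    offset = _HEADER_SIZE + max(nsymbt, 0)
    if len(raw) < offset + n_vox * dtype.itemsize:
        raise MRCFormatError(f"{path}: truncated data section")
    arr = np.frombuffer(raw, dtype=dtype, count=n_vox, offset=offset)
    arr = arr.reshape(nz, ny, nx)  # (sections, rows, columns)
    # File axes (section, row, column) carry world axes (maps, mapr, mapc);
    # permute into canonical (z=3, y=2, x=1).
    file_world = (maps, mapr, mapc)
    perm = tuple(file_world.index(w) for w in (3, 2, 1))
    data = np.ascontiguousarray(arr.transpose(perm))
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise MRCFormatError(f"{path}: volume contains non-finite values")
    # Voxel size per world axis from cell dimensions / sampling counts.
    sx = xlen / mx if mx > 0 and xlen > 0 else 1.0
    sy = ylen / my if my > 0 and ylen > 0 else 1.0
    sz = zlen / mz if mz > 0 and zlen > 0 else 1.0
    return Volume(data, (sx, sy, sz), (ox, oy, oz), (mapc, mapr, maps))


def write_volume(v: Volume, path) -> None:
    """Write a volume as MRC2014, restoring the recorded file axis layout."""
    path = Path(path)
    data = v.data
    if np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.bool_):
        lo, hi = (int(data.min()), int(data.max())) if data.size else (0, 0)
        if -128 <= lo and hi <= 127:
            mode, dtype = 0, np.int8
        elif -32768 <= lo and hi <= 32767:
            mode, dtype = 1, np.int16
        else:
            mode, dtype = 2, np.float32
    else:
        mode, dtype = 2, np.float32
    mapc, mapr, maps = v.axis_map
    file_world = (maps, mapr, mapc)
    # canonical axis index for world axis w: z->0, y->1, x->2
    canon_of_world = {3: 0, 2: 1, 1: 2}
    perm = tuple(canon_of_world[w] for w in file_world)
    arr = np.ascontiguousarray(data.transpose(perm)).astype(dtype)
    nz_f, ny_f, nx_f = arr.shape
    # world-axis sampling counts (x, y, z) from canonical shape (z, y, x)
    mx, my, mz = data.shape[2], data.shape[1], data.shape[0]
    sx, sy, sz = v.voxel_size
    stats = data.astype(np.float64)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx_f, ny_f, nz_f, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart/nystart/nzstart
    struct.pack_into("<3i", header, 28, mx, my, mz)
    struct.pack_into("<3f", header, 40, sx * mx, sy * my, sz * mz)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps)
    struct.pack_into("<3f", header, 76, float(stats.min()), float(stats.max()), float(stats.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    struct.pack_into("<i", header, 108, 20140)  # nversion
    struct.pack_into("<3f", header, 196, *v.origin)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(stats.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.astype(np.dtype(dtype).newbyteorder("<"), copy=False).tobytes())


# ---------------------------------------------------------------------------
# Particle coordinate tables
# ---------------------------------------------------------------------------

def particle_table(rows=None) -> pd.DataFrame:
    """Build a validated particle table from (class_id, x, y, z) rows."""
    df = pd.DataFrame(rows if rows is not None else [], columns=PARTICLE_COLUMNS)
    return _validate_particles(df)


def _validate_particles(df: pd.DataFrame, path=None) -> pd.DataFrame:
    where = f"{path}: " if path else ""
    if list(df.columns) != PARTICLE_COLUMNS:
        raise ParticleParseError(f"{where}expected columns {PARTICLE_COLUMNS}, got {list(df.columns)}")
    out = df.copy()
    for col in PARTICLE_COLUMNS:
        values = np.empty(len(df), dtype=np.float64)
        for row, raw in enumerate(df[col]):
            try:
                values[row] = float(raw)  # exact round-trip parsing
            except (TypeError, ValueError):
                line = row + 2  # +1 header, +1 1-based
                raise ParticleParseError(
                    f"{where}malformed value in column '{col}' at line {line}"
                ) from None
        out[col] = values
    if len(out) and not np.isfinite(out[["x", "y", "z"]].to_numpy()).all():
        raise ParticleParseError(f"{where}non-finite coordinate")
    cid = out["class_id"].to_numpy()
    if len(out) and (not np.isfinite(cid).all() or (cid != np.round(cid)).any()):
        raise ParticleParseError(f"{where}class_id must be an integer")
    out["class_id"] = out["class_id"].astype(np.int64)
    if len(out) and (out["class_id"] < 1).any():
        raise ParticleParseError(f"{where}class_id must be >= 1 (0 is background)")
    out[["x", "y", "z"]] = out[["x", "y", "z"]].astype(np.float64)
    return out.reset_index(drop=True)


def read_particles(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise ParticleParseError(f"{path}: empty file, expected a header line") from exc
    except pd.errors.ParserError as exc:
        raise ParticleParseError(f"{path}: {exc}") from exc
    return _validate_particles(df, path=path)


def write_particles(table: pd.DataFrame, path) -> None:
    # %.17g round-trips float64 exactly
    _validate_particles(pd.DataFrame(table, columns=PARTICLE_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Grid bundles
# ---------------------------------------------------------------------------

_BUNDLE_FIELDS = ("grid", "i", "j", "k", "di", "dj", "dk", "pad",
                  "source_shape", "voxel_size", "origin", "axis_map")


def save_bundle(b: GridBundle, path) -> None:
    np.savez_compressed(
        path,
        grid=b.grid,
        i=b.placement[0], j=b.placement[1], k=b.placement[2],
        di=b.extents[0], dj=b.extents[1], dk=b.extents[2],
        pad=b.pad,
        source_shape=np.asarray(b.source_shape, dtype=np.int64),
        voxel_size=np.asarray(b.voxel_size, dtype=np.float64),
        origin=np.asarray(b.origin, dtype=np.float64),
        axis_map=np.asarray(b.axis_map, dtype=np.int64),
    )


def load_bundle(path) -> GridBundle:
    with np.load(path) as npz:
        missing = [f for f in _BUNDLE_FIELDS if f not in npz.files]
        if missing:
            raise BundleFormatError(f"{path}: missing bundle fields {missing}")
        return GridBundle(
            grid=npz["grid"],
            placement=(int(npz["i"]), int(npz["j"]), int(npz["k"])),
            extents=(int(npz["di"]), int(npz["dj"]), int(npz["dk"])),
            pad=int(npz["pad"]),
            source_shape=tuple(int(s) for s in npz["source_shape"]),
            voxel_size=tuple(float(s) for s in npz["voxel_size"]),
            origin=tuple(float(o) for o in npz["origin"]),
            axis_map=tuple(int(a) for a in npz["axis_map"]),
        )
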