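"""Volumetric stack, binary mask and surface-mesh I/O.

Conventions
-----------
* Voxel indices are 0-based and arrays are indexed ``(x, y, z)``.
* Physical position of voxel ``(i, j, k)`` is ``(i*sx, j*sy, k*sz)`` in µm.
* Intensities are normalized to ``[0, 1]`` on load.
* Masks are stored as 8-bit TIFF with values {0, 255}; meshes as OBJ
  (PLY also supported through :mod:`trimesh`).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from contextlib import contextmanager

import numpy as np
import tifffile
import trimesh

log = logging.getLogger("lapcell")
if not log.handlers:  # stderr logging with per-stage timing, configured once
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@contextmanager
def stage_timer(name: str):
    """Log wall-clock duration of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    yield
    log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)


class FormatError(ValueError):
    """Input file does not have the expected layout (e.g. not a 3D raster)."""


class DegenerateInputError(ValueError):
    """Input is valid but carries no usable signal (e.g. constant image)."""


DEFAULT_SPACING = (1.0, 1.0, 1.0)


@dataclasses.dataclass
class VolumeStack:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D float array, shape ``(nx, ny, nz)``, finite values.
    spacing:
        ``(sx, sy, sz)`` voxel size in µm, strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D stack, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class BinaryVolume:
    """A 3D boolean mask with physical voxel spacing."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={mask.ndim}")
        if mask.dtype != bool:
            vals = np.unique(mask)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValueError("mask values must be binary (0/1 or 0/255)")
            mask = mask > 0
        self.mask = mask
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclasses.dataclass
class SurfaceMesh:
    """A triangulated surface in physical µm coordinates.

    ``vertices`` is ``(V, 3)`` float, ``faces`` is ``(F, 3)`` int with
    consistent outward orientation.  Closedness/manifoldness is a contract of
    the extraction step, checked there rather than on every construction.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise ValueError("mesh must have at least one vertex and one face")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (E, 2), sorted pairs."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def is_closed_manifold(self) -> bool:
        """Every undirected edge shared by exactly two faces."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


# ---------------------------------------------------------------------------
# stacks and masks


def read_stack(path, spacing: tuple[float, float, float] | None = None) -> VolumeStack:
    """Read a multi-page TIFF into a normalized :class:`VolumeStack`.

    TIFF pages are z-slices stored ``(z, y, x)``; they are transposed to the
    package's ``(x, y, z)`` axis order.  Intensities are rescaled to [0, 1]
    by ``(v - min) / (max - min)``.  ``spacing`` overrides any metadata.
    """
    raw = tifffile.imread(str(path))
    if raw.ndim != 3:
        raise FormatError(f"{path}: expected a multi-page (3D) TIFF, got shape {raw.shape}")
    data = np.ascontiguousarray(np.transpose(raw, (2, 1, 0)).astype(np.float64))
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise DegenerateInputError(f"{path}: constant image (max == min), cannot normalize")
    data = (data - lo) / (hi - lo)
    if spacing is None:
        spacing = _spacing_from_tiff(str(path)) or DEFAULT_SPACING
    return VolumeStack(data, spacing)


def _spacing_from_tiff(path: str):
    """Best-effort (sx, sy, sz) from TIFF resolution tags; None if absent."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            meta = tf.imagej_metadata or {}
            sz = float(meta.get("spacing", 0.0)) or None
            if xres is None or yres is None or sz is None:
                return None
            sx = xres.value[1] / xres.value[0]
            sy = yres.value[1] / yres.value[0]
            return (float(sx), float(sy), float(sz))
    except Exception:
        return None


def write_stack(stack: VolumeStack, path) -> None:
    """Write a stack as 32-bit multi-page TIFF with spacing metadata."""
    data = np.transpose(stack.data, (2, 1, 0)).astype(np.float32)
    sx, sy, sz = stack.spacing
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def read_mask(path, spacing: tuple[float, float, float] | None = None) -> BinaryVolume:
    raw = tifffile.imread(str(path))
    if raw.ndim != 3:
        raise FormatError(f"{path}: expected a multi-page (3D) TIFF, got shape {raw.shape}")
    mask = np.ascontiguousarray(np.transpose(raw, (2, 1, 0))) > 0
    if spacing is None:
        spacing = _spacing_from_tiff(str(path)) or DEFAULT_SPACING
    return BinaryVolume(mask, spacing)


def write_mask(vol: BinaryVolume, path) -> None:
    data = (np.transpose(vol.mask, (2, 1, 0)) * np.uint8(255))
    sx, sy, sz = vol.spacing
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


# ---------------------------------------------------------------------------
# meshes


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as OBJ (or PLY, by extension).

    Output is byte-stable for a fixed input; vertices keep full float
    precision so a read round-trips exactly.
    """
    path = str(path)
    if path.lower().endswith(".obj"):
        lines = []
        for v in mesh.vertices:
            lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
        for f in mesh.faces:
            lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(path)


def read_mesh(path) -> SurfaceMesh:
    path = str(path)
    if path.lower().endswith(".obj"):
        verts, faces = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0] == "v":
                    verts.append([float(x) for x in parts[1:4]])
                elif parts[0] == "f":
                    faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
        return SurfaceMesh(np.array(verts), np.array(faces))
    tm = trimesh.load_mesh(path, process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
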