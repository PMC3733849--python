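"""Domain containers and on-disk formats.

The package moves five kinds of artifact around: diffusion gradient tables
(FSL-style ``bval``/``bvec`` text), 4D diffusion-weighted stacks, derived
scalar maps (MD, Trace(D), FA), integer anatomical label maps with a JSON
legend sidecar, and rendered color maps (PNG).  Everything volumetric is
NIfTI-1 via nibabel.

Conventions
-----------
* Voxel indexing is 0-based with axis order ``(x, y, slice)``; the slice
  axis is always the last array axis.
* Gradient directions live in the image coordinate frame; no scanner-frame
  reorientation is attempted.
* A :class:`LabelMap` legend is stored in a ``<stem>.labels.json`` sidecar
  because NIfTI itself has no standard label legend.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from matplotlib import colormaps

__all__ = [
    "ImageGrid",
    "GradientTable",
    "DWIStack",
    "ScalarMap",
    "LabelMap",
    "default_gradient_table",
    "read_gradient_table",
    "write_gradient_table",
    "read_volume",
    "write_volume",
    "render_scalar_map",
    "MD_RENDER_RANGE",
]

#: Display range for mean-diffusivity color maps, mm^2/s.
MD_RENDER_RANGE = (0.0, 5.0e-4)

#: b-value (s/mm^2) of the built-in ex-vivo acquisition scheme.
DEFAULT_BVALUE = 1496.0


# ---------------------------------------------------------------------------
# grids and gradient tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGrid:
    """Geometry of an image volume: shape ``(nx, ny, nslices)``, voxel size
    and origin in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def __eq__(self, other) -> bool:
        # geometry travels through float32 NIfTI affines; compare with the
        # corresponding tolerance rather than bit-exactly
        return (
            isinstance(other, ImageGrid)
            and self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, rtol=1e-5, atol=1e-6)
            and np.allclose(self.origin, other.origin, rtol=1e-5, atol=1e-5)
        )

    def __hash__(self) -> int:
        return hash(self.shape)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape, affine) -> "ImageGrid":
        vox = tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        return cls(tuple(int(s) for s in shape[:3]), vox, tuple(float(v) for v in affine[:3, 3]))


@dataclass(frozen=True)
class GradientTable:
    """Diffusion-sensitizing scheme: per-measurement b-value (s/mm^2) and
    unit direction vector.

    Invariants enforced at construction: b >= 0 everywhere, at least one
    b = 0 entry, and every b > 0 direction has unit norm (re-normalized when
    within 1e-3 of unit, rejected otherwise).
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvecs.shape[0] != bvals.size:
            raise ValueError(
                f"length mismatch: {bvals.size} b-values vs {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        if not np.any(bvals == 0):
            raise ValueError("gradient table must contain at least one b=0 entry")
        bvecs = bvecs.copy()
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length direction vector with b > 0")
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("direction vectors with b > 0 must be unit length (within 1e-3)")
        bvecs[dw] /= norms[:, None]
        bvals.setflags(write=False)
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    def __eq__(self, other) -> bool:  # value semantics for tests
        return (
            isinstance(other, GradientTable)
            and self.bvals.shape == other.bvals.shape
            and np.allclose(self.bvals, other.bvals, atol=1e-9)
            and np.allclose(self.bvecs, other.bvecs, atol=1e-9)
        )


def default_gradient_table(b_value: float = DEFAULT_BVALUE) -> GradientTable:
    """The built-in 13-measurement scheme: one b=0 frame plus 12 diffusion
    directions of the (±2, 0, ±1)-permutation family normalized by √5.

    The second six directions repeat the first six with the unit component
    negated.  The printed source table is corrupt, so this reconstruction is
    a documented best effort; supply ``bval``/``bvec`` files to override it.
    """
    base = np.array(
        [
            [2, 0, 1], [0, 1, 2], [1, 2, 0], [2, 1, 0], [0, 2, 1], [1, 0, 2],
            [2, 0, -1], [0, -1, 2], [-1, 2, 0], [2, -1, 0], [0, 2, -1], [-1, 0, 2],
        ],
        dtype=float,
    ) / np.sqrt(5.0)
    bvals = np.concatenate([[0.0], np.full(12, float(b_value))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], base])
    return GradientTable(bvals, bvecs)


def _parse_numeric(source: str | os.PathLike) -> np.ndarray:
    """Accept either a path to a whitespace-separated text file or the text
    itself."""
    text = str(source)
    p = Path(text)
    try:
        if p.exists() and p.is_file():
            text = p.read_text()
    except OSError:
        pass
    rows = [r.split() for r in text.strip().splitlines() if r.strip()]
    try:
        return np.array([[float(x) for x in r] for r in rows], dtype=float)
    except ValueError as exc:
        raise ValueError(f"could not parse numeric table from {source!r}") from exc


def read_gradient_table(bval_source, bvec_source) -> GradientTable:
    """Parse FSL-style ``bval``/``bvec`` sources (paths or raw text).

    The bvec layout is auto-detected: 3 rows of n values (FSL dialect) or
    n rows of 3 values.  Both layouts of the same table parse identically.
    """
    bvals = _parse_numeric(bval_source).ravel()
    bvecs = _parse_numeric(bvec_source)
    if bvecs.ndim != 2:
        raise ValueError("bvec source must be a 2D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        if bvecs.shape[0] == 3:  # ambiguous 3x3 treated as FSL rows
            bvecs = bvecs.T
        else:
            raise ValueError(f"bvec table must have 3 rows or 3 columns, got {bvecs.shape}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] == 3:
        # 3x3 is genuinely ambiguous; FSL row-major is the convention here.
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"length mismatch: {bvals.size} b-values vs {bvecs.shape[0]} directions"
        )
    return GradientTable(bvals, bvecs)


def write_gradient_table(table: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL row-major bval/bvec text files."""
    Path(bval_path).write_text(" ".join(f"{b:.10g}" for b in table.bvals) + "\n")
    lines = [" ".join(f"{v:.10g}" for v in table.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class DWIStack:
    """A 4D diffusion-weighted stack: ``signal[x, y, slice, measurement]``,
    nonnegative intensities in arbitrary units, one frame per gradient-table
    entry."""

    grid: ImageGrid
    table: GradientTable
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4D (x, y, slice, measurement)")
        if self.signal.shape[:3] != self.grid.shape:
            raise ValueError(
                f"signal shape {self.signal.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.signal.shape[3] != len(self.table):
            raise ValueError(
                f"{self.signal.shape[3]} frames but gradient table has {len(self.table)} entries"
            )
        if np.any(self.signal < 0):
            raise ValueError("DWI signal must be nonnegative")


@dataclass
class ScalarMap:
    """A derived per-voxel scalar map (MD, TraceD, FA, ...).  Undefined
    voxels are NaN."""

    grid: ImageGrid
    values: np.ndarray
    name: str = "other"
    units: str = "mm^2/s"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class LabelMap:
    """Integer anatomical labels on a grid with a region-name legend.
    Label 0 is background and never appears in the legend."""

    grid: ImageGrid
    labels: np.ndarray
    legend: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        known = set(int(v) for v in self.legend.values())
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in map but absent from legend")

    def id_of(self, region: str) -> int:
        try:
            return int(self.legend[region])
        except KeyError:
            raise KeyError(f"region {region!r} not in legend {sorted(self.legend)}") from None

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == self.id_of(region)


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def _legend_sidecar(path) -> Path:
    p = Path(path)
    stem = p.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return p.with_name(stem + ".labels.json")


def write_volume(obj, path, *, table_paths: tuple | None = None) -> None:
    """Write a DWIStack, ScalarMap or LabelMap to NIfTI-1.

    A LabelMap's legend goes to a ``.labels.json`` sidecar.  For a DWIStack,
    pass ``table_paths=(bval_path, bvec_path)`` to write the gradient table
    alongside (defaults to ``<stem>.bval``/``<stem>.bvec``).
    """
    path = Path(path)
    if isinstance(obj, DWIStack):
        img = nib.Nifti1Image(obj.signal.astype(np.float64), obj.grid.affine())
        nib.save(img, str(path))
        if table_paths is None:
            stem = str(path)
            for suf in (".nii.gz", ".nii"):
                if stem.endswith(suf):
                    stem = stem[: -len(suf)]
            table_paths = (stem + ".bval", stem + ".bvec")
        write_gradient_table(obj.table, *table_paths)
    elif isinstance(obj, ScalarMap):
        img = nib.Nifti1Image(obj.values.astype(np.float64), obj.grid.affine())
        img.header["descrip"] = f"{obj.name} [{obj.units}]".encode()[:80]
        nib.save(img, str(path))
    elif isinstance(obj, LabelMap):
        img = nib.Nifti1Image(obj.labels.astype(np.int32), obj.grid.affine())
        nib.save(img, str(path))
        _legend_sidecar(path).write_text(json.dumps(obj.legend, indent=1, sort_keys=True))
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_volume(path, kind: str = "auto", table: GradientTable | None = None):
    """Read a NIfTI volume back as a DWIStack, ScalarMap or LabelMap.

    ``kind`` is one of ``{"auto", "dwi", "scalar", "labels"}``.  ``auto``
    maps 4D data to DWIStack (gradient table loaded from the bval/bvec
    siblings unless given), 3D integer data with a legend sidecar to
    LabelMap, and any other 3D data to ScalarMap.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = ImageGrid.from_affine(data.shape, img.affine)
    sidecar = _legend_sidecar(path)

    if kind == "auto":
        if data.ndim == 4:
            kind = "dwi"
        elif sidecar.exists():
            kind = "labels"
        else:
            kind = "scalar"

    if kind == "dwi":
        if data.ndim != 4:
            raise ValueError(f"{path} is {data.ndim}D; a DWI stack must be 4D")
        if table is None:
            stem = str(path)
            for suf in (".nii.gz", ".nii"):
                if stem.endswith(suf):
                    stem = stem[: -len(suf)]
            table = read_gradient_table(stem + ".bval", stem + ".bvec")
        return DWIStack(grid, table, data.astype(float))
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D volume")
    if kind == "labels":
        if not sidecar.exists():
            raise FileNotFoundError(f"label map {path} has no legend sidecar {sidecar}")
        legend = {str(k): int(v) for k, v in json.loads(sidecar.read_text()).items()}
        return LabelMap(grid, np.asarray(data).astype(np.int32), legend)
    if kind == "scalar":
        name = "other"
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
        if descrip:
            name = descrip.split(" [")[0]
        return ScalarMap(grid, data.astype(float), name=name)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_scalar_map(
    smap: ScalarMap,
    path=None,
    *,
    vmin: float | None = None,
    vmax: float | None = None,
    slice_index: int = 0,
    cmap: str = "jet",
) -> np.ndarray:
    """Render one slice of a scalar map as an 8-bit RGB color image.

    The default display window is 0 to 5.0e-4 mm^2/s, the conventional MD
    color-map range for rodent ex-vivo data; values at or below ``vmin``
    take the bottom palette color, values at or above ``vmax`` the top.
    Undefined (NaN) voxels render black.  Returns the RGB array; also writes
    a PNG when ``path`` is given.
    """
    if vmin is None and vmax is None:
        vmin, vmax = MD_RENDER_RANGE
    elif vmin is None or vmax is None:
        raise ValueError("give both vmin and vmax, or neither")
    if not vmin < vmax:
        raise ValueError(f"vmin must be < vmax, got ({vmin}, {vmax})")
    nz = smap.grid.shape[2]
    if not 0 <= slice_index < nz:
        raise IndexError(f"slice index {slice_index} out of range [0, {nz})")
    sl = smap.values[:, :, slice_index]
    norm = np.clip((sl - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = colormaps[cmap](np.nan_to_num(norm, nan=0.0))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~np.isfinite(sl)] = 0
    # image rows run along y: transpose to (row=y, col=x) for display
    rgb = np.transpose(rgb, (1, 0, 2))
    if path is not None:
        iio.imwrite(Path(path), rgb)
    return rgb
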