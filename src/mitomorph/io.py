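"""Reading and writing label volumes, meshes, and morphometry tables.

A :class:`LabelVolume` is the digital stand-in for a traced serial-section
EM stack: a 3D integer grid indexed ``(z, y, x)`` — z is the slice/cutting
axis — together with per-axis voxel spacing in nanometres and a table
mapping every nonzero label to a semantic class (mitochondrion,
presynaptic terminal, postsynaptic compartment, ...).

Two on-disk forms are supported:

* multi-page grayscale integer TIFF plus a mandatory JSON sidecar holding
  the spacing and label table (TIFF itself has no reliable 3D spacing
  convention), and
* HDF5 with one 3D integer dataset and the same metadata as attributes.

Spacing is never guessed: a volume can only be constructed when the voxel
size is supplied explicitly or found in the file metadata.  Internally all
lengths are nanometres; volumes and areas are converted to µm³/µm² only at
reporting boundaries (CSV tables, group statistics).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import trimesh

__all__ = [
    "SemanticClass",
    "Compartment",
    "VoxelSpacing",
    "LabelEntry",
    "LabelTable",
    "LabelVolume",
    "read_label_stack",
    "write_label_stack",
    "export_mesh",
    "write_morphometry_table",
    "read_morphometry_table",
    "MORPHOMETRY_COLUMNS",
]

NM3_PER_UM3 = 1e9
NM2_PER_UM2 = 1e6


class SemanticClass(str, Enum):
    """Annotation classes used in the segmentations."""

    BACKGROUND = "background"
    MITOCHONDRION = "mitochondrion"
    PRESYNAPTIC_TERMINAL = "presynaptic_terminal"
    POSTSYNAPTIC_COMPARTMENT = "postsynaptic_compartment"
    ENDOPLASMIC_RETICULUM = "endoplasmic_reticulum"
    MEMBRANE_INVAGINATION = "membrane_invagination"
    UNANNOTATED = "unannotated"


class Compartment(str, Enum):
    """Synaptic compartment a mitochondrion is assigned to."""

    PRESYNAPTIC = "presynaptic"
    POSTSYNAPTIC = "postsynaptic"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in nanometres.

    Parameters
    ----------
    dx, dy : float
        In-plane pixel size along x and y.
    dz : float
        Section thickness along the slice axis z.  Serial block-face data
        can be strongly anisotropic (e.g. 8.5 × 8.5 × 100 nm).
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"spacing {name}={v!r} must be positive and finite")

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Spacing ordered like array axes ``(z, y, x)``."""
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume_nm3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def mean_pitch_nm(self) -> float:
        """Mean per-axis pitch; the sub-voxel surface localisation scale."""
        return (self.dx + self.dy + self.dz) / 3.0

    def to_json_obj(self) -> dict:
        return {"dx_nm": self.dx, "dy_nm": self.dy, "dz_nm": self.dz}

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "VoxelSpacing":
        return cls(dx=float(obj["dx_nm"]), dy=float(obj["dy_nm"]), dz=float(obj["dz_nm"]))


@dataclass(frozen=True)
class LabelEntry:
    semantic_class: SemanticClass
    name: str


class LabelTable:
    """Mapping from integer label IDs to semantic classes.

    Label 0 is always background and need not be listed explicitly.
    """

    def __init__(self, entries: Mapping[int, LabelEntry] | None = None) -> None:
        self._entries: dict[int, LabelEntry] = {}
        if entries:
            for label, entry in entries.items():
                self.add(int(label), entry.semantic_class, entry.name)

    def add(self, label: int, semantic_class: SemanticClass | str, name: str | None = None) -> None:
        label = int(label)
        if label == 0:
            raise ValueError("label 0 is reserved for background")
        if label < 0:
            raise ValueError(f"label IDs must be non-negative, got {label}")
        cls = SemanticClass(semantic_class)
        self._entries[label] = LabelEntry(cls, name if name is not None else f"{cls.value}_{label}")

    @classmethod
    def from_pairs(cls, pairs: Mapping[int, SemanticClass | str]) -> "LabelTable":
        table = cls()
        for label, semantic in pairs.items():
            table.add(label, semantic)
        return table

    def __contains__(self, label: int) -> bool:
        return int(label) == 0 or int(label) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        return self._entries == other._entries

    @property
    def labels(self) -> list[int]:
        return sorted(self._entries)

    def entry(self, label: int) -> LabelEntry:
        if int(label) == 0:
            return LabelEntry(SemanticClass.BACKGROUND, "background")
        return self._entries[int(label)]

    def class_of(self, label: int) -> SemanticClass:
        return self.entry(label).semantic_class

    def ids_of_class(self, semantic_class: SemanticClass | str) -> list[int]:
        cls = SemanticClass(semantic_class)
        return sorted(l for l, e in self._entries.items() if e.semantic_class == cls)

    def classes(self) -> set[SemanticClass]:
        return {e.semantic_class for e in self._entries.values()}

    def class_lut(self, semantic_class: SemanticClass | str, size: int) -> np.ndarray:
        """Boolean lookup table of length ``size`` marking labels of a class."""
        lut = np.zeros(size, dtype=bool)
        for label in self.ids_of_class(semantic_class):
            if label < size:
                lut[label] = True
        return lut

    def to_json_obj(self) -> dict:
        return {
            str(label): {"class": e.semantic_class.value, "name": e.name}
            for label, e in sorted(self._entries.items())
        }

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "LabelTable":
        table = cls()
        for label, entry in obj.items():
            table.add(int(label), SemanticClass(entry["class"]), entry["name"])
        return table

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"LabelTable({len(self._entries)} labels, classes={sorted(c.value for c in self.classes())})"


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical spacing and a label table.

    ``grid`` is indexed ``(z, y, x)``; z indexes slices in cutting order.
    """

    grid: np.ndarray
    spacing: VoxelSpacing
    labels: LabelTable
    source_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D (z, y, x), got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError(f"grid must have an integer dtype, got {self.grid.dtype}")
        if any(s < 1 for s in self.grid.shape):
            raise ValueError(f"grid dimensions must all be >= 1, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def present_labels(self) -> np.ndarray:
        """Sorted array of labels that actually occur in the grid (incl. 0)."""
        max_label = int(self.grid.max(initial=0))
        if max_label >= 10_000_000:
            return np.unique(self.grid)
        counts = np.zeros(max_label + 1, dtype=np.int64)
        # chunked bincount: avoids the int64 promotion of the full ravel
        for z0 in range(0, self.grid.shape[0], 64):
            chunk = self.grid[z0 : z0 + 64]
            counts += np.bincount(chunk.ravel(), minlength=max_label + 1)
        return np.flatnonzero(counts)

    def validate_labels(self, permissive: bool = False) -> "LabelVolume":
        """Check that every nonzero label in the grid appears in the table.

        With ``permissive=True`` unknown labels are added to the table as
        :attr:`SemanticClass.UNANNOTATED` instead of raising; silent class
        misassignment would corrupt compartment statistics, so this is
        opt-in only.
        """
        unknown = [int(l) for l in self.present_labels() if l != 0 and l not in self.labels]
        if unknown:
            if not permissive:
                raise ValueError(
                    f"labels {unknown} occur in the grid but are missing from the "
                    "label table; pass permissive=True to map them to 'unannotated'"
                )
            for label in unknown:
                self.labels.add(label, SemanticClass.UNANNOTATED, f"unannotated_{label}")
        if int(self.grid.min(initial=0)) < 0:
            raise ValueError("grid contains negative labels")
        return self

    def class_mask(self, semantic_class: SemanticClass | str) -> np.ndarray:
        """Boolean mask of all voxels whose label belongs to a class."""
        max_label = int(self.grid.max(initial=0))
        lut = self.labels.class_lut(semantic_class, max_label + 1)
        return lut[self.grid]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("tiff", "hdf5"):
            raise ValueError(f"unsupported format {fmt!r}; use 'tiff' or 'hdf5'")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format explicitly")


def read_label_stack(
    path: str | Path,
    format: str | None = None,
    spacing: VoxelSpacing | None = None,
    labels: LabelTable | None = None,
    permissive: bool = False,
    source_id: str | None = None,
) -> LabelVolume:
    """Read a segmentation stack into a :class:`LabelVolume`.

    Parameters
    ----------
    path
        TIFF stack (with JSON sidecar) or HDF5 file.
    format
        ``"tiff"`` or ``"hdf5"``; inferred from the suffix when omitted.
    spacing, labels
        Explicit metadata; when omitted they must be present in the sidecar
        (TIFF) or attributes (HDF5).  Missing spacing is always an error —
        never guessed.
    permissive
        Map grid labels absent from the table to ``unannotated`` instead of
        failing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)

    if fmt == "tiff":
        grid = tifffile.imread(path)
        if grid.ndim == 2:
            grid = grid[None]
        if grid.ndim != 3 or grid.dtype == object:
            raise ValueError(f"{path}: expected a stack of equal-sized 2D integer pages")
        if not np.issubdtype(grid.dtype, np.integer):
            raise TypeError(f"{path}: non-integer pixel type {grid.dtype}")
        meta: dict = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if spacing is None:
            if "spacing" not in meta:
                raise ValueError(
                    f"{path}: voxel spacing not provided and no 'spacing' entry in "
                    f"sidecar {sidecar.name}; refusing to guess"
                )
            spacing = VoxelSpacing.from_json_obj(meta["spacing"])
        if labels is None:
            if "labels" not in meta:
                raise ValueError(
                    f"{path}: label table not provided and no 'labels' entry in sidecar"
                )
            labels = LabelTable.from_json_obj(meta["labels"])
        if source_id is None:
            source_id = meta.get("source_id", str(path))
    else:
        with h5py.File(path, "r") as f:
            if "labels" not in f:
                raise ValueError(f"{path}: missing 'labels' dataset")
            dset = f["labels"]
            if dset.ndim != 3:
                raise ValueError(f"{path}: 'labels' dataset must be 3D, got ndim={dset.ndim}")
            if not np.issubdtype(dset.dtype, np.integer):
                raise TypeError(f"{path}: non-integer dataset type {dset.dtype}")
            grid = dset[()]
            attrs = dict(f.attrs)
        if spacing is None:
            missing = [k for k in ("spacing_dx_nm", "spacing_dy_nm", "spacing_dz_nm") if k not in attrs]
            if missing:
                raise ValueError(
                    f"{path}: voxel spacing not provided and attributes {missing} absent; "
                    "refusing to guess"
                )
            spacing = VoxelSpacing(
                dx=float(attrs["spacing_dx_nm"]),
                dy=float(attrs["spacing_dy_nm"]),
                dz=float(attrs["spacing_dz_nm"]),
            )
        if labels is None:
            if "label_table" not in attrs:
                raise ValueError(f"{path}: label table not provided and 'label_table' attribute absent")
            labels = LabelTable.from_json_obj(json.loads(attrs["label_table"]))
        if source_id is None:
            source_id = str(attrs.get("source_id", str(path)))

    volume = LabelVolume(grid=grid, spacing=spacing, labels=labels, source_id=source_id or str(path))
    return volume.validate_labels(permissive=permissive)


def write_label_stack(volume: LabelVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a :class:`LabelVolume` losslessly; round-trips with
    :func:`read_label_stack` bit-exactly for grid, spacing, and table."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)

    if fmt == "tiff":
        # explicit photometric: a 3-slice stack must stay a z-stack, not RGB
        tifffile.imwrite(path, volume.grid, photometric="minisblack")
        sidecar = _sidecar_path(path)
        sidecar.write_text(
            json.dumps(
                {
                    "spacing": volume.spacing.to_json_obj(),
                    "labels": volume.labels.to_json_obj(),
                    "source_id": volume.source_id,
                },
                indent=1,
                sort_keys=True,
            )
        )
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=volume.grid, compression="gzip", compression_opts=1)
            f.attrs["spacing_dx_nm"] = volume.spacing.dx
            f.attrs["spacing_dy_nm"] = volume.spacing.dy
            f.attrs["spacing_dz_nm"] = volume.spacing.dz
            f.attrs["label_table"] = json.dumps(volume.labels.to_json_obj(), sort_keys=True)
            f.attrs["source_id"] = volume.source_id
    return path


def export_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Export a triangle surface mesh (vertex coordinates in nm) to OBJ or PLY.

    The mesh must have at least 4 vertices and 4 triangular faces, and every
    face index must reference an existing vertex.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}; use 'obj' or 'ply'")
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise ValueError("vertices must be an (n, 3) array")
    if faces.ndim != 2 or faces.shape[1] != 3 or len(faces) == 0:
        raise ValueError("faces must be a nonempty (m, 3) array of triangles")
    if len(vertices) < 4 or len(faces) < 4:
        raise ValueError("degenerate mesh: need >= 4 vertices and >= 4 faces")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise ValueError("face index out of range")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path, file_type=fmt)
    return path


#: Column order for morphometry CSV tables.  Volumes are µm³, areas µm²,
#: extents µm; MCI is dimensionless.
MORPHOMETRY_COLUMNS = [
    "object_id",
    "volume_um3",
    "surface_area_um2",
    "mci",
    "extent_um",
    "n_voxels",
    "compartment",
    "spanned_terminals",
    "touches_boundary",
]


def write_morphometry_table(records: Sequence, path: str | Path, float_format: str = "%.6g") -> Path:
    """Write per-mitochondrion morphometry records to CSV.

    ``records`` may be dataclass instances (e.g. ``MitoMorphometry``) or
    mappings with the :data:`MORPHOMETRY_COLUMNS` fields.  An empty record
    list yields a header-only CSV.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rec = dataclasses.asdict(rec)
        rows.append({c: rec.get(c) for c in MORPHOMETRY_COLUMNS})
    frame = pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)
    if len(frame):
        frame["compartment"] = [
            c.value if isinstance(c, Compartment) else c for c in frame["compartment"]
        ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=float_format)
    return path


def read_morphometry_table(path: str | Path) -> pd.DataFrame:
    """Read a morphometry CSV back into a DataFrame."""
    return pd.read_csv(path)
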