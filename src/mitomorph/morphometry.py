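"""Per-mitochondrion 3D morphometry: volume, surface area, shape complexity, extent.

Individual mitochondria are extracted from a :class:`~mitomorph.io.LabelVolume`
as 3D connected components of the mitochondrion class — serial-section
tracings show several 2D profiles per slice that belong to one organelle, so
connectivity is resolved in 3D, not per slice.  For each component the module
computes:

* **volume** — exact voxel count × physical voxel volume (no estimation);
* **surface area** — default: area of a marching-cubes isosurface extracted
  from the (lightly smoothed) binary mask with true anisotropic spacing;
  a transparent voxel-face-counting estimator is kept as a diagnostic (it
  systematically over-estimates curved surfaces by up to ~50%);
* **mitochondrial complexity index (MCI)** — the dimensionless,
  scale-invariant score ``SA³ / (16 π² V²)``; a sphere scores 9/(4π) ≈ 0.716
  and the isoperimetric inequality makes that the lower bound.  A normalised
  variant ``SA³ / (36 π V²)`` (sphere = 1) is available behind a flag;
* **extent** — span of the voxel centres projected on the first principal
  axis, in µm; the natural "length" of an elongated organelle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .io import (
    NM2_PER_UM2,
    NM3_PER_UM3,
    Compartment,
    LabelVolume,
    SemanticClass,
    VoxelSpacing,
)

__all__ = [
    "SegmentedObject",
    "MitoMorphometry",
    "MeasureConfig",
    "connected_components",
    "object_volume",
    "object_surface_area",
    "object_mesh",
    "mci",
    "MCI_SPHERE",
    "object_extent",
    "measure_all",
]

#: MCI of a perfect sphere under the default ("vincent") constant.
MCI_SPHERE = 9.0 / (4.0 * np.pi)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentedObject:
    """One 3D-connected component of a label volume.

    The voxel set is stored as a boolean mask cropped to the component's
    bounding box, with ``offset`` giving the crop origin in global
    ``(z, y, x)`` indices.
    """

    object_id: int
    semantic_class: SemanticClass
    mask: np.ndarray
    offset: tuple[int, int, int]
    spacing: VoxelSpacing
    source_id: str = ""
    touches_boundary: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or not self.mask.any():
            raise ValueError("object mask must be a nonempty 3D boolean array")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_indices(self) -> np.ndarray:
        """Global ``(n, 3)`` integer voxel indices ``(z, y, x)``."""
        zyx = np.argwhere(self.mask)
        return zyx + np.asarray(self.offset, dtype=zyx.dtype)

    def voxel_centers_nm(self) -> np.ndarray:
        """Physical voxel-centre coordinates ``(n, 3)`` in nm, order (z, y, x).

        The centre of voxel ``(z, y, x)`` sits at ``((z + 0.5) dz, ...)``.
        """
        idx = self.voxel_indices().astype(np.float64)
        idx += 0.5
        idx *= np.asarray(self.spacing.zyx)
        return idx


@dataclass
class MitoMorphometry:
    """Measurement record for one mitochondrion (reporting units)."""

    object_id: int
    volume_um3: float
    surface_area_um2: float
    mci: float
    extent_um: float
    n_voxels: int
    compartment: Compartment = Compartment.UNASSIGNED
    spanned_terminals: int = 0
    touches_boundary: bool = False


@dataclass(frozen=True)
class MeasureConfig:
    """Knobs for :func:`measure_all`.

    ``connectivity`` defaults to 26 — human tracers connect oblique
    profiles that only share corners.  ``min_voxels`` is 0 (no size
    filter); raise it for noise-injected synthetic scenes.
    ``exclude_boundary`` drops volume-truncated objects instead of merely
    flagging them.
    """

    connectivity: int = 26
    surface_method: str = "mesh"
    mci_variant: str = "vincent"
    smooth_sigma_nm: float | None = None
    min_voxels: int = 0
    exclude_boundary: bool = False


def connected_components(
    volume: LabelVolume,
    class_filter: SemanticClass | str = SemanticClass.MITOCHONDRION,
    connectivity: int = 26,
) -> list[SegmentedObject]:
    """Partition all voxels of one semantic class into 3D connected components.

    Components are ordered (and numbered from 1) by their lexicographically
    smallest ``(z, y, x)`` voxel, which makes object IDs stable across runs.
    An absent class raises; a present class with zero voxels returns ``[]``.
    """
    cls = SemanticClass(class_filter)
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    if cls not in volume.labels.classes():
        raise ValueError(f"class {cls.value!r} is not present in the label table")
    mask = volume.class_mask(cls)
    # Label into a uint16 array when it can hold the component count; the
    # int32 default would double the footprint on gigavoxel stacks.
    labeled = np.zeros(mask.shape, dtype=np.uint16)
    try:
        n = ndimage.label(mask, structure=_STRUCTURES[connectivity], output=labeled)
    except RuntimeError:  # more components than uint16 can hold
        labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    del mask
    if n == 0:
        return []
    slices = ndimage.find_objects(labeled)
    shape = volume.shape

    # First-encountered voxel in C (raster) order == lexicographic minimum.
    first_voxel = []
    for lab, slc in enumerate(slices, start=1):
        crop = labeled[slc] == lab
        rel = np.unravel_index(np.argmax(crop), crop.shape)
        first_voxel.append(tuple(rel[i] + slc[i].start for i in range(3)))
    order = sorted(range(n), key=lambda i: first_voxel[i])

    objects: list[SegmentedObject] = []
    for new_id, i in enumerate(order, start=1):
        slc = slices[i]
        crop = labeled[slc] == (i + 1)
        touches = any(
            slc[ax].start == 0 or slc[ax].stop == shape[ax] for ax in range(3)
        )
        objects.append(
            SegmentedObject(
                object_id=new_id,
                semantic_class=cls,
                mask=crop,
                offset=(slc[0].start, slc[1].start, slc[2].start),
                spacing=volume.spacing,
                source_id=volume.source_id,
                touches_boundary=touches,
            )
        )
    return objects


def object_volume(obj: SegmentedObject) -> float:
    """Exact object volume in µm³: voxel count × physical voxel volume."""
    return obj.n_voxels * obj.spacing.voxel_volume_nm3 / NM3_PER_UM3


def _smooth_sigma_vox(spacing: VoxelSpacing, sigma_nm: float | None) -> tuple[float, float, float]:
    # Default: blur at 0.8× the coarsest sampling axis, isotropically in
    # physical space.  On anisotropic stacks the staircase "risers" at each
    # slice edge are wide in-plane features, so the blur must act at the
    # slice-thickness scale along every axis to bevel them.
    if sigma_nm is None:
        sigma_nm = 0.8 * max(spacing.dx, spacing.dy, spacing.dz)
    return tuple(sigma_nm / s for s in spacing.zyx)  # type: ignore[return-value]


def object_mesh(
    obj: SegmentedObject,
    smooth_sigma_nm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isosurface triangulation of the object's mask in physical nm coordinates.

    The binary mask is padded, converted to a float field, smoothed with an
    isotropic physical-space Gaussian (default σ = 0.8 × the largest
    spacing component) and triangulated with marching cubes using the true
    anisotropic spacing.  Smoothing removes the voxel staircase that would
    otherwise bias the area of curved surfaces upward; the iso-level is
    then chosen as the field quantile that preserves the exact voxel count
    (a volume-matched level), which cancels the inward surface shift the
    blur would otherwise introduce on small objects.  If smoothing washes a
    tiny object out entirely, the raw mask is triangulated at level 0.5
    instead — single-voxel objects never fail.

    Returns ``(vertices_nm, faces)``; vertices are absolute (global)
    coordinates, order ``(z, y, x)``.
    """
    sigma = _smooth_sigma_vox(obj.spacing, smooth_sigma_nm)
    pad = np.ceil(4 * np.asarray(sigma)).astype(int) + 2
    field = np.pad(obj.mask, [(p, p) for p in pad]).astype(np.float32)
    ndimage.gaussian_filter(field, sigma=sigma, output=field)
    flat = field.ravel()
    n = obj.n_voxels
    level = float(np.partition(flat, flat.size - n)[flat.size - n])
    fmax = float(field.max())
    if not (1e-3 < level < fmax * 0.999):
        # Degenerate (tiny object over-smoothed): mesh the raw mask.
        field = np.pad(obj.mask, [(p, p) for p in pad]).astype(np.float32)
        level = 0.5
    verts, faces, _, _ = marching_cubes(field, level=level, spacing=obj.spacing.zyx)
    shift = (np.asarray(obj.offset, dtype=np.float64) - pad + 0.5) * np.asarray(
        obj.spacing.zyx
    )
    return verts + shift, faces


def object_surface_area(
    obj: SegmentedObject,
    method: str = "mesh",
    smooth_sigma_nm: float | None = None,
) -> float:
    """Surface area of one object in µm².

    ``method="mesh"`` (reporting default) measures the marching-cubes
    isosurface; ``method="voxel_faces"`` sums the physical areas of exposed
    voxel faces — a transparent diagnostic that over-estimates curved
    surfaces and upper-bounds the mesh value.
    """
    if method == "mesh":
        verts, faces = object_mesh(obj, smooth_sigma_nm=smooth_sigma_nm)
        return float(mesh_surface_area(verts, faces)) / NM2_PER_UM2
    if method == "voxel_faces":
        dz, dy, dx = obj.spacing.zyx
        padded = np.pad(obj.mask, 1)
        area_nm2 = 0.0
        face_areas = (dx * dy, dx * dz, dy * dz)  # faces normal to z, y, x
        for axis, a in enumerate(face_areas):
            transitions = np.diff(padded, axis=axis)
            area_nm2 += a * np.count_nonzero(transitions)
        return area_nm2 / NM2_PER_UM2
    raise ValueError(f"unknown surface-area method {method!r}")


def mci(surface_area: float, volume: float, variant: str = "vincent") -> float:
    """Mitochondrial complexity index from surface area and volume.

    ``variant="vincent"`` (default): ``SA³ / (16 π² V²)``; a sphere scores
    ``9/(4π)``.  ``variant="normalized"``: ``SA³ / (36 π V²)``; a sphere
    scores exactly 1.  Both are scale-invariant:
    ``mci(s²·SA, s³·V) == mci(SA, V)`` for any ``s > 0`` — units cancel as
    long as area and volume use the same length unit.
    """
    if not (surface_area > 0 and volume > 0):
        raise ValueError(f"surface area and volume must be positive, got SA={surface_area}, V={volume}")
    if variant == "vincent":
        return surface_area**3 / (16.0 * np.pi**2 * volume**2)
    if variant == "normalized":
        return surface_area**3 / (36.0 * np.pi * volume**2)
    raise ValueError(f"unknown MCI variant {variant!r}")


def object_extent(obj: SegmentedObject) -> float:
    """Longest principal-axis extent of the voxel centres, in µm.

    Centres are taken in physical nm coordinates, projected on the first
    principal axis (largest-eigenvalue eigenvector of their covariance),
    and the max-minus-min span is returned.  A single voxel has extent 0.
    """
    centers = obj.voxel_centers_nm()
    if len(centers) == 1:
        return 0.0
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]  # eigh sorts ascending
    proj = centered @ axis
    return float(proj.max() - proj.min()) / 1000.0


def measure_all(volume: LabelVolume, config: MeasureConfig = MeasureConfig()) -> list[MitoMorphometry]:
    """Measure every connected mitochondrion in a label volume.

    Compartment and spanned-terminal fields are left at their defaults for
    the synapse-mapping stage to fill.  Ordering and IDs are deterministic
    (see :func:`connected_components`).
    """
    objects = connected_components(
        volume, SemanticClass.MITOCHONDRION, connectivity=config.connectivity
    )
    records: list[MitoMorphometry] = []
    for obj in objects:
        if obj.n_voxels < config.min_voxels:
            continue
        if config.exclude_boundary and obj.touches_boundary:
            continue
        try:
            vol = object_volume(obj)
            area = object_surface_area(
                obj, method=config.surface_method, smooth_sigma_nm=config.smooth_sigma_nm
            )
            records.append(
                MitoMorphometry(
                    object_id=obj.object_id,
                    volume_um3=vol,
                    surface_area_um2=area,
                    mci=mci(area, vol, variant=config.mci_variant),
                    extent_um=object_extent(obj),
                    n_voxels=obj.n_voxels,
                    touches_boundary=obj.touches_boundary,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"measurement failed for object {obj.object_id} "
                f"(source {obj.source_id!r}, {obj.n_voxels} voxels)"
            ) from exc
    return records
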