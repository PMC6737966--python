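"""Synthetic label volumes with analytic ground truth.

Real inputs to this kind of analysis are manually traced serial-section EM
stacks, which cannot be regenerated at desk scale.  This module builds
label volumes whose statistical structure matches the four study regions —
nucleus accumbens (NA, 4×4×4 nm voxels), hippocampal CA1 (8×8×8 nm),
somatosensory cortex (6×6×30 nm) and dorsal cochlear nucleus (DCN,
8.5×8.5×100 nm) — from parametric organelle phantoms with closed-form
volume and surface area, so every pipeline stage can be validated against
exact ground truth.

Phantom mitochondria are capsules (spherocylinders): presynaptic ones are
short and near-spherical, postsynaptic ones elongated, mirroring the
small-and-short vs long-and-filamentous morphology seen in the tracings.
Per-object volumes are drawn from log-normal distributions (a three-
component log-normal mixture for the cortex postsynaptic group, which has
visibly distinct subpopulations) parameterised so the arithmetic mean
matches the region's group mean and the spread matches s.e.m.·√n.  Each
mitochondrion sits inside its own compartment phantom (terminal or
dendrite) so the compartment-assignment stage can be exercised end to end.

Voxelisation uses the voxel-centre inclusion rule: a voxel belongs to a
shape iff its centre lies inside the continuous shape.  This is unambiguous
and keeps the voxel-count volume an exact, independently recomputable
oracle; anti-aliasing would break that exactness.  Seeds are mandatory
wherever randomness exists and are recorded in the manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io import (
    NM2_PER_UM2,
    NM3_PER_UM3,
    Compartment,
    LabelTable,
    LabelVolume,
    SemanticClass,
    VoxelSpacing,
)

__all__ = [
    "Sphere",
    "Capsule",
    "Ellipsoid",
    "BranchedTube",
    "LogNormalComponent",
    "GroupSpec",
    "CohortParams",
    "Fig3Params",
    "ManifestObject",
    "GroundTruthManifest",
    "voxelize_shape",
    "generate_cohort",
    "generate_fig3_scene",
    "add_boundary_jitter",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("NA", "CA1", "cortex", "DCN", "fig3")

_ORGANELLE_CLASSES = {
    SemanticClass.MITOCHONDRION,
    SemanticClass.ENDOPLASMIC_RETICULUM,
    SemanticClass.MEMBRANE_INVAGINATION,
}
_COMPARTMENT_CLASSES = {
    SemanticClass.PRESYNAPTIC_TERMINAL,
    SemanticClass.POSTSYNAPTIC_COMPARTMENT,
}


# ---------------------------------------------------------------------------
# Parametric shapes (all coordinates (z, y, x) in nm)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sphere:
    center_nm: tuple[float, float, float]
    radius_nm: float

    @property
    def analytic_volume_nm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_nm**3

    @property
    def analytic_surface_nm2(self) -> float:
        return 4.0 * math.pi * self.radius_nm**2

    def bounds_nm(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_nm)
        return c - self.radius_nm, c + self.radius_nm

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        cz, cy, cx = self.center_nm
        d2 = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
        return d2 <= self.radius_nm**2

    def to_json_obj(self) -> dict:
        return {"shape": "sphere", "center_nm": list(self.center_nm), "radius_nm": self.radius_nm}


@dataclass(frozen=True)
class Capsule:
    """Spherocylinder: cylinder of radius r between two endpoints + hemispherical caps."""

    p0_nm: tuple[float, float, float]
    p1_nm: tuple[float, float, float]
    radius_nm: float

    @property
    def axis_length_nm(self) -> float:
        """Cylindrical segment length (tip-to-tip length is this + 2r)."""
        return float(np.linalg.norm(np.subtract(self.p1_nm, self.p0_nm)))

    @property
    def tip_to_tip_nm(self) -> float:
        return self.axis_length_nm + 2.0 * self.radius_nm

    @property
    def analytic_volume_nm3(self) -> float:
        r, L = self.radius_nm, self.axis_length_nm
        return math.pi * r**2 * L + 4.0 / 3.0 * math.pi * r**3

    @property
    def analytic_surface_nm2(self) -> float:
        r, L = self.radius_nm, self.axis_length_nm
        return 2.0 * math.pi * r * L + 4.0 * math.pi * r**2

    def bounds_nm(self) -> tuple[np.ndarray, np.ndarray]:
        p0, p1 = np.asarray(self.p0_nm), np.asarray(self.p1_nm)
        return np.minimum(p0, p1) - self.radius_nm, np.maximum(p0, p1) + self.radius_nm

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0_nm, dtype=np.float32)
        d = np.asarray(self.p1_nm, dtype=np.float32) - p0
        L2 = float(d @ d)
        coords = (z, y, x)
        if L2 == 0.0:
            d2 = sum((np.asarray(c, dtype=np.float32) - p0[i]) ** 2 for i, c in enumerate(coords))
            return d2 <= np.float32(self.radius_nm**2)
        t = sum((np.asarray(c, dtype=np.float32) - p0[i]) * d[i] for i, c in enumerate(coords))
        t /= np.float32(L2)
        np.clip(t, 0.0, 1.0, out=t)
        d2 = np.zeros_like(t)
        for i, c in enumerate(coords):
            comp = np.asarray(c, dtype=np.float32) - p0[i] - t * d[i]
            d2 += comp * comp
        return d2 <= np.float32(self.radius_nm**2)

    def to_json_obj(self) -> dict:
        return {
            "shape": "capsule",
            "p0_nm": list(map(float, self.p0_nm)),
            "p1_nm": list(map(float, self.p1_nm)),
            "radius_nm": self.radius_nm,
        }


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned or rotated ellipsoid; surface area by the Thomsen
    approximation (p = 1.6075, relative error below ~1.1%)."""

    center_nm: tuple[float, float, float]
    semi_axes_nm: tuple[float, float, float]
    rotation: tuple[tuple[float, float, float], ...] | None = None

    @property
    def analytic_volume_nm3(self) -> float:
        a, b, c = self.semi_axes_nm
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def analytic_surface_nm2(self) -> float:
        a, b, c = self.semi_axes_nm
        p = 1.6075
        return 4.0 * math.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3.0) ** (1.0 / p)

    def _rot(self) -> np.ndarray:
        if self.rotation is None:
            return np.eye(3)
        return np.asarray(self.rotation, dtype=float)

    def bounds_nm(self) -> tuple[np.ndarray, np.ndarray]:
        # Extent of a rotated ellipsoid along axis i: sqrt(sum_j (R[i,j] a_j)^2)
        R = self._rot()
        ext = np.sqrt(((R * np.asarray(self.semi_axes_nm)) ** 2).sum(axis=1))
        c = np.asarray(self.center_nm)
        return c - ext, c + ext

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        R = self._rot().astype(np.float32)
        c = np.asarray(self.center_nm, dtype=np.float32)
        axes = np.asarray(self.semi_axes_nm, dtype=np.float32)
        coords = (z, y, x)
        q = np.zeros(np.broadcast_shapes(*(np.shape(c_) for c_ in coords)), dtype=np.float32)
        for i in range(3):
            body = sum(
                np.float32(R[i, j]) * (np.asarray(coords[j], dtype=np.float32) - c[j])
                for j in range(3)
            )
            q += (body / axes[i]) ** 2
        return q <= 1.0

    def to_json_obj(self) -> dict:
        return {
            "shape": "ellipsoid",
            "center_nm": list(map(float, self.center_nm)),
            "semi_axes_nm": list(map(float, self.semi_axes_nm)),
            "rotation": None if self.rotation is None else [list(map(float, r)) for r in self.rotation],
        }


@dataclass(frozen=True)
class BranchedTube:
    """Union of capsules radiating from a hub — an MCI stress phantom.

    No closed-form surface area exists for the union (arms overlap at the
    hub), so the analytic surface is ``None``; volume and area are bounded
    by the sums over arms.
    """

    center_nm: tuple[float, float, float]
    arm_directions: tuple[tuple[float, float, float], ...]
    arm_length_nm: float
    radius_nm: float

    def _arms(self) -> list[Capsule]:
        c = np.asarray(self.center_nm, dtype=float)
        arms = []
        for d in self.arm_directions:
            u = np.asarray(d, dtype=float)
            u = u / np.linalg.norm(u)
            arms.append(Capsule(tuple(c), tuple(c + u * self.arm_length_nm), self.radius_nm))
        return arms

    @property
    def analytic_volume_nm3(self) -> None:
        return None

    @property
    def analytic_surface_nm2(self) -> None:
        return None

    def bounds_nm(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(a.bounds_nm() for a in self._arms()))
        return np.min(los, axis=0), np.max(his, axis=0)

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        inside = None
        for arm in self._arms():
            m = arm.contains(z, y, x)
            inside = m if inside is None else (inside | m)
        return inside

    def to_json_obj(self) -> dict:
        return {
            "shape": "branched_tube",
            "center_nm": list(map(float, self.center_nm)),
            "arm_directions": [list(map(float, d)) for d in self.arm_directions],
            "arm_length_nm": self.arm_length_nm,
            "radius_nm": self.radius_nm,
        }


Shape = Sphere | Capsule | Ellipsoid | BranchedTube


def voxelize_shape(
    shape: Shape,
    spacing: VoxelSpacing,
    grid_shape: tuple[int, int, int],
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, int]:
    """Voxelise a continuous shape onto a grid; returns ``(mask, n_voxels)``.

    Voxel ``(z, y, x)`` has its centre at ``origin + ((z, y, x) + 0.5) ·
    spacing`` and is included iff the centre lies inside the shape.  The
    shape must fit inside the grid's physical bounds.
    """
    step = np.asarray(spacing.zyx)
    origin = np.asarray(origin_nm, dtype=float)
    lo, hi = shape.bounds_nm()
    phys_hi = origin + np.asarray(grid_shape) * step
    if np.any(lo < origin - 1e-9) or np.any(hi > phys_hi + 1e-9):
        raise ValueError(
            f"shape bounds {lo.tolist()}..{hi.tolist()} nm exceed grid extent "
            f"{origin.tolist()}..{phys_hi.tolist()} nm"
        )
    # Only evaluate inside the shape's index-space bounding box.
    i_lo = np.maximum(0, np.floor((lo - origin) / step - 0.5).astype(int))
    i_hi = np.minimum(grid_shape, np.ceil((hi - origin) / step + 0.5).astype(int))
    mask = np.zeros(grid_shape, dtype=bool)
    if np.any(i_hi <= i_lo):
        return mask, 0
    zz = (origin[0] + (np.arange(i_lo[0], i_hi[0]) + 0.5) * step[0]).astype(np.float32)
    yy = (origin[1] + (np.arange(i_lo[1], i_hi[1]) + 0.5) * step[1]).astype(np.float32)
    xx = (origin[2] + (np.arange(i_lo[2], i_hi[2]) + 0.5) * step[2]).astype(np.float32)
    sub = shape.contains(zz[:, None, None], yy[None, :, None], xx[None, None, :])
    mask[i_lo[0] : i_hi[0], i_lo[1] : i_hi[1], i_lo[2] : i_hi[2]] = sub
    return mask, int(sub.sum())


# ---------------------------------------------------------------------------
# Cohort parameters and presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalComponent:
    """One log-normal mixture component for per-object volumes (µm³)."""

    weight: float
    median_um3: float
    gsd: float  # geometric standard deviation, > 1 for nondegenerate spread

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.median_um3 <= 0 or self.gsd < 1.0:
            raise ValueError(f"invalid log-normal component {self!r}")

    @classmethod
    def from_mean_sd(cls, mean_um3: float, sd_um3: float, weight: float = 1.0) -> "LogNormalComponent":
        """Component whose arithmetic mean and sd match the given values."""
        if mean_um3 <= 0 or sd_um3 < 0:
            raise ValueError("mean must be positive and sd non-negative")
        sigma2 = math.log1p((sd_um3 / mean_um3) ** 2)
        return cls(weight=weight, median_um3=mean_um3 * math.exp(-sigma2 / 2.0), gsd=math.exp(math.sqrt(sigma2)))

    @property
    def mean_um3(self) -> float:
        s2 = math.log(self.gsd) ** 2
        return self.median_um3 * math.exp(s2 / 2.0)

    @property
    def sd_um3(self) -> float:
        s2 = math.log(self.gsd) ** 2
        return self.mean_um3 * math.sqrt(math.expm1(s2))


@dataclass(frozen=True)
class GroupSpec:
    """Per-compartment generator settings for one region preset."""

    n: int
    components: tuple[LogNormalComponent, ...]
    aspect_range: tuple[float, float]  # tip-to-tip length / diameter of the capsule
    target_mean_um3: float
    target_sem_um3: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group count n must be >= 1")
        w = sum(c.weight for c in self.components)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        lo, hi = self.aspect_range
        if not (1.0 <= lo <= hi):
            raise ValueError(f"aspect range must satisfy 1 <= lo <= hi, got {self.aspect_range}")

    @property
    def mixture_mean_um3(self) -> float:
        return sum(c.weight * c.mean_um3 for c in self.components)


@dataclass(frozen=True)
class CohortParams:
    """Everything needed to generate one synthetic region cohort."""

    name: str
    spacing: VoxelSpacing
    groups: Mapping[str, GroupSpec]  # keys: "presynaptic", "postsynaptic"
    seed: int
    jitter_amplitude_vox: int = 0
    compartment_pad_nm: float = 40.0
    margin_vox: int = 2
    min_radius_factor: float = 1.5  # floor on capsule radius, × max spacing

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class Fig3Params:
    """A dendrite contacted by several boutons, with one long mitochondrion."""

    boutons: int
    extent_fraction: float
    spacing: VoxelSpacing
    seed: int
    dendrite_radius_nm: float = 400.0
    mito_radius_nm: float = 200.0
    bouton_radius_nm: float = 300.0
    cleft_nm: float = 8.0
    bouton_pitch_nm: float = 1500.0


@dataclass
class ManifestObject:
    """Ground truth for one planted object (organelle or compartment)."""

    label: int
    semantic_class: SemanticClass
    shape: dict
    compartment: Compartment | None = None
    analytic_volume_um3: float | None = None
    analytic_surface_um2: float | None = None
    analytic_mci: float | None = None
    analytic_extent_um: float | None = None
    realized_voxels: int = 0
    spanned_bouton_ids: list[int] = field(default_factory=list)

    def to_json_obj(self) -> dict:
        return {
            "label": self.label,
            "class": self.semantic_class.value,
            "shape": self.shape,
            "compartment": self.compartment.value if self.compartment else None,
            "analytic_volume_um3": self.analytic_volume_um3,
            "analytic_surface_um2": self.analytic_surface_um2,
            "analytic_mci": self.analytic_mci,
            "analytic_extent_um": self.analytic_extent_um,
            "realized_voxels": self.realized_voxels,
            "spanned_bouton_ids": self.spanned_bouton_ids,
        }


@dataclass
class GroundTruthManifest:
    """Complete record of a generated scene: seed, parameters, per-object truth."""

    preset: str
    seed: int
    spacing: VoxelSpacing
    objects: list[ManifestObject]

    def mitochondria(self, compartment: Compartment | None = None) -> list[ManifestObject]:
        out = [o for o in self.objects if o.semantic_class == SemanticClass.MITOCHONDRION]
        if compartment is not None:
            out = [o for o in out if o.compartment == compartment]
        return out

    def to_json_obj(self) -> dict:
        return {
            "preset": self.preset,
            "seed": self.seed,
            "spacing": self.spacing.to_json_obj(),
            "objects": [o.to_json_obj() for o in self.objects],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_obj(), indent=1, sort_keys=True) + "\n")
        return path

    def check_complete(self, volume: LabelVolume) -> None:
        """Every nonzero label in the volume must have exactly one entry."""
        present = {int(l) for l in volume.present_labels() if l != 0}
        listed = [o.label for o in self.objects]
        if len(listed) != len(set(listed)):
            raise AssertionError("duplicate labels in manifest")
        if present != set(listed):
            raise AssertionError(
                f"manifest incomplete: volume labels {sorted(present)} vs manifest {sorted(listed)}"
            )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _sample_volumes_um3(
    group: GroupSpec, rng: np.random.Generator, v_min_um3: float, max_tries: int = 1000
) -> np.ndarray:
    """Draw n per-object volumes from the group's log-normal mixture.

    Draws below ``v_min_um3`` (shapes too small to be resolvable at the
    target spacing) are rejected and redrawn; for the shipped presets this
    is a vanishingly rare event, so the mixture mean is preserved.
    """
    weights = np.array([c.weight for c in group.components])
    out = np.empty(group.n)
    for i in range(group.n):
        for _ in range(max_tries):
            comp = group.components[rng.choice(len(weights), p=weights)]
            v = comp.median_um3 * math.exp(math.log(comp.gsd) * rng.standard_normal())
            if v >= v_min_um3:
                out[i] = v
                break
        else:
            raise RuntimeError(f"could not draw a volume >= {v_min_um3} µm³")
    return out


def _capsule_from_volume(
    volume_nm3: float, aspect: float, r_min_nm: float
) -> tuple[float, float]:
    """Radius and cylinder length of a capsule with given volume and
    tip-to-tip/diameter aspect ratio; radius floored at ``r_min_nm``."""
    # V = π r² L + 4/3 π r³ with L = 2 r (aspect − 1)
    coeff = math.pi * (2.0 * (aspect - 1.0) + 4.0 / 3.0)
    r = (volume_nm3 / coeff) ** (1.0 / 3.0)
    if r < r_min_nm:
        # Shrink the aspect so the radius reaches the resolvability floor.
        r = r_min_nm
        L = max(0.0, (volume_nm3 - 4.0 / 3.0 * math.pi * r**3) / (math.pi * r**2))
        return r, L
    return r, 2.0 * r * (aspect - 1.0)


def _shelf_pack(cells: Sequence[tuple[int, int, int]]) -> tuple[tuple[int, int, int], list[tuple[int, int, int]]]:
    """Pack axis-aligned cells into a compact 3D grid (shelf heuristic).

    Returns the overall grid shape and the per-cell ``(z, y, x)`` offsets, in
    the input order.  A one-voxel border keeps objects off the volume faces.
    """
    n = len(cells)
    total = sum(c[0] * c[1] * c[2] for c in cells)
    max_x = max(c[2] for c in cells)
    max_y = max(c[1] for c in cells)
    target_x = max(max_x, int(math.ceil(total ** (1.0 / 3.0) * 1.4)))
    target_y = max(max_y, int(math.ceil(math.sqrt(total / max(1, target_x)) * 1.2)))

    order = sorted(range(n), key=lambda i: (-cells[i][0], -cells[i][1], -cells[i][2]))
    offsets: list[tuple[int, int, int] | None] = [None] * n
    z0 = y0 = x0 = 0
    row_y = layer_z = 0
    used_x = used_y = used_z = 0
    for i in order:
        cz, cy, cx = cells[i]
        if x0 + cx > target_x and x0 > 0:
            x0 = 0
            y0 += row_y
            row_y = 0
        if y0 + cy > target_y and y0 > 0 and x0 == 0:
            y0 = 0
            z0 += layer_z
            layer_z = 0
        offsets[i] = (z0 + 1, y0 + 1, x0 + 1)
        x0 += cx
        row_y = max(row_y, cy)
        layer_z = max(layer_z, cz)
        used_x = max(used_x, x0)
        used_y = max(used_y, y0 + row_y)
        used_z = max(used_z, z0 + layer_z)
    shape = (used_z + 2, used_y + 2, used_x + 2)
    return shape, offsets  # type: ignore[return-value]


def generate_cohort(params: CohortParams) -> tuple[LabelVolume, GroundTruthManifest]:
    """Generate one synthetic region cohort.

    Each mitochondrion is a capsule inside its own compartment phantom (the
    same capsule inflated by ``compartment_pad_nm``, at least 1.5 voxels per
    axis); presynaptic objects are near-spherical, postsynaptic ones
    elongated, with per-object volumes drawn from the preset mixture.
    Mitochondrion labels are 1..N; each compartment's label is N + its
    mitochondrion's label.  The same seed reproduces the volume and
    manifest bit for bit.
    """
    rng = np.random.default_rng(params.seed)
    spacing = params.spacing
    step = np.asarray(spacing.zyx)
    r_min = params.min_radius_factor * max(spacing.zyx)
    v_min_um3 = 4.0 / 3.0 * math.pi * r_min**3 / NM3_PER_UM3

    order = [k for k in ("presynaptic", "postsynaptic") if k in params.groups]
    specs: list[tuple[str, float, float]] = []  # (group, radius_nm, cyl_length_nm)
    for group_name in order:
        group = params.groups[group_name]
        volumes = _sample_volumes_um3(group, rng, v_min_um3)
        aspects = rng.uniform(group.aspect_range[0], group.aspect_range[1], size=group.n)
        for v_um3, aspect in zip(volumes, aspects):
            r, L = _capsule_from_volume(v_um3 * NM3_PER_UM3, float(aspect), r_min)
            specs.append((group_name, r, L))  # type: ignore[arg-type]

    # Per-axis compartment padding: at least the configured pad, and at
    # least 1.5 voxels so the compartment encloses the mitochondrion even
    # on a strongly anisotropic slice axis.
    pad = np.maximum(params.compartment_pad_nm, 1.5 * step)
    pad_r = float(pad.max())

    cells: list[tuple[int, int, int]] = []
    for _, r, L in specs:  # type: ignore[misc]
        ext = np.array([2 * (r + pad_r), 2 * (r + pad_r), L + 2 * (r + pad_r)])
        dims = np.ceil(ext / step).astype(int) + 2 * params.margin_vox
        cells.append(tuple(dims))  # type: ignore[arg-type]

    grid_shape, offsets = _shelf_pack(cells)
    n_total = len(specs)
    dtype = np.uint16 if 2 * n_total < np.iinfo(np.uint16).max else np.uint32
    grid = np.zeros(grid_shape, dtype=dtype)

    table = LabelTable()
    objects: list[ManifestObject] = []
    comp_class = {
        "presynaptic": SemanticClass.PRESYNAPTIC_TERMINAL,
        "postsynaptic": SemanticClass.POSTSYNAPTIC_COMPARTMENT,
    }
    comp_truth = {
        "presynaptic": Compartment.PRESYNAPTIC,
        "postsynaptic": Compartment.POSTSYNAPTIC,
    }
    comp_prefix = {"presynaptic": "terminal", "postsynaptic": "dendrite"}

    for i, ((group_name, r, L), cell, off) in enumerate(zip(specs, cells, offsets)):  # type: ignore[misc]
        mito_label = i + 1
        comp_label = n_total + mito_label
        origin = np.asarray(off) * step
        center = origin + np.asarray(cell) * step / 2.0
        half = L / 2.0
        mito = Capsule(
            p0_nm=(center[0], center[1], center[2] - half),
            p1_nm=(center[0], center[1], center[2] + half),
            radius_nm=r,
        )
        comp = Capsule(p0_nm=mito.p0_nm, p1_nm=mito.p1_nm, radius_nm=r + pad_r)
        crop = grid[off[0] : off[0] + cell[0], off[1] : off[1] + cell[1], off[2] : off[2] + cell[2]]
        comp_mask, _ = voxelize_shape(comp, spacing, tuple(cell), origin_nm=tuple(origin))
        mito_mask, n_vox = voxelize_shape(mito, spacing, tuple(cell), origin_nm=tuple(origin))
        if n_vox == 0:
            raise RuntimeError(f"object {mito_label} voxelised to zero voxels: {mito}")
        crop[comp_mask] = comp_label
        crop[mito_mask] = mito_label

        table.add(mito_label, SemanticClass.MITOCHONDRION, f"mito_{mito_label:04d}")
        table.add(comp_label, comp_class[group_name], f"{comp_prefix[group_name]}_{mito_label:04d}")
        sa = mito.analytic_surface_nm2
        vol = mito.analytic_volume_nm3
        objects.append(
            ManifestObject(
                label=mito_label,
                semantic_class=SemanticClass.MITOCHONDRION,
                shape=mito.to_json_obj(),
                compartment=comp_truth[group_name],
                analytic_volume_um3=vol / NM3_PER_UM3,
                analytic_surface_um2=sa / NM2_PER_UM2,
                analytic_mci=sa**3 / (16.0 * math.pi**2 * vol**2),
                analytic_extent_um=mito.tip_to_tip_nm / 1000.0,
                realized_voxels=n_vox,
            )
        )
        objects.append(
            ManifestObject(
                label=comp_label,
                semantic_class=comp_class[group_name],
                shape=comp.to_json_obj(),
                compartment=comp_truth[group_name],
                realized_voxels=int(comp_mask.sum()) - n_vox,
            )
        )

    volume = LabelVolume(grid=grid, spacing=spacing, labels=table, source_id=f"synthetic:{params.name}:seed{params.seed}")
    manifest = GroundTruthManifest(
        preset=params.name, seed=params.seed, spacing=spacing, objects=objects
    )
    if params.jitter_amplitude_vox > 0:
        volume = add_boundary_jitter(
            volume, params.jitter_amplitude_vox, seed=int(rng.integers(2**31))
        )
    manifest.check_complete(volume)
    return volume, manifest


# ---------------------------------------------------------------------------
# Multi-synapse (dendrite-spanning) scene
# ---------------------------------------------------------------------------


def generate_fig3_scene(
    boutons: int,
    extent_fraction: float = 1.0,
    spacing: VoxelSpacing = VoxelSpacing(6.0, 6.0, 30.0),
    seed: int = 0,
    params: Fig3Params | None = None,
) -> tuple[LabelVolume, GroundTruthManifest]:
    """One dendrite tube contacted by ``boutons`` presynaptic terminals,
    holding a single dendritic mitochondrion that spans a configurable
    fraction of them.

    The mitochondrion underlies the first ``round(extent_fraction ·
    boutons)`` terminals; the manifest records exactly which, providing the
    end-to-end oracle for terminal-spanning counts.
    """
    if boutons < 1:
        raise ValueError("need at least one bouton")
    if params is None:
        params = Fig3Params(
            boutons=boutons, extent_fraction=extent_fraction, spacing=spacing, seed=seed
        )
    spacing = params.spacing
    step = np.asarray(spacing.zyx)
    R, r_m, r_b = params.dendrite_radius_nm, params.mito_radius_nm, params.bouton_radius_nm
    pitch, cleft = params.bouton_pitch_nm, params.cleft_nm
    end_margin = 1000.0
    border = 4 * float(step.max())

    tube_len = 2 * end_margin + boutons * pitch
    bouton_x = [border + end_margin + (i + 0.5) * pitch for i in range(boutons)]
    k = int(round(params.extent_fraction * boutons))
    k = max(0, min(boutons, k))

    y_tube = border + R
    z_mid = border + R
    x_hi = border * 2 + tube_len
    y_hi = y_tube + R + cleft + 2 * r_b + border
    z_hi = 2 * z_mid
    grid_shape = tuple(int(math.ceil(v / s)) for v, s in zip((z_hi, y_hi, x_hi), step))

    # Tip-to-tip dendrite length == tube_len (caps extend R past the endpoints).
    dendrite = Capsule(
        p0_nm=(z_mid, y_tube, border + R),
        p1_nm=(z_mid, y_tube, border + tube_len - R),
        radius_nm=R,
    )
    if k >= 1:
        span_lo, span_hi = bouton_x[0] - 300.0, bouton_x[k - 1] + 300.0
    else:
        span_lo, span_hi = border + 2 * r_m, border + 2 * r_m + 600.0
    mito = Capsule(
        p0_nm=(z_mid, y_tube, span_lo + r_m),
        p1_nm=(z_mid, y_tube, span_hi - r_m),
        radius_nm=r_m,
    )
    bouton_shapes = [
        Sphere(center_nm=(z_mid, y_tube + R + cleft + r_b, x), radius_nm=r_b) for x in bouton_x
    ]

    grid = np.zeros(grid_shape, dtype=np.uint16)
    table = LabelTable()
    for shape_obj, label in [(dendrite, 2), *[(b, 3 + i) for i, b in enumerate(bouton_shapes)], (mito, 1)]:
        mask, n_vox = voxelize_shape(shape_obj, spacing, grid_shape)
        if n_vox == 0:
            raise RuntimeError(f"fig3 scene: shape voxelised empty ({shape_obj})")
        grid[mask] = label
    table.add(1, SemanticClass.MITOCHONDRION, "mito_0001")
    table.add(2, SemanticClass.POSTSYNAPTIC_COMPARTMENT, "dendrite_0001")
    for i in range(boutons):
        table.add(3 + i, SemanticClass.PRESYNAPTIC_TERMINAL, f"terminal_{i + 1:04d}")

    objects = [
        ManifestObject(
            label=1,
            semantic_class=SemanticClass.MITOCHONDRION,
            shape=mito.to_json_obj(),
            compartment=Compartment.POSTSYNAPTIC,
            analytic_volume_um3=mito.analytic_volume_nm3 / NM3_PER_UM3,
            analytic_surface_um2=mito.analytic_surface_nm2 / NM2_PER_UM2,
            analytic_extent_um=mito.tip_to_tip_nm / 1000.0,
            realized_voxels=int(np.count_nonzero(grid == 1)),
            spanned_bouton_ids=[3 + i for i in range(k)],
        ),
        ManifestObject(
            label=2,
            semantic_class=SemanticClass.POSTSYNAPTIC_COMPARTMENT,
            shape=dendrite.to_json_obj(),
            realized_voxels=int(np.count_nonzero(grid == 2)),
        ),
    ]
    for i, b in enumerate(bouton_shapes):
        objects.append(
            ManifestObject(
                label=3 + i,
                semantic_class=SemanticClass.PRESYNAPTIC_TERMINAL,
                shape=b.to_json_obj(),
                realized_voxels=int(np.count_nonzero(grid == 3 + i)),
            )
        )

    volume = LabelVolume(
        grid=grid, spacing=spacing, labels=table, source_id=f"synthetic:fig3:{boutons}b:seed{params.seed}"
    )
    manifest = GroundTruthManifest(preset="fig3", seed=params.seed, spacing=spacing, objects=objects)
    manifest.check_complete(volume)
    return volume, manifest


# ---------------------------------------------------------------------------
# Boundary jitter (tracing-variability emulation)
# ---------------------------------------------------------------------------


def add_boundary_jitter(volume: LabelVolume, amplitude_vox: int, seed: int) -> LabelVolume:
    """Randomly dilate/erode object surfaces by up to ``amplitude_vox`` voxels.

    Emulates the slice-to-slice variability of human boundary tracing.  Per
    step, each surface voxel is eroded with probability ½ and each eligible
    neighbouring voxel annexed with probability ½.  Organelles may grow into
    background or into compartment-class voxels (their hosts); compartments
    may grow into background only — labels never bleed into another object's
    interior.  Amplitude 0 returns an identical copy.
    """
    if amplitude_vox < 0:
        raise ValueError("amplitude must be >= 0")
    grid = volume.grid.copy()
    out = LabelVolume(
        grid=grid, spacing=volume.spacing, labels=volume.labels, source_id=volume.source_id
    )
    if amplitude_vox == 0:
        return out
    rng = np.random.default_rng(seed)
    struct = ndimage.generate_binary_structure(3, 1)
    max_label = int(grid.max(initial=0))
    comp_lut = np.zeros(max_label + 1, dtype=bool)
    for cls in _COMPARTMENT_CLASSES:
        comp_lut |= volume.labels.class_lut(cls, max_label + 1)

    for _ in range(amplitude_vox):
        for slc, label in _label_bboxes(grid):
            slc = tuple(
                slice(max(0, s.start - 2), min(dim, s.stop + 2))
                for s, dim in zip(slc, grid.shape)
            )
            crop = grid[slc]
            mask = crop == label
            organelle = volume.labels.class_of(label) in _ORGANELLE_CLASSES
            allowed = crop == 0
            if organelle:
                allowed |= comp_lut[crop]
            grow = ndimage.binary_dilation(mask, structure=struct) & allowed
            grow_idx = np.flatnonzero(grow.ravel())
            take = grow_idx[rng.random(grow_idx.size) < 0.5]
            shrink = mask & ~ndimage.binary_erosion(mask, structure=struct)
            shrink_idx = np.flatnonzero(shrink.ravel())
            drop = shrink_idx[rng.random(shrink_idx.size) < 0.5]
            if drop.size >= mask.sum():  # never erase an object entirely
                drop = drop[: max(0, int(mask.sum()) - 1)]
            flat = crop.ravel()
            flat[drop] = 0
            flat[take] = label
    return out


def _label_bboxes(grid: np.ndarray):
    """Yield ``(bbox_slices, label)`` for every nonzero label in the grid."""
    slices = ndimage.find_objects(grid)
    for label, slc in enumerate(slices, start=1):
        if slc is not None:
            yield slc, label


# ---------------------------------------------------------------------------
# Preset library
# ---------------------------------------------------------------------------


def _group_from_json(obj: Mapping) -> GroupSpec:
    n = int(obj["n"])
    sem = float(obj["target_sem_um3"])
    comps = []
    for c in obj["components"]:
        sd = c.get("sd_um3")
        if sd is None:
            sd = sem * math.sqrt(n)  # single component: spread from s.e.m.·√n
        comps.append(LogNormalComponent.from_mean_sd(float(c["mean_um3"]), float(sd), float(c["weight"])))
    return GroupSpec(
        n=n,
        components=tuple(comps),
        aspect_range=tuple(obj["aspect_range"]),  # type: ignore[arg-type]
        target_mean_um3=float(obj["target_mean_um3"]),
        target_sem_um3=sem,
    )


def load_preset(name: str, seed: int | None = None) -> CohortParams | Fig3Params:
    """Load a shipped region preset (``NA``, ``CA1``, ``cortex``, ``DCN``)
    or the multi-synapse scene preset (``fig3``).

    ``seed`` overrides the preset's default seed.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("mitomorph.presets").joinpath(f"{name}.json").read_text()
    obj = json.loads(text)
    spacing = VoxelSpacing.from_json_obj(obj["spacing_nm"])
    use_seed = int(obj["seed"] if seed is None else seed)
    if obj.get("kind") == "fig3_scene":
        return Fig3Params(
            boutons=int(obj["boutons"]),
            extent_fraction=float(obj["extent_fraction"]),
            spacing=spacing,
            seed=use_seed,
        )
    groups = {k: _group_from_json(v) for k, v in obj["groups"].items()}
    return CohortParams(
        name=obj["name"],
        spacing=spacing,
        groups=groups,
        seed=use_seed,
        jitter_amplitude_vox=int(obj.get("jitter_amplitude_vox", 0)),
    )
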