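"""Compartment assignment, synapse-spanning counts, and organelle contacts.

Presynaptic mitochondria sit inside presynaptic terminals (boutons);
postsynaptic/dendritic mitochondria sit in the postsynaptic compartment or
dendrite.  In a label volume the organelle voxels carry the organelle's own
label, so a compartment's *region* is recovered by filling the cavities its
organelles occupy (hole filling on the compartment class mask, done locally
around each object).  Assignment is by majority overlap with a configurable
threshold.

Distances honour the anisotropic voxel spacing and use voxel centres; a
surface-to-surface gap is approximated as the minimum centre-to-centre
distance minus one mean voxel pitch, clamped at zero — sub-voxel surface
localisation is beyond the data's resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .io import NM2_PER_UM2, Compartment, LabelVolume, SemanticClass, VoxelSpacing
from .morphometry import MitoMorphometry, SegmentedObject, connected_components

__all__ = [
    "CompartmentAssignment",
    "ContactRecord",
    "assign_compartment",
    "assign_all",
    "count_spanned_terminals",
    "detect_contacts",
]

#: Semantic classes that delimit synaptic compartments, mapped to the
#: compartment a contained mitochondrion belongs to.
_COMPARTMENT_CLASSES = {
    SemanticClass.PRESYNAPTIC_TERMINAL: Compartment.PRESYNAPTIC,
    SemanticClass.POSTSYNAPTIC_COMPARTMENT: Compartment.POSTSYNAPTIC,
}


@dataclass(frozen=True)
class CompartmentAssignment:
    """Result of assigning one mitochondrion to a synaptic compartment."""

    object_id: int
    compartment: Compartment
    overlap_fraction: float
    extends_beyond: bool


@dataclass(frozen=True)
class ContactRecord:
    """A close apposition between two objects of different classes."""

    object_a_id: int
    object_b_id: int
    class_pair: tuple[SemanticClass, SemanticClass]
    min_gap_nm: float
    contact_area_um2: float


def _expand_slices(
    slc: tuple[slice, slice, slice], margin: Sequence[int], shape: Sequence[int]
) -> tuple[slice, slice, slice]:
    return tuple(
        slice(max(0, s.start - m), min(dim, s.stop + m))
        for s, m, dim in zip(slc, margin, shape)
    )  # type: ignore[return-value]


def _object_bbox(obj: SegmentedObject) -> tuple[slice, slice, slice]:
    return tuple(
        slice(o, o + s) for o, s in zip(obj.offset, obj.mask.shape)
    )  # type: ignore[return-value]


def assign_compartment(
    mito: SegmentedObject,
    compartments: LabelVolume,
    threshold: float = 0.5,
    margin_vox: int = 4,
) -> CompartmentAssignment:
    """Assign a mitochondrion to the compartment holding most of its voxels.

    For each compartment class the class mask is hole-filled on a local
    crop around the mitochondrion (organelles carve cavities out of their
    host compartment in a label volume), and the fraction of mitochondrion
    voxels inside the filled region is computed.  The winning class is
    assigned when its fraction reaches ``threshold`` (default 0.5 —
    majority rule); otherwise the object stays unassigned.
    ``extends_beyond`` flags any voxel outside the winning region.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mito.spacing != compartments.spacing:
        raise ValueError("mitochondrion and compartment volume have different spacing")
    for off, size, dim in zip(mito.offset, mito.mask.shape, compartments.shape):
        if off < 0 or off + size > dim:
            raise ValueError("mitochondrion mask does not fit inside the compartment volume")

    bbox = _object_bbox(mito)
    crop_slc = _expand_slices(bbox, (margin_vox,) * 3, compartments.shape)
    crop = compartments.grid[crop_slc]
    max_label = int(crop.max(initial=0))

    # mito mask placed inside the crop
    local = tuple(
        slice(b.start - c.start, b.stop - c.start) for b, c in zip(bbox, crop_slc)
    )
    mito_in_crop = np.zeros(crop.shape, dtype=bool)
    mito_in_crop[local] = mito.mask
    n_mito = mito.n_voxels

    fractions: dict[Compartment, float] = {}
    for cls, compartment in _COMPARTMENT_CLASSES.items():
        lut = compartments.labels.class_lut(cls, max_label + 1)
        mask = lut[crop]
        if not mask.any():
            fractions[compartment] = 0.0
            continue
        filled = ndimage.binary_fill_holes(mask)
        fractions[compartment] = float(np.count_nonzero(filled & mito_in_crop)) / n_mito

    winner = max(fractions, key=lambda c: (fractions[c], c.value))
    frac = fractions[winner]
    if frac >= threshold:
        return CompartmentAssignment(
            object_id=mito.object_id,
            compartment=winner,
            overlap_fraction=frac,
            extends_beyond=frac < 1.0,
        )
    return CompartmentAssignment(
        object_id=mito.object_id,
        compartment=Compartment.UNASSIGNED,
        overlap_fraction=frac,
        extends_beyond=frac < 1.0,
    )


def assign_all(
    objects: Sequence[SegmentedObject],
    volume: LabelVolume,
    records: Sequence[MitoMorphometry] | None = None,
    threshold: float = 0.5,
    margin_vox: int = 4,
) -> list[CompartmentAssignment]:
    """Assign every object; optionally fill matching morphometry records in place."""
    by_id = {r.object_id: r for r in records} if records is not None else {}
    assignments = []
    for obj in objects:
        a = assign_compartment(obj, volume, threshold=threshold, margin_vox=margin_vox)
        assignments.append(a)
        if a.object_id in by_id:
            by_id[a.object_id].compartment = a.compartment
    return assignments


def _full_mask(obj: SegmentedObject, shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[_object_bbox(obj)] = obj.mask
    return mask


def _min_center_gap_nm(
    mask_a: np.ndarray, mask_b: np.ndarray, spacing: VoxelSpacing
) -> float:
    """Minimum centre-to-centre distance from A voxels to B voxels (nm)."""
    edt = ndimage.distance_transform_edt(~mask_b, sampling=spacing.zyx)
    return float(edt[mask_a].min())


def count_spanned_terminals(
    mito: SegmentedObject,
    terminals: Sequence[SegmentedObject],
    dendrite: SegmentedObject,
    proximity_nm: float = 20.0,
    mito_reach_nm: float = 500.0,
) -> tuple[int, list[int]]:
    """Count presynaptic terminals whose synapse a dendritic mitochondrion underlies.

    A terminal forms a synaptic contact when its surface comes within
    ``proximity_nm`` (the scale of a synaptic cleft) of the host dendrite's
    surface.  The mitochondrion is credited with a terminal when it passes
    within ``proximity_nm + mito_reach_nm`` of that contact zone — large
    dendritic mitochondria can traverse several terminals this way.

    Raises ``ValueError`` when the mitochondrion is not inside the dendrite
    (misuse: the operation is defined for postsynaptic mitochondria only).
    """
    shape = None
    for obj in [mito, dendrite, *terminals]:
        if obj.spacing != mito.spacing:
            raise ValueError("all objects must share voxel spacing")
        end = tuple(o + s for o, s in zip(obj.offset, obj.mask.shape))
        shape = end if shape is None else tuple(max(a, b) for a, b in zip(shape, end))
    assert shape is not None
    spacing = mito.spacing
    pitch = spacing.mean_pitch_nm

    dend_mask = _full_mask(dendrite, shape)
    mito_mask = _full_mask(mito, shape)
    filled_dend = ndimage.binary_fill_holes(dend_mask)
    inside = np.count_nonzero(filled_dend & mito_mask) / mito.n_voxels
    if inside < 0.5:
        raise ValueError(
            f"mitochondrion {mito.object_id} is not inside the dendrite "
            f"(only {inside:.0%} of its voxels are) — count_spanned_terminals "
            "applies to postsynaptic mitochondria"
        )

    spanned: list[int] = []
    for term in sorted(terminals, key=lambda t: t.object_id):
        term_mask = _full_mask(term, shape)
        edt_term = ndimage.distance_transform_edt(~term_mask, sampling=spacing.zyx)
        gap_dend = max(0.0, float(edt_term[dend_mask].min()) - pitch)
        if gap_dend > proximity_nm:
            continue  # no synaptic contact with the host dendrite
        # Contact zone: dendrite voxels apposed to this terminal.
        zone = dend_mask & (np.maximum(edt_term - pitch, 0.0) <= proximity_nm)
        if not zone.any():
            continue
        gap_mito = max(0.0, _min_center_gap_nm(mito_mask, zone, spacing) - pitch)
        if gap_mito <= proximity_nm + mito_reach_nm:
            spanned.append(term.object_id)
    return len(spanned), spanned


def detect_contacts(
    volume: LabelVolume,
    class_pair: tuple[SemanticClass | str, SemanticClass | str],
    gap_threshold_nm: float = 30.0,
    connectivity: int = 26,
) -> list[ContactRecord]:
    """Find close appositions between objects of two semantic classes.

    For every object pair (one per class) whose surfaces approach within
    ``gap_threshold_nm`` — physical distance under anisotropic spacing — a
    record reports the minimum gap and the area of the first object's
    exposed surface lying within the gap threshold of the second.  Pairs
    farther apart are omitted; for intra-class pairs (e.g. mito–mito) each
    unordered pair is reported once and self-contacts are excluded.
    """
    cls_a, cls_b = (SemanticClass(c) for c in class_pair)
    objs_a = connected_components(volume, cls_a, connectivity=connectivity)
    objs_b = connected_components(volume, cls_b, connectivity=connectivity)
    spacing = volume.spacing
    pitch = spacing.mean_pitch_nm
    shape = volume.shape
    # Prescreen margin: bounding boxes must come within threshold + 2 pitches.
    reach_nm = gap_threshold_nm + 2.0 * pitch
    margin = tuple(int(np.ceil(reach_nm / s)) + 1 for s in spacing.zyx)

    records: list[ContactRecord] = []
    for a in objs_a:
        bbox_a = _object_bbox(a)
        search = _expand_slices(bbox_a, margin, shape)
        for b in objs_b:
            if cls_a == cls_b and b.object_id <= a.object_id:
                continue  # one record per unordered pair; no self-contact
            bbox_b = _object_bbox(b)
            if any(
                bbox_b[ax].start >= search[ax].stop or bbox_b[ax].stop <= search[ax].start
                for ax in range(3)
            ):
                continue
            # Work on the union crop expanded by the search margin.
            union = tuple(
                slice(min(bbox_a[ax].start, bbox_b[ax].start), max(bbox_a[ax].stop, bbox_b[ax].stop))
                for ax in range(3)
            )
            crop_slc = _expand_slices(union, margin, shape)
            crop_shape = tuple(s.stop - s.start for s in crop_slc)
            origin = tuple(s.start for s in crop_slc)

            def place(obj: SegmentedObject) -> np.ndarray:
                m = np.zeros(crop_shape, dtype=bool)
                loc = tuple(
                    slice(obj.offset[ax] - origin[ax], obj.offset[ax] - origin[ax] + obj.mask.shape[ax])
                    for ax in range(3)
                )
                m[loc] = obj.mask
                return m

            mask_a = place(a)
            mask_b = place(b)
            edt_b = ndimage.distance_transform_edt(~mask_b, sampling=spacing.zyx)
            min_center = float(edt_b[mask_a].min())
            min_gap = max(0.0, min_center - pitch)
            if min_gap > gap_threshold_nm:
                continue
            # Contact area: exposed faces of A whose outward neighbour sits
            # within the gap threshold of B.
            near_b = np.maximum(edt_b - pitch, 0.0) <= gap_threshold_nm
            dz, dy, dx = spacing.zyx
            face_areas = (dx * dy, dx * dz, dy * dz)
            area_nm2 = 0.0
            for axis, face_area in enumerate(face_areas):
                for shift in (1, -1):
                    neighbour_free = ~np.roll(mask_a, shift, axis=axis)
                    # roll wraps; voxels on the crop border face outside, which
                    # is free space far from B given the margin
                    exposed = mask_a & neighbour_free
                    outward = np.roll(near_b, shift, axis=axis)
                    area_nm2 += face_area * np.count_nonzero(exposed & outward)
            records.append(
                ContactRecord(
                    object_a_id=a.object_id,
                    object_b_id=b.object_id,
                    class_pair=(cls_a, cls_b),
                    min_gap_nm=min_gap,
                    contact_area_um2=area_nm2 / NM2_PER_UM2,
                )
            )
    return records
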