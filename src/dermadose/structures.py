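"""TPS structure building: HU thresholding, contour expansion, the
surface-voxel (contact) contour and inward skin rinds.

The contact contour is the single layer of body-boundary voxels adjacent to
the cradle — the voxel-level counterpart of intersecting body and cradle
contours. Skin rinds extend a fixed thickness inward from that contour,
measured with an anisotropic Euclidean distance transform (morphological
box erosion would be wrong at 0.25 cm slice spacing).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage

from .core import GeometryError, StructureMask, VoxelGrid

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def threshold_structure(
    ct: VoxelGrid,
    hu_lo: float,
    hu_hi: float,
    keep_largest: bool = False,
    label: str = "",
) -> StructureMask:
    """Voxels with ``hu_lo <= HU <= hu_hi`` (inclusive both ends).

    With ``keep_largest``, only the largest 26-connected component is kept;
    an empty result in that case is an error.
    """
    if hu_lo > hu_hi:
        raise ValueError("hu_lo must not exceed hu_hi")
    mask = (ct.values >= hu_lo) & (ct.values <= hu_hi)
    if keep_largest:
        labels, n = ndimage.label(mask, structure=_CONN26)
        if n == 0:
            raise GeometryError(
                f"threshold [{hu_lo}, {hu_hi}] selected no voxels"
            )
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == np.argmax(counts)
    return StructureMask(mask, ct.spacing, ct.origin, label)


def expand_contour(mask: StructureMask, distance: float) -> StructureMask:
    """All voxels whose centre lies within ``distance`` cm of the mask.

    Anisotropic Euclidean distance; ``distance = 0`` is the identity. Used
    e.g. for the 2.0 cm extended body contour.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance == 0 or not mask.mask.any():
        return StructureMask(mask.mask.copy(), mask.spacing, mask.origin,
                             mask.label)
    dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
    return StructureMask(mask.mask | (dist <= distance), mask.spacing,
                         mask.origin, f"{mask.label}+{distance:g}cm")


def contact_surface(body: StructureMask, cradle: StructureMask,
                    trim_partial_slices: bool = True) -> StructureMask:
    """Surface-voxel contour: body boundary voxels touching the cradle.

    Implemented as body AND (cradle dilated by one voxel, 26-connectivity)
    restricted to the body's outer boundary layer, so the result is one voxel
    thick along the local surface normal. A literal intersection of the two
    disjoint masks would be empty; adjacency reproduces the intended
    "region of the breast in contact with the cradle".

    ``trim_partial_slices`` drops leading/trailing z slices whose contact
    arc is fragmentary (fewer than 60% of the median per-slice voxels);
    such slices arise from diagonal 3D adjacency just beyond the cradle
    edge and would otherwise break per-slice contour traversal.
    """
    if not body.same_lattice(cradle):
        raise GeometryError("body and cradle masks must share the lattice")
    touching = ndimage.binary_dilation(cradle.mask, structure=_CONN26)
    interior = ndimage.binary_erosion(body.mask, structure=_CONN26,
                                      border_value=1)
    contact = body.mask & ~interior & touching
    if not contact.any():
        raise GeometryError("body and cradle are not in contact: no film region")
    if trim_partial_slices:
        counts = contact.sum(axis=(0, 1))
        present = np.nonzero(counts)[0]
        med = np.median(counts[present])
        lo, hi = present[0], present[-1]
        while lo <= hi and counts[lo] < 0.6 * med:
            contact[:, :, lo] = False
            lo += 1
        while hi >= lo and counts[hi] < 0.6 * med:
            contact[:, :, hi] = False
            hi -= 1
        if not contact.any():
            raise GeometryError("contact region empty after slice trimming")
    return StructureMask(contact, body.spacing, body.origin, "surface_voxels")


def make_rind(surface: StructureMask, body: StructureMask,
              thickness: float) -> StructureMask:
    """Skin rind: body voxels within ``thickness`` cm of the surface contour.

    The surface layer itself is always included; ``thickness = 0`` returns
    the surface layer. Distances are anisotropic Euclidean from surface voxel
    centres.
    """
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    if not surface.same_lattice(body):
        raise GeometryError("surface and body masks must share the lattice")
    if np.any(surface.mask & ~body.mask):
        raise GeometryError("surface contour must be contained in the body")
    if thickness == 0:
        rind = surface.mask.copy()
    else:
        dist = ndimage.distance_transform_edt(~surface.mask,
                                              sampling=surface.spacing)
        rind = surface.mask | (body.mask & (dist <= thickness))
    return StructureMask(rind, body.spacing, body.origin,
                         f"rind_{thickness:g}cm")
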