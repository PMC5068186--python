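"""Region-of-interest construction from phantom ground truth.

Stands in for the manual ROI drawing a reader performs on fused PET/CT:
a perimeter ROI around the valve on every en-face slice, 120-degree cusp
sectors, circular ROIs on 5 contiguous axial slices of the
brachiocephalic vein (most caudal at the innominate junction), and a
2-cm^2 right-atrium ROI at the right-coronary-ostium level.  An optional
craniocaudal placement jitter emulates the slice-selection uncertainty
of manual coregistration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EnFaceStack
from .phantom import CUSP_ANGLES_DEG, CUSPS, PhantomTruth
from .volume import ImageVolume


class RoiError(ValueError):
    pass


@dataclass
class RoiSet:
    """ROIs for one scan: en-face valve/cusp/atrium masks plus axial vein masks."""

    valve_masks: dict[int, np.ndarray]
    valve_polygons: dict[int, np.ndarray]           # (N, 2) in-plane mm
    cusp_masks: dict[str, dict[int, np.ndarray]]
    vein_slice_indices: list[int] = field(default_factory=list)  # axial k, caudal->cranial
    vein_masks: list[np.ndarray] = field(default_factory=list)
    atrium_slice: int | None = None                  # en-face slice index
    atrium_mask: np.ndarray | None = None            # applies to slice and slice+1

    def to_dict(self) -> dict:
        return {
            "valve_polygons_mm": {int(k): p.tolist() for k, p in self.valve_polygons.items()},
            "vein_slice_indices": [int(k) for k in self.vein_slice_indices],
            "atrium_slice": None if self.atrium_slice is None else int(self.atrium_slice),
        }


def _circle_polygon(center_u: float, center_v: float, radius: float,
                    n_vertices: int = 72) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([center_u + radius * np.cos(ang),
                            center_v + radius * np.sin(ang)])


def rois_from_truth(
    truth: PhantomTruth,
    dilation_mm: float = 0.0,
    stack: EnFaceStack | None = None,
    volume: ImageVolume | None = None,
    atrium_area_cm2: float = 2.0,
    vein_level_jitter_mm: float = 0.0,
    atrium_level_jitter_mm: float = 0.0,
) -> RoiSet:
    """Build the analysis ROIs for one scan from ground truth.

    Parameters
    ----------
    dilation_mm : float
        Outward dilation of the valve perimeter ROI; with zero dilation
        the ROI pixel set equals the true valve mask on each slice.
    stack : EnFaceStack, optional
        En-face geometry on which the valve, cusp and atrium ROIs are
        defined.  Required for those ROIs.
    volume : ImageVolume, optional
        Axial grid on which the brachiocephalic-vein ROIs are defined.
    vein_level_jitter_mm, atrium_level_jitter_mm : float
        Craniocaudal displacement of the ROI placement level, emulating
        manual slice selection/coregistration error.
    """
    cfg = truth.config
    if cfg.annulus_radius_mm <= 0:
        raise RoiError("truth has an empty valve mask")

    valve_masks: dict[int, np.ndarray] = {}
    valve_polygons: dict[int, np.ndarray] = {}
    cusp_masks: dict[str, dict[int, np.ndarray]] = {c: {} for c in CUSPS}
    atrium_slice = None
    atrium_mask = None

    if stack is not None:
        u, v = stack.pixel_centers_plane()
        U, V = np.meshgrid(u, v, indexing="ij")
        r_roi = cfg.annulus_radius_mm + dilation_mm
        half = truth.valve_slab_halfwidth()
        in_roi = U * U + V * V <= r_roi * r_roi
        ang = np.rad2deg(np.arctan2(V, U)) % 360.0
        for k, off in enumerate(stack.slice_offsets()):
            if abs(off) > half + 1e-9:
                continue
            valve_masks[k] = in_roi
            valve_polygons[k] = _circle_polygon(0.0, 0.0, r_roi)
            for cusp in CUSPS:
                sector = (ang - CUSP_ANGLES_DEG[cusp] + 60.0) % 360.0 < 120.0
                cusp_masks[cusp][k] = in_roi & sector
        if not valve_masks:
            raise RoiError("no en-face slice intersects the valve slab")

        # 2-cm^2 right-atrium ROI: the round(area / pixel-area) pixels closest
        # to the atrium center, on the ostium-level slice and one superior
        ua, va, wa = stack.plane.world_to_plane(truth.atrium_center)[0]
        offsets = stack.slice_offsets()
        atrium_slice = int(np.argmin(np.abs(offsets - (wa + atrium_level_jitter_mm))))
        if atrium_slice + 1 >= stack.n_slices:
            atrium_slice = stack.n_slices - 2
        px_area = stack.in_plane_spacing ** 2
        n_px = int(round(atrium_area_cm2 * 100.0 / px_area))
        d2 = (U - ua) ** 2 + (V - va) ** 2
        flat_order = np.lexsort((np.arange(d2.size), d2.ravel()))
        atrium_mask = np.zeros(d2.shape, dtype=bool)
        atrium_mask.ravel()[flat_order[:n_px]] = True

    vein_idx: list[int] = []
    vein_masks: list[np.ndarray] = []
    if volume is not None:
        spacing = float(volume.spacing[2])
        k0 = int(round((cfg.vein_junction_z_mm + vein_level_jitter_mm) / spacing))
        x = np.arange(volume.shape[0]) * volume.spacing[0]
        y = np.arange(volume.shape[1]) * volume.spacing[1]
        X, Y = np.meshgrid(x, y, indexing="ij")
        vx, vy = cfg.vein_xy_mm
        for k in range(k0, k0 + 5):
            if not (0 <= k < volume.shape[2]):
                raise RoiError("vein ROI slice outside the volume")
            r = float(cfg.vein_radius_at(k * spacing))
            mask = (X - vx) ** 2 + (Y - vy) ** 2 <= r * r
            if not mask.any():
                raise RoiError(f"empty vein ROI on axial slice {k}")
            vein_idx.append(k)
            vein_masks.append(mask)

    return RoiSet(valve_masks, valve_polygons, cusp_masks,
                  vein_idx, vein_masks, atrium_slice, atrium_mask)
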