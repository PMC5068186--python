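"""Valve-plane geometry and en-face (short-axis) reslicing.

The aortic valve plane is defined by the three leaflet-base landmarks
(right-coronary, noncoronary and left-coronary cusp bases).  Volumes are
resampled into contiguous slices perpendicular to the valve normal so
that each slice shows the valve en face, mirroring the oblique
multiplanar reformat a reader performs on a fused PET/CT workstation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

CRANIAL = np.array([0.0, 0.0, 1.0])  # world +z points cranially


class GeometryError(ValueError):
    pass


@dataclass
class ValvePlane:
    """Rigid en-face frame derived from the three leaflet-base landmarks.

    Attributes
    ----------
    landmarks : (3, 3) array
        World coordinates (mm) of the right-coronary, noncoronary and
        left-coronary cusp bases, in that order.
    origin : (3,) array
        Landmark centroid; the en-face frame origin.
    axes : (3, 3) array
        Rows are the orthonormal frame axes (x, y, z) in world
        coordinates.  z is the valve normal, oriented cranially; x
        points from the centroid toward the right-coronary landmark.
    """

    landmarks: np.ndarray
    origin: np.ndarray = field(init=False)
    axes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.landmarks, dtype=float)
        if pts.shape != (3, 3):
            raise GeometryError("exactly three 3-D landmarks required")
        v1 = pts[1] - pts[0]
        v2 = pts[2] - pts[0]
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        scale = max(np.linalg.norm(v1), np.linalg.norm(v2))
        if scale == 0 or norm < 1e-9 * scale * scale:
            raise GeometryError("landmarks are collinear or duplicated")
        normal /= norm
        if normal @ CRANIAL < 0:
            normal = -normal
        origin = pts.mean(axis=0)
        x = pts[0] - origin
        x = x - (x @ normal) * normal
        x /= np.linalg.norm(x)
        y = np.cross(normal, x)
        self.landmarks = pts
        self.origin = origin
        self.axes = np.vstack([x, y, normal])

    @property
    def normal(self) -> np.ndarray:
        return self.axes[2]

    def world_to_plane(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - self.origin) @ self.axes.T

    def plane_to_world(self, uvw: np.ndarray) -> np.ndarray:
        uvw = np.atleast_2d(np.asarray(uvw, dtype=float))
        return uvw @ self.axes + self.origin


def fit_valve_plane(p_right, p_noncoronary, p_left) -> ValvePlane:
    """Fit the en-face valve plane to the three cusp-base landmarks.

    All three landmarks lie at z = 0 in the resulting frame; the frame
    z-axis (valve normal) has a non-negative component along the world
    cranial axis, and the in-plane x-axis points from the landmark
    centroid toward the right-coronary cusp base.
    """
    return ValvePlane(np.array([p_right, p_noncoronary, p_left], dtype=float))


@dataclass
class EnFaceStack:
    """Contiguous en-face slices resampled perpendicular to the valve normal.

    ``slices[k][u, v]`` samples the point
    ``origin + (u - (nu-1)/2) * dx * x + (v - (nv-1)/2) * dx * y
    + offset_k * z`` where ``offset_k = (k - (n-1)/2) * thickness``;
    slice index increases toward the cranial side of the valve.
    """

    slices: np.ndarray  # (n_slices, nu, nv)
    thickness: float
    in_plane_spacing: float
    plane: ValvePlane
    out_of_volume: np.ndarray  # per-slice bool flags

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise GeometryError("slice thickness must be positive")
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise GeometryError("stack needs at least one slice")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    def slice_offsets(self) -> np.ndarray:
        n = self.n_slices
        return (np.arange(n) - (n - 1) / 2.0) * self.thickness

    def pixel_centers_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (u, v) coordinates (mm) of pixel centers."""
        nu, nv = self.slices.shape[1:]
        u = (np.arange(nu) - (nu - 1) / 2.0) * self.in_plane_spacing
        v = (np.arange(nv) - (nv - 1) / 2.0) * self.in_plane_spacing
        return u, v

    def to_volume(self) -> ImageVolume:
        """Pack the stack as a volume whose affine encodes the en-face frame."""
        nu, nv = self.slices.shape[1:]
        aff = np.eye(4)
        axes = self.plane.axes
        aff[:3, 0] = axes[0] * self.in_plane_spacing
        aff[:3, 1] = axes[1] * self.in_plane_spacing
        aff[:3, 2] = axes[2] * self.thickness
        corner = self.plane.plane_to_world(
            [[-(nu - 1) / 2.0 * self.in_plane_spacing,
              -(nv - 1) / 2.0 * self.in_plane_spacing,
              self.slice_offsets()[0]]]
        )[0]
        aff[:3, 3] = corner
        return ImageVolume(np.moveaxis(self.slices, 0, 2), aff)


def resample_en_face(
    volume: ImageVolume,
    plane: ValvePlane,
    thickness: float = 3.0,
    n_slices: int = 9,
    in_plane_spacing: float | None = None,
    in_plane_extent: float = 140.0,
    n_subsamples: int = 3,
) -> EnFaceStack:
    """Resample a volume into contiguous en-face slices of given thickness.

    Slices are centered on the landmark centroid, half extending
    cranially and half caudally along the valve normal.  Each slice
    value is the trilinear interpolation of the volume averaged through
    the slab thickness using ``n_subsamples`` symmetric sub-planes
    (exact for fields varying linearly along the normal).  A slab no
    thicker than the native voxel is sampled once at its center, so
    reslicing along the grid axis at native thickness is a no-op.
    Samples falling outside the volume contribute zero and set the
    slice's out-of-volume flag.
    """
    if thickness <= 0:
        raise GeometryError("slice thickness must be positive")
    if n_slices < 1:
        raise GeometryError("need at least one slice")
    if n_subsamples < 1 or n_subsamples % 2 == 0:
        raise GeometryError("n_subsamples must be odd and >= 1")
    if in_plane_spacing is None:
        in_plane_spacing = float(np.min(volume.spacing))

    half = (in_plane_extent / 2.0) // in_plane_spacing
    coords_1d = np.arange(-half, half + 1) * in_plane_spacing
    nu = nv = coords_1d.size
    U, V = np.meshgrid(coords_1d, coords_1d, indexing="ij")

    offsets = (np.arange(n_slices) - (n_slices - 1) / 2.0) * thickness
    if thickness <= float(np.min(volume.spacing)) + 1e-9:
        n_subsamples = 1
    if n_subsamples == 1:
        sub = np.array([0.0])
    else:
        sub = np.linspace(-thickness / 3.0, thickness / 3.0, n_subsamples)

    slices = np.zeros((n_slices, nu, nv))
    oov = np.zeros(n_slices, dtype=bool)
    upper = np.array(volume.shape, dtype=float) - 1.0
    for k, off in enumerate(offsets):
        acc = np.zeros((nu, nv))
        for s in sub:
            uvw = np.column_stack([U.ravel(), V.ravel(), np.full(U.size, off + s)])
            world = plane.plane_to_world(uvw)
            idx = volume.world_to_index(world)
            if np.any((idx < -1e-9) | (idx > upper + 1e-9)):
                oov[k] = True
            acc += ndimage.map_coordinates(
                volume.data, idx.T, order=1, mode="constant", cval=0.0
            ).reshape(nu, nv)
        slices[k] = acc / len(sub)
    return EnFaceStack(slices, float(thickness), float(in_plane_spacing), plane, oov)


def apply_rigid_shift(volume: ImageVolume, shift_mm) -> ImageVolume:
    """Translate a volume rigidly by ``shift_mm`` (world mm), resampling
    with a cubic spline.  A one-voxel-spacing shift is an exact grid roll
    (with zero fill at the trailing edge); shift followed by its inverse
    restores the volume up to interpolation error."""
    shift_mm = np.asarray(shift_mm, dtype=float)
    if shift_mm.shape != (3,) or not np.all(np.isfinite(shift_mm)):
        raise GeometryError("shift must be a finite 3-vector (mm)")
    # world shift expressed in voxel units of the grid
    shift_vox = np.linalg.solve(volume.affine[:3, :3], shift_mm)
    data = ndimage.shift(volume.data, shift_vox, order=3, mode="constant", cval=0.0)
    return ImageVolume(data, volume.affine.copy())
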