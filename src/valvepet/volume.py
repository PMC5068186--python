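"""Volumetric containers for PET/CT-like images.

An :class:`ImageVolume` is a 3-D scalar grid in SUV units together with a
4x4 voxel-to-world affine (world coordinates in mm).  Array axes are
``(i, j, k)`` with ``k`` increasing caudal-to-cranial, so ``data[:, :, k]``
is one axial slice.  A :class:`GatedSeries` is an ordered set of gate
volumes spanning the cardiac cycle, with per-gate event bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """3-D scalar image in SUV units with voxel spacing and affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def from_spacing(cls, data: np.ndarray, spacing: float | tuple[float, float, float]) -> "ImageVolume":
        s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        if np.any(s <= 0):
            raise ValueError("voxel spacing must be positive")
        aff = np.diag([s[0], s[1], s[2], 1.0])
        return cls(data, aff)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three array axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        return cls(np.asanyarray(img.dataobj, dtype=float), img.affine)


@dataclass
class GatedSeries:
    """Ordered cardiac-gate volumes with event-count bookkeeping.

    Gate ``g`` of ``n`` covers the cardiac-phase window
    ``[g/n, (g+1)/n)`` expressed as a fraction of the RR interval.
    """

    gates: list[ImageVolume]
    gate_counts: np.ndarray
    phase_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gate_counts = np.asarray(self.gate_counts, dtype=int)
        if len(self.gate_counts) != len(self.gates):
            raise ValueError("one event count per gate required")
        if not self.phase_windows:
            n = len(self.gates)
            self.phase_windows = [(g / n, (g + 1) / n) for g in range(n)]

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    @property
    def total_events(self) -> int:
        return int(self.gate_counts.sum())

    def nongated(self) -> ImageVolume:
        """Event-weighted combination of all gates (ungated reconstruction)."""
        w = self.gate_counts / max(self.total_events, 1)
        data = sum(wi * g.data for wi, g in zip(w, self.gates))
        return ImageVolume(np.asarray(data), self.gates[0].affine.copy())
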