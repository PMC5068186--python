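"""Valvular uptake quantification: per-slice SUV statistics, whole-valve
and most-diseased-segment (MDS) summaries, and the two blood-pool
correction schemes (ratio -> TBR, subtraction -> corrected SUV).

The MDS value of a statistic is the average over the two contiguous
en-face slices with the highest values of that statistic; it avoids the
observer-dependent choice of where the valve begins and ends along its
axis.  The mean- and max-based slice pairs are selected independently
and both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .geometry import EnFaceStack
from .rois import RoiSet

SUV_METRICS = ("suv_mean", "suv_max", "suv_mds_mean", "suv_mds_max")


class QuantifyError(ValueError):
    pass


@dataclass
class SliceStats:
    """Mean/max SUV over the ROI pixels of one en-face slice."""

    index: int
    suv_mean: float
    suv_max: float
    n_pixels: int
    out_of_volume: bool = False

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise QuantifyError(f"slice {self.index}: empty ROI")
        if self.suv_max < self.suv_mean - 1e-12:
            raise QuantifyError(f"slice {self.index}: max below mean")


@dataclass
class BloodPool:
    """Blood-pool SUVmean with provenance.

    ``brachiocephalic`` averages 5 contiguous axial vein slices;
    ``right_atrium`` averages two 2-cm^2 ROIs on adjacent en-face slices.
    """

    method: str
    value: float
    slice_values: list[float]

    def __post_init__(self) -> None:
        if self.method not in ("brachiocephalic", "right_atrium"):
            raise QuantifyError(f"unknown blood-pool method {self.method!r}")
        n_req = 5 if self.method == "brachiocephalic" else 2
        if len(self.slice_values) != n_req:
            raise QuantifyError(
                f"{self.method} blood pool needs {n_req} slice values, "
                f"got {len(self.slice_values)}")
        if self.value <= 0:
            raise QuantifyError("blood-pool SUV must be positive")


@dataclass
class MDSSelection:
    mean_value: float
    mean_pair: tuple[int, int]
    max_value: float
    max_pair: tuple[int, int]


@dataclass
class UptakeResult:
    """All summary uptake metrics for one scan, plus provenance."""

    slice_stats: list[SliceStats]
    suv_mean: float
    suv_max: float
    suv_mds_mean: float
    suv_mds_max: float
    mds_mean_pair: tuple[int, int]
    mds_max_pair: tuple[int, int]
    blood_pool: BloodPool
    tbr_mean: float = field(init=False)
    tbr_max: float = field(init=False)
    tbr_mds_mean: float = field(init=False)
    tbr_mds_max: float = field(init=False)
    csuv_mean: float = field(init=False)
    csuv_max: float = field(init=False)
    csuv_mds_mean: float = field(init=False)
    csuv_mds_max: float = field(init=False)
    negative_csuv: bool = field(init=False)
    cusp_flags: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        b = self.blood_pool.value
        for m in SUV_METRICS:
            setattr(self, m.replace("suv", "tbr", 1), tbr(getattr(self, m), b))
            setattr(self, m.replace("suv", "csuv", 1), corrected_suv(getattr(self, m), b))
        self.negative_csuv = any(
            getattr(self, m.replace("suv", "csuv", 1)) < 0 for m in SUV_METRICS)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {}
        for m in SUV_METRICS:
            row[m] = getattr(self, m)
            row[m.replace("suv", "tbr", 1)] = getattr(self, m.replace("suv", "tbr", 1))
            row[m.replace("suv", "csuv", 1)] = getattr(self, m.replace("suv", "csuv", 1))
        row["blood_pool"] = self.blood_pool.value
        row["blood_pool_method"] = self.blood_pool.method
        if self.cusp_flags is not None:
            for cusp, flag in self.cusp_flags.items():
                row[f"uptake_{cusp}"] = float(flag)
        return row


# ---------------------------------------------------------------------------
# per-slice and summary statistics


def polygon_to_mask(polygon: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pixels of the (u, v) grid whose centers fall inside the polygon."""
    U, V = np.meshgrid(u, v, indexing="ij")
    pts = np.column_stack([U.ravel(), V.ravel()])
    inside = MplPath(np.asarray(polygon)).contains_points(pts)
    return inside.reshape(U.shape)


def slice_suv_stats(slice_values: np.ndarray, roi_mask: np.ndarray,
                    index: int = 0, out_of_volume: bool = False) -> SliceStats:
    """Mean and max SUV over ROI pixels (pixel-center containment)."""
    slice_values = np.asarray(slice_values, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != slice_values.shape:
        raise QuantifyError(f"slice {index}: ROI/grid shape mismatch")
    vals = slice_values[roi_mask]
    if vals.size == 0:
        raise QuantifyError(f"slice {index}: ROI does not intersect the grid")
    return SliceStats(index, float(vals.mean()), float(vals.max()),
                      int(vals.size), out_of_volume)


def whole_valve_uptake(stats: list[SliceStats]) -> tuple[float, float]:
    """Unweighted across-slice averages of per-slice SUVmean and SUVmax."""
    if not stats:
        raise QuantifyError("no slices to average")
    return (float(np.mean([s.suv_mean for s in stats])),
            float(np.mean([s.suv_max for s in stats])))


def _best_pair(values: np.ndarray) -> tuple[int, float]:
    sums = values[:-1] + values[1:]
    i = int(np.argmax(sums))  # argmax takes the first maximum: lower-index tie-break
    return i, float(sums[i] / 2.0)


def mds_uptake(stats: list[SliceStats]) -> MDSSelection:
    """Most-diseased-segment metrics: for each statistic independently,
    the contiguous slice pair with the highest summed value, averaged.
    Ties go to the more caudal (lower-index) pair."""
    if len(stats) < 2:
        raise QuantifyError("MDS needs at least 2 contiguous slices")
    means = np.array([s.suv_mean for s in stats])
    maxes = np.array([s.suv_max for s in stats])
    im, vm = _best_pair(means)
    ix, vx = _best_pair(maxes)
    idx = [s.index for s in stats]
    return MDSSelection(vm, (idx[im], idx[im + 1]), vx, (idx[ix], idx[ix + 1]))


# ---------------------------------------------------------------------------
# blood pool


def blood_pool_brachiocephalic(slice_means) -> BloodPool:
    """Blood pool as the mean SUVmean over ROIs on 5 contiguous axial
    slices of the brachiocephalic vein (most caudal at the innominate
    junction); per-slice values are retained for gradient diagnostics."""
    vals = [float(s.suv_mean) if isinstance(s, SliceStats) else float(s)
            for s in slice_means]
    if len(vals) != 5:
        raise QuantifyError(f"brachiocephalic blood pool needs 5 slices, got {len(vals)}")
    return BloodPool("brachiocephalic", float(np.mean(vals)), vals)


def blood_pool_right_atrium(stack: EnFaceStack, rois: RoiSet,
                            truth=None) -> BloodPool:
    """Blood pool as the mean of two 2-cm^2 ROI SUVmeans in the center of
    the right atrium, at the right-coronary-ostium level and one slice
    superiorly.  If phantom truth is supplied, warns when the ROI
    overlaps non-blood structure."""
    if rois.atrium_slice is None or rois.atrium_mask is None:
        raise QuantifyError("ROI set has no atrium ROI")
    k = rois.atrium_slice
    vals = [float(stack.slices[k][rois.atrium_mask].mean()),
            float(stack.slices[k + 1][rois.atrium_mask].mean())]
    if truth is not None:
        import warnings
        cfg = truth.config
        u, v = stack.pixel_centers_plane()
        U, V = np.meshgrid(u, v, indexing="ij")
        for kk in (k, k + 1):
            w = stack.slice_offsets()[kk]
            pts = stack.plane.plane_to_world(
                np.column_stack([U[rois.atrium_mask], V[rois.atrium_mask],
                                 np.full(int(rois.atrium_mask.sum()), w)]))
            d2 = np.sum((pts - truth.atrium_center) ** 2, axis=1)
            if np.any(d2 > cfg.atrium_radius_mm ** 2):
                warnings.warn("atrium ROI extends beyond the blood pool",
                              stacklevel=2)
    return BloodPool("right_atrium", float(np.mean(vals)), vals)


# ---------------------------------------------------------------------------
# corrections


def tbr(suv: float, blood_pool: float) -> float:
    """Tissue-to-background ratio: valvular SUV divided by blood-pool SUV."""
    if blood_pool <= 0:
        raise QuantifyError("blood pool must be positive for TBR")
    return float(suv) / float(blood_pool)


def corrected_suv(suv: float, blood_pool: float) -> float:
    """Subtraction-corrected SUV: valvular SUV minus blood-pool SUV.
    May be negative; callers flag negative results."""
    return float(suv) - float(blood_pool)


def suv_from_activity(concentration_bq_ml: float, injected_dose_bq: float,
                      body_weight_g: float) -> float:
    """Standard uptake value from activity concentration, dose and weight.

    Provided for completeness; the phantom generates voxels directly in
    SUV units so the pipeline never calls this."""
    if injected_dose_bq <= 0 or body_weight_g <= 0:
        raise QuantifyError("dose and weight must be positive")
    return concentration_bq_ml * body_weight_g / injected_dose_bq


# ---------------------------------------------------------------------------
# full-valve quantification


def cusp_uptake_flags(stack: EnFaceStack, cusp_rois: dict[str, dict[int, np.ndarray]],
                      blood_pool: BloodPool, threshold: float = 1.25
                      ) -> dict[str, bool]:
    """Per-cusp uptake-present flags: a cusp is positive when the SUVmax
    over its 120-degree sector (all slices) exceeds ``threshold`` times
    the blood pool.  The threshold is a configurable stand-in for the
    visual windowing call anchored at right-atrium blood-pool activity."""
    flags: dict[str, bool] = {}
    for cusp, per_slice in cusp_rois.items():
        if not per_slice:
            raise QuantifyError(f"missing sector ROI for {cusp} cusp")
        mx = max(float(stack.slices[k][m].max())
                 for k, m in per_slice.items() if m.any())
        flags[cusp] = mx > threshold * blood_pool.value
    return flags


def quantify_valve(stack: EnFaceStack, rois: RoiSet, blood_pool: BloodPool,
                   cusp_threshold: float = 1.25) -> UptakeResult:
    """Compute the full uptake profile of one scan.

    Produces per-slice statistics over the valve perimeter ROIs, the
    whole-valve and MDS summaries, their TBR (ratio) and corrected-SUV
    (subtraction) variants against the supplied blood pool, and per-cusp
    uptake flags when sector ROIs are available.
    """
    stats = [slice_suv_stats(stack.slices[k], mask, index=k,
                             out_of_volume=bool(stack.out_of_volume[k]))
             for k, mask in sorted(rois.valve_masks.items())]
    wv_mean, wv_max = whole_valve_uptake(stats)
    mds = mds_uptake(stats)
    flags = None
    if any(rois.cusp_masks.values()):
        flags = cusp_uptake_flags(stack, rois.cusp_masks, blood_pool, cusp_threshold)
    return UptakeResult(
        slice_stats=stats,
        suv_mean=wv_mean, suv_max=wv_max,
        suv_mds_mean=mds.mean_value, suv_mds_max=mds.max_value,
        mds_mean_pair=mds.mean_pair, mds_max_pair=mds.max_pair,
        blood_pool=blood_pool, cusp_flags=flags)
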