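"""Digital gated cardiac PET/CT phantom for 18F-fluoride valve imaging.

The phantom emulates the statistical structure of a gated 18F-fluoride
acquisition over the aortic valve: blood-pool activity in the cardiac
chambers and great vessels (redrawn per scan around SUV 1.10 +/- 0.35),
focal valve lesions as Gaussian blobs at commissures, leaflet tips or
cusp bodies, low lung background, zero myocardial uptake, a tapering
brachiocephalic vein whose measured values decline cranially after
partial-volume blur, count-dependent noise, and rigid per-gate valve
motion.  Every random element is driven by a single seed plus a scan
index, so identical inputs give bit-identical volumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import GatedSeries, ImageVolume

CUSPS = ("right", "noncoronary", "left")
CUSP_ANGLES_DEG = {"right": 0.0, "noncoronary": 120.0, "left": 240.0}
LESION_LOCATIONS = ("commissure", "tip", "cusp-body")
# fraction of PET data per gate; gate 2 covers the 50-75% RR diastolic window
N_GATES = 4
# per-gate rigid valve displacement as a fraction of the motion amplitude;
# zero in diastole so the gated reconstruction sees the resting anatomy
GATE_MOTION_WEIGHTS = (1.0, 0.5, 0.0, 0.5)


class PhantomConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Lesion:
    """A focal microcalcification lesion on the valve.

    ``location`` places the lesion at a commissure (between the named
    cusp and its counterclockwise neighbour), at the leaflet tip of the
    named cusp (near the coaptation point), or in the cusp body.
    """

    location: str
    cusp: str
    peak_suv: float
    radius_mm: float

    def __post_init__(self) -> None:
        if self.location not in LESION_LOCATIONS:
            raise PhantomConfigError(f"unknown lesion location {self.location!r}")
        if self.cusp not in CUSPS:
            raise PhantomConfigError(f"unknown cusp {self.cusp!r}")
        if self.peak_suv < 0 or self.radius_mm <= 0:
            raise PhantomConfigError("lesion needs peak SUV >= 0 and radius > 0")


@dataclass
class PhantomConfig:
    """Full parameterisation of the gated phantom.

    Geometry is in world mm with the z axis pointing cranially; axial
    slices are ordered caudal to cranial.  Defaults describe a
    mild-to-moderate aortic-stenosis patient: two lesions (noncoronary
    leaflet tip and right/noncoronary commissure), blood pool drawn from
    a zero-truncated normal(1.10, 0.35) per scan, faint lung background
    and a reconstructed resolution of about 4 mm FWHM.
    """

    shape: tuple[int, int, int] = (72, 72, 96)
    spacing_mm: float = 2.0
    valve_center: tuple[float, float, float] = (72.0, 72.0, 100.0)
    annulus_radius_mm: float = 12.0
    valve_tilt_deg: tuple[float, float] = (15.0, 0.0)
    valve_half_thickness_mm: float = 4.0
    lesions: tuple[Lesion, ...] = (
        Lesion("tip", "noncoronary", 3.0, 3.0),
        Lesion("commissure", "right", 2.5, 3.0),
    )
    blood_suv_mean: float = 1.10
    blood_suv_sd: float = 0.35
    # exponent coupling tissue/lung activity to the per-scan blood level:
    # 1 = uptake fully tracks tracer availability (lesion and lung activity
    # scale with blood), 0 = uptake independent of the circulating level
    tracer_availability_coupling: float = 1.0
    lung_suv: float = 0.2
    psf_fwhm_mm: float = 4.0
    total_events: int = 200_000
    noise_coeff: float = 30.0
    motion_amplitude_mm: float = 3.0
    # great-vessel / chamber geometry
    atrium_offset_mm: float = 36.0
    atrium_radius_mm: float = 20.0
    aorta_radius_mm: float = 14.0
    chamber_radius_mm: float = 38.0
    vein_xy_mm: tuple[float, float] = (40.0, 72.0)
    vein_junction_z_mm: float = 140.0
    vein_radius_caudal_mm: float = 5.0
    vein_radius_cranial_mm: float = 2.0
    vein_taper_length_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise PhantomConfigError("voxel spacing must be positive")
        if self.total_events <= 0:
            raise PhantomConfigError("total event count must be positive")
        if self.psf_fwhm_mm < 0:
            raise PhantomConfigError("PSF FWHM must be non-negative")
        for name in ("blood_suv_mean", "blood_suv_sd", "lung_suv", "noise_coeff",
                     "motion_amplitude_mm"):
            if getattr(self, name) < 0:
                raise PhantomConfigError(f"{name} must be non-negative")
        self.lesions = tuple(self.lesions)

    # -- derived geometry ---------------------------------------------------

    def plane_rotation(self) -> np.ndarray:
        """Rotation taking the axial frame into the valve frame."""
        rx, ry = np.deg2rad(self.valve_tilt_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        return Rx @ Ry

    def valve_frame_point(self, u: float, v: float, w: float) -> np.ndarray:
        """Valve-frame (in-plane u, v; normal w) point in world mm."""
        R = self.plane_rotation()
        return np.asarray(self.valve_center) + R @ np.array([u, v, w])

    def landmarks(self) -> np.ndarray:
        """Leaflet-base landmarks (right, noncoronary, left) in world mm."""
        pts = []
        for cusp in CUSPS:
            a = np.deg2rad(CUSP_ANGLES_DEG[cusp])
            pts.append(self.valve_frame_point(
                self.annulus_radius_mm * np.cos(a),
                self.annulus_radius_mm * np.sin(a), 0.0))
        return np.array(pts)

    def lesion_center(self, lesion: Lesion) -> np.ndarray:
        a = CUSP_ANGLES_DEG[lesion.cusp]
        r = self.annulus_radius_mm
        if lesion.location == "commissure":
            # midpoint between the named cusp and the next one, nudged into
            # the named cusp's sector so truth flags are unambiguous
            ang, rad, w = a + 55.0, r, 0.0
        elif lesion.location == "tip":
            ang, rad, w = a, 0.25 * r, 2.0
        else:  # cusp-body
            ang, rad, w = a, 0.6 * r, 0.0
        ang = np.deg2rad(ang)
        return self.valve_frame_point(rad * np.cos(ang), rad * np.sin(ang), w)

    def atrium_center(self) -> np.ndarray:
        """Right-atrium center, in-plane at the right-coronary-ostium level."""
        return self.valve_frame_point(self.atrium_offset_mm, 0.0, 0.0)

    def vein_radius_at(self, z: np.ndarray) -> np.ndarray:
        """Local brachiocephalic-vein radius (mm) at axial level z."""
        z = np.asarray(z, dtype=float)
        t = np.clip((z - self.vein_junction_z_mm) / self.vein_taper_length_mm, 0.0, 1.0)
        return self.vein_radius_caudal_mm + t * (
            self.vein_radius_cranial_mm - self.vein_radius_caudal_mm)

    def true_cusp_flags(self) -> dict[str, bool]:
        """Which cusps carry a lesion whose center falls in their 120-degree sector."""
        flags = {c: False for c in CUSPS}
        for les in self.lesions:
            ctr = self.lesion_center(les)
            R = self.plane_rotation()
            uvw = R.T @ (ctr - np.asarray(self.valve_center))
            ang = np.rad2deg(np.arctan2(uvw[1], uvw[0])) % 360.0
            for cusp, ca in CUSP_ANGLES_DEG.items():
                if (ang - ca + 60.0) % 360.0 < 120.0:
                    flags[cusp] = True
                    break
        return flags

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lesions"] = [dataclasses.asdict(l) for l in self.lesions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["lesions"] = tuple(Lesion(**l) for l in d.get("lesions", ()))
        for key in ("shape", "valve_center", "valve_tilt_deg", "vein_xy_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def ideal(cls, lesions: tuple[Lesion, ...] | None = None,
              blood_suv: float = 1.0, **kw) -> "PhantomConfig":
        """Noise-, blur-, motion- and tilt-free configuration.

        The valve plane is axial and lesion centers fall on voxel
        centers, so the identity pipeline preserves peak values exactly.
        Useful as a ground-truth-recovery baseline.
        """
        if lesions is None:
            lesions = (Lesion("cusp-body", "right", 3.0, 3.0),)
        kw.setdefault("annulus_radius_mm", 10.0)
        kw.setdefault("valve_tilt_deg", (0.0, 0.0))
        kw.setdefault("psf_fwhm_mm", 0.0)
        kw.setdefault("noise_coeff", 0.0)
        kw.setdefault("motion_amplitude_mm", 0.0)
        kw.setdefault("blood_suv_sd", 0.0)
        kw.setdefault("blood_suv_mean", blood_suv)
        return cls(lesions=lesions, **kw)


@dataclass
class PhantomTruth:
    """Ground truth accompanying one simulated scan."""

    config: PhantomConfig
    scan_index: int
    activity: ImageVolume          # noise-free, blur-free, diastolic anatomy
    landmarks: np.ndarray          # (3, 3) world mm: right, noncoronary, left
    lesion_centers: np.ndarray     # (n_lesions, 3) world mm, diastolic
    lesion_peak_suvs: np.ndarray
    blood_suv: float
    cusp_flags: dict[str, bool]
    atrium_center: np.ndarray

    def valve_slab_halfwidth(self) -> float:
        """Half-extent (mm) of valve structures along the valve normal."""
        half = self.config.valve_half_thickness_mm
        for les in self.config.lesions:
            w = 2.0 if les.location == "tip" else 0.0
            half = max(half, abs(w) + les.radius_mm)
        return half

    def to_dict(self) -> dict:
        return {
            "scan_index": self.scan_index,
            "blood_suv": self.blood_suv,
            "landmarks_mm": self.landmarks.tolist(),
            "lesion_centers_mm": self.lesion_centers.tolist(),
            "lesion_peak_suvs": self.lesion_peak_suvs.tolist(),
            "cusp_flags": self.cusp_flags,
            "atrium_center_mm": self.atrium_center.tolist(),
            "config": self.config.to_dict(),
        }


# ---------------------------------------------------------------------------
# gating helpers


def bin_events_to_gates(event_phases, n_gates: int) -> np.ndarray:
    """Bin cardiac phases (fractions of the RR interval in [0, 1)) into
    equal-width gates; returns per-gate event counts summing to the
    number of events."""
    phases = np.asarray(event_phases, dtype=float)
    if n_gates < 1:
        raise ValueError("n_gates must be >= 1")
    if phases.size and (phases.min() < 0.0 or phases.max() >= 1.0):
        raise ValueError("cardiac phases must lie in [0, 1)")
    idx = np.floor(n_gates * phases).astype(int)
    return np.bincount(idx, minlength=n_gates)


def select_diastolic_gate(series: GatedSeries) -> ImageVolume:
    """Return the gate covering 50-75% of the RR interval (diastole,
    when cardiac motion is at a minimum).  Requires a 4-gate series."""
    if series.n_gates != N_GATES:
        raise ValueError(f"diastolic gating expects {N_GATES} gates, got {series.n_gates}")
    lo, hi = series.phase_windows[2]
    if not (abs(lo - 0.50) < 1e-9 and abs(hi - 0.75) < 1e-9):
        raise ValueError("gate 2 does not cover the [0.50, 0.75) RR window")
    return series.gates[2]


# ---------------------------------------------------------------------------
# activity painting


def _world_grids(config: PhantomConfig):
    n = config.shape
    s = config.spacing_mm
    x = np.arange(n[0]) * s
    y = np.arange(n[1]) * s
    z = np.arange(n[2]) * s
    return np.meshgrid(x, y, z, indexing="ij")


def _paint_anatomy(config: PhantomConfig, blood_suv: float,
                   availability: float = 1.0) -> np.ndarray:
    """Static (non-valve) activity: chambers, atrium, aorta, vein, lung."""
    X, Y, Z = _world_grids(config)
    act = np.zeros(config.shape)

    # lung background around the vein (low uptake, cranial mediastinum)
    lung = (Z >= config.vein_junction_z_mm - 16.0) & (Z <= config.vein_junction_z_mm + 50.0) \
        & (X >= 10.0) & (X <= 70.0)
    act[lung] = config.lung_suv * availability

    ctr = np.asarray(config.valve_center)
    R = config.plane_rotation()
    U = (X - ctr[0]) * R[0, 0] + (Y - ctr[1]) * R[1, 0] + (Z - ctr[2]) * R[2, 0]
    V = (X - ctr[0]) * R[0, 1] + (Y - ctr[1]) * R[1, 1] + (Z - ctr[2]) * R[2, 1]
    W = (X - ctr[0]) * R[0, 2] + (Y - ctr[1]) * R[1, 2] + (Z - ctr[2]) * R[2, 2]

    blood = np.zeros(config.shape, dtype=bool)
    # aortic root / LVOT column through the valve plane
    blood |= (U * U + V * V <= config.aorta_radius_mm ** 2) & (W >= -25.0) & (W <= 40.0)
    # cardiac chambers blob caudal to the valve
    cham = ctr + R @ np.array([0.0, 0.0, -0.9 * config.chamber_radius_mm])
    blood |= ((X - cham[0]) ** 2 + (Y - cham[1]) ** 2 + (Z - cham[2]) ** 2
              <= config.chamber_radius_mm ** 2)
    # right atrium at the right-coronary-ostium level
    atr = config.atrium_center()
    blood |= ((X - atr[0]) ** 2 + (Y - atr[1]) ** 2 + (Z - atr[2]) ** 2
              <= config.atrium_radius_mm ** 2)
    # brachiocephalic vein: tapering cylinder rising into the lung, with a
    # wider innominate stub below the junction
    vx, vy = config.vein_xy_mm
    r_local = config.vein_radius_at(Z)
    dist2 = (X - vx) ** 2 + (Y - vy) ** 2
    vein = (Z >= config.vein_junction_z_mm) & (Z <= config.vein_junction_z_mm + 40.0) \
        & (dist2 <= r_local ** 2)
    stub = (Z >= config.vein_junction_z_mm - 14.0) & (Z < config.vein_junction_z_mm) \
        & (dist2 <= 7.0 ** 2)
    blood |= vein | stub

    act[blood] = blood_suv
    return act


def _paint_lesions(config: PhantomConfig, act: np.ndarray,
                   displacement: np.ndarray,
                   availability: float = 1.0) -> np.ndarray:
    """Add lesion blobs (rigidly displaced valve substructure) via max-combine."""
    if not config.lesions:
        return act
    X, Y, Z = _world_grids(config)
    out = act.copy()
    for les in config.lesions:
        c = config.lesion_center(les) + displacement
        # flat core of the nominal radius with a Gaussian shoulder: a compact
        # macrocalcific focus whose peak survives interpolation exactly
        core = les.radius_mm
        sigma = les.radius_mm / 2.0
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        excess = np.maximum(d - core, 0.0)
        blob = les.peak_suv * availability * np.exp(-(excess ** 2) / (2.0 * sigma ** 2))
        blob[d > core + 3.0 * sigma] = 0.0
        np.maximum(out, blob, out=out)
    return out


def generate_phantom(config: PhantomConfig, scan_index: int = 1
                     ) -> tuple[GatedSeries, PhantomTruth]:
    """Simulate one gated scan: 4 gate volumes plus ground truth.

    ``scan_index`` selects an independent noise realisation and a
    re-drawn blood-pool SUV on the same anatomy, emulating repeat scans
    of the same patient.  The pipeline is: paint noise-free activity,
    displace the valve substructure rigidly per gate, blur with the
    Gaussian PSF, then add count-scaled noise with each gate receiving
    its binned share of the total events.
    """
    rng = np.random.default_rng([int(config.seed) % (2 ** 31), int(scan_index)])

    # per-scan blood pool: zero-truncated normal
    blood = float(rng.normal(config.blood_suv_mean, config.blood_suv_sd)) \
        if config.blood_suv_sd > 0 else float(config.blood_suv_mean)
    while blood <= 0:
        blood = float(rng.normal(config.blood_suv_mean, config.blood_suv_sd))

    phases = rng.random(config.total_events)
    counts = bin_events_to_gates(phases, N_GATES)

    # tissue and lung activity track the circulating tracer level, so a
    # high-blood scan raises valvular SUV too (ratio correction cancels it)
    availability = 1.0
    if config.blood_suv_mean > 0 and config.tracer_availability_coupling != 0:
        availability = (blood / config.blood_suv_mean) \
            ** config.tracer_availability_coupling

    base = _paint_anatomy(config, blood, availability)
    motion_dir = config.plane_rotation() @ np.array([0.0, 0.0, 1.0])
    sigma_vox = (config.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                 / config.spacing_mm) if config.psf_fwhm_mm > 0 else 0.0

    gates: list[ImageVolume] = []
    for g in range(N_GATES):
        disp = config.motion_amplitude_mm * GATE_MOTION_WEIGHTS[g] * motion_dir
        act = _paint_lesions(config, base, disp, availability)
        if sigma_vox > 0:
            act = ndimage.gaussian_filter(act, sigma_vox)
        if config.noise_coeff > 0 and counts[g] > 0:
            sigma = config.noise_coeff * np.sqrt(np.maximum(act, 0.0) / counts[g])
            act = act + rng.standard_normal(act.shape) * sigma
        gates.append(ImageVolume.from_spacing(act, config.spacing_mm))

    truth_act = _paint_lesions(config, base, np.zeros(3), availability)
    truth = PhantomTruth(
        config=config,
        scan_index=scan_index,
        activity=ImageVolume.from_spacing(truth_act, config.spacing_mm),
        landmarks=config.landmarks(),
        lesion_centers=np.array([config.lesion_center(l) for l in config.lesions])
        if config.lesions else np.zeros((0, 3)),
        lesion_peak_suvs=availability * np.array([l.peak_suv for l in config.lesions]),
        blood_suv=blood,
        cusp_flags=config.true_cusp_flags(),
        atrium_center=config.atrium_center(),
    )
    return GatedSeries(gates, counts), truth
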