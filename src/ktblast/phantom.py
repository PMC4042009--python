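"""Synthetic contracting left-ventricle cine phantom.

Generates multi-slice short-axis image series of a beating LV in which the
cavity and wall volumes are known analytically at every frame, so that every
downstream stage (undersampling, reconstruction, volumetry) can be checked
against ground truth.  Geometry per slice/frame is two concentric discs:
the cavity (bright blood pool) inside a myocardial annulus, on a dim
background.  Radii follow a raised-cosine contraction between end-diastolic
and end-systolic values, with a linear apex-to-base taper, optionally with a
hypokinetic angular sector emulating a myocardial infarct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "PhantomSpec",
    "CineStack",
    "GroundTruth",
    "generate_phantom",
    "corrupt_kspace",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_CAVITY = 2


@dataclass
class PhantomSpec:
    """Geometry, signal and acquisition parameters of the cine phantom.

    Radii are given at the base slice; ``taper_apex`` scales them linearly
    down towards the apical slice.  Intensities are arbitrary units; the
    blood pool must be brighter than the myocardium (CNR sign convention).
    """

    matrix_size: int = 192
    fov_mm: float = 30.0
    n_slices: int = 8
    slice_thickness_mm: float = 1.0
    n_frames: int = 12
    endo_radius_ed_mm: float = 1.95
    endo_radius_es_mm: float = 1.23
    epi_radius_ed_mm: float = 3.17
    epi_radius_es_mm: float = 2.78
    taper_apex: float = 0.6
    signal_blood: float = 1.0
    signal_myo: float = 0.45
    signal_background: float = 0.05
    noise_sd: float = 0.2
    heart_rate_bpm: float = 500.0
    seed: int = 0
    systole_frame_fraction: float = 1.0 / 3.0
    # hypokinetic sector (infarct emulation): radius excursion within the
    # sector is multiplied by (1 - infarct_severity); severity 0 disables.
    infarct_sector_deg: float = 0.0
    infarct_severity: float = 0.0

    def __post_init__(self) -> None:
        if self.matrix_size < 2 or self.matrix_size % 2:
            raise ValueError("matrix_size must be even and >= 2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for name in ("endo_radius_ed_mm", "endo_radius_es_mm",
                     "epi_radius_ed_mm", "epi_radius_es_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.endo_radius_ed_mm >= self.epi_radius_ed_mm
                or self.endo_radius_es_mm >= self.epi_radius_es_mm):
            raise ValueError("endocardial radius must be < epicardial radius")
        if not self.signal_blood > self.signal_myo:
            raise ValueError("signal_blood must exceed signal_myo")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.taper_apex <= 1.0:
            raise ValueError("taper_apex must be in [0, 1]")
        if not 0.0 <= self.infarct_severity <= 1.0:
            raise ValueError("infarct_severity must be in [0, 1]")
        if not 0.0 <= self.infarct_sector_deg <= 360.0:
            raise ValueError("infarct_sector_deg must be in [0, 360]")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix_size

    @property
    def frame_duration_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm / self.n_frames

    def slice_taper(self) -> np.ndarray:
        """Per-slice radius scale, 1.0 at the base down to taper_apex."""
        if self.n_slices == 1:
            return np.array([1.0])
        return np.linspace(1.0, self.taper_apex, self.n_slices)

    def contraction(self) -> np.ndarray:
        """Per-frame contraction weight in [0, 1]; 1 at end systole.

        Raised cosine with its maximum at systole_frame_fraction of the
        cycle, so the motion is smooth and periodic over the frames.
        """
        t = np.arange(self.n_frames) / self.n_frames
        return (1.0 + np.cos(2.0 * np.pi * (t - self.systole_frame_fraction))) / 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


@dataclass
class CineStack:
    """Real-valued cine image series indexed (y, x, slice, frame)."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    frame_duration_ms: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (y, x, slice, frame)")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]


@dataclass
class GroundTruth:
    """Analytic per-frame volumes and rasterised label masks of the phantom."""

    cavity_volume_ul: np.ndarray   # (n_frames,)
    wall_volume_ul: np.ndarray     # (n_frames,)
    masks: np.ndarray              # uint8 (y, x, slice, frame), labels 0/1/2
    center_px: tuple[float, float]  # (y, x)
    endo_radius_mm: np.ndarray     # (n_slices, n_frames) outside any infarct sector
    epi_radius_mm: np.ndarray      # (n_slices, n_frames)

    @property
    def ed_frame(self) -> int:
        return int(np.argmax(self.cavity_volume_ul))

    @property
    def es_frame(self) -> int:
        return int(np.argmin(self.cavity_volume_ul))


def _radii_per_slice_frame(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray,
                                                       np.ndarray, np.ndarray]:
    """Radii arrays (n_slices, n_frames) for normal and infarcted tissue."""
    taper = spec.slice_taper()[:, None]          # (s, 1)
    w = spec.contraction()[None, :]              # (1, t)
    sev = spec.infarct_severity if spec.infarct_sector_deg > 0 else 0.0

    def interp(r_ed: float, r_es: float, severity: float) -> np.ndarray:
        excursion = (r_ed - r_es) * (1.0 - severity)
        return taper * (r_ed - excursion * w)

    endo = interp(spec.endo_radius_ed_mm, spec.endo_radius_es_mm, 0.0)
    epi = interp(spec.epi_radius_ed_mm, spec.epi_radius_es_mm, 0.0)
    endo_inf = interp(spec.endo_radius_ed_mm, spec.endo_radius_es_mm, sev)
    epi_inf = interp(spec.epi_radius_ed_mm, spec.epi_radius_es_mm, sev)
    return endo, epi, endo_inf, epi_inf


def _analytic_volumes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame cavity and wall volumes in microlitres (1 mm^3 = 1 uL).

    With a hypokinetic sector of angle theta the cross-sectional cavity area
    is (theta/2pi)*pi*r_inf^2 + (1-theta/2pi)*pi*r^2, summed over slices.
    """
    endo, epi, endo_inf, epi_inf = _radii_per_slice_frame(spec)
    frac = spec.infarct_sector_deg / 360.0 if spec.infarct_severity > 0 else 0.0
    area_cav = np.pi * ((1 - frac) * endo ** 2 + frac * endo_inf ** 2)
    area_epi = np.pi * ((1 - frac) * epi ** 2 + frac * epi_inf ** 2)
    dz = spec.slice_thickness_mm
    cavity = area_cav.sum(axis=0) * dz
    wall = (area_epi - area_cav).sum(axis=0) * dz
    return cavity, wall


def generate_phantom(spec: PhantomSpec) -> tuple[CineStack, GroundTruth]:
    """Rasterise the noise-free phantom and its analytic ground truth.

    Pixels are assigned by centre-point containment (no anti-aliasing), so
    mask volumes are exact voxel counts; analytic volumes come from the
    radii, not from pixel counts.  Deterministic given the spec.
    """
    n = spec.matrix_size
    px = spec.pixel_mm
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy = (yy - c) * px
    dx = (xx - c) * px
    dist = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0

    endo, epi, endo_inf, epi_inf = _radii_per_slice_frame(spec)
    use_inf = spec.infarct_severity > 0 and spec.infarct_sector_deg > 0
    in_sector = theta < spec.infarct_sector_deg if use_inf else np.zeros((n, n), bool)

    img = np.full((n, n, spec.n_slices, spec.n_frames), spec.signal_background)
    masks = np.zeros((n, n, spec.n_slices, spec.n_frames), dtype=np.uint8)
    for s in range(spec.n_slices):
        for t in range(spec.n_frames):
            r_en = np.where(in_sector, endo_inf[s, t], endo[s, t])
            r_ep = np.where(in_sector, epi_inf[s, t], epi[s, t])
            cav = dist < r_en
            myo = (dist < r_ep) & ~cav
            img[cav, s, t] = spec.signal_blood
            img[myo, s, t] = spec.signal_myo
            masks[cav, s, t] = LABEL_CAVITY
            masks[myo, s, t] = LABEL_MYOCARDIUM

    cavity, wall = _analytic_volumes(spec)
    stack = CineStack(
        values=img,
        voxel_size_mm=(px, px, spec.slice_thickness_mm),
        frame_duration_ms=spec.frame_duration_ms,
        metadata={"source": "phantom", "spec": spec.to_dict()},
    )
    gt = GroundTruth(
        cavity_volume_ul=cavity,
        wall_volume_ul=wall,
        masks=masks,
        center_px=(c, c),
        endo_radius_mm=endo,
        epi_radius_mm=epi,
    )
    return stack, gt


def corrupt_kspace(stack: CineStack, noise_sd: float, seed: int,
                   n_averages: int = 1):
    """Forward-transform a cine stack to k-space and add complex noise.

    Each slice/frame is taken to k-space with a unitary 2-D FFT (DC at the
    centre) and independent complex Gaussian noise of standard deviation
    ``noise_sd`` per real/imaginary channel is added.  ``n_averages``
    simulates signal averaging on the scanner: the noise of each average is
    independent and the complex averages are combined, so the effective
    noise SD is noise_sd / sqrt(n_averages).  Fully sampled mask.
    """
    from .sampling import KtData  # local import: avoid a module cycle

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    rng = np.random.default_rng(seed)
    img = stack.values.astype(complex)
    k = np.fft.fftshift(
        np.fft.fft2(img, axes=(0, 1), norm="ortho"), axes=(0, 1)
    )
    if noise_sd > 0:
        sd = noise_sd / np.sqrt(n_averages)
        noise = rng.normal(scale=sd, size=k.shape) + 1j * rng.normal(scale=sd, size=k.shape)
        k = k + noise
    mask = np.ones((k.shape[0], k.shape[3]), dtype=bool)
    meta = dict(stack.metadata)
    meta.update({"noise_sd": noise_sd, "seed": seed, "n_averages": n_averages})
    return KtData(
        samples=k,
        mask=mask,
        voxel_size_mm=stack.voxel_size_mm,
        frame_duration_ms=stack.frame_duration_ms,
        metadata=meta,
    )
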