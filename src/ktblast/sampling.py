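"""k-t sampling schemes: sheared-lattice undersampling and training scans.

The accelerated acquisition samples every r-th phase-encode row, with the
index of the first sampled row incremented by one between time frames
(mask[k, t] = 1 iff k = t mod r).  The training scan acquires only a band
of central rows (default 16) at every frame, giving a low-spatial-resolution
but fully time-resolved view of each voxel's temporal spectrum.

k-space is stored with DC at the centre row (index n_ky // 2); training-band
row indices depend on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

__all__ = [
    "SamplingScheme",
    "KtData",
    "make_lattice_mask",
    "extract_training",
    "apply_mask",
    "net_acceleration",
]


@dataclass
class SamplingScheme:
    """r-fold sheared-lattice undersampling with per-frame row offset t mod r."""

    r: int
    n_ky: int
    n_frames: int
    training_rows: int = 16

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("acceleration factor r must be >= 1")
        if self.n_ky < 1 or self.n_frames < 1:
            raise ValueError("n_ky and n_frames must be >= 1")
        if self.training_rows % 2 or not 0 <= self.training_rows <= self.n_ky:
            raise ValueError("training_rows must be even and <= n_ky")

    @property
    def offset_schedule(self) -> np.ndarray:
        return np.arange(self.n_frames) % self.r

    def require_divisible(self) -> None:
        """Reconstruction needs r | n_frames (alias sets close in f)."""
        if self.n_frames % self.r:
            raise ValueError(
                f"n_frames={self.n_frames} must be divisible by r={self.r} "
                "for kt-BLAST reconstruction"
            )


@dataclass
class KtData:
    """Complex k-space samples (ky, kx, slice, frame) with a (ky, frame) mask."""

    samples: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    frame_duration_ms: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.samples.ndim != 4:
            raise ValueError("samples must be 4-D (ky, kx, slice, frame)")
        if self.mask.shape != (self.samples.shape[0], self.samples.shape[3]):
            raise ValueError("mask must have shape (n_ky, n_frames)")
        unsampled = ~self.mask[:, None, None, :]
        if not np.all(self.samples[np.broadcast_to(unsampled, self.samples.shape)] == 0):
            raise ValueError("samples must be zero wherever the mask is zero")

    @property
    def n_ky(self) -> int:
        return self.samples.shape[0]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[3]

    @property
    def fully_sampled(self) -> bool:
        return bool(self.mask.all())


def make_lattice_mask(scheme: SamplingScheme) -> np.ndarray:
    """Boolean (n_ky, n_frames) mask: row k sampled at frame t iff k = t (mod r)."""
    k = np.arange(scheme.n_ky)[:, None]
    t = np.arange(scheme.n_frames)[None, :]
    return (k % scheme.r) == (t % scheme.r)


def training_band(n_ky: int, training_rows: int) -> slice:
    """Row slice of the centred training band under the DC-at-centre convention."""
    if training_rows > n_ky:
        raise ValueError("training_rows exceeds n_ky")
    lo = n_ky // 2 - training_rows // 2
    return slice(lo, lo + training_rows)


def extract_training(full: KtData, training_rows: int) -> KtData:
    """Keep only the central ``training_rows`` rows (all frames) of full k-space."""
    if not full.fully_sampled:
        raise ValueError("training extraction requires fully sampled k-space")
    band = training_band(full.n_ky, training_rows)
    samples = np.zeros_like(full.samples)
    samples[band] = full.samples[band]
    mask = np.zeros_like(full.mask)
    mask[band] = True
    meta = dict(full.metadata)
    meta["training_rows"] = training_rows
    return KtData(samples, mask, full.voxel_size_mm, full.frame_duration_ms, meta)


def apply_mask(full: KtData, mask: np.ndarray) -> KtData:
    """Zero out unsampled rows of k-space and record the mask. Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != full.mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match data {full.mask.shape}"
        )
    samples = full.samples * mask[:, None, None, :]
    return KtData(samples, mask & full.mask, full.voxel_size_mm,
                  full.frame_duration_ms, dict(full.metadata))


def net_acceleration(n_ky: int, r: int, training_rows: int = 16) -> float:
    """Overall speed-up once the separate training scan is accounted for.

    n_ky / (rows per accelerated frame + training rows); e.g. a nominal
    threefold undersampling of 192 rows with a 16-row training scan is a net
    192 / (64 + 16) = 2.4-fold acceleration.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if training_rows < 0:
        raise ValueError("training_rows must be >= 0")
    return n_ky / (ceil(n_ky / r) + training_rows)
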