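"""Image-quality metrics: normalised reconstruction error and blood-myocardium CNR.

The reconstruction error is the mean, over every frame, slice and pixel of a
heart-centred region of interest, of |I_f - I_u| / I_f, where I_f is the
image from full k-space and I_u the one from undersampled k-space.  Division
by I_f is unstable near zero, so pixels where I_f falls below a small floor
(1% of the ROI maximum) are excluded from both the sum and the count; the
exclusion fraction is reported.

CNR = (S_blood - S_myo) / sigma with sigma the root-sum-of-squares of the
two regions' standard deviations, measured on one slice at one frame
(conventionally a mid-ventricular slice at end diastole).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import CineStack

__all__ = ["RoiSpec", "MetricReport", "reconstruction_error", "cnr"]

REL_FLOOR = 0.01  # exclude pixels with I_f below this fraction of the ROI max


@dataclass
class RoiSpec:
    """Axis-aligned ROI centred on the heart; default 60 x 60 pixels."""

    center_px: tuple[float, float]  # (y, x)
    height_px: int = 60
    width_px: int = 60

    def slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        cy, cx = self.center_px
        y0 = int(np.floor(cy - self.height_px / 2 + 0.5))
        x0 = int(np.floor(cx - self.width_px / 2 + 0.5))
        if y0 < 0 or x0 < 0 or y0 + self.height_px > shape[0] \
                or x0 + self.width_px > shape[1]:
            raise ValueError("ROI does not lie fully inside the image")
        return slice(y0, y0 + self.height_px), slice(x0, x0 + self.width_px)


@dataclass
class MetricReport:
    epsilon: Optional[float] = None
    n_terms: Optional[int] = None
    excluded_fraction: Optional[float] = None
    cnr: Optional[float] = None
    s_blood: Optional[float] = None
    s_myo: Optional[float] = None
    sd_blood: Optional[float] = None
    sd_myo: Optional[float] = None
    sigma: Optional[float] = None
    provenance: dict = field(default_factory=dict)


def reconstruction_error(full: CineStack, under: CineStack,
                         roi: RoiSpec) -> MetricReport:
    """Mean normalised absolute error over all frames, slices and ROI pixels."""
    if full.values.shape != under.values.shape:
        raise ValueError("image stacks must share a common shape")
    ys, xs = roi.slices(full.values.shape[:2])
    i_f = full.values[ys, xs]
    i_u = under.values[ys, xs]
    floor = REL_FLOOR * i_f.max()
    valid = i_f > floor
    n_total = i_f.size
    n_terms = int(valid.sum())
    if n_terms == 0:
        raise ValueError("ROI is empty after flooring the reference image")
    eps = float(np.sum(np.abs(i_f[valid] - i_u[valid]) / i_f[valid]) / n_terms)
    return MetricReport(
        epsilon=eps,
        n_terms=n_terms,
        excluded_fraction=1.0 - n_terms / n_total,
        provenance={"roi": (roi.height_px, roi.width_px), "floor": float(floor)},
    )


def cnr(stack: CineStack, blood_mask: np.ndarray, myo_mask: np.ndarray,
        slice_index: int, frame: int) -> MetricReport:
    """Blood-to-myocardium contrast-to-noise ratio on one slice/frame."""
    blood_mask = np.asarray(blood_mask, dtype=bool)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if not blood_mask.any() or not myo_mask.any():
        raise ValueError("blood and myocardium masks must be non-empty")
    if np.any(blood_mask & myo_mask):
        raise ValueError("blood and myocardium masks must be disjoint")
    img = stack.values[:, :, slice_index, frame]
    s_blood = float(img[blood_mask].mean())
    s_myo = float(img[myo_mask].mean())
    sd_blood = float(img[blood_mask].std(ddof=1))
    sd_myo = float(img[myo_mask].std(ddof=1))
    sigma = float(np.hypot(sd_blood, sd_myo))
    if sigma == 0.0:
        raise ValueError("zero combined SD (noise-free input); use noise_sd > 0")
    return MetricReport(
        cnr=(s_blood - s_myo) / sigma,
        s_blood=s_blood, s_myo=s_myo,
        sd_blood=sd_blood, sd_myo=sd_myo, sigma=sigma,
        provenance={"slice": slice_index, "frame": frame,
                    "myo_region": "full annulus"},
    )
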