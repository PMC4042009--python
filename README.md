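# ktblast

Accelerated cardiac cine MRI, simulated end to end: a contracting
left-ventricle phantom, sheared-lattice k-t undersampling, kt-BLAST
reconstruction, and the downstream functional measurements
(EDV/ESV/SV/EF/mass) with Bland–Altman agreement statistics.

Dynamic MRI can be sped up by acquiring only every r-th phase-encode row
per frame, with the sampled rows shifted by one row each frame
(`mask[k, t] = 1` iff `k ≡ t mod r`). The resulting aliasing separates in
x-f space (image space × temporal frequency): each voxel (y, f) is folded
with r−1 partners offset by multiples of (n_y/r, n_frames/r). kt-BLAST
resolves the fold using a low-spatial-resolution but fully time-resolved
*training* scan (central 16 rows of k-space), which provides an expected
signal power M²(y, x, f). Each aliased measurement a is then split among
its alias set by Wiener-style shrinkage:

    v̂ᵢ = M²ᵢ / (Σⱼ M²ⱼ + ψ) · a,

with ψ a noise-power regulariser, after the temporal-average (DC) image —
exactly recoverable from the union of sampled rows — has been resolved
separately. This package is aimed at preclinical imaging scientists who
want to quantify, before touching a scanner, how much acceleration their
functional measurements can tolerate: the phantom has analytically known
cavity and wall volumes at every frame, so every bias introduced by
undersampling, reconstruction and segmentation is measurable against
ground truth.

## Worked example

```python
import numpy as np
from ktblast import (PhantomSpec, generate_phantom, corrupt_kspace,
                     SamplingScheme, make_lattice_mask, apply_mask,
                     extract_training, KTBlast, RoiSpec,
                     reconstruction_error, net_acceleration,
                     segment_reconstruction, compute_indices)
from ktblast.recon import kt_to_image
from ktblast.phantom import CineStack

spec = PhantomSpec()                       # 192x192, 8 slices, 12 frames
stack, truth = generate_phantom(spec)
kt = corrupt_kspace(stack, spec.noise_sd, seed=7, n_averages=3)

full = CineStack(np.abs(kt_to_image(kt.samples)), kt.voxel_size_mm,
                 kt.frame_duration_ms)

scheme = SamplingScheme(r=3, n_ky=kt.n_ky, n_frames=kt.n_frames)
und = apply_mask(kt, make_lattice_mask(scheme))
recon = KTBlast().fit(extract_training(kt, 16)).transform(und)

eps = reconstruction_error(full, recon, RoiSpec(center_px=truth.center_px))
idx_full = compute_indices(segment_reconstruction(full, truth, spec))
idx_ktb = compute_indices(segment_reconstruction(recon, truth, spec))
print(f"net acceleration {net_acceleration(192, 3, 16):.1f}x")
print(f"epsilon = {eps.epsilon:.3f}")
print(f"EF full {idx_full.ef_pct:.1f}%  EF ktB-3 {idx_ktb.ef_pct:.1f}%")
```

prints

```
net acceleration 2.4x
epsilon = 0.538
EF full 60.0%  EF ktB-3 55.0%
```

A nominal threefold undersampling is a net 2.4× speed-up once the 16
training rows are paid for. ε ≈ 0.53 is the mean per-pixel normalised
error over a 60×60 heart ROI — dominated by noise-level background pixels,
which is why its trend over r, not its absolute value, is the informative
quantity. The ~5-percentage-point EF drop is the method's characteristic
bias: the shrinkage filter smooths temporal dynamics, so the end-systolic
cavity is overestimated and EF falls, while end-diastolic volume is
approximately maintained.

The same stages are available from the shell (`ktblast phantom`,
`acquire`, `undersample`, `train`, `recon`, `metrics`, `indices`, `sweep`,
`study`), exchanging NIfTI-1 images, HDF5 k-space and CSV/JSON reports.

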