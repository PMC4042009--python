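"""x-f transform, training variance, alias geometry and kt-BLAST unaliasing."""

import dataclasses

import numpy as np
import pytest

from ktblast import (KTBlast, KtData, PhantomSpec, SamplingScheme,
                     TrainingEstimate, alias_sets, apply_mask, corrupt_kspace,
                     estimate_training_variance, extract_training,
                     generate_phantom, make_lattice_mask, xf_transform)
from ktblast.recon import ixf_transform, kt_to_image, image_to_kt


# ---------------------------------------------------------------- x-f space

def test_xf_constant_signal_all_energy_at_dc():
    xf = xf_transform(np.ones((4, 4, 1, 8)))
    assert np.allclose(np.abs(xf[..., 0]), np.sqrt(8))
    assert np.allclose(xf[..., 1:], 0.0)


def test_xf_round_trip():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 5, 2, 12)) + 1j * rng.normal(size=(5, 5, 2, 12))
    assert np.allclose(ixf_transform(xf_transform(x)), x, atol=1e-12)


def test_xf_sinusoid_matches_direct_dft_oracle():
    n = 12
    t = np.arange(n)
    sig = np.cos(2 * np.pi * 2 * t / n)
    xf = xf_transform(sig.reshape(1, 1, 1, n))[0, 0, 0]
    nonzero = np.where(np.abs(xf) > 1e-10)[0]
    assert set(nonzero) == {2, 10}
    oracle = np.array([np.sum(sig * np.exp(-2j * np.pi * f * t / n)) for f in range(n)])
    oracle /= np.sqrt(n)
    assert np.allclose(xf, oracle, atol=1e-12)


def test_xf_rejects_single_frame():
    with pytest.raises(ValueError):
        xf_transform(np.ones((4, 4, 1, 1)))


# ------------------------------------------------------- training estimate

def test_training_variance_static_scene_only_dc(static_spec):
    stack, _ = generate_phantom(static_spec)
    kt = corrupt_kspace(stack, 0.0, 0)
    est = estimate_training_variance(extract_training(kt, 16))
    assert np.all(est.m_squared[..., 1:] < 1e-20)
    assert est.m_squared[..., 0].max() > 0


def test_training_variance_zero_data_is_zero():
    kt = KtData(samples=np.zeros((8, 8, 1, 4), complex),
                mask=np.ones((8, 4), bool), voxel_size_mm=(1, 1, 1),
                frame_duration_ms=1.0)
    est = estimate_training_variance(extract_training(kt, 4))
    assert not est.m_squared.any()


def test_training_variance_matches_brute_force_dft():
    """8x8x4 instance against an explicit triple-loop DFT."""
    rng = np.random.default_rng(7)
    imgs = rng.normal(size=(8, 8, 1, 4))
    kt = KtData(samples=image_to_kt(imgs.astype(complex)),
                mask=np.ones((8, 4), bool), voxel_size_mm=(1, 1, 1),
                frame_duration_ms=1.0)
    training = extract_training(kt, 4)
    got = estimate_training_variance(training).m_squared[:, :, 0, :]

    k = np.fft.ifftshift(training.samples[:, :, 0, :], axes=(0, 1))
    oracle = np.zeros((8, 8, 4))
    for y in range(8):
        for x in range(8):
            tser = np.zeros(4, complex)
            for tt in range(4):
                acc = 0.0
                for ky in range(8):
                    for kx in range(8):
                        acc += k[ky, kx, tt] * np.exp(
                            2j * np.pi * (ky * y + kx * x) / 8)
                tser[tt] = acc / 8.0
            for f in range(4):
                oracle[y, x, f] = np.abs(
                    np.sum(tser * np.exp(-2j * np.pi * f * np.arange(4) / 4))
                    / 2.0) ** 2
    assert np.allclose(got, oracle, atol=1e-10)


def test_training_variance_rejects_off_centre_band(small_kt):
    bad_mask = np.zeros_like(small_kt.mask)
    bad_mask[0:16] = True
    bad = apply_mask(small_kt, bad_mask)
    with pytest.raises(ValueError):
        estimate_training_variance(bad)


# ----------------------------------------------------------- alias geometry

def test_alias_sets_r1_singletons():
    sets = alias_sets(SamplingScheme(r=1, n_ky=4, n_frames=4, training_rows=0), 4)
    assert all(len(s) == 1 for s in sets)
    assert len(sets) == 16


def test_alias_sets_r2_pairs():
    sets = alias_sets(SamplingScheme(r=2, n_ky=4, n_frames=4, training_rows=0), 4)
    pair = [s for s in sets if (0, 0) in s][0]
    assert set(pair) == {(0, 0), (2, 2)}


@pytest.mark.parametrize("ny,nf,r", [(6, 6, 2), (6, 6, 3), (12, 12, 4)])
def test_alias_sets_match_zero_fill_superposition(ny, nf, r):
    """Zero-filled reconstruction of an x-f delta lands exactly (in magnitude)
    on the delta's predicted alias set and nowhere else."""
    scheme = SamplingScheme(r=r, n_ky=ny, n_frames=nf, training_rows=0)
    mask = make_lattice_mask(scheme)
    sets = alias_sets(scheme, ny)
    rng = np.random.default_rng(1)
    for _ in range(8):
        y0, f0 = int(rng.integers(ny)), int(rng.integers(nf))
        xf = np.zeros((ny, 1, 1, nf), complex)
        xf[y0, 0, 0, f0] = 1.0
        k = image_to_kt(ixf_transform(xf))
        rho = r * xf_transform(kt_to_image(k * mask[:, None, None, :]))
        members = next(s for s in sets if (y0, f0) in s)
        expected = np.zeros((ny, nf))
        for (y, f) in members:
            expected[y, f] = 1.0
        assert np.allclose(np.abs(rho[:, 0, 0, :]), expected, atol=1e-10)


def test_alias_sets_divisibility_enforced():
    with pytest.raises(ValueError):
        alias_sets(SamplingScheme(r=3, n_ky=6, n_frames=4, training_rows=0), 6)


# ------------------------------------------------------------- kt-BLAST

def full_magnitude(kt):
    return np.abs(kt_to_image(kt.samples))


def test_r1_transform_equals_full_reconstruction(small_kt):
    est = KTBlast().fit(extract_training(small_kt, 16))
    out = est.transform(small_kt)
    assert np.allclose(out.values, full_magnitude(small_kt), atol=1e-12)


@pytest.mark.parametrize("r", [2, 3, 4, 6])
def test_static_scene_reconstructed_exactly(static_spec, r):
    stack, _ = generate_phantom(static_spec)
    kt = corrupt_kspace(stack, 0.0, 0)
    est = KTBlast().fit(extract_training(kt, 16))
    scheme = SamplingScheme(r=r, n_ky=kt.n_ky, n_frames=kt.n_frames)
    out = est.transform(apply_mask(kt, make_lattice_mask(scheme)))
    ref = full_magnitude(kt)
    assert np.abs(out.values - ref).max() <= 1e-8 * ref.max()


def test_dominant_training_member_takes_whole_alias_value():
    """1-D toy (n_y=6, n_frames=6, r=3): when each alias set has a single
    dominant member in the training prior, the filter must assign the whole
    aliased value to it, reproducing the truth exactly."""
    ny = nf = 6
    rng = np.random.default_rng(5)
    truth_xf = np.zeros((ny, 1, 1, nf), complex)
    truth_xf[:, 0, 0, 0] = rng.normal(size=ny) + 1j * rng.normal(size=ny)
    truth_xf[:, 0, 0, 1] = rng.normal(size=ny) + 1j * rng.normal(size=ny)
    k = image_to_kt(ixf_transform(truth_xf))
    scheme = SamplingScheme(r=3, n_ky=ny, n_frames=nf, training_rows=0)
    und = KtData(samples=k * make_lattice_mask(scheme)[:, None, None, :],
                 mask=make_lattice_mask(scheme), voxel_size_mm=(1, 1, 1),
                 frame_duration_ms=1.0)
    m2 = np.zeros((ny, 1, 1, nf))
    m2[..., 0] = 1.0
    m2[..., 1] = 1.0  # alias partners of f in {0,1} sit at f in {2..5}
    est = KTBlast(psi=0.0, baseline_mode="none")
    est.training_ = TrainingEstimate(m_squared=m2, training_rows=0)
    est.n_frames_ = nf
    out = est.transform(und)
    expected = np.abs(ixf_transform(truth_xf))
    assert np.allclose(out.values, expected, atol=1e-10)


def test_reconstruction_linear_in_amplitude(noisy_kt, small_kt):
    scheme = SamplingScheme(r=3, n_ky=noisy_kt.n_ky, n_frames=noisy_kt.n_frames)
    mask = make_lattice_mask(scheme)
    est = KTBlast(psi=1e-4).fit(extract_training(noisy_kt, 16))
    und = apply_mask(noisy_kt, mask)
    scaled = KtData(samples=3.0 * und.samples, mask=und.mask,
                    voxel_size_mm=und.voxel_size_mm,
                    frame_duration_ms=und.frame_duration_ms)
    a = est.transform(und)
    b = est.transform(scaled)
    assert np.allclose(b.values, 3.0 * a.values, rtol=1e-10, atol=1e-12)


def test_zero_psi_with_empty_alias_set_raises():
    kt = KtData(samples=np.zeros((12, 12, 1, 12), complex),
                mask=np.ones((12, 12), bool), voxel_size_mm=(1, 1, 1),
                frame_duration_ms=1.0)
    est = KTBlast(psi=0.0).fit(extract_training(kt, 4))
    scheme = SamplingScheme(r=3, n_ky=12, n_frames=12, training_rows=4)
    und = apply_mask(kt, make_lattice_mask(scheme))
    with pytest.raises(ValueError, match="psi"):
        est.transform(und)


def test_positive_psi_zeroes_signal_free_regions():
    kt = KtData(samples=np.zeros((12, 12, 1, 12), complex),
                mask=np.ones((12, 12), bool), voxel_size_mm=(1, 1, 1),
                frame_duration_ms=1.0)
    est = KTBlast(psi=1e-3).fit(extract_training(kt, 4))
    scheme = SamplingScheme(r=3, n_ky=12, n_frames=12, training_rows=4)
    out = est.transform(apply_mask(kt, make_lattice_mask(scheme)))
    assert not out.values.any()


def test_error_grows_with_acceleration_and_blur_reduces_motion():
    """On the moving phantom the reconstruction error is non-decreasing in r,
    and the shrinkage filter can only damp frame-to-frame variance."""
    from ktblast import RoiSpec, reconstruction_error, CineStack
    spec = PhantomSpec(noise_sd=0.0)
    stack, truth = generate_phantom(spec)
    kt = corrupt_kspace(stack, 0.0, 0)
    full = CineStack(values=full_magnitude(kt), voxel_size_mm=kt.voxel_size_mm,
                     frame_duration_ms=kt.frame_duration_ms)
    est = KTBlast().fit(extract_training(kt, 16))
    roi = RoiSpec(center_px=truth.center_px)
    eps = []
    var_full = stack_temporal_variance(full.values)
    for r in (2, 3, 4, 6):
        scheme = SamplingScheme(r=r, n_ky=kt.n_ky, n_frames=kt.n_frames)
        out = est.transform(apply_mask(kt, make_lattice_mask(scheme)))
        eps.append(reconstruction_error(full, out, roi).epsilon)
        assert stack_temporal_variance(out.values) <= var_full * (1 + 1e-9)
    assert all(b > a for a, b in zip(eps, eps[1:]))


def stack_temporal_variance(values):
    return float(values.var(axis=3).sum())


def test_transform_requires_fit(small_kt):
    with pytest.raises(RuntimeError):
        KTBlast().transform(small_kt)


def test_get_params_round_trip():
    est = KTBlast(psi=0.5, baseline_mode="none")
    params = est.get_params()
    clone = KTBlast(**params)
    assert clone.get_params() == params
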