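"""Radon and masked-Fourier operators, adjoints, and noise models."""

import numpy as np
import pytest

from eqrecon import (
    CTNoiseModel,
    MRISampling,
    RadonGeometry,
    adjoint_residual,
    calibrate_mu,
    discrepancy_gradient,
    fbp,
    generate_cartesian_mask,
    mri_adjoint,
    mri_apply,
    mri_operator,
    operator_norm,
    radon_adjoint,
    radon_apply,
    radon_operator,
    simulate_ct,
    simulate_mri,
)


@pytest.fixture(scope="module")
def disk64():
    n, r = 64, 20
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2.0
    d = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    return np.clip((r - d) / 1.5 + 0.5, 0.0, 1.0), r


@pytest.fixture(scope="module")
def geom16():
    return RadonGeometry(16, n_angles=12)


class TestRadon:
    def test_zero_image_gives_zero_sinogram(self, geom16):
        assert np.all(radon_apply(np.zeros((16, 16)), geom16) == 0.0)

    def test_linearity(self, geom16, rng):
        u1, u2 = rng.normal(size=(2, 16, 16))
        np.testing.assert_allclose(
            radon_apply(u1 + u2, geom16),
            radon_apply(u1, geom16) + radon_apply(u2, geom16),
            atol=1e-10,
        )

    def test_disk_projections_match_chord_length(self, disk64):
        # dense numerical line-integration oracle: chord length 2*sqrt(r^2-s^2)
        disk, r = disk64
        geom = RadonGeometry(64, n_angles=8)
        sino = radon_apply(disk, geom)
        offsets = (np.arange(geom.n_detectors) - (geom.n_detectors - 1) / 2.0)
        interior = np.abs(offsets) < r - 3
        expected = 2.0 * np.sqrt(np.maximum(r**2 - offsets**2, 0.0))
        for ia in range(geom.n_angles):
            np.testing.assert_allclose(
                sino[ia][interior], expected[interior], rtol=0.05, atol=0.5
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_adjoint_dot_product_identity(self, geom16, seed):
        assert adjoint_residual(radon_operator(geom16), seed) <= 1e-6

    def test_adjoint_of_zero_is_zero(self, geom16):
        assert np.all(radon_adjoint(np.zeros(geom16.sinogram_shape), geom16) == 0.0)

    def test_single_ray_backprojects_to_streak(self):
        geom = RadonGeometry(32, n_angles=4)
        sino = np.zeros(geom.sinogram_shape)
        sino[0, geom.n_detectors // 2] = 1.0  # central vertical-offset ray, angle 0
        img = radon_adjoint(sino, geom)
        # angle 0: the ray runs along the x axis through the centre -> a
        # horizontal streak; mass concentrated on the central rows
        central = np.abs(img[15:17, :]).sum()
        assert central / np.abs(img).sum() > 0.9

    def test_fbp_recovers_smooth_disk(self, disk64):
        disk, _ = disk64
        geom = RadonGeometry(64, n_angles=360)
        rec = fbp(radon_apply(disk, geom), geom)
        rel = np.linalg.norm(rec - disk) / np.linalg.norm(disk)
        assert rel <= 0.05

    def test_fbp_linearity_and_zero(self, geom16, rng):
        assert np.all(fbp(np.zeros(geom16.sinogram_shape), geom16) == 0.0)
        s1, s2 = rng.normal(size=(2,) + geom16.sinogram_shape)
        np.testing.assert_allclose(
            fbp(s1 + s2, geom16), fbp(s1, geom16) + fbp(s2, geom16), atol=1e-10
        )


class TestCTNoise:
    def test_noiseless_measurement_equals_line_integrals(self, disk64):
        disk, _ = disk64
        geom = RadonGeometry(64, n_angles=10)
        y = simulate_ct(disk, geom, CTNoiseModel(seed=0), noiseless=True)
        np.testing.assert_allclose(y, radon_apply(disk, geom), atol=1e-10)

    def test_zero_counts_hit_the_clip(self):
        geom = RadonGeometry(16, n_angles=4)
        u = np.ones((16, 16)) * 100.0  # opaque object: counts are all zero
        noise = CTNoiseModel(mu=1.0, eta=1e-8, seed=0)
        y = simulate_ct(u, geom, noise)
        sino = radon_apply(u, geom)
        hit = sino > 50.0
        np.testing.assert_allclose(y[hit], -np.log(1e-8), atol=1e-10)

    def test_mean_posts_log_measurement_near_noiseless(self, rng):
        # Monte-Carlo oracle on a small phantom
        geom = RadonGeometry(16, n_angles=4)
        u = np.zeros((16, 16))
        u[5:11, 5:11] = 1.0
        mu = calibrate_mu(u, geom)
        draws = np.stack(
            [
                simulate_ct(u, geom, CTNoiseModel(mu=mu, seed=s))
                for s in range(400)
            ]
        )
        noiseless = radon_apply(u, geom)
        sem = draws.std(axis=0) / np.sqrt(draws.shape[0])
        bright = noiseless < noiseless.max() / 2  # avoid the clipped low-count tail
        diff = np.abs(draws.mean(axis=0) - noiseless)
        assert np.all(diff[bright] <= 3 * sem[bright] + 5e-3)

    def test_calibrated_mu_attenuates_to_target(self, disk64):
        disk, _ = disk64
        geom = RadonGeometry(64, n_angles=10)
        mu = calibrate_mu(disk, geom, target=5.0)
        assert mu * radon_apply(disk, geom).max() == pytest.approx(5.0)


class TestCartesianMask:
    def test_full_fraction_gives_all_ones(self):
        samp = generate_cartesian_mask((16, 16), 1.0, 0.1, seed=0)
        assert samp.sampled_fraction == 1.0

    def test_sampled_fraction_matches_target_within_one_column(self):
        samp = generate_cartesian_mask((64, 64), 0.203, 0.08, seed=5)
        assert abs(samp.mask[0].sum() - round(0.203 * 64)) <= 1

    def test_deterministic_given_seed(self):
        m1 = generate_cartesian_mask((32, 32), 0.3, 0.1, seed=9)
        m2 = generate_cartesian_mask((32, 32), 0.3, 0.1, seed=9)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_mask_is_union_of_columns(self):
        samp = generate_cartesian_mask((32, 32), 0.25, 0.1, seed=1)
        cols = samp.mask[0]
        np.testing.assert_array_equal(samp.mask, np.broadcast_to(cols, (32, 32)))

    def test_target_below_center_rejected(self):
        with pytest.raises(ValueError):
            generate_cartesian_mask((32, 32), 0.05, 0.2, seed=0)

    def test_non_column_mask_rejected(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            MRISampling(mask=mask)


class TestMaskedFourier:
    def test_full_mask_roundtrip_is_identity(self, rng):
        samp = MRISampling(mask=np.ones((16, 16), dtype=bool))
        u = rng.normal(size=(2, 16, 16))
        np.testing.assert_allclose(mri_adjoint(mri_apply(u, samp), samp), u, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_adjoint_identity_tight(self, seed):
        samp = generate_cartesian_mask((16, 16), 0.4, 0.1, seed=3)
        assert adjoint_residual(mri_operator(samp), seed) <= 1e-10

    def test_nonzero_singular_values_all_one(self):
        # the masked unitary DFT keeps rows of a unitary matrix
        samp = generate_cartesian_mask((8, 8), 0.5, 0.25, seed=0)
        mat = np.zeros((64, 64), dtype=complex)
        for i in range(64):
            e = np.zeros(64)
            e[i] = 1.0
            k = np.fft.fftshift(np.fft.fft2(e.reshape(8, 8), norm="ortho"))
            mat[:, i] = (k * samp.mask).ravel()
        svals = np.linalg.svd(mat, compute_uv=False)
        nonzero = svals[svals > 1e-8]
        assert len(nonzero) == samp.mask.sum()
        np.testing.assert_allclose(nonzero, 1.0, atol=1e-10)

    def test_partial_isometry_on_sampled_lines(self, rng):
        samp = generate_cartesian_mask((16, 16), 0.4, 0.1, seed=2)
        y = rng.normal(size=(2, 16, 16)) * samp.mask
        op = mri_operator(samp)
        np.testing.assert_allclose(op.apply(op.adjoint(y)), y, atol=1e-12)

    def test_noise_only_on_sampled_lines(self):
        samp = generate_cartesian_mask((16, 16), 0.4, 0.1, seed=2)
        noisy = MRISampling(mask=samp.mask, noise_sd=0.5, seed=7)
        y = simulate_mri(np.zeros((2, 16, 16)), noisy)
        assert np.all(y[:, :, ~samp.mask[0]] == 0.0)
        assert y[:, :, samp.mask[0]].std() > 0.3


class TestDiscrepancyGradient:
    def test_zero_at_consistent_data(self, geom16, rng):
        op = radon_operator(geom16)
        u = rng.normal(size=(16, 16))
        y = op.apply(u)
        np.testing.assert_allclose(discrepancy_gradient(u, y, op), 0.0, atol=1e-10)

    @pytest.mark.parametrize("modality", ["ct", "mri"])
    def test_matches_central_differences(self, modality, rng):
        if modality == "ct":
            op = radon_operator(RadonGeometry(12, n_angles=6))
        else:
            op = mri_operator(generate_cartesian_mask((12, 12), 0.4, 0.1, seed=0))
        u = rng.normal(size=op.in_shape)
        y = rng.normal(size=op.out_shape)
        d = rng.normal(size=op.in_shape)
        g = discrepancy_gradient(u, y, op)

        def energy(v):
            r = op.apply(v) - y
            return 0.5 * float(np.sum(r * r))

        eps = 1e-5
        fd = (energy(u + eps * d) - energy(u - eps * d)) / (2 * eps)
        assert fd == pytest.approx(float(np.sum(g * d)), rel=1e-4)

    def test_linear_in_inputs(self, geom16, rng):
        op = radon_operator(geom16)
        u, y = rng.normal(size=(16, 16)), rng.normal(size=geom16.sinogram_shape)
        np.testing.assert_allclose(
            discrepancy_gradient(2.0 * u, 2.0 * y, op),
            2.0 * discrepancy_gradient(u, y, op),
            atol=1e-10,
        )

    def test_operator_norm_matches_dense_svd(self, geom16):
        op = radon_operator(geom16)
        dense = geom16.matrix().toarray()
        top = np.linalg.svd(dense, compute_uv=False)[0]
        assert operator_norm(op) == pytest.approx(top, rel=1e-3)
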