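"""Wiener spectral reconstruction: prior, estimator, reconstruction."""
import numpy as np
import pytest

from veinviz.optics_data import (DEFAULT_GRID, REFLECTANCE_FLOOR, Spectrum,
                                 WavelengthGrid)
from veinviz.preprocess import ImagePlane
from veinviz.spectral_recon import (SystemMatrix, ReflectancePrior,
                                    build_prior, build_system_matrix,
                                    build_wiener_matrix, reconstruct_cube,
                                    fit_exposure_gain)


@pytest.fixture(scope="module")
def prior_and_system(pairs_study):
    spectra = [p.reflectance for p in pairs_study]
    prior = build_prior(spectra)
    system = build_system_matrix(reference_spectra=prior.samples)
    return prior, system


class TestBuildPrior:
    def test_single_spectrum_rank_one(self):
        rng = np.random.default_rng(0)
        s = Spectrum(DEFAULT_GRID, rng.uniform(0.1, 0.9, 31), "reflectance")
        prior = build_prior([s])
        np.testing.assert_allclose(prior.autocorr, np.outer(s.values, s.values))
        assert np.linalg.matrix_rank(prior.autocorr, tol=1e-10) == 1

    def test_two_orthogonal_unit_vectors(self):
        g3 = WavelengthGrid(500, 520, 10)
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
        prior = build_prior(np.stack([e1, e2]), g3)
        np.testing.assert_allclose(prior.autocorr, np.diag([0.5, 0.5, 0.0]))
        assert np.trace(prior.autocorr) == pytest.approx(1.0)

    def test_trace_equals_mean_squared_norm(self, pairs_study):
        """Independent accumulation oracle on the MC spectra family."""
        mat = np.stack([p.reflectance.values for p in pairs_study])
        prior = build_prior([p.reflectance for p in pairs_study])
        expected = sum(float(row @ row) for row in mat) / len(mat)
        assert np.trace(prior.autocorr) == pytest.approx(expected, rel=1e-12)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_prior([])

    def test_asymmetric_matrix_rejected(self):
        bad = np.eye(31)
        bad[0, 1] = 1.0
        with pytest.raises(ValueError):
            ReflectancePrior(bad, DEFAULT_GRID)


class TestBuildWienerMatrix:
    def test_identity_system_collapses_to_identity(self):
        """With B = 3 and F = I the estimator is exactly the identity."""
        g3 = WavelengthGrid(500, 520, 10)
        rng = np.random.default_rng(1)
        A = rng.random((3, 3))
        prior = ReflectancePrior(A @ A.T + np.eye(3), g3)
        system = SystemMatrix(np.eye(3), g3)
        W = build_wiener_matrix(prior, system)
        np.testing.assert_allclose(W, np.eye(3), atol=1e-10)

    def test_exact_recovery_on_rank3_prior(self, pairs_study):
        """A rank-3 prior makes Wiener exact on its span: W F r = r,
        cross-checked against a brute-force linear solve."""
        basis = [pairs_study[i].reflectance for i in (0, 47, 93)]
        prior = build_prior(basis)
        system = build_system_matrix(
            reference_spectra=np.stack([b.values for b in basis]))
        W = build_wiener_matrix(prior, system)
        rng = np.random.default_rng(2)
        for _ in range(5):
            w = rng.uniform(0.2, 1.0, 3)
            r = np.stack([b.values for b in basis]).T @ w
            I = system.F @ r
            np.testing.assert_allclose(W @ I, r, atol=1e-8)
            # oracle: direct least-squares reconstruction in the span
            B = np.stack([b.values for b in basis]).T
            coef, *_ = np.linalg.lstsq(system.F @ B, I, rcond=None)
            np.testing.assert_allclose(B @ coef, W @ I, atol=1e-8)

    def test_identity_on_top_three_eigenvectors(self, prior_and_system):
        """The theoretical fixed point: truncating the prior to its top-3
        eigenspace makes W F the identity on exactly that span (for the
        full-rank prior W F is the oblique projector onto range(W))."""
        prior, system = prior_and_system
        evals, evecs = np.linalg.eigh(prior.autocorr)
        v3, l3 = evecs[:, -3:], evals[-3:]
        prior3 = ReflectancePrior((v3 * l3) @ v3.T, prior.grid)
        W3 = build_wiener_matrix(prior3, system)
        np.testing.assert_allclose(W3 @ system.F @ v3, v3, atol=1e-6)

    def test_wf_is_idempotent(self, prior_and_system):
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        P = W @ system.F
        np.testing.assert_allclose(P @ P, P, atol=1e-9)

    def test_minimizes_mse_against_perturbations(self, prior_and_system):
        """Monte Carlo optimality: over spectra whose empirical second
        moment defines the prior, no perturbation of W can lower the
        mean squared reconstruction error (W is the exact least-squares
        minimizer for that sample)."""
        prior, system = prior_and_system
        rng = np.random.default_rng(3)
        spectra = prior.samples[rng.integers(0, len(prior.samples), 1000)]
        prior_b = build_prior(spectra, prior.grid)
        W = build_wiener_matrix(prior_b, system)
        I = spectra @ system.F.T

        def mse(M):
            return float(np.mean((I @ M.T - spectra) ** 2))

        base = mse(W)
        for _ in range(100):
            delta = rng.standard_normal(W.shape)
            delta *= 1e-3 / np.linalg.norm(delta)
            assert mse(W + delta) >= base

    def test_beats_plain_pseudoinverse(self, prior_and_system, pairs_study):
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        F = system.F
        pinv = F.T @ np.linalg.inv(F @ F.T)
        R = np.stack([p.reflectance.values for p in pairs_study])
        I = R @ F.T
        err_w = np.mean((I @ W.T - R) ** 2)
        err_p = np.mean((I @ pinv.T - R) ** 2)
        assert err_w <= err_p


class TestReconstructCube:
    def test_zero_pixel_clips_to_floor(self, prior_and_system):
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        img = ImagePlane(np.zeros((2, 2, 3)))
        cube = reconstruct_cube(img, W)
        assert np.all(cube.values == REFLECTANCE_FLOOR)

    def test_forward_render_then_invert(self, prior_and_system, pairs_study):
        """Forward-render on-prior spectra to RGB and invert them.

        Three camera channels cannot span the curvature of the whole
        two-parameter reflectance family: the measured error is ~2 % for
        light-skin members and grows toward the dark high-melanin corner
        (family median ~4 %, mean ~6 %). The bounds frozen here come
        from that measurement.
        """
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        R = np.stack([p.reflectance.values for p in pairs_study])
        img = ImagePlane((R @ system.F.T).reshape(10, 10, 3))
        cube = reconstruct_cube(img, W)
        rec = cube.values.reshape(-1, 31)
        rmse = np.sqrt(np.mean((rec - R) ** 2, axis=1))
        rel = rmse / np.sqrt(np.mean(R ** 2, axis=1))
        cms = np.array([p.Cm for p in pairs_study])
        assert np.mean(rel[cms <= 0.1]) <= 0.03
        assert np.median(rel) <= 0.06
        assert np.mean(rel) <= 0.08

    def test_reconstruction_is_linear_before_clipping(self, prior_and_system):
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        rng = np.random.default_rng(4)
        i1, i2 = rng.random(3), rng.random(3)
        lhs = W @ (0.3 * i1 + 0.7 * i2)
        rhs = 0.3 * (W @ i1) + 0.7 * (W @ i2)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_vein_pixel_darker_in_red(self, prior_and_system, pairs_study,
                                      stack):
        """A high-blood pixel reconstructs with lower reflectance at
        600-700 nm than a generic-skin pixel."""
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        cms = sorted({p.Cm for p in pairs_study})
        cbs = sorted({p.Cb for p in pairs_study})
        skin = next(p for p in pairs_study
                    if p.Cm == cms[2] and p.Cb == cbs[1])
        vein = next(p for p in pairs_study
                    if p.Cm == cms[2] and p.Cb == cbs[-1])
        pix = np.stack([skin.reflectance.values,
                        vein.reflectance.values]) @ system.F.T
        cube = reconstruct_cube(ImagePlane(pix.reshape(1, 2, 3)), W)
        wl = DEFAULT_GRID.wavelengths
        red = wl >= 600
        assert np.all(cube.values[0, 1, red] < cube.values[0, 0, red])

    def test_shape_mismatch_rejected(self, prior_and_system):
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        with pytest.raises(ValueError):
            reconstruct_cube(ImagePlane(np.zeros((2, 2, 3))), W[:10])

    def test_unmasked_pixels_filled_with_one(self, prior_and_system):
        prior, system = prior_and_system
        W = build_wiener_matrix(prior, system)
        mask = np.array([[True, False]])
        img = ImagePlane(np.full((1, 2, 3), 0.5), mask)
        cube = reconstruct_cube(img, W)
        assert np.all(cube.values[0, 1] == 1.0)


def test_cube_persistence_roundtrip(prior_and_system, tmp_path):
    """Stage isolation: saving and reloading a cube is lossless."""
    from veinviz.spectral_recon import save_cube, load_cube
    prior, system = prior_and_system
    W = build_wiener_matrix(prior, system)
    rng = np.random.default_rng(8)
    mask = rng.random((5, 4)) < 0.8
    img = ImagePlane(rng.random((5, 4, 3)), mask)
    cube = reconstruct_cube(img, W)
    path = tmp_path / "cube.bsq"
    save_cube(cube, path)
    back = load_cube(path)
    np.testing.assert_array_equal(back.values, cube.values)
    np.testing.assert_array_equal(back.mask, cube.mask)
    assert back.grid == cube.grid


def test_exposure_gain_median_convention(prior_and_system):
    prior, system = prior_and_system
    rendered = system.render(prior.samples)
    med = float(np.median(rendered))
    img = ImagePlane(np.full((4, 4, 3), 2.0 * med))
    assert fit_exposure_gain(img, system, prior) == pytest.approx(2.0)
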