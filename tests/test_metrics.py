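"""Density compensation, PSF/FWHM, pseudo-replica SNR and SAPR."""

import numpy as np
import pytest

from conetraj import (
    NUFFT3,
    SAPRInputs,
    density_compensation,
    effective_snr,
    fwhm,
    golden_axis,
    psf,
    sapr,
)
from conetraj.metrics import MetricUndefinedError

from conftest import cartesian_coords


def radial_samples(n_spokes: int, n_per: int, k_max: float, seed: int = 0) -> np.ndarray:
    axes = golden_axis(np.arange(n_spokes))
    radii = np.linspace(0, k_max, n_per + 1)[1:]
    return (axes[:, None, :] * radii[None, :, None]).reshape(-1, 3)


def gaussian_volume(n: int, sigma: float) -> np.ndarray:
    x = np.arange(n) - n // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    return np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * sigma ** 2))


class TestDensityCompensation:
    def test_cartesian_weights_constant(self):
        n = 12
        w = density_compensation(cartesian_coords(n), n)
        assert w.std() / w.mean() < 0.01

    def test_duplicating_samples_halves_weights(self):
        n = 12
        k = cartesian_coords(n)
        w1 = density_compensation(k, n)
        w2 = density_compensation(np.vstack([k, k]), n)
        assert np.allclose(w2[: len(k)], 0.5 * w1, rtol=0.01)

    def test_radial_weights_follow_quadratic_density(self):
        """3D radial sampling density falls as 1/|k|^2, so the mean weight per
        radial shell rises as |k|^2 (interior shells; the outermost shell sits
        on the sampling boundary where the analytic density argument fails)."""
        k_max = 0.45
        n_spokes, n_per = 2000, 32
        samples = radial_samples(n_spokes, n_per, k_max)
        w = density_compensation(samples, 32, 1.0).reshape(n_spokes, n_per)
        radii = np.linspace(0, k_max, n_per + 1)[1:]
        shell_mean = w.mean(axis=0)
        sel = (radii > 0.1 * k_max) & (radii <= 0.95 * k_max)
        coef = np.polyfit(radii[sel] ** 2, shell_mean[sel], 1)
        fit = np.polyval(coef, radii[sel] ** 2)
        ss_res = np.sum((shell_mean[sel] - fit) ** 2)
        ss_tot = np.sum((shell_mean[sel] - shell_mean[sel].mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.99

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            density_compensation(np.zeros((0, 3)), 16)


class TestPSF:
    def test_cartesian_psf_is_delta(self):
        n = 12
        k = cartesian_coords(n)
        w = density_compensation(k, n)
        vol = psf(k, w, n)
        flat = np.sort(vol.ravel())
        assert flat[-1] == 1.0
        assert flat[-2] < 1e-6

    def test_hann_never_decreases_fwhm(self):
        k_max = 0.45
        samples = radial_samples(300, 24, k_max)
        op = NUFFT3(samples, 24, 1.0)
        w = density_compensation(samples, 24, nufft=op)
        plain = fwhm(psf(samples, w, 24, nufft=op))[0]
        windowed = fwhm(psf(samples, w, 24, hann=True, k_max=k_max, nufft=op))[0]
        assert np.all(windowed >= plain - 1e-9)

    def test_cartesian_cut_matches_dirichlet_kernel(self):
        """PSF of N^3 Cartesian sampling on a 2x finer grid is the periodic
        Dirichlet kernel along each axis."""
        n = 8
        k = cartesian_coords(n)                   # spacing 1/n
        vol = psf(k, np.ones(len(k)), 2 * n, 0.5, nufft=NUFFT3(k, 2 * n, 0.5, width=8))
        cut = vol[:, n, n]
        x = (np.arange(2 * n) - n) * 0.5
        with np.errstate(invalid="ignore"):
            dirichlet = np.abs(np.sin(np.pi * n * x / n) / (n * np.sin(np.pi * x / n)))
        dirichlet[n] = 1.0
        assert np.max(np.abs(cut - dirichlet)) < 1e-6


class TestFWHM:
    @pytest.mark.parametrize("sigma", [1.5, 2.5])
    def test_gaussian_closed_form(self, sigma):
        vol = gaussian_volume(48, sigma)
        mm, vox = fwhm(vol, 1.0)
        assert np.allclose(vox, 2.3548 * sigma, rtol=0.01)
        assert np.allclose(mm, vox)

    def test_doubling_kmax_halves_fwhm(self):
        """Fourier scaling: stretching the same sampling geometry to twice the
        k radius (with the grid refined to match) halves the FWHM in mm."""
        n = 32
        fw = []
        for k_max, voxel in ((0.2, 1.0), (0.4, 0.5)):
            samples = radial_samples(500, 24, k_max)
            w = density_compensation(samples, n, voxel)
            fw.append(fwhm(psf(samples, w, n, voxel), voxel)[0].mean())
        assert fw[0] / fw[1] == pytest.approx(2.0, rel=0.05)

    def test_isotropic_psf_equal_widths(self):
        mm, _ = fwhm(gaussian_volume(40, 2.0), 1.0)
        assert np.ptp(mm) < 0.01 * mm.mean()

    def test_boundary_peak_rejected(self):
        vol = np.zeros((16, 16, 16))
        vol[0, 8, 8] = 1.0
        with pytest.raises(MetricUndefinedError):
            fwhm(vol)

    def test_nondecaying_profile_rejected(self):
        with pytest.raises(MetricUndefinedError):
            fwhm(np.ones((8, 8, 8)) + 1e-3 * gaussian_volume(8, 20.0))


@pytest.fixture(scope="module")
def snr_setup():
    n, k_max = 20, 0.45
    samples = radial_samples(250, 20, k_max, seed=0)
    op = NUFFT3(samples, n, 1.0)
    w = density_compensation(samples, n, nufft=op)
    vol = gaussian_volume(n, 2.0)
    mask = vol > 0.3
    data = op.forward(vol.astype(complex))
    return op, samples, w, mask, data


class TestEffectiveSNR:
    def test_doubling_sigma_halves_snr(self, snr_setup):
        op, samples, w, mask, data = snr_setup
        sigma = 0.02 * np.abs(data).max()
        s1 = effective_snr(data, samples, w, mask, sigma, n_replicas=64, seed=1, nufft=op)
        s2 = effective_snr(data, samples, w, mask, 2 * sigma, n_replicas=64, seed=2, nufft=op)
        assert s1 / s2 == pytest.approx(2.0, rel=0.15)

    def test_deterministic_given_seed(self, snr_setup):
        op, samples, w, mask, data = snr_setup
        sigma = 0.05 * np.abs(data).max()
        a = effective_snr(data, samples, w, mask, sigma, n_replicas=8, seed=3, nufft=op)
        b = effective_snr(data, samples, w, mask, sigma, n_replicas=8, seed=3, nufft=op)
        assert a == b

    def test_noise_propagation_matches_linear_operator(self, snr_setup):
        """For the weighted adjoint, per-voxel replica std of pure noise is
        sigma * sqrt(sum w^2) propagated through unit-magnitude exponentials."""
        op, samples, w, mask, data = snr_setup
        sigma = 1.0
        rng = np.random.default_rng(4)
        n_rep = 96
        stds = np.zeros(np.count_nonzero(mask))
        for _ in range(n_rep):
            noise = sigma * (rng.standard_normal(len(w))
                             + 1j * rng.standard_normal(len(w))) / np.sqrt(2)
            rec = op.adjoint(w * noise)[mask]
            stds += np.abs(rec) ** 2
        measured = np.mean(np.sqrt(stds / n_rep))
        predicted = sigma * np.sqrt(np.sum(w ** 2))
        assert measured == pytest.approx(predicted, rel=0.05)

    def test_zero_foreground_rejected(self, snr_setup):
        op, samples, w, mask, data = snr_setup
        with pytest.raises(ValueError):
            effective_snr(data, samples, w, np.zeros_like(mask), 1.0, nufft=op)


class TestSAPR:
    def test_hand_example(self):
        img = np.array([[[2.0]], [[1.0]]])
        m_f = np.array([[[True]], [[False]]])
        assert sapr(SAPRInputs(img, m_f, ~m_f)) == pytest.approx(4.0)

    def test_scale_invariant(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 8))
        m_f = np.zeros_like(img, bool)
        m_f[2:5, 2:5, 2:5] = True
        a = sapr(SAPRInputs(img, m_f, ~m_f))
        b = sapr(SAPRInputs(7.3 * img, m_f, ~m_f))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_background_flagged_infinite(self):
        img = np.zeros((4, 4, 4))
        img[1, 1, 1] = 3.0
        m_f = img > 0
        with pytest.warns(UserWarning):
            assert sapr(SAPRInputs(img, m_f, ~m_f)) == np.inf

    def test_overlapping_masks_rejected(self):
        img = np.ones((4, 4, 4))
        m = np.ones_like(img, bool)
        with pytest.raises(ValueError):
            SAPRInputs(img, m, m)


class TestRotationInvariance:
    def test_fwhm_invariant_under_rigid_rotation(self):
        """Rotating the whole trajectory leaves the PSF width unchanged (2%)."""
        from scipy.spatial.transform import Rotation

        n, k_max = 28, 0.45
        samples = radial_samples(400, 24, k_max)
        rot = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        fw = []
        for s in (samples, samples @ rot.T):
            w = density_compensation(s, n, 1.0)
            fw.append(fwhm(psf(s, w, n, 1.0))[0].mean())
        assert fw[1] == pytest.approx(fw[0], rel=0.02)
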