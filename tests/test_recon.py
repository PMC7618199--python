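"""Adjoint and locally-low-rank reconstruction."""

import numpy as np
import pytest

from conetraj import (
    CoilModel,
    DigitalPhantom,
    LLRConfig,
    adjoint_recon,
    compress_coils,
    dual_reconstruct,
    llr_recon,
    make_coil_model,
    make_perfusion_phantom,
    make_vessel_phantom,
    simulate_acquisition,
    subtract_label_control,
)
from conetraj.recon import ReconProblem
from conetraj import ConeParams, ProtocolParams, base_cone, build_schedule

from conftest import cartesian_coords


def cg_normal_equations(problem: ReconProblem, n_iter: int = 60, rtol: float = 1e-12):
    """Conjugate gradient on A^H A x = A^H y from zero init (min-norm LS)."""
    nf = problem.n_frames

    def aha(x):
        return np.stack([problem.AH(f, problem.A(f, x[f])) for f in range(nf)])

    b = np.stack([problem.AH(f, problem.data[f]) for f in range(nf)])
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    b2 = np.vdot(b, b).real
    for _ in range(n_iter):
        ap = aha(p)
        alpha = rs / np.vdot(p, ap).real
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        if rs_new < rtol ** 2 * b2:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


@pytest.fixture(scope="module")
def small_problem():
    """16^3, 3 frames, 3 coils, fully-sampled Cartesian, mild noise."""
    n = 16
    kc = cartesian_coords(n)
    coil = make_coil_model(n, 3, seed=2)
    vessel = make_vessel_phantom(32, 1.0, seed=1)
    data = []
    for f in range(3):
        vol = vessel.volume[:n, :n, :n] * (0.5 + 0.25 * f)
        ph = DigitalPhantom(vol, 1.0, vol != 0, "vessel")
        data.append(simulate_acquisition(ph, coil, kc, noise_sigma=0.01, seed=f))
    return ReconProblem(data, [kc] * 3, coil.sensitivities, 1.0)


class TestAdjointRecon:
    def test_cartesian_single_coil_recovers_phantom(self):
        n = 24
        ph = make_perfusion_phantom(n, 1.0, seed=1)
        sens = np.ones((1, n, n, n), complex)
        kc = cartesian_coords(n)
        data = simulate_acquisition(ph, CoilModel(sens), kc)
        rec = adjoint_recon(ReconProblem([data], [kc], sens, 1.0))
        err = np.linalg.norm(np.abs(rec[0]) - ph.volume) / np.linalg.norm(ph.volume)
        assert err < 1e-3

    def test_uniform_coils_equal_plain_average(self):
        n = 16
        kc = cartesian_coords(n)
        rng = np.random.default_rng(0)
        y = rng.standard_normal((3, len(kc))) + 1j * rng.standard_normal((3, len(kc)))
        sens = np.ones((3, n, n, n), complex)
        prob = ReconProblem([y], [kc], sens, 1.0)
        rec = adjoint_recon(prob)[0]
        from conetraj import density_compensation

        w = density_compensation(kc, n, nufft=prob.nuffts[0])
        per_coil = np.stack([prob.nuffts[0].adjoint(w * y[c]) for c in range(3)])
        assert np.allclose(rec, per_coil.mean(axis=0), atol=1e-10)

    def test_linear_in_data(self, small_problem):
        p = small_problem
        w = [np.ones(c.shape[0]) for c in p.coords]
        rec1 = adjoint_recon(p, weights=w)
        doubled = ReconProblem([2.0 * d for d in p.data], p.coords, p.sens, 1.0)
        rec2 = adjoint_recon(doubled, weights=w)
        assert np.allclose(rec2, 2.0 * rec1, rtol=1e-10)


class TestLLR:
    def test_lambda_zero_matches_cg(self, small_problem):
        res = llr_recon(small_problem,
                        LLRConfig(lam=0.0, max_iter=60, cycle_spin=False, tol=1e-12))
        x_cg = cg_normal_equations(small_problem)
        err = np.linalg.norm(res.image - x_cg) / np.linalg.norm(x_cg)
        assert err < 1e-3

    def test_objective_monotone_without_cycle_spin(self, small_problem):
        res = llr_recon(small_problem,
                        LLRConfig(lam=0.05, patch=4, max_iter=25, cycle_spin=False))
        obj = res.log["objective"].to_numpy()
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]) + 1e-12)

    def test_identical_frames_agree(self, small_problem):
        p = small_problem
        same = ReconProblem([p.data[0]] * 3, p.coords, p.sens, 1.0)
        img = llr_recon(same, LLRConfig(lam=0.05, patch=4, max_iter=15)).image
        spread = np.max(np.abs(img[0] - img[1])) / max(np.max(np.abs(img[0])), 1e-30)
        assert spread < 1e-4

    def test_huge_lambda_gives_zero(self, small_problem):
        img = llr_recon(small_problem, LLRConfig(lam=1e9, patch=4, max_iter=5)).image
        assert np.linalg.norm(img) == 0.0

    def test_gauge_invariance(self, small_problem):
        """Scaling y and C consistently leaves the lam=0 solution unchanged."""
        p = small_problem
        base = llr_recon(p, LLRConfig(lam=0.0, max_iter=30, cycle_spin=False)).image
        scaled = ReconProblem([3.0 * d for d in p.data], p.coords, 3.0 * p.sens, 1.0)
        other = llr_recon(scaled, LLRConfig(lam=0.0, max_iter=30, cycle_spin=False)).image
        assert np.linalg.norm(other - base) / np.linalg.norm(base) < 1e-6

    def test_deterministic_given_seed(self, small_problem):
        cfg = LLRConfig(lam=0.05, patch=4, max_iter=8, seed=3)
        a = llr_recon(small_problem, cfg).image
        b = llr_recon(small_problem, cfg).image
        assert np.array_equal(a, b)


class TestSubtraction:
    def test_identical_inputs_zero(self):
        x = np.random.default_rng(0).random((2, 4, 4, 4))
        assert np.all(subtract_label_control(x, x) == 0.0)

    def test_difference_supported_on_vessel_mask(self):
        control = np.ones((1, 8, 8, 8), complex)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:4, 2:4, 2:4] = True
        label = control.copy()
        label[0][mask] -= 0.3
        diff = subtract_label_control(control, label)
        assert np.all(diff[0][mask] == pytest.approx(0.3))
        assert np.all(diff[0][~mask] == 0.0)

    def test_linear_in_both_arguments(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal((2, 4, 4, 4)) + 1j * rng.standard_normal((2, 4, 4, 4))
        l = rng.standard_normal((2, 4, 4, 4)) + 1j * rng.standard_normal((2, 4, 4, 4))
        assert np.allclose(
            subtract_label_control(2 * c, 2 * l), 2 * subtract_label_control(c, l)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_label_control(np.zeros((2, 4)), np.zeros((3, 4)))


class TestCompressCoils:
    def test_identity_compression_keeps_all_energy(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 100)) + 1j * rng.standard_normal((4, 100))
        _, _, energy = compress_coils(data, 4)
        assert energy == pytest.approx(1.0, abs=1e-12)

    def test_rank_two_data_compresses_losslessly(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((6, 2)) + 1j * rng.standard_normal((6, 2))
        comps = rng.standard_normal((2, 300)) + 1j * rng.standard_normal((2, 300))
        _, _, energy = compress_coils(basis @ comps, 2)
        assert energy > 0.999

    def test_compression_consistent_with_recon(self):
        """Adjoint recon of compressed data with compressed sensitivities
        equals the uncompressed recon when no energy is discarded."""
        n = 12
        kc = cartesian_coords(n)
        coil = make_coil_model(n, 4, seed=5)
        ph = make_perfusion_phantom(n, 1.0, seed=2)
        data = simulate_acquisition(ph, coil, kc)
        rec_full = adjoint_recon(ReconProblem([data], [kc], coil.sensitivities, 1.0))
        comp, mixing, energy = compress_coils(data, 4)
        sens_c = np.einsum("co,cxyz->oxyz", mixing.conj(), coil.sensitivities)
        rec_comp = adjoint_recon(ReconProblem([comp], [kc], sens_c, 1.0))
        assert energy == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(rec_comp - rec_full) / np.linalg.norm(rec_full) < 1e-6


class TestDualReconstruct:
    @pytest.fixture(scope="class")
    def dual_setup(self):
        prot = ProtocolParams(tr=14.7, train_duration=2116.8, readout_time=10.0)
        sched = build_schedule(prot, n_repeats=2, seed=0)
        cone = ConeParams(theta=30, m=0.5, n=3, A=6.0, k_max=0.5,
                          readout_duration=1.0)
        base_samples = base_cone(cone, 400).points[::8]
        n = 16
        coil = make_coil_model(n, 2, seed=1)
        ph = make_vessel_phantom(32, 1.0, seed=2)
        vol = ph.volume[8:24, 8:24, 8:24]
        phc = DigitalPhantom(vol, 1.0, vol != 0, "vessel")
        data = np.empty((2, sched.n_shots, base_samples.shape[0]), complex)
        for s in range(sched.n_shots):
            coords = base_samples @ sched.rotations[s].T
            data[:, s, :] = simulate_acquisition(phc, coil, coords, seed=s)
        return data, sched, base_samples, coil

    def test_protocol_frame_counts_and_grids(self, dual_setup):
        data, sched, base_samples, coil = dual_setup
        angio, perf = dual_reconstruct(
            data, sched, base_samples, coil.sensitivities, 1.0,
            angio_window=176.4, perf_window=352.8, perf_radius=1.0 / 3.0,
        )
        assert angio.shape[0] == 12
        assert perf.shape[0] == 6
        # perfusion grid is ~3x coarser for a 1/3 k radius
        assert perf.shape[1] == pytest.approx(angio.shape[1] / 3, abs=1)

    def test_identity_configuration_coincides(self, dual_setup):
        data, sched, base_samples, coil = dual_setup
        angio, perf = dual_reconstruct(
            data, sched, base_samples, coil.sensitivities, 1.0,
            angio_window=352.8, perf_window=352.8, perf_radius=1.0,
        )
        assert np.allclose(angio, perf, atol=1e-12)


class TestLLRBeatsAdjointOnDynamics:
    def test_llr_suppresses_background_aliasing(self):
        """On a dynamic series with complementary undersampling, LLR at the
        reference settings (lam 0.1, 5^3 patches) deposits less energy outside
        the true support than the plain adjoint."""
        n, n_frames, k_max = 16, 4, 0.45
        vessel = make_vessel_phantom(32, 1.0, seed=4)
        vol = vessel.volume[8:24, 8:24, 8:24]
        profile = np.array([0.4, 1.0, 0.8, 0.5])
        coil = make_coil_model(n, 2, seed=3)
        rng = np.random.default_rng(0)

        from conetraj import golden_axis

        data, coords = [], []
        n_spokes, n_per = 60, 16
        for f in range(n_frames):
            axes = golden_axis(np.arange(f * n_spokes, (f + 1) * n_spokes))
            radii = np.linspace(0, k_max, n_per + 1)[1:]
            k = (axes[:, None, :] * radii[None, :, None]).reshape(-1, 3)
            ph = DigitalPhantom(profile[f] * vol, 1.0, vol != 0, "vessel")
            data.append(simulate_acquisition(ph, coil, k, noise_sigma=0.005, seed=f))
            coords.append(k)
        problem = ReconProblem(data, coords, coil.sensitivities, 1.0)

        adj = adjoint_recon(problem)
        llr = llr_recon(problem, LLRConfig(lam=0.1, patch=5, max_iter=30)).image

        bg = ~(vol != 0)
        def bg_power(series):
            s = np.abs(series)
            s = s / s.max()
            return float(np.mean(s[:, bg] ** 2))

        assert bg_power(llr) < bg_power(adj)
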