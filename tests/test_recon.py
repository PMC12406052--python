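"""Reconstruction: operators, CS solver, SURE weight, series strategies."""

import numpy as np
import pytest

from ksim import (
    CoilProfile,
    KSpaceFrame,
    ReconProblem,
    SamplingPattern,
    Shot,
    adjoint_recon,
    contrast_volume,
    cs_recon_frame,
    epi_3d,
    estimate_mu_sure,
    make_coil_profiles,
    make_synthetic_phantom,
    reconstruct_series,
    simulate_shot_basic,
    stack_of_spirals,
)
from ksim.recon import FrameOperator, WaveletTransform, sure_soft_threshold


@pytest.fixture(scope="module")
def cart_frame():
    ph = make_synthetic_phantom((16, 16, 16), seed=0)
    cv = contrast_volume(ph, 50, 25, 12)
    coils = make_coil_profiles(ph, 1)
    pat = SamplingPattern(shots=epi_3d(ph.shape, 25.0), grid_shape=ph.shape)
    data = np.stack([simulate_shot_basic(cv, coils, s) for s in pat.shots], axis=1)
    return KSpaceFrame(data=data, pattern=pat), coils, cv


class TestFrameOperator:
    @pytest.mark.parametrize("force_nufft", [False, True])
    def test_adjoint_dot_product(self, cart_frame, rng, force_nufft):
        frame, coils, _ = cart_frame
        op = FrameOperator(frame.pattern, coils, force_nufft=force_nufft)
        x = rng.normal(size=op.shape) + 1j * rng.normal(size=op.shape)
        y = rng.normal(size=(1, op.n_samples)) + 1j * rng.normal(size=(1, op.n_samples))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.sum(np.conj(op.adjoint(y)) * x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_cartesian_and_nufft_paths_agree(self, cart_frame, rng):
        frame, coils, _ = cart_frame
        a = FrameOperator(frame.pattern, coils)
        b = FrameOperator(frame.pattern, coils, force_nufft=True)
        x = rng.normal(size=a.shape)
        ya, yb = a.forward(x), b.forward(x)
        assert np.abs(ya - yb).max() / np.abs(ya).max() < 1e-5


class TestAdjointRecon:
    def test_fully_sampled_cartesian_is_exact(self, cart_frame):
        frame, coils, cv = cart_frame
        x = adjoint_recon(frame, coils)
        assert np.linalg.norm(x - cv.values) / np.linalg.norm(cv.values) < 1e-6

    def test_zero_data_gives_zero_image(self, cart_frame):
        frame, coils, _ = cart_frame
        zero = KSpaceFrame(data=np.zeros_like(frame.data), pattern=frame.pattern)
        assert np.all(adjoint_recon(zero, coils) == 0)

    def test_nyquist_stack_of_spirals_quality(self):
        """Noiseless fully stacked spirals: density-compensated adjoint is
        faithful (bound fixed from the shipped compensation rule)."""
        from ksim.analysis import image_metrics

        ph = make_synthetic_phantom((32, 32, 32), seed=0)
        cv = contrast_volume(ph, 50, 25, 12)
        coils = make_coil_profiles(ph, 1)
        pat = stack_of_spirals(
            nz=32, center_frac=0.0, AF=1, grid_shape=(32, 32, 32),
            n_samples=3000, n_turns=16, Tobs=30.0,
        )
        data = np.stack([simulate_shot_basic(cv, coils, s) for s in pat.shots], axis=1)
        x = adjoint_recon(KSpaceFrame(data=data, pattern=pat), coils)
        m = image_metrics(x, cv)
        assert m["psnr"] > 28.0
        assert m["ssim"] > 0.95


class TestWavelet:
    def test_orthonormality(self, rng):
        wt = WaveletTransform((32, 32, 32), "sym8", 3)
        x = rng.normal(size=(32, 32, 32)) + 1j * rng.normal(size=(32, 32, 32))
        a = wt.forward(x)
        assert abs(np.linalg.norm(a) - np.linalg.norm(x)) / np.linalg.norm(x) < 1e-10
        assert np.abs(wt.inverse(a) - x).max() < 1e-10


class TestCsReconFrame:
    def test_mu_zero_fully_sampled_matches_adjoint(self, cart_frame):
        frame, coils, _ = cart_frame
        adj = adjoint_recon(frame, coils)
        for algo in ("pogm", "fista"):
            x, diag = cs_recon_frame(
                ReconProblem(frame=frame, coils=coils, mu=0.0, algorithm=algo,
                             max_iter=50, tol=1e-12)
            )
            assert np.linalg.norm(x - adj) / np.linalg.norm(adj) < 1e-6, algo

    def test_zero_data_prox_fixed_point(self, cart_frame):
        frame, coils, _ = cart_frame
        zero = KSpaceFrame(data=np.zeros_like(frame.data), pattern=frame.pattern)
        x, _ = cs_recon_frame(ReconProblem(frame=zero, coils=coils, mu=1.0))
        assert np.all(x == 0)

    def test_cost_never_exceeds_initial(self, cart_frame):
        frame, coils, _ = cart_frame
        for algo in ("pogm", "fista"):
            _, diag = cs_recon_frame(
                ReconProblem(frame=frame, coils=coils, mu=0.01, algorithm=algo, max_iter=15)
            )
            assert diag["final_cost"] <= diag["initial_cost"]

    def test_sparse_recovery_from_undersampled_cartesian(self, rng):
        """50-sparse wavelet image, 2x random Cartesian undersampling."""
        shape = (32, 32, 32)
        wt = WaveletTransform(shape)
        coef = wt.forward(np.zeros(shape))
        idx = rng.choice(coef.size, 50, replace=False)
        coef.ravel()[idx] = rng.normal(size=50)
        img = wt.inverse(coef)
        kall = np.stack(
            np.meshgrid(*[(np.arange(32) - 16) / 32] * 3, indexing="ij"), -1
        ).reshape(-1, 3)
        keep = (rng.random(len(kall)) < 0.5) | (np.abs(kall).max(1) <= 4 / 32)
        k = kall[keep][: (int(keep.sum()) // 2) * 2]
        shot = Shot(samples=k, times=np.linspace(-10, 10, len(k)))
        coils = CoilProfile(maps=np.ones((1,) + shape), covariance=np.eye(1))
        y = simulate_shot_basic(img, coils, shot)
        frame = KSpaceFrame(
            data=y[:, None, :], pattern=SamplingPattern(shots=[shot], grid_shape=shape)
        )
        x, _ = cs_recon_frame(
            ReconProblem(frame=frame, coils=coils, mu=10.0, max_iter=200, tol=1e-10)
        )
        assert np.linalg.norm(x - img) / np.linalg.norm(img) <= 1e-2

    def test_divergent_step_raises(self, cart_frame):
        # force divergence by lying about the Lipschitz constant
        frame, coils, _ = cart_frame
        op = FrameOperator(frame.pattern, coils)
        op._lip = op.lipschitz() * 1e-4
        with pytest.raises(RuntimeError, match="step"):
            cs_recon_frame(
                ReconProblem(frame=frame, coils=coils, mu=0.0, max_iter=50, tol=0.0),
                operator=op,
            )


class TestSure:
    def test_noiseless_data_gives_negligible_mu(self, cart_frame):
        frame, coils, cv = cart_frame
        mu = estimate_mu_sure(frame, coils)
        assert mu <= 1e-8 * np.abs(cv.values).max()

    def test_pure_noise_threshold_near_universal(self, rng):
        sigma, M = 1.3, 40000
        c = rng.normal(scale=sigma, size=M)
        thr, _ = sure_soft_threshold(c, sigma)
        uni = sigma * np.sqrt(2 * np.log(M))
        assert 0.5 * uni <= thr <= 1.2 * uni

    def test_sure_tracks_oracle_risk(self, rng):
        """Averaged over realisations, SURE is within 5% of the true risk."""
        sigma, M = 1.0, 30000
        theta = np.zeros(M)
        theta[:1500] = 5.0
        sures, risks = [], []
        for _ in range(5):
            y = theta + rng.normal(scale=sigma, size=M)
            thr, val = sure_soft_threshold(y, sigma)
            shrunk = np.sign(y) * np.maximum(np.abs(y) - thr, 0)
            sures.append(val)
            risks.append(np.sum((shrunk - theta) ** 2))
        assert abs(np.mean(sures) - np.mean(risks)) / np.mean(risks) < 0.05

    def test_zero_variance_data(self, cart_frame):
        frame, coils, _ = cart_frame
        zero = KSpaceFrame(data=np.zeros_like(frame.data), pattern=frame.pattern)
        assert estimate_mu_sure(zero, coils) == 0.0


@pytest.fixture(scope="module")
def noisy_frames():
    """Three noisy fully sampled Cartesian frames of a static phantom."""
    from ksim import NoiseSpec, add_noise, phantom_energy

    ph = make_synthetic_phantom((16, 16, 16), seed=2)
    cv = contrast_volume(ph, 50, 25, 12)
    coils = make_coil_profiles(ph, 1)
    pat = SamplingPattern(shots=epi_3d(ph.shape, 25.0), grid_shape=ph.shape)
    noise = NoiseSpec(
        snr_in=200.0, energy=phantom_energy(cv, ph.head_mask()),
        covariance=np.eye(1), seed=0,
    )
    frames = []
    for t in range(3):
        data = np.stack(
            [
                add_noise(simulate_shot_basic(cv, coils, s), noise, t * 16 + i)
                for i, s in enumerate(pat.shots)
            ],
            axis=1,
        )
        frames.append(KSpaceFrame(data=data, pattern=pat, frame_index=t))
    return frames, coils


class TestReconstructSeries:
    def test_single_frame_strategies_agree(self, noisy_frames):
        frames, coils = noisy_frames
        tpl = {"coils": coils, "mu": 0.0, "max_iter": 10, "tol": 1e-8}
        outs = [
            reconstruct_series(frames[:1], s, tpl).volumes
            for s in ("cold", "warm", "refined")
        ]
        assert np.array_equal(outs[0], outs[1])
        assert np.array_equal(outs[0], outs[2])

    def test_warm_start_converges_faster(self, cart_frame):
        """Static noiseless frames: warm restarts stop almost immediately."""
        frame, coils, _ = cart_frame
        frames = [frame] * 3
        tpl = {"coils": coils, "mu": 1e-6, "max_iter": 40, "tol": 1e-8}
        cold = reconstruct_series(frames, "cold", tpl)
        warm = reconstruct_series(frames, "warm", tpl)
        it_cold = [d["iterations"] for d in cold.diagnostics]
        it_warm = [d["iterations"] for d in warm.diagnostics]
        assert all(w <= c for w, c in zip(it_warm[1:], it_cold[1:]))
        assert sum(it_warm[1:]) < sum(it_cold[1:])

    def test_refined_identical_frames_agree(self, noisy_frames):
        frames, coils = noisy_frames
        same = [frames[0]] * 3
        tpl = {"coils": coils, "mu": 1e-6, "max_iter": 40, "tol": 1e-10}
        out = reconstruct_series(same, "refined", tpl)
        v = out.volumes
        assert np.linalg.norm(v[0] - v[1]) / np.linalg.norm(v[0]) < 1e-4
        assert np.linalg.norm(v[0] - v[2]) / np.linalg.norm(v[0]) < 1e-4

    def test_sure_weight_shrinks_with_warm_history(self):
        """Dynamic undersampled frames: the data innovation, hence the
        SURE weight, shrinks as the warm initialisation accumulates
        k-space coverage."""
        ph = make_synthetic_phantom((16, 16, 16), seed=2)
        cv = contrast_volume(ph, 50, 25, 12)
        coils = make_coil_profiles(ph, 2)
        frames = []
        for t in range(4):
            pat = stack_of_spirals(
                nz=16, center_frac=0.125, AF=4, dynamic=True, frame_index=t,
                seed=3, grid_shape=(16, 16, 16), n_samples=256, n_turns=6, Tobs=30.0,
            )
            data = np.stack([simulate_shot_basic(cv, coils, s) for s in pat.shots], axis=1)
            frames.append(KSpaceFrame(data=data, pattern=pat, frame_index=t))
        tpl = {"coils": coils, "mu": "auto", "max_iter": 30, "tol": 1e-6}
        warm = reconstruct_series(frames, "warm", tpl)
        mus = [d["mu"] for d in warm.diagnostics]
        assert mus[-1] <= mus[0]  # late frames less regularised than frame 1
        assert mus[-1] <= mus[1]

    def test_unknown_strategy_rejected(self, noisy_frames):
        frames, coils = noisy_frames
        with pytest.raises(ValueError):
            reconstruct_series(frames, "tepid", {"coils": coils})

    def test_initialisation_lineage_recorded(self, noisy_frames):
        frames, coils = noisy_frames
        tpl = {"coils": coils, "mu": 0.0, "max_iter": 5, "tol": 1e-6}
        ref = reconstruct_series(frames, "refined", tpl)
        sources = [d["init"] for d in ref.diagnostics]
        assert sources[:3] == ["none", "previous", "previous"]
        assert set(sources[3:]) == {"warm_final"}
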