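"""Acquisition engine: forward models, noise, off-resonance, streaming runs."""

import hashlib

import h5py
import numpy as np
import pytest

from ksim import (
    CoilProfile,
    ContrastVolume,
    HandlerChain,
    NoiseSpec,
    SamplingPattern,
    SequenceParams,
    Shot,
    add_noise,
    build_off_resonance,
    calibrate_snr,
    contrast_volume,
    epi_3d,
    make_coil_profiles,
    make_phantom_state,
    make_synthetic_phantom,
    phantom_energy,
    read_mrd,
    run_acquisition,
    simulate_shot_basic,
    simulate_shot_t2s,
)
from ksim.phantom import DEFAULT_TISSUES, TissueParams

from conftest import brute_force_dft


def random_shot(rng, n=50, Tobs=25.0):
    k = rng.uniform(-0.5, 0.5, (n, 3))
    return Shot(samples=k, times=np.linspace(-Tobs / 2, Tobs / 2, n))


def payload_hash(path):
    h = hashlib.sha256()
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            h.update(np.ascontiguousarray(fh[key][...]).tobytes())
    return h.hexdigest()


class TestPhantomEnergy:
    def test_uniform_volume(self):
        vol = ContrastVolume(values=np.full((8, 8, 8), 2.0), tref=25.0)
        assert phantom_energy(vol) == pytest.approx(4.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            phantom_energy(ContrastVolume(values=np.zeros((8, 8, 8)), tref=25.0))

    def test_permutation_invariance(self, contrast16, phantom16, rng):
        e = phantom_energy(contrast16, phantom16.head_mask())
        vals = contrast16.values.ravel().copy()
        rng.shuffle(vals)
        mask = np.abs(vals) > 1e-12
        e2 = float(np.mean(vals[mask] ** 2))
        assert e2 == pytest.approx(
            float(np.mean(contrast16.values[np.abs(contrast16.values) > 1e-12] ** 2))
        )
        assert e > 0


class TestBasicEngine:
    def test_point_phantom_fourier_shift(self, rng):
        shape = (8, 8, 8)
        vol = np.zeros(shape)
        r0 = np.array([1, -2, 3])
        vol[tuple(r0 + 4)] = 1.0
        coils = CoilProfile(maps=np.ones((1,) + shape), covariance=np.eye(1))
        shot = random_shot(rng)
        y = simulate_shot_basic(vol, coils, shot)
        expected = np.exp(-2j * np.pi * (shot.samples @ r0))
        assert np.allclose(y[0], expected, atol=1e-10)

    def test_dc_sample_is_volume_sum(self, rng):
        shape = (8, 8, 8)
        vol = rng.normal(size=shape)
        coils = CoilProfile(maps=np.ones((1,) + shape), covariance=np.eye(1))
        shot = Shot(samples=np.zeros((4, 3)), times=np.linspace(-1, 1, 4))
        y = simulate_shot_basic(vol, coils, shot)
        assert np.allclose(y[0], vol.sum())

    def test_matches_brute_force_oracle_both_paths(self, rng):
        shape = (8, 8, 8)
        vol = rng.normal(size=shape)
        coils = CoilProfile(maps=np.ones((1,) + shape), covariance=np.eye(1))
        shot = random_shot(rng)
        y0 = brute_force_dft(vol, shot.samples)
        y_exact = simulate_shot_basic(vol, coils, shot)
        y_nufft = simulate_shot_basic(vol, coils, shot, force_nufft=True)
        assert np.abs(y_exact[0] - y0).max() / np.abs(y0).max() < 1e-6
        assert np.abs(y_nufft[0] - y0).max() / np.abs(y0).max() < 1e-4

    def test_linearity_in_contrast(self, rng):
        shape = (8, 8, 8)
        a, b = rng.normal(size=shape), rng.normal(size=shape)
        coils = CoilProfile(maps=np.ones((1,) + shape), covariance=np.eye(1))
        shot = random_shot(rng)
        ya = simulate_shot_basic(a, coils, shot)
        yb = simulate_shot_basic(b, coils, shot)
        yab = simulate_shot_basic(a + b, coils, shot)
        assert np.allclose(ya + yb, yab)

    def test_parseval_on_full_cartesian_volume(self, contrast16, single_coil16, epi_pattern16):
        total = 0.0
        for shot in epi_pattern16.shots:
            y = simulate_shot_basic(contrast16, single_coil16, shot)
            total += float(np.sum(np.abs(y) ** 2))
        n = np.prod(contrast16.values.shape)
        assert total == pytest.approx(n * float(np.sum(contrast16.values**2)), rel=1e-9)


class TestT2sEngine:
    def test_reduces_to_basic_when_decay_negligible(self, rng):
        tissues = tuple(
            TissueParams(t.name, t.rho, t.T1, 1e12) for t in DEFAULT_TISSUES
        )
        ph = make_synthetic_phantom((16, 16, 16), seed=0, tissues=tissues)
        state = make_phantom_state(ph, 50, 25, 12)
        coils = make_coil_profiles(ph, 1)
        shot = random_shot(rng)
        yb = simulate_shot_basic(state.total_contrast(), coils, shot)
        yt = simulate_shot_t2s(state, coils, shot)
        assert np.abs(yt - yb).max() / np.abs(yb).max() < 1e-6

    def test_single_tissue_decay_commutes(self, rng):
        ph = make_synthetic_phantom((16, 16, 16), seed=0)
        state = make_phantom_state(ph, 50, 25, 12)
        state.maps[0] = state.maps[1] = 0.0  # CSF only
        coils = make_coil_profiles(ph, 1)
        shot = random_shot(rng)
        yt = simulate_shot_t2s(state, coils, shot)
        yb = simulate_shot_basic(state.total_contrast(), coils, shot)
        decay = np.exp(-shot.times / state.t2s[2])
        assert np.allclose(yt, decay * yb, rtol=1e-10)

    def test_matches_brute_force_with_constant_off_resonance(self, rng):
        shape = (8, 8, 8)
        ph = make_synthetic_phantom((16, 16, 16), seed=0)
        state = make_phantom_state(ph, 50, 25, 12)
        # restrict to an 8^3 two-tissue crop for the voxel-sum oracle
        maps = state.maps[:2, 4:12, 4:12, 4:12].copy()
        t2s = state.t2s[:2]
        from ksim.dynamics import PhantomState

        st = PhantomState(maps=maps, t2s=t2s, tissue_names=("WM", "GM"), shape=shape)
        coils = CoilProfile(maps=np.ones((1,) + shape), covariance=np.eye(1))
        shot = random_shot(rng)
        f0 = 20.0
        offres = build_off_resonance(np.full(shape, f0), shot.times, P=1)
        assert offres.residual < 1e-12
        y = simulate_shot_t2s(st, coils, shot, offres=offres)
        t_s = shot.times * 1e-3
        y0 = np.zeros(shot.n_samples, dtype=complex)
        for i in range(2):
            y0 += (
                np.exp(-shot.times / t2s[i])
                * np.exp(-2j * np.pi * f0 * t_s)
                * brute_force_dft(maps[i], shot.samples)
            )
        assert np.abs(y[0] - y0).max() / np.abs(y0).max() < 1e-4

    def test_fourier_call_count(self, rng):
        ph = make_synthetic_phantom((16, 16, 16), seed=0)
        state = make_phantom_state(ph, 50, 25, 12)
        coils = make_coil_profiles(ph, 2)
        shot = random_shot(rng)
        offres = build_off_resonance(np.zeros((16, 16, 16)), shot.times, P=3)
        simulate_shot_t2s(state, coils, shot, offres=offres)
        assert simulate_shot_t2s.last_ft_calls == 3 * 3 * 2  # n_tis * P * L


class TestOffResonance:
    def test_zero_field_is_exact(self):
        om = build_off_resonance(np.zeros((8, 8, 8)), np.linspace(-10, 10, 30), P=1)
        assert om.residual < 1e-12
        assert np.allclose(om.b, 1.0)

    def test_constant_field_rank_one_exact(self):
        om = build_off_resonance(np.full((8, 8, 8), 37.0), np.linspace(-10, 10, 30), P=1)
        assert om.residual < 1e-10

    def test_smooth_map_eight_interpolators(self, rng):
        from scipy.ndimage import gaussian_filter

        fmap = gaussian_filter(rng.uniform(-50, 50, (16, 16, 16)), 3)
        fmap *= 50 / np.abs(fmap).max()
        om = build_off_resonance(fmap, np.linspace(-12.5, 12.5, 200), P=8)
        assert om.residual <= 1e-3


class TestNoise:
    def test_infinite_snr_is_identity(self, rng):
        y = rng.normal(size=(2, 30)) + 1j * rng.normal(size=(2, 30))
        ns = NoiseSpec(snr_in=float("inf"), energy=1.0, covariance=np.eye(2), seed=0)
        assert np.array_equal(add_noise(y, ns, 3), y)

    def test_per_sample_variance_calibration(self):
        """1e5 iid complex draws: empirical variance within 3% of E/SNRi."""
        energy, snr = 2.0, 50.0
        ns = NoiseSpec(snr_in=snr, energy=energy, covariance=np.eye(1), seed=11)
        y = add_noise(np.zeros((1, 100_000), dtype=complex), ns, 0)
        var = float(np.mean(np.abs(y) ** 2))
        assert abs(var - energy / snr) / (energy / snr) < 0.03

    def test_cross_coil_covariance(self):
        cov = np.eye(3)
        cov[0, 1] = cov[1, 0] = 0.5
        ns = NoiseSpec(snr_in=10.0, energy=1.0, covariance=cov, seed=4)
        y = add_noise(np.zeros((3, 200_000), dtype=complex), ns, 0)
        emp = (y @ y.conj().T) / y.shape[1]
        target = cov * (1.0 / 10.0)
        assert np.abs(emp - target).max() / np.abs(target).max() < 0.05

    def test_seeded_per_shot(self):
        ns = NoiseSpec(snr_in=10.0, energy=1.0, covariance=np.eye(1), seed=5)
        a = add_noise(np.zeros((1, 10), dtype=complex), ns, 3)
        b = add_noise(np.zeros((1, 10), dtype=complex), ns, 3)
        c = add_noise(np.zeros((1, 10), dtype=complex), ns, 4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestRunAcquisition:
    def _setup(self, L=1, shape=(16, 16, 16)):
        ph = make_synthetic_phantom(shape, seed=0)
        seq = SequenceParams()
        coils = make_coil_profiles(ph, L)
        pats = [
            SamplingPattern(shots=epi_3d(shape, seq.Tobs), grid_shape=shape, frame_index=t)
            for t in range(2)
        ]
        return ph, seq, coils, pats

    def test_container_matches_direct_simulation(self, tmp_path):
        ph, seq, coils, pats = self._setup()
        out = str(tmp_path / "run.mrd")
        run_acquisition(ph, HandlerChain(), pats, sequence=seq, out=out, coils=coils)
        run = read_mrd(out)
        assert run.data.shape[0] == 32
        cv = contrast_volume(ph, seq.TR_shot, seq.TE, seq.FA)
        y = simulate_shot_basic(cv, coils, pats[0].shots[3])
        assert np.allclose(run.data[3], y.astype(np.complex64))

    def test_bit_identical_rerun_and_parallel(self, tmp_path):
        ph, seq, coils, pats = self._setup(L=2)
        cv = contrast_volume(ph, seq.TR_shot, seq.TE, seq.FA)
        noise = NoiseSpec(
            snr_in=100.0, energy=phantom_energy(cv, ph.head_mask()),
            covariance=coils.covariance, seed=9,
        )
        hashes = []
        for name, n_jobs in (("a", 1), ("b", 1), ("c", 3)):
            out = str(tmp_path / f"{name}.mrd")
            run_acquisition(
                ph, HandlerChain(), pats, sequence=seq, out=out,
                noise=noise, coils=coils, n_jobs=n_jobs,
            )
            hashes.append(payload_hash(out))
        assert hashes[0] == hashes[1] == hashes[2]

    def test_shot_budget_five_minute_run(self):
        # 5 min at TR_shot = 50 ms is a budget of 6000 shots
        assert int(300.0 / 50e-3) == 6000

    def test_snr_calibration_roundtrip(self, tmp_path):
        ph, seq, coils, pats = self._setup()
        cv = contrast_volume(ph, seq.TR_shot, seq.TE, seq.FA)
        energy = phantom_energy(cv, ph.head_mask())
        noise = NoiseSpec(snr_in=200.0, energy=energy, covariance=np.eye(1), seed=2)
        out = str(tmp_path / "rf_off.mrd")
        zero_state = make_phantom_state(ph, seq.TR_shot, seq.TE, seq.FA)
        zero_state.maps[:] = 0.0
        run_acquisition(zero_state, HandlerChain(), pats, sequence=seq, out=out, noise=noise)
        est = calibrate_snr(out, energy)
        assert est == pytest.approx(200.0, rel=0.05)
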