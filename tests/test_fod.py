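"""FOD estimation: SH basis, response, CSD, ball-and-stick, peak finding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ortrack import (
    GradientScheme,
    ResponseFunction,
    ballstick_fit,
    csd_fit,
    estimate_response,
    fit_dti,
    fod_peaks,
    generate_gradient_scheme,
)
from ortrack.fod import sh_basis_matrix, sh_degrees, sphere_grid

from conftest import FIBER_EVALS, make_voxel_dwi, stick_signal, tensor_signal


def angle_deg(a, b):
    return np.degrees(np.arccos(min(1.0, abs(np.dot(a, b)))))


@pytest.fixture(scope="module")
def response(dwi_noiseless, scheme30, tensor_noiseless):
    return estimate_response(dwi_noiseless, scheme30, tensor_noiseless, fa_cutoff=0.7)


class TestSphericalHarmonics:
    def test_coefficient_count(self):
        for lmax, n in [(0, 1), (2, 6), (4, 15), (6, 28), (8, 45)]:
            ls, ms = sh_degrees(lmax)
            assert len(ls) == (lmax + 1) * (lmax + 2) // 2 == n

    def test_orthonormal_on_dense_quadrature(self):
        grid = sphere_grid(20_000)
        B = sh_basis_matrix(6, grid)
        gram = (B.T @ B) * (4 * np.pi / len(grid))
        assert np.abs(gram - np.eye(28)).max() < 1e-3

    def test_antipodal_symmetry(self):
        rng = np.random.default_rng(0)
        dirs = rng.standard_normal((20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert np.allclose(sh_basis_matrix(6, dirs), sh_basis_matrix(6, -dirs))


class TestResponse:
    def test_reconvolution_reproduces_aligned_signal(self, response, scheme30):
        # forward oracle: response (x) delta(+z) == the aligned single-fiber signal
        cos_gamma = scheme30.directions[:, 2]
        predicted = response.signal(cos_gamma)
        truth = tensor_signal(
            scheme30.directions, 3000.0, np.array([0, 0, 1.0]), FIBER_EVALS, f=0.8
        )
        rms = np.sqrt(np.mean((predicted - truth) ** 2) / np.mean(truth**2))
        assert rms < 0.02

    def test_zonal_l2_negative(self, response):
        # the DW signal has its minimum along the fiber: l=2 zonal term < 0
        assert response.zonal_coeffs[0] > 0
        assert response.zonal_coeffs[1] < 0

    def test_isotropic_data_rejected(self, scheme30):
        sig = np.exp(-3000.0 * 1e-3) * np.ones(30)
        data = np.tile(
            make_voxel_dwi(scheme30, sig).data, (4, 4, 4, 1)
        )
        from ortrack import DWIVolume

        dwi = DWIVolume(data, np.eye(4), scheme30)
        with pytest.raises(ValueError, match="FA > 0.7"):
            estimate_response(dwi, scheme30, fit_dti(dwi), fa_cutoff=0.7)

    def test_nonpositive_l0_rejected(self):
        with pytest.raises(ValueError, match="l=0"):
            ResponseFunction(zonal_coeffs=[-1.0, 0.2], b_value=3000.0)


class TestCSD:
    def test_lmax6_yields_28_coefficients(self, dwi_noiseless, scheme30, response):
        mask = np.zeros(dwi_noiseless.data.shape[:3], bool)
        mask[20, 25, 9] = True
        fodf = csd_fit(dwi_noiseless, scheme30, response, lmax=6, mask=mask)
        assert fodf.coeffs.shape[-1] == 28

    def test_delta_recovery_within_2_degrees(self, scheme30, response):
        rng = np.random.default_rng(3)
        for _ in range(3):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            sig = response.signal(scheme30.directions @ v)
            fodf = csd_fit(make_voxel_dwi(scheme30, sig), scheme30, response)
            peaks = fod_peaks(fodf.coeffs[0, 0, 0])
            assert len(peaks) >= 1
            assert angle_deg(peaks[0], v) < 2.0

    def test_crossing_90deg_snr30(self, scheme30, response):
        v1, v2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        sig = 0.5 * tensor_signal(scheme30.directions, 3000.0, v1, f=0.8) + \
            0.5 * tensor_signal(scheme30.directions, 3000.0, v2, f=0.8)
        dwi = make_voxel_dwi(scheme30, sig, snr=30.0, seed=42)
        fodf = csd_fit(dwi, scheme30, response)
        peaks = fod_peaks(fodf.coeffs[0, 0, 0], min_relative_amplitude=0.4)
        assert len(peaks) == 2
        errs = sorted([min(angle_deg(p, v1), angle_deg(p, v2)) for p in peaks])
        assert max(errs) < 10.0
        # both true fibers found (not twice the same)
        assert min(angle_deg(peaks[0], v1), angle_deg(peaks[1], v1)) < 10.0
        assert min(angle_deg(peaks[0], v2), angle_deg(peaks[1], v2)) < 10.0
        amps = [
            (sh_basis_matrix(6, p[None]) @ fodf.coeffs[0, 0, 0]).item() for p in peaks
        ]
        ratio = amps[0] / amps[1]
        assert 0.7 <= ratio <= 1.4 or 0.7 <= 1 / ratio <= 1.4

    def test_deconvolution_sharpens(self, scheme30, response):
        # the FOD is sharper than the raw signal once the response is deconvolved
        v = np.array([0.0, 0.0, 1.0])
        sig = response.signal(scheme30.directions @ v)
        fodf = csd_fit(make_voxel_dwi(scheme30, sig), scheme30, response)
        grid = sphere_grid(600)
        fod_amp = sh_basis_matrix(6, grid) @ fodf.coeffs[0, 0, 0]
        sig_amp = response.signal(grid @ v)
        # normalized peak-to-mean: deconvolution concentrates mass
        sharp_fod = fod_amp.max() / np.abs(fod_amp).mean()
        sharp_sig = sig_amp.max() / np.abs(sig_amp).mean()
        assert sharp_fod > sharp_sig

    def test_soft_nonnegativity(self, scheme30, response):
        rng = np.random.default_rng(11)
        v = np.array([1.0, 0, 0])
        sig = tensor_signal(scheme30.directions, 3000.0, v, f=0.8)
        dwi = make_voxel_dwi(scheme30, sig, snr=30.0, seed=8)
        fodf = csd_fit(dwi, scheme30, response)
        amps = sh_basis_matrix(6, sphere_grid(300)) @ fodf.coeffs[0, 0, 0]
        assert amps.min() >= -0.1 * np.abs(amps).mean() - 1e-6

    def test_rotation_equivariance_of_peaks(self, scheme30, response):
        R = Rotation.from_euler("zyx", [33, -21, 58], degrees=True).as_matrix()
        v = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])
        peaks = []
        for rot in (np.eye(3), R):
            dirs = scheme30.directions @ rot.T
            scheme = GradientScheme(dirs, scheme30.b_values, scheme30.n_b0)
            sig = tensor_signal(dirs, 3000.0, rot @ v, f=0.8)
            fodf = csd_fit(make_voxel_dwi(scheme, sig), scheme, response)
            peaks.append(fod_peaks(fodf.coeffs[0, 0, 0])[0])
        assert angle_deg(R @ peaks[0], peaks[1]) < 1.0

    def test_odd_lmax_rejected(self, dwi_noiseless, scheme30, response):
        with pytest.raises(ValueError, match="lmax"):
            csd_fit(dwi_noiseless, scheme30, response, lmax=5)

    def test_empty_mask_warns(self, dwi_noiseless, scheme30, response):
        mask = np.zeros(dwi_noiseless.data.shape[:3], bool)
        with pytest.warns(UserWarning, match="empty"):
            fodf = csd_fit(dwi_noiseless, scheme30, response, mask=mask)
        assert not fodf.coeffs.any()

    def test_angular_resolution_better_at_b3000(self):
        # premise of high-b acquisition: a 45-degree crossing is resolved in
        # more noise realizations at b=3000 than at b=1000.  lmax=8 is used
        # here: 45 degrees sits below the angular resolution of the lmax=6
        # basis at either b-value.
        n_rep = 24
        lmax = 8
        v1 = np.array([1.0, 0, 0])
        v2 = np.array([np.cos(np.radians(45)), np.sin(np.radians(45)), 0])
        resolved = {}
        for b in (1000.0, 3000.0):
            scheme = generate_gradient_scheme(30, b, seed=1)
            resp_sig = tensor_signal(scheme.directions, b, np.array([0, 0, 1.0]), f=1.0)
            dirs = scheme.directions
            ls, ms = sh_degrees(lmax)
            B = sh_basis_matrix(lmax, dirs)
            coeffs, *_ = np.linalg.lstsq(B, resp_sig, rcond=None)
            resp = ResponseFunction(coeffs[ms == 0], b)
            sig = 0.5 * tensor_signal(dirs, b, v1, f=1.0) + 0.5 * tensor_signal(dirs, b, v2, f=1.0)
            count = 0
            for rep in range(n_rep):
                dwi = make_voxel_dwi(scheme, sig, snr=30.0, seed=100 + rep)
                fodf = csd_fit(dwi, scheme, resp, lmax=lmax)
                peaks = fod_peaks(fodf.coeffs[0, 0, 0], min_relative_amplitude=0.3)
                if len(peaks) >= 2:
                    errs = sorted(
                        min(angle_deg(p, v1), angle_deg(p, v2)) for p in peaks[:2]
                    )
                    sep = angle_deg(peaks[0], peaks[1])
                    if max(errs) < 20 and sep > 25:
                        count += 1
            resolved[b] = count
        assert resolved[3000.0] > resolved[1000.0]


class TestBallStick:
    def test_single_stick_recovery(self, scheme30):
        vx = np.array([1.0, 0, 0])
        sig = stick_signal(scheme30.directions, 3000.0, vx, d=1.7e-3, f=0.6)
        dwi = make_voxel_dwi(scheme30, sig, snr=30.0, seed=7)
        post = ballstick_fit(dwi, scheme30, n_sticks=1, seed=3)
        assert abs(post.mean_f[0, 0] - 0.6) < 0.05
        dirs = post.dir_samples[0, 0]
        sgn = np.where(dirs @ dirs[0] < 0, -1.0, 1.0)[:, None]
        mean_dir = (dirs * sgn).mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        assert angle_deg(mean_dir, vx) < 5.0
        assert post.n_samples >= 50
        assert np.all(np.linalg.norm(post.dir_samples, axis=-1) - 1 < 1e-6)

    def test_isotropic_voxel_low_fraction(self, scheme30):
        sig = np.exp(-3000.0 * 1e-3) * np.ones(30)
        dwi = make_voxel_dwi(scheme30, sig, snr=30.0, seed=7)
        post = ballstick_fit(dwi, scheme30, n_sticks=1, seed=3)
        assert post.mean_f[0, 0] < 0.1

    def test_identical_seed_identical_chains(self, scheme30):
        sig = stick_signal(scheme30.directions, 3000.0, np.array([0, 1.0, 0]), 1.5e-3, 0.5)
        dwi = make_voxel_dwi(scheme30, sig, snr=30.0, seed=2)
        a = ballstick_fit(dwi, scheme30, n_sticks=2, seed=9)
        b = ballstick_fit(dwi, scheme30, n_sticks=2, seed=9)
        assert np.array_equal(a.f_samples, b.f_samples)
        assert np.array_equal(a.dir_samples, b.dir_samples)

    def test_posterior_credible_interval_calibration(self, scheme30):
        # 50 repeats in one vectorized fit: the 90% CI for f covers the truth
        # in at least 70% of them (a loose bound that catches sampler bugs)
        truth_f = 0.6
        vx = np.array([1.0, 0, 0])
        sig = stick_signal(scheme30.directions, 3000.0, vx, d=1.7e-3, f=truth_f)
        rng = np.random.default_rng(21)
        s0, sigma = 1000.0, 1000.0 / 30.0
        data = np.empty((50, 1, 1, 31))
        clean = np.full(31, s0)
        clean[scheme30.dwi_indices] = s0 * sig
        for r in range(50):
            data[r, 0, 0] = np.hypot(
                clean + rng.normal(0, sigma, 31), rng.normal(0, sigma, 31)
            )
        from ortrack import DWIVolume

        dwi = DWIVolume(data, np.eye(4), scheme30)
        post = ballstick_fit(dwi, scheme30, n_sticks=1, seed=5)
        lo = np.quantile(post.f_samples[:, 0, :], 0.05, axis=1)
        hi = np.quantile(post.f_samples[:, 0, :], 0.95, axis=1)
        coverage = np.mean((lo <= truth_f) & (truth_f <= hi))
        assert coverage >= 0.70

    def test_invalid_arguments(self, scheme30):
        sig = np.ones(30) * 0.5
        dwi = make_voxel_dwi(scheme30, sig)
        with pytest.raises(ValueError, match="n_sticks"):
            ballstick_fit(dwi, scheme30, n_sticks=4)
        with pytest.raises(ValueError, match="positive"):
            ballstick_fit(dwi, scheme30, burn_in=0)


class TestFODPeaks:
    def delta_coeffs(self, v):
        return sh_basis_matrix(6, np.asarray(v)[None])[0]

    def test_single_delta_peak(self):
        peaks = fod_peaks(self.delta_coeffs([0, 0, 1.0]))
        assert len(peaks) == 1
        assert angle_deg(peaks[0], np.array([0, 0, 1.0])) < 1.0

    def test_two_orthogonal_deltas(self):
        coeffs = self.delta_coeffs([1.0, 0, 0]) + self.delta_coeffs([0, 1.0, 0])
        peaks = fod_peaks(coeffs)
        assert len(peaks) == 2

    def test_threshold_above_max_gives_empty(self):
        assert fod_peaks(self.delta_coeffs([0, 0, 1.0]), min_relative_amplitude=1.01) == []

    def test_all_zero_coefficients(self):
        assert fod_peaks(np.zeros(28)) == []

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fod_peaks(self.delta_coeffs([0, 0, 1.0]), grid=sphere_grid(50))
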