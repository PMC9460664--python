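import numpy as np
import pytest

from eegscrub import (
    DegenerateInputError,
    InvalidConfigError,
    InvalidInputError,
    MultichannelData,
    SobiConfig,
    joint_diagonalize,
    lagged_covariances,
    sobi_separate,
    whiten,
)


def ar1(phi: float, n: int, rng) -> np.ndarray:
    e = rng.standard_normal(n)
    x = np.zeros(n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def match_to_permutation(est: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-based matching; returns (best indices, |corr| values)."""
    m = est.shape[0]
    c = np.corrcoef(np.vstack([est, true]))[:m, m:]
    best = np.abs(c).argmax(axis=1)
    return best, np.abs(c[np.arange(m), best])


class TestMultichannelData:
    def test_single_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            MultichannelData(np.zeros((1, 100)))

    def test_short_record_rejected(self):
        with pytest.raises(InvalidInputError):
            MultichannelData(np.zeros((3, 3)))

    def test_non_finite_rejected(self):
        arr = np.zeros((2, 50))
        arr[0, 0] = np.inf
        with pytest.raises(InvalidInputError):
            MultichannelData(arr)


class TestWhiten:
    def test_uncorrelated_channels_give_diagonal_q(self, rng):
        # exactly uncorrelated, zero-mean channels with distinct variances:
        # Q is the inverse-scale diagonal up to sign/permutation and z
        # reproduces the normalized input
        raw = rng.standard_normal((3, 2000))
        raw -= raw.mean(axis=1, keepdims=True)
        basis, _ = np.linalg.qr(raw.T)
        scales = np.array([1.0, 2.0, 5.0])
        x = (basis * np.sqrt(2000 - 1)).T * scales[:, None]
        q, z = whiten(MultichannelData(x))
        perm = np.abs(q) * scales[None, :]
        np.testing.assert_allclose(perm.max(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(perm.sum(axis=1), 1.0, atol=1e-6)
        # z matches x up to per-channel sign/permutation and scale
        c = np.abs(np.corrcoef(np.vstack([z.channels, x]))[:3, 3:])
        np.testing.assert_allclose(np.sort(c.max(axis=1)), 1.0, atol=1e-8)

    def test_output_covariance_identity(self, rng):
        x = rng.standard_normal((3, 500))
        x[1] += 0.5 * x[0]
        x[2] *= 4.0
        _, z = whiten(MultichannelData(x))
        cov = np.cov(z.channels)
        np.testing.assert_allclose(cov, np.eye(3), atol=1e-8)

    def test_zero_mean_output(self, rng):
        x = rng.standard_normal((2, 300)) + 7.0
        _, z = whiten(MultichannelData(x))
        np.testing.assert_allclose(z.channels.mean(axis=1), 0.0, atol=1e-10)

    def test_rank_deficiency_raises(self, rng):
        base = rng.standard_normal(200)
        x = np.vstack([base, 2.0 * base])
        with pytest.raises(DegenerateInputError):
            whiten(MultichannelData(x))

    def test_ridge_rescues_rank_deficiency(self, rng):
        base = rng.standard_normal(200)
        x = np.vstack([base, 2.0 * base])
        q, z = whiten(MultichannelData(x), ridge=1e-6)
        assert np.all(np.isfinite(q))

    def test_whitening_idempotent(self, rng):
        x = rng.standard_normal((3, 5000))
        x[2] += 0.7 * x[0]
        q1, z1 = whiten(MultichannelData(x))
        q2, _ = whiten(z1)
        # whitening an already-white record: Q2 orthogonal (identity up to
        # an orthogonal factor)
        np.testing.assert_allclose(q2 @ q2.T, np.eye(3), atol=1e-6)


class TestLaggedCovariances:
    def test_white_noise_near_zero(self, rng):
        t = 20000
        x = rng.standard_normal((3, t))
        _, z = whiten(MultichannelData(x))
        for r in lagged_covariances(z, [1, 5, 20]):
            assert np.max(np.abs(r)) < 5.0 / np.sqrt(t)

    def test_lag_zero_identity_on_whitened(self, rng):
        x = rng.standard_normal((3, 400))
        _, z = whiten(MultichannelData(x))
        (r0,) = lagged_covariances(z, [0])
        np.testing.assert_allclose(r0, np.eye(3), atol=1e-8)

    def test_sinusoid_closed_form(self):
        # autocovariance of a unit sinusoid is (power) * cos(2 pi f tau)
        f = 0.05
        t = np.arange(8000)
        x = np.vstack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
        data = MultichannelData(x)
        for tau in (3, 7):
            (r,) = lagged_covariances(data, [tau])
            expected = 0.5 * np.cos(2 * np.pi * f * tau)
            assert r[0, 0] == pytest.approx(expected, abs=0.01)
            assert r[1, 1] == pytest.approx(expected, abs=0.01)

    def test_symmetry(self, rng):
        x = rng.standard_normal((3, 1000))
        _, z = whiten(MultichannelData(x))
        for r in lagged_covariances(z, [1, 2, 3]):
            np.testing.assert_array_equal(r, r.T)

    def test_lag_too_large(self, rng):
        x = rng.standard_normal((2, 50))
        data = MultichannelData(x)
        with pytest.raises(InvalidConfigError):
            lagged_covariances(data, [50])


class TestJointDiagonalize:
    def test_already_diagonal(self):
        v = joint_diagonalize([np.diag([3.0, 1.0, 2.0])])
        # identity up to column sign/permutation
        assert np.allclose(np.sort(np.abs(v).max(axis=0)), 1.0)
        np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-12)

    def test_recovers_planted_rotation(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        mats = [q @ np.diag(rng.uniform(1, 10, 4)) @ q.T for _ in range(6)]
        v = joint_diagonalize(mats)
        overlap = np.abs(v.T @ q)
        # |V^T P| is a permutation matrix
        assert np.allclose(overlap.max(axis=0), 1.0, atol=1e-6)
        assert np.allclose(overlap.sum(axis=0), 1.0, atol=1e-6)

    def test_commuting_matrices(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        m1 = q @ np.diag([1.0, 2.0, 3.0]) @ q.T
        m2 = q @ np.diag([5.0, 1.0, 4.0]) @ q.T
        v, info = joint_diagonalize([m1, m2], return_info=True)
        off = 0.0
        for m in (m1, m2):
            d = v.T @ m @ v
            off += np.sum(d**2) - np.sum(np.diag(d) ** 2)
        assert off < 1e-10

    def test_off_mass_non_increasing(self, rng):
        mats = []
        for _ in range(4):
            a = rng.standard_normal((5, 5))
            mats.append(a + a.T)
        v, info = joint_diagonalize(mats, return_info=True)
        hist = info["off_mass"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_non_square_rejected(self):
        with pytest.raises(InvalidInputError):
            joint_diagonalize([np.zeros((2, 3))])

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(InvalidInputError):
            joint_diagonalize([np.eye(2), np.eye(3)])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            joint_diagonalize([])


class TestSobiSeparate:
    def test_ar_sources_recovered(self, rng):
        t = 5000
        true = np.vstack(
            [ar1(0.9, t, rng), ar1(0.3, t, rng), ar1(-0.5, t, rng)]
        )
        mixing = rng.standard_normal((3, 3))
        data = MultichannelData(mixing @ true)
        res = sobi_separate(data)
        best, corrs = match_to_permutation(res.sources, true)
        assert sorted(best) == [0, 1, 2]  # matches form a permutation
        assert np.all(corrs > 0.95)

    def test_identity_mixing_spectrally_distinct(self, rng):
        t = 5000
        true = np.vstack([ar1(0.8, t, rng), ar1(-0.8, t, rng)])
        true = (true - true.mean(axis=1, keepdims=True)) / true.std(axis=1, keepdims=True)
        res = sobi_separate(MultichannelData(true))
        best, corrs = match_to_permutation(res.sources, true)
        assert sorted(best) == [0, 1]
        assert np.all(corrs > 0.95)

    def test_mixing_times_sources_reconstructs_centered_input(self, rng):
        t = 2000
        true = np.vstack([ar1(0.9, t, rng), ar1(0.2, t, rng), ar1(-0.6, t, rng)])
        x = rng.standard_normal((3, 3)) @ true + rng.uniform(-5, 5, size=(3, 1))
        data = MultichannelData(x)
        res = sobi_separate(data)
        xc = x - x.mean(axis=1, keepdims=True)
        err = np.linalg.norm(res.mixing @ res.sources - xc) / np.linalg.norm(xc)
        assert err < 1e-6

    def test_rotation_orthogonal(self, rng):
        x = rng.standard_normal((3, 1000)).cumsum(axis=1)
        res = sobi_separate(MultichannelData(x))
        np.testing.assert_allclose(
            res.rotation.T @ res.rotation, np.eye(3), atol=1e-10
        )

    def test_invalid_lag_config(self, rng):
        x = rng.standard_normal((2, 100))
        with pytest.raises(InvalidConfigError):
            sobi_separate(MultichannelData(x), SobiConfig(lags=(200,)))
        with pytest.raises(InvalidConfigError):
            SobiConfig(lags=())
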