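"""Analytic signal, complex PCA, varimax rotation, elbow and phase movies."""

import copy
import itertools

import numpy as np
import pytest

import qppdyn as q


def _random_analytic(rng, T=30, V=20):
    X = rng.standard_normal((T, V)) + 1j * rng.standard_normal((T, V))
    return q.AnalyticDataset(X, tr=1.0)


class TestAnalyticSignal:
    def test_cosine_becomes_unit_modulus_phasor(self):
        T = 256
        t = np.arange(T)
        x = np.cos(2 * np.pi * 8 * t / T)  # integer number of cycles
        ds = q.BoldDataset(np.tile(x[:, None], (1, 2)), tr=1.0)
        a = q.analytic_signal(ds)
        np.testing.assert_allclose(np.abs(a.data), 1.0, atol=1e-10)
        np.testing.assert_allclose(a.data[:, 0].real, x, atol=1e-10)

    def test_constant_series_is_zero_after_demeaning(self):
        ds = q.BoldDataset(np.full((16, 3), 4.2), tr=1.0)
        a = q.analytic_signal(ds)
        assert np.abs(a.data).max() < 1e-12

    def test_negative_frequency_energy_suppressed(self, rng):
        ds = q.BoldDataset(rng.standard_normal((64, 5)), tr=1.0)
        a = q.analytic_signal(ds)
        spec = np.fft.fft(a.data, axis=0)
        neg = np.abs(spec[33:]) ** 2  # strictly negative frequencies for T=64
        total = (np.abs(spec) ** 2).sum(axis=0)
        assert (neg.sum(axis=0) / total).max() <= 1e-10

    def test_real_part_equals_demeaned_input(self, rng):
        data = rng.standard_normal((50, 4)) + 7.0
        ds = q.BoldDataset(data, tr=1.0)
        a = q.analytic_signal(ds)
        np.testing.assert_allclose(
            a.data.real, data - data.mean(axis=0), atol=1e-10
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            q.analytic_signal(q.BoldDataset(np.zeros((3, 2)) + np.arange(3)[:, None], tr=1.0))


class TestComplexPca:
    def test_rank_one_input(self):
        u = np.exp(1j * np.linspace(0, 4, 12))
        v = np.linspace(1, 2, 7) * np.exp(1j * 0.3)
        X = np.outer(u, v)
        res = q.complex_pca(q.AnalyticDataset(X, 1.0), 1)
        np.testing.assert_allclose(res.explained_variance_ratio, [1.0], atol=1e-12)

    def test_two_planted_components_with_4_to_1_variance(self):
        rng = np.random.default_rng(0)
        v1 = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        v1 /= np.linalg.norm(v1)
        v2 = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        v2 -= v1 * np.vdot(v1, v2)
        v2 /= np.linalg.norm(v2)
        T = 400
        s1 = rng.standard_normal(T) + 1j * rng.standard_normal(T)
        s2 = rng.standard_normal(T) + 1j * rng.standard_normal(T)
        s1 *= 2.0 / np.sqrt((np.abs(s1) ** 2).mean())
        s2 *= 1.0 / np.sqrt((np.abs(s2) ** 2).mean())
        X = np.outer(s1, v1.conj()) + np.outer(s2, v2.conj())
        res = q.complex_pca(q.AnalyticDataset(X, 1.0), 2)
        # eigendecomposition oracle on the complex covariance
        w = np.linalg.eigvalsh(X.conj().T @ X)[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio[:2], w[:2] / w.sum(), atol=1e-10
        )
        np.testing.assert_allclose(res.explained_variance_ratio, [0.8, 0.2], atol=0.02)

    def test_full_rank_reconstruction(self, rng):
        an = _random_analytic(rng, T=15, V=9)
        res = q.complex_pca(an, 9)
        err = np.abs(res.scores @ res.loadings.conj().T - an.data).max()
        assert err <= 1e-8

    def test_loadings_orthonormal_and_phase_fixed(self, rng):
        an = _random_analytic(rng)
        res = q.complex_pca(an, 5)
        G = res.loadings.conj().T @ res.loadings
        np.testing.assert_allclose(G, np.eye(5), atol=1e-10)
        for k, rec in enumerate(res.phase_convention):
            anchor = res.loadings[rec["anchor_location"], k]
            assert abs(np.angle(anchor)) < 1e-10 and anchor.real > 0

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(1, 9), np.ones(5)).astype(complex)
        with pytest.raises(ValueError, match="rank"):
            q.complex_pca(q.AnalyticDataset(X, 1.0), 3)


class TestVarimax:
    @staticmethod
    def _two_block_loadings(V=40):
        L = np.zeros((V, 2))
        L[: V // 2, 0] = 1.0
        L[V // 2 :, 1] = 1.0
        return L / np.linalg.norm(L, axis=0)

    @staticmethod
    def _result_from_loadings(L):
        K = L.shape[1]
        return q.CpcaResult(
            loadings=np.asarray(L, dtype=complex),
            scores=np.ones((5, K), dtype=complex),
            singular_values=np.ones(K),
            explained_variance_ratio=np.full(K, 1 / K),
            total_variance=float(K),
            rotation=np.eye(K),
        )

    @pytest.mark.parametrize("theta", [0.4, -0.7, 0.15])
    def test_recovers_known_mixing_angle_against_grid_oracle(self, theta):
        L = self._two_block_loadings()
        R0 = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        mixed = L @ R0
        rot = q.varimax_complex(
            self._result_from_loadings(mixed), weight_by_variance=False
        )
        # 1-D grid-search oracle over the rotation angle
        grid = np.linspace(-np.pi / 2, np.pi / 2, 36001)
        crits = [
            q.varimax_criterion(
                mixed @ np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            )
            for t in grid
        ]
        assert rot.criterion_after >= max(crits) - 1e-10
        # recovered loadings equal the simple structure up to permutation/sign
        ok = any(
            np.abs(np.abs(rot.loadings)[:, list(p)] - np.abs(L)).max() < 1e-3
            for p in itertools.permutations(range(2))
        )
        assert ok

    def test_fixed_point_for_simple_structure(self):
        L = self._two_block_loadings() * np.exp(1j * 0.3)
        rot = q.varimax_complex(self._result_from_loadings(L), weight_by_variance=False)
        np.testing.assert_allclose(np.abs(rot.rotation), np.eye(2), atol=1e-8)

    def test_criterion_never_decreases_and_reconstruction_preserved(self, rng):
        for _ in range(25):
            an = _random_analytic(rng)
            res = q.complex_pca(an, 5)
            for weighted in (True, False):
                rot = q.varimax_complex(copy.deepcopy(res), weight_by_variance=weighted)
                assert rot.criterion_after >= rot.criterion_before - 1e-12
                recon = np.abs(
                    rot.scores @ rot.loadings.conj().T
                    - res.scores @ res.loadings.conj().T
                ).max()
                assert recon <= 1e-8

    def test_explained_variance_resorted_descending(self, rng):
        an = _random_analytic(rng, T=60, V=30)
        rot = q.varimax_complex(q.complex_pca(an, 6))
        evr = rot.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        # rotation preserves total retained variance
        before = q.complex_pca(an, 6).explained_variance_ratio.sum()
        np.testing.assert_allclose(evr.sum(), before, atol=1e-10)

    def test_single_component_rejected(self, rng):
        res = q.complex_pca(_random_analytic(rng), 1)
        with pytest.raises(ValueError):
            q.varimax_complex(res)


class TestMagnitudePhase:
    def test_modulus_and_argument(self):
        res = q.CpcaResult(
            loadings=np.eye(2, dtype=complex),
            scores=np.array([[3 + 4j, 0.0]]),
            singular_values=np.array([5.0, 1.0]),
            explained_variance_ratio=np.array([0.9, 0.1]),
            total_variance=1.0,
            rotation=np.eye(2),
        )
        sm = q.component_magnitude_phase(res)
        assert sm.magnitudes[0, 0] == pytest.approx(5.0)
        assert sm.phases[0, 0] == pytest.approx(np.arctan2(4, 3))
        # zero score has phase 0 by convention
        assert sm.magnitudes[0, 1] == 0.0 and sm.phases[0, 1] == 0.0

    def test_noise_free_magnitudes_track_planted_envelope(self, pattern_library):
        specs = [
            q.EnvelopeSpec("linear_ramp", 0.5, 1.5),
            q.EnvelopeSpec("constant", 1e-4),
            q.EnvelopeSpec("constant", 1e-4),
        ]
        ds, gt = q.simulate_subject(pattern_library, specs, 600, 0.72, 0.0, seed=2)
        res = q.complex_pca(q.analytic_signal(ds), 1)
        mags = q.component_magnitude_phase(res).magnitudes[:, 0]
        assert np.corrcoef(mags, gt.envelopes[:, 0])[0, 1] >= 0.99


class TestElbow:
    def test_override_short_circuits(self):
        assert q.select_elbow([0.5, 0.3, 0.1, 0.05], k_override=3) == 3
        with pytest.raises(ValueError):
            q.select_elbow([0.5, 0.3], k_override=5)

    def test_max_distance_rule_matches_hand_computation(self):
        # distances to the chord peak at k=4 for this scree
        # (proportional to 0.705, 1.11, 1.395, 0.93 at k=2..5)
        ratios = [0.5, 0.3, 0.15, 0.02, 0.015, 0.01, 0.005]
        assert q.select_elbow(ratios) == 4

    def test_linear_scree_gives_smallest_k(self):
        r = np.linspace(0.4, 0.1, 6)
        assert q.select_elbow(r / r.sum()) == 1

    def test_increasing_ratios_rejected(self):
        with pytest.raises(ValueError):
            q.select_elbow([0.2, 0.5, 0.3])


class TestPhaseMovie:
    @staticmethod
    def _result(loadings):
        K = loadings.shape[1]
        return q.CpcaResult(
            loadings=loadings.astype(complex),
            scores=np.zeros((4, K), dtype=complex),
            singular_values=np.ones(K),
            explained_variance_ratio=np.full(K, 1 / K),
            total_variance=1.0,
            rotation=np.eye(K),
        )

    def test_real_loading_gives_cosine_frames(self):
        l = np.array([[1.0], [0.5], [2.0]])
        frames = q.reconstruct_phase_movie(self._result(l), 0, n_bins=8)
        theta = 2 * np.pi * np.arange(8) / 8
        np.testing.assert_allclose(frames, l * np.cos(theta)[None, :], atol=1e-12)

    def test_anti_phase_locations_are_exact_negatives(self):
        l = np.array([1.0 * np.exp(1j * 0.0), 1.0 * np.exp(1j * np.pi)])[:, None]
        frames = q.reconstruct_phase_movie(self._result(l), 0, n_bins=12)
        np.testing.assert_allclose(frames[0], -frames[1], atol=1e-12)

    def test_linear_phase_gradient_propagates(self):
        V, B = 32, 32
        phases = np.linspace(0, 2 * np.pi, V, endpoint=False)
        l = np.exp(1j * phases)[:, None]
        frames = q.reconstruct_phase_movie(self._result(l), 0, n_bins=B)
        peaks = frames.argmax(axis=0)
        # peak advances by one location per phase bin (circularly)
        steps = np.diff(np.concatenate([peaks, peaks[:1]])) % V
        assert set(steps) <= {V - 1, 0}  # monotone circular propagation
        assert (steps == V - 1).sum() >= B - 2

    def test_invalid_arguments(self, rng):
        res = self._result(np.ones((4, 2)))
        with pytest.raises(ValueError):
            q.reconstruct_phase_movie(res, 5)
        with pytest.raises(ValueError):
            q.reconstruct_phase_movie(res, 0, n_bins=3)


def test_small_matrix_oracle_equivalence(rng):
    """Loadings and ratios match a complex-covariance eigendecomposition oracle."""
    for _ in range(25):
        T = int(rng.integers(6, 13))
        V = int(rng.integers(4, 13))
        X = rng.standard_normal((T, V)) + 1j * rng.standard_normal((T, V))
        K = min(T, V)
        res = q.complex_pca(q.AnalyticDataset(X, 1.0), K)
        w, Vecs = np.linalg.eigh(X.conj().T @ X)
        w, Vecs = w[::-1], Vecs[:, ::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, w[:K] / w.sum(), atol=1e-8
        )
        for k in range(K):
            a, b = res.loadings[:, k], Vecs[:, k]
            b = b * np.exp(1j * np.angle(np.vdot(b, a)))
            assert np.abs(a - b).max() <= 1e-7
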