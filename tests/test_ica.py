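"""Group ICA: PCA reduction, Infomax recovery, ICASSO stability, dual
regression, component selection."""

import numpy as np
import pytest

from dynfc.ica import (GroupICA, amari_index, back_reconstruct,
                       flag_noise_components, icasso_stability, infomax_ica,
                       select_components, two_stage_pca)
from dynfc.simulate import make_spatial_maps


def super_gaussian_mixture(n_sources=3, n_samples=5000, seed=0):
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((n_sources, n_samples)) ** 3
    A = rng.standard_normal((n_sources, n_sources)) + 0.5 * np.eye(n_sources)
    return A @ S, A, S


def matched_correlation(est_maps, true_maps):
    """Mean spatial |r| under greedy max-correlation assignment."""
    C = np.abs(np.corrcoef(np.vstack([est_maps, true_maps]))
               [:len(est_maps), len(est_maps):])
    out = []
    C = C.copy()
    for _ in range(min(C.shape)):
        i, j = np.unravel_index(C.argmax(), C.shape)
        out.append(C[i, j])
        C[i, :] = -1
        C[:, j] = -1
    return float(np.mean(out))


class TestTwoStagePCA:
    def _structured_subjects(self, n_subj=6, T=60, V=200, rank=8, seed=0):
        # fast-decaying spectrum so 95% variance needs < 30 directions
        rng = np.random.default_rng(seed)
        subs = []
        for _ in range(n_subj):
            U = rng.standard_normal((T, rank))
            Vt = rng.standard_normal((rank, V))
            s = 3.0 ** -np.arange(rank)
            subs.append((U * s) @ Vt + 0.01 * rng.standard_normal((T, V)))
        return subs

    def test_group_dimension_default(self):
        subs = self._structured_subjects(n_subj=10, rank=25)
        red, G = two_stage_pca(subs)
        assert G.shape[0] == 20
        assert red.n_group_components == 20

    def test_subject_variance_retained(self):
        subs = self._structured_subjects()
        red, _ = two_stage_pca(subs, n_group_components=5)
        assert all(v >= 0.95 for v in red.subject_variance_retained)

    def test_exact_low_rank(self):
        rng = np.random.default_rng(1)
        subs = [rng.standard_normal((40, 3)) @ rng.standard_normal((3, 100))
                for _ in range(3)]
        red, G = two_stage_pca(subs, n_group_components=3)
        assert all(d <= 3 for d in red.subject_dims)
        # reconstruction from the retained subject basis is exact
        X = subs[0] - subs[0].mean(0)
        U = red.subject_bases[0]
        assert np.allclose(U @ (U.T @ X), X, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(2)
        subs = [rng.standard_normal((10, 2)) @ rng.standard_normal((2, 50))
                for _ in range(2)]
        with pytest.raises(ValueError):
            two_stage_pca(subs, n_group_components=10)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            two_stage_pca([np.zeros((10, 20))])


class TestInfomax:
    def test_recovers_super_gaussian_sources(self):
        X, A, _ = super_gaussian_mixture()
        W, S, info = infomax_ica(X, 3, seed=1)
        assert info["converged"]
        assert amari_index(W, A) < 0.05

    def test_whitening_spheres_data(self):
        from dynfc.ica import _whiten
        rng = np.random.default_rng(3)
        X = rng.standard_normal((4, 2000)) * np.array([[3.0, 1, 0.5, 2]]).T
        Xw, K, _ = _whiten(X, 4)
        cov = Xw @ Xw.T / Xw.shape[1]
        assert np.allclose(cov, np.eye(4), atol=1e-8)

    def test_sources_unit_variance_sign_fixed(self):
        X, _, _ = super_gaussian_mixture(seed=4)
        _, S, _ = infomax_ica(X, 3, seed=0)
        assert np.allclose(S.std(axis=1), 1.0)
        for row in S:
            assert row[np.abs(row).argmax()] > 0

    def test_seed_determinism(self):
        X, _, _ = super_gaussian_mixture(seed=5)
        W1, _, _ = infomax_ica(X, 3, seed=9)
        W2, _, _ = infomax_ica(X, 3, seed=9)
        assert np.array_equal(W1, W2)

    def test_amari_index_extremes(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((4, 4))
        assert amari_index(np.linalg.inv(A), A) == pytest.approx(0.0, abs=1e-12)
        assert amari_index(np.ones((4, 4)), np.eye(4)) > 0.5


class TestIcasso:
    @pytest.fixture(scope="class")
    def stable_mixture(self):
        maps = make_spatial_maps(4, (16, 16, 8), 1.5, seed=2)
        rng = np.random.default_rng(3)
        mix = rng.standard_normal((10, 4))
        return mix @ (maps - maps.mean(1, keepdims=True)) \
            + 0.02 * rng.standard_normal((10, maps.shape[1]))

    def test_identical_runs_unit_quality(self, stable_mixture):
        report, _ = icasso_stability(stable_mixture, 4, n_runs=4, seed=0,
                                     force_identical=True)
        assert np.allclose(report.intra_similarity, 1.0)
        assert report.iq.min() > 0.9

    def test_stable_fixture_high_iq(self, stable_mixture):
        report, consensus = icasso_stability(stable_mixture, 4, n_runs=6,
                                             seed=1)
        assert report.iq.min() > 0.9
        assert consensus.shape[0] == 4

    def test_noise_less_stable_than_signal(self, stable_mixture):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal((10, stable_mixture.shape[1]))
        rep_noise, _ = icasso_stability(noise, 4, n_runs=6, seed=1)
        rep_stable, _ = icasso_stability(stable_mixture, 4, n_runs=6, seed=1)
        assert np.nanmean(rep_noise.iq) < np.nanmean(rep_stable.iq)

    def test_requires_two_runs(self, stable_mixture):
        with pytest.raises(ValueError):
            icasso_stability(stable_mixture, 4, n_runs=1)


class TestBackReconstruct:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        maps = make_spatial_maps(4, (10, 10, 4), 1.5, seed=1)
        tc = rng.standard_normal((80, 4))
        comps = back_reconstruct(maps, tc @ maps)
        for k in range(4):
            r = np.corrcoef(comps.timecourses[:, k], tc[:, k])[0, 1]
            assert abs(r) > 0.999

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        maps = make_spatial_maps(3, (10, 10), 1.5, seed=2)
        X = rng.standard_normal((50, 3)) @ maps \
            + 0.1 * rng.standard_normal((50, 100))
        a = back_reconstruct(maps, X)
        b = back_reconstruct(maps * np.array([[2.0], [1.0], [0.5]]), X)
        for k in range(3):
            r = np.corrcoef(a.timecourses[:, k], b.timecourses[:, k])[0, 1]
            assert abs(r) > 1 - 1e-9

    def test_subject_map_recovery_at_snr2(self, small_cohort):
        comps = back_reconstruct(small_cohort.spatial_maps,
                                 small_cohort.voxel_series[0])
        assert matched_correlation(comps.subject_maps,
                                   small_cohort.spatial_maps) > 0.8

    def test_collinear_maps_rejected(self):
        maps = np.vstack([np.ones((1, 50)), np.ones((1, 50))])
        with pytest.raises(ValueError):
            back_reconstruct(maps, np.zeros((10, 50)))


class TestSelectComponents:
    def _components(self, K=20, T=100):
        rng = np.random.default_rng(0)
        from dynfc.ica import SubjectComponents
        return SubjectComponents(subject_maps=rng.standard_normal((K, 50)),
                                 timecourses=rng.standard_normal((T, K)))

    def test_keep_subset(self):
        out = select_components(self._components(), keep_list=list(range(15)))
        assert out.subject_maps.shape[0] == 15
        assert out.timecourses.shape[1] == 15
        from dynfc.connectivity import static_fc
        assert static_fc(out.timecourses).shape == (105,)

    def test_keep_all_identity(self):
        comps = self._components(K=6)
        out = select_components(comps)
        assert np.array_equal(out.subject_maps, comps.subject_maps)

    def test_spectral_heuristic(self):
        tr = 2.0
        t = np.arange(200) * tr
        slow = np.sin(2 * np.pi * 0.03 * t)
        fast = np.sin(2 * np.pi * 0.2 * t)
        tc = np.column_stack([slow, fast])
        flags = flag_noise_components(tc, tr=tr)
        assert list(flags) == [False, True]
        from dynfc.ica import SubjectComponents
        comps = SubjectComponents(subject_maps=np.zeros((2, 10)),
                                  timecourses=tc)
        out = select_components(comps, heuristic=True, tr=tr)
        assert list(out.kept_indices) == [0]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            select_components(self._components(), keep_list=[])


class TestGroupICAEndToEnd:
    def test_recovers_ground_truth_networks(self, small_cohort):
        ica = GroupICA(n_components=5, icasso_runs=4,
                       random_state=0).fit(small_cohort.voxel_series)
        assert matched_correlation(ica.group_maps_,
                                   small_cohort.spatial_maps) > 0.8

    def test_transform_requires_fit(self, small_cohort):
        with pytest.raises(RuntimeError):
            GroupICA().transform(small_cohort.voxel_series[:1])

    def test_keep_list_restricts_maps(self, small_cohort):
        ica = GroupICA(n_components=5, icasso_runs=2, keep_list=[0, 1, 2],
                       random_state=0).fit(small_cohort.voxel_series)
        assert ica.group_maps_.shape[0] == 3
        comps = ica.transform(small_cohort.voxel_series[:1])
        assert comps[0].timecourses.shape == (100, 3)
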