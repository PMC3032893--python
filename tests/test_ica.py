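import numpy as np
import pytest
from scipy import stats

import tractica as tr
from tractica.ica import _fastica_core, _preprocess_rows, _assemble_matrix

from conftest import match_components


class TestRecovery:
    def test_noise_free_phantom_components_recovered(self, noise_free_group):
        ph, group = noise_free_group
        model = tr.GroupICA(n_components=3, random_state=0).fit(group)
        truth = [b.pathway_map for b in ph.bundles]
        est = [model.component_volume(k, ph.grid_shape)
               for k in range(3)]
        _, _, corrs = match_components(truth, est)
        assert np.all(corrs >= 0.95)

    def test_subject_amplitudes_recovered(self, default_phantom,
                                          fitted_ica):
        # amplitude-only subject variability: subject loadings must track
        # the planted per-subject amplitudes after component matching
        ph = default_phantom
        truth = [b.pathway_map for b in ph.bundles]
        est = [fitted_ica.component_volume(k, ph.grid_shape)
               for k in range(3)]
        ri, ci, _ = match_components(truth, est)
        for i, j in zip(ri, ci):
            r = abs(np.corrcoef(ph.bundles[i].subject_amplitudes,
                                fitted_ica.subject_loadings_[j])[0, 1])
            assert r >= 0.9

    def test_rank1_fraction_is_one_on_rank1_mixing(self):
        rng = np.random.default_rng(0)
        src = rng.laplace(size=500)
        seed_w = np.array([1.0, 2.0, 3.0, 4.0])
        subj_w = np.array([1.0, 0.5])
        data = (subj_w[:, None, None] * seed_w[None, :, None]
                * src[None, None, :])
        model = tr.GroupICA(n_components=1, var_norm=False,
                            random_state=0).fit(data)
        assert model.rank1_fit_fraction_[0] == pytest.approx(1.0, abs=1e-9)


class TestConventions:
    def test_unit_variance_positive_skew_maps(self, fitted_ica):
        sds = fitted_ica.components_.std(axis=1)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)
        assert np.all(stats.skew(fitted_ica.components_, axis=1) >= 0)

    def test_subject_loadings_unit_norm(self, fitted_ica):
        norms = np.linalg.norm(fitted_ica.subject_loadings_, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_deterministic_under_fixed_seed(self, noise_free_group):
        _, group = noise_free_group
        a = tr.GroupICA(n_components=3, random_state=1).fit(group)
        b = tr.GroupICA(n_components=3, random_state=1).fit(group)
        np.testing.assert_array_equal(a.components_, b.components_)
        np.testing.assert_array_equal(a.seed_loadings_, b.seed_loadings_)

    def test_reconstruction_within_truncation_loss(self, noise_free_group):
        # whitened data ~ mixing x maps; on rank-3 data with k=3 the
        # residual is the (zero) truncation loss
        _, group = noise_free_group
        model = tr.GroupICA(n_components=3, random_state=0).fit(group)
        M, _, _ = _assemble_matrix(group)
        M = _preprocess_rows(M)
        recon = model.mixing_ @ model.components_
        rel = np.linalg.norm(M - recon) / np.linalg.norm(M)
        assert rel < 1e-6

    def test_degenerate_stack_rejected(self):
        data = np.zeros((2, 5, 100))
        with pytest.raises(ValueError, match="degenerate"):
            tr.GroupICA(n_components=2).fit(data)

    def test_too_many_components_rejected(self):
        data = np.random.default_rng(0).normal(size=(1, 4, 50))
        with pytest.raises(ValueError, match="n_components"):
            tr.GroupICA(n_components=4).fit(data)


class TestOrderEstimation:
    def test_rank3_noise_free_gives_3(self, noise_free_group):
        _, group = noise_free_group
        assert tr.estimate_n_components(group) == 3

    @pytest.mark.parametrize("rep", range(20))
    def test_iid_noise_gives_at_most_2(self, rep):
        arr = np.random.default_rng(rep).normal(size=(1, 60, 2000))
        assert tr.estimate_n_components(arr) <= 2

    def test_floor_of_one(self):
        arr = np.random.default_rng(0).normal(size=(1, 20, 500))
        assert tr.estimate_n_components(arr, multiplier=1e12) == 1

    def test_too_few_eigenvalues_rejected(self):
        arr = np.random.default_rng(0).normal(size=(1, 2, 50))
        with pytest.raises(ValueError, match="eigenvalues"):
            tr.estimate_n_components(arr)

    def test_auto_falls_back_on_flat_spectrum(self):
        arr = np.random.default_rng(1).normal(size=(1, 40, 800))
        with pytest.warns(UserWarning, match="eigen-gap"):
            model = tr.GroupICA(n_components="auto",
                                default_components=2,
                                random_state=0).fit(arr)
        assert model.n_components_ == 2


def test_fastica_core_agrees_with_sklearn():
    # independent cross-check of the fixed-point core against sklearn's
    # FastICA on the same whitened data
    from sklearn.decomposition import FastICA
    rng = np.random.default_rng(5)
    S_true = rng.laplace(size=(3, 4000))
    A = rng.normal(size=(12, 3))
    X = A @ S_true
    X -= X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Z = Vt[:3] * np.sqrt(X.shape[1])
    W, converged, _ = _fastica_core(Z, tol=1e-6, max_iter=1000,
                                    rng=np.random.default_rng(0))
    assert converged
    mine = W @ Z
    sk = FastICA(n_components=3, whiten="unit-variance", random_state=0,
                 fun="logcosh").fit_transform(X.T).T
    _, _, corrs = match_components(list(mine), list(sk))
    assert np.all(corrs > 0.99)
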