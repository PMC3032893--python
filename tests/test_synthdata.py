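import numpy as np
import pytest

import tractica as tr
from tractica.synthdata import seed_scan_order


class TestMakePhantom:
    def test_pathway_maps_unit_sum(self, default_phantom):
        assert len(default_phantom.bundles) == 3
        for b in default_phantom.bundles:
            assert b.pathway_map.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(b.pathway_map >= 0)

    def test_subregions_inside_seed_mask(self, default_phantom):
        for b in default_phantom.bundles:
            assert not np.any(b.seed_subregion & ~default_phantom.seed_mask)
            assert b.seed_subregion.sum() > 0

    def test_deterministic_for_fixed_seed(self):
        a = tr.make_phantom(n_bundles=3, n_subjects=5, rng_seed=1)
        b = tr.make_phantom(n_bundles=3, n_subjects=5, rng_seed=1)
        np.testing.assert_array_equal(a.seed_mask, b.seed_mask)
        for ba, bb in zip(a.bundles, b.bundles):
            np.testing.assert_array_equal(ba.pathway_map, bb.pathway_map)
            np.testing.assert_array_equal(ba.seed_subregion,
                                          bb.seed_subregion)
            np.testing.assert_array_equal(ba.subject_amplitudes,
                                          bb.subject_amplitudes)
        np.testing.assert_array_equal(a.orientation_field.directions,
                                      b.orientation_field.directions)

    def test_overlap_produces_shared_seed_voxels(self):
        # brute-force count of voxels in pairwise subregion intersections
        ph = tr.make_phantom(n_bundles=4, overlap=0.3, rng_seed=7)
        subs = [b.seed_subregion for b in ph.bundles]
        shared = 0
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                shared += int(np.sum(subs[i] & subs[j]))
        assert shared >= 1

    def test_default_subregions_disjoint(self, default_phantom):
        counts = np.sum([b.seed_subregion for b in
                         default_phantom.bundles], axis=0)
        assert counts.max() == 1

    def test_target_rois_cover_bundle_endpoints(self, default_phantom):
        for b in default_phantom.bundles:
            assert len(b.target_roi_ids) >= 1

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            tr.make_phantom(grid_shape=(8, 8, 8))

    def test_too_many_bundles_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            tr.make_phantom(n_bundles=8)
        ph = tr.make_phantom(n_bundles=8, allow_shared_targets=True)
        assert len(ph.bundles) == 8


class TestDirectSampling:
    def test_single_bundle_large_n_matches_pathway(self):
        # law of large numbers: empirical tractogram converges on the
        # pathway density (amplitude fixed at 1, no noise floor)
        ph = tr.make_phantom(n_bundles=1, n_subjects=1,
                             amplitude_sigma=0.0, noise_floor=0.0,
                             rng_seed=3)
        stacks = tr.sample_tractograms_direct(ph, 100_000, rng_seed=4)
        seeds = seed_scan_order(ph.seed_mask)
        owned = ph.bundles[0].seed_subregion[tuple(seeds.T)]
        v = int(np.flatnonzero(owned)[0])
        emp = stacks[0].data[..., v].ravel()
        r = np.corrcoef(emp / emp.sum(),
                        ph.bundles[0].pathway_map.ravel())[0, 1]
        assert r > 0.99

    def test_zero_streamlines_rejected(self, default_phantom):
        with pytest.raises(ValueError):
            tr.sample_tractograms_direct(default_phantom, 0)

    def test_same_subregion_seeds_share_expectation(self, default_phantom):
        ph = default_phantom
        sub = ph.bundles[0].seed_subregion
        vox = np.argwhere(sub)[:2]
        m0 = tr.expected_rate_map(ph, vox[0], subject=0)
        m1 = tr.expected_rate_map(ph, vox[1], subject=0)
        np.testing.assert_array_equal(m0, m1)

    def test_unowned_seed_is_pure_noise_floor(self, default_phantom):
        ph = default_phantom
        owned = np.zeros(ph.grid_shape, bool)
        for b in ph.bundles:
            owned |= b.seed_subregion
        free = np.argwhere(ph.seed_mask & ~owned)[0]
        assert tr.expected_rate_map(ph, free, subject=0).sum() == 0

    def test_deterministic_sampling(self, default_phantom):
        a = tr.sample_tractograms_direct(default_phantom, 200, rng_seed=9)
        b = tr.sample_tractograms_direct(default_phantom, 200, rng_seed=9)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[-1].data, b[-1].data)

    def test_noise_free_disjoint_matrix_has_rank_k(self):
        ph = tr.make_phantom(n_subjects=1, noise_floor=0.0, rng_seed=5)
        stacks = tr.sample_tractograms_direct(ph, 5000, rng_seed=6,
                                              noise="none")
        mat = stacks[0].data.reshape(-1, stacks[0].n_seeds).T
        assert np.linalg.matrix_rank(mat) == len(ph.bundles)

    def test_scan_order_x_fastest(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = mask[0, 1, 0] = True
        seeds = seed_scan_order(mask)
        np.testing.assert_array_equal(seeds,
                                      [[0, 0, 0], [1, 0, 0], [0, 1, 0]])


def test_write_phantom_roundtrip(tmp_path, default_phantom):
    from tractica.stack import load_volume
    tr.synthdata.write_phantom(default_phantom, tmp_path)
    assert (tmp_path / "ground_truth.json").exists()
    mask = load_volume(tmp_path / "seed_mask.nii")
    np.testing.assert_array_equal(mask.astype(bool),
                                  default_phantom.seed_mask)
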