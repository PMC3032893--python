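import numpy as np
import pytest

import tractica as tr
from tractica.hardseg import (TargetCountTable, UNCLASSIFIED,
                              sign_flip_pvalues, winner_takes_all)


def table(rows, names=("a", "b", "c")):
    return TargetCountTable(counts=np.asarray(rows), target_names=names)


class TestWinnerTakesAll:
    def test_argmax_row(self):
        seg = winner_takes_all(table([[10, 3, 0]]))
        assert seg.labels[0] == 0

    def test_tie_goes_to_lowest_index_and_is_counted(self):
        seg = winner_takes_all(table([[5, 5, 0]]))
        assert seg.labels[0] == 0
        assert seg.n_ties == 1

    def test_all_zero_row_unclassified(self):
        seg = winner_takes_all(table([[0, 0, 0]]))
        assert seg.labels[0] == UNCLASSIFIED

    def test_min_count_gate(self):
        seg = winner_takes_all(table([[2, 1, 0]]), min_count=3)
        assert seg.labels[0] == UNCLASSIFIED

    def test_matches_per_row_argmax_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(1000, 5))
        seg = winner_takes_all(
            TargetCountTable(counts=counts,
                             target_names=tuple("abcde")))
        for row, lab in zip(counts, seg.labels):
            expected = UNCLASSIFIED if row.max() < 1 else int(np.argmax(row))
            assert lab == expected


class TestCountTargetHits:
    def make_stack(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 5, size=(6, 6, 6, 4)).astype(float)
        return tr.TractogramStack(data=data,
                                  seed_table=[[0, 0, i] for i in range(4)])

    def rois(self):
        a = np.zeros((6, 6, 6), bool)
        a[0] = True
        b = np.zeros((6, 6, 6), bool)
        b[5] = True
        empty = np.zeros((6, 6, 6), bool)
        return {"a": a, "b": b, "empty": empty}

    def test_mass_fallback_counts_roi_sums(self):
        stack = self.make_stack()
        t = tr.count_target_hits(stack, self.rois())
        for v in range(4):
            assert t.counts[v, 0] == stack.data[0, :, :, v].sum()

    def test_empty_roi_gives_zero_column(self):
        t = tr.count_target_hits(self.make_stack(), self.rois())
        assert np.all(t.counts[:, 2] == 0)

    def test_target_order_permutes_columns(self):
        rois = self.rois()
        t1 = tr.count_target_hits(self.make_stack(), rois)
        rev = dict(reversed(list(rois.items())))
        t2 = tr.count_target_hits(self.make_stack(), rev)
        np.testing.assert_array_equal(t1.counts, t2.counts[:, ::-1])

    def test_tracker_target_mode_hits_used_exactly(self):
        # streamline route: straight-x field, every streamline reaches the
        # far face and none the near one
        shape = (9, 9, 9)
        dirs = np.zeros(shape + (3,))
        dirs[..., 0] = 1.0
        field = tr.OrientationField(directions=dirs,
                                    concentration=np.full(shape, np.inf))
        mask = np.zeros(shape, bool)
        mask[4, 4, 4] = True
        far = np.zeros(shape, bool)
        far[8] = True
        near = np.zeros(shape, bool)
        near[0] = True
        params = tr.TrackingParams(n_streamlines=17, max_steps=50,
                                   rng_seed=0)
        stack = tr.track_all_seeds(field, mask, params,
                                   target_rois={"far": far, "near": near})
        t = tr.count_target_hits(stack, {"far": far, "near": near})
        assert t.counts[0, 0] == 17
        assert t.counts[0, 1] == 0


class TestSignFlip:
    def test_full_enumeration_minimal_p(self):
        # S=12 identical positive maps: only the identity sign pattern
        # reaches t = +inf, so p = 1 / 2^12
        data = np.ones((12, 3))
        p = sign_flip_pvalues(data, n_permutations=4096)
        np.testing.assert_allclose(p, 1 / 2 ** 12)

    def test_absent_voxel_never_significant(self):
        data = np.zeros((12, 2))
        data[:, 1] = 1.0
        p = sign_flip_pvalues(data, n_permutations=4096)
        assert p[0] == 1.0

    def test_superuniform_on_gaussian_null(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(8, 4000))
        p = sign_flip_pvalues(data, n_permutations=4096)  # full: 2^8=256
        for alpha in (0.05, 0.2):
            rate = np.mean(p < alpha)
            se = np.sqrt(alpha * (1 - alpha) / 4000)
            assert rate <= alpha + 2 * se

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            sign_flip_pvalues(np.ones((1, 5)))


class TestGroupHardSegmentation:
    def segs(self, labels, names=("a", "b")):
        return [tr.HardSegmentation(labels=np.asarray(l),
                                    target_names=names,
                                    subject_id=str(i))
                for i, l in enumerate(labels)]

    def test_unanimous_label_survives_full_enumeration(self):
        labels = [[0, 1, UNCLASSIFIED]] * 12
        maps = tr.group_hard_segmentation(self.segs(labels),
                                          n_permutations=4096)
        np.testing.assert_array_equal(maps["a"], [True, False, False])
        np.testing.assert_array_equal(maps["b"], [False, True, False])

    def test_monte_carlo_floor_warning(self):
        labels = [[0, 0]] * 5
        with pytest.warns(UserWarning, match="floor"):
            tr.group_hard_segmentation(self.segs(labels),
                                       n_permutations=16, alpha=0.001)

    def test_disagreeing_names_rejected(self):
        segs = self.segs([[0], [0]])
        segs[1].target_names = ("x", "y")
        with pytest.raises(ValueError, match="target names"):
            tr.group_hard_segmentation(segs)
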