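"""Winner-takes-all hard segmentation and the group sign-flip t-test.

The comparison method: every seed voxel is labelled by the cortical target
receiving the greatest number of its streamlines (winner-takes-all),
per subject; group maps are then formed per target by a voxelwise
one-sample t-test of the binarised per-subject memberships, assessed by
sign-flipping permutation, keeping seeds with an uncorrected p < alpha
(0.001 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .stack import TractogramStack

logger = logging.getLogger(__name__)

UNCLASSIFIED = -1


@dataclass
class TargetCountTable:
    counts: np.ndarray                  # (n_seeds, n_targets), int
    target_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(
                self.target_names):
            raise ValueError("counts must be (n_seeds, n_targets)")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")


@dataclass
class HardSegmentation:
    labels: np.ndarray                  # per-seed target index or -1
    target_names: tuple[str, ...]
    subject_id: str = ""
    n_ties: int = 0


def count_target_hits(stack: TractogramStack,
                      rois: dict[str, np.ndarray]) -> TargetCountTable:
    """Streamline hit counts per (seed, target).

    When the stack was tracked in target mode the tracker's per-streamline
    ROI hit records are used directly (a hit = a surviving streamline whose
    path intersects the target; overlapping targets may share streamlines).
    For direct-sampled stacks, which have no individual streamlines, the
    visitation-count mass inside each ROI stands in for the hit count.
    """
    names = tuple(rois)
    for name, roi in rois.items():
        if roi.shape != stack.grid_shape:
            raise ValueError(f"ROI {name!r} grid mismatch")
    if stack.target_hits is not None and stack.target_names is not None:
        cols = []
        for name in names:
            if name in stack.target_names:
                cols.append(stack.target_hits[
                    :, stack.target_names.index(name)])
            else:
                cols.append(np.zeros(stack.n_seeds, dtype=int))
        counts = np.stack(cols, axis=1)
    else:
        flat = stack.data.reshape(-1, stack.n_seeds)
        counts = np.stack(
            [flat[roi.ravel().astype(bool)].sum(axis=0) for roi in
             rois.values()], axis=1)
        counts = np.rint(counts).astype(np.int64)
    return TargetCountTable(counts=counts, target_names=names)


def winner_takes_all(table: TargetCountTable,
                     min_count: int = 1,
                     subject_id: str = "") -> HardSegmentation:
    """Label each seed by the target with the largest count; below
    ``min_count`` the seed is UNCLASSIFIED (-1).  Ties go to the lowest
    target index and are counted in ``n_ties``."""
    counts = table.counts
    labels = np.argmax(counts, axis=1)          # lowest index wins ties
    best = counts[np.arange(len(counts)), labels]
    labels = np.where(best >= min_count, labels, UNCLASSIFIED)
    is_tie = (counts == best[:, None]).sum(axis=1) > 1
    n_ties = int(np.sum(is_tie & (best >= min_count)))
    if n_ties:
        logger.info("winner_takes_all: %d tied seeds (lowest index kept)",
                    n_ties)
    return HardSegmentation(labels=labels, target_names=table.target_names,
                            subject_id=subject_id, n_ties=n_ties)


def sign_flip_pvalues(data: np.ndarray, n_permutations: int = 4096,
                      rng_seed: int = 0, chunk: int = 4096) -> np.ndarray:
    """One-sided sign-flipping permutation p-values for a voxelwise
    one-sample t-test against zero.

    ``data`` is (n_subjects, n_voxels).  The null is built by flipping the
    sign of whole subjects: full enumeration of the 2^S patterns when
    2^S <= n_permutations, otherwise Monte Carlo with the identity pattern
    counted (p = (1 + #{t_perm >= t_obs}) / (n_draws + 1)).  Degenerate
    voxels: zero variance with positive mean gives t = +inf (only the
    all-positive pattern matches); an all-zero voxel gives t = 0 and can
    never be significant.
    """
    data = np.asarray(data, dtype=float)
    S, n_vox = data.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    full = 2 ** S <= n_permutations
    if full:
        bits = np.arange(2 ** S)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(S)) & 1)
    else:
        rng = np.random.default_rng(rng_seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, S))

    def t_from_means(means, ss):
        var = (ss - S * means ** 2) / (S - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / S)
        t = np.where(var > 0, t,
                     np.where(means > 0, np.inf,
                              np.where(means < 0, -np.inf, 0.0)))
        return t

    pvals = np.empty(n_vox)
    for start in range(0, n_vox, chunk):
        block = data[:, start:start + chunk]
        ss = np.sum(block ** 2, axis=0)         # invariant under sign flips
        t_obs = t_from_means(block.mean(axis=0), ss)
        means = (signs @ block) / S
        t_perm = t_from_means(means, ss[None, :])
        exceed = np.sum(t_perm >= t_obs[None, :], axis=0)
        if full:
            pvals[start:start + chunk] = exceed / len(signs)
        else:
            pvals[start:start + chunk] = (1 + exceed) / (len(signs) + 1)
    return pvals


def group_hard_segmentation(per_subject: list[HardSegmentation],
                            n_permutations: int = 4096,
                            alpha: float = 0.001,
                            rng_seed: int = 0) -> dict[str, np.ndarray]:
    """Group-level hard segmentation: per target, binarise each subject's
    membership, test the mean against zero by sign-flip permutation and
    keep seeds with p < alpha (strict).  Returns target -> binary seed
    vector."""
    if len(per_subject) < 2:
        raise ValueError("need at least 2 subjects")
    names = per_subject[0].target_names
    for seg in per_subject[1:]:
        if seg.target_names != names:
            raise ValueError("subjects disagree on target names")
    S = len(per_subject)
    if 2 ** S > n_permutations and S < 10:
        floor = 1.0 / (n_permutations + 1)
        if floor > alpha:
            warnings.warn(
                f"with {S} subjects and Monte Carlo permutation the "
                f"p-value floor {floor:.2g} exceeds alpha={alpha}")
    labels = np.stack([seg.labels for seg in per_subject], axis=0)
    out = {}
    for t, name in enumerate(names):
        membership = (labels == t).astype(float)
        p = sign_flip_pvalues(membership, n_permutations=n_permutations,
                              rng_seed=rng_seed)
        out[name] = p < alpha
    return out
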