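"""Seed-space Z maps, anatomical classification and the ICA parcellation.

Each component's seed loadings say how strongly every seed voxel's
tractogram expresses that component.  Standardising them -- the distance of
each seed's loading from the mean loading, in units of (sample) standard
deviation -- gives a Z statistic over seed voxels; seeds with Z above a
one-sided threshold (3.09 by default, the standard-normal quantile at
p = 0.001) are the seed cluster of the component.  Components are then
classified anatomically by which target ROIs their thresholded spatial map
passes through (a map straddling several ROIs contributes to all of them),
and the per-ROI union of significant seed sets is the ICA parcellation of
the seed structure.  A seed voxel may belong to several components and
hence to several ROI maps: there is deliberately no constraint that a seed
voxel joins exactly one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ica import GroupICA
from .mixture import GaussianGammaMixture, threshold_map

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.09


def z_for_p(p: float) -> float:
    """One-sided standard-normal quantile for tail probability ``p``
    (p = 0.001 -> 3.09...)."""
    return float(stats.norm.isf(p))


@dataclass
class SeedZMap:
    z: np.ndarray
    threshold: float
    significant_seeds: np.ndarray
    component_id: int


@dataclass
class ComponentClassification:
    component_id: int
    roi_labels: frozenset[str]


def seed_zmap(components, k: int,
              threshold: float = DEFAULT_Z_THRESHOLD) -> SeedZMap:
    """Standardise component ``k``'s seed loadings into a Z map and keep
    seeds strictly above the one-sided threshold.

    ``components`` is a fitted :class:`~tractica.ica.GroupICA` or a
    (n_components, n_seeds) loadings array.  The sample standard deviation
    uses the n-1 denominator.  By construction z is invariant to affine
    rescaling w -> a w + b (a > 0) of the loadings.
    """
    loadings = getattr(components, "seed_loadings_", components)
    w = np.asarray(loadings[k], dtype=float)
    if len(w) < 3:
        raise ValueError("need at least 3 seeds for a Z map")
    sd = w.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(w).max())):
        raise ValueError("constant seed loadings: zero standard deviation")
    z = (w - w.mean()) / sd
    return SeedZMap(z=z, threshold=float(threshold),
                    significant_seeds=z > threshold, component_id=k)


def classify_component(thresholded_map: np.ndarray,
                       rois: dict[str, np.ndarray],
                       min_overlap_voxels: int = 1,
                       component_id: int = -1) -> ComponentClassification:
    """Label a thresholded component map with every ROI it passes through
    (intersection of at least ``min_overlap_voxels`` voxels)."""
    tm = np.asarray(thresholded_map).astype(bool)
    if not tm.any():
        logger.info("component %d: empty thresholded map, no labels",
                    component_id)
    labels = set()
    for name, roi in rois.items():
        if roi.shape != tm.shape:
            raise ValueError(f"ROI {name!r} grid mismatch")
        if int(np.sum(tm & roi.astype(bool))) >= min_overlap_voxels:
            labels.add(name)
    return ComponentClassification(component_id=component_id,
                                   roi_labels=frozenset(labels))


def ica_parcellation(components: GroupICA, rois: dict[str, np.ndarray],
                     z_threshold: float = DEFAULT_Z_THRESHOLD,
                     grid_shape=None, posterior_cut: float = 0.5,
                     min_overlap_voxels: int = 1,
                     ) -> tuple[dict[str, np.ndarray],
                                list[ComponentClassification],
                                list[SeedZMap]]:
    """Parcellate the seed structure by ROI: for every ROI, the union
    (sum then binarise) of significant seed sets over all components
    classified to that ROI.

    Per component the spatial map is mixture-thresholded (Gaussian
    background + gamma positive tail, posterior > ``posterior_cut``) before
    ROI classification.  Returns (per-ROI binary seed vectors,
    classifications, per-component seed Z maps).
    """
    if grid_shape is None:
        first = next(iter(rois.values()))
        grid_shape = first.shape
    classifications, zmaps = [], []
    roi_maps = {name: np.zeros(components.n_seeds_, dtype=bool)
                for name in rois}
    for k in range(components.n_components_):
        vol = components.component_volume(k, grid_shape)
        fit = GaussianGammaMixture().fit(vol.ravel())
        thr = threshold_map(vol, fit, posterior_cut)
        cls = classify_component(thr, rois,
                                 min_overlap_voxels=min_overlap_voxels,
                                 component_id=k)
        zmap = seed_zmap(components, k, threshold=z_threshold)
        classifications.append(cls)
        zmaps.append(zmap)
        for name in cls.roi_labels:
            roi_maps[name] |= zmap.significant_seeds
    return roi_maps, classifications, zmaps
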