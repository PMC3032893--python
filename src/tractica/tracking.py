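"""Minimal probabilistic streamline tracker.

Streamlines are propagated through an :class:`~tractica.synthdata.OrientationField`
by repeatedly sampling a direction from the local axial orientation
distribution (von Mises-Fisher around the voxel axis with the voxel's
concentration, antipodally symmetrised) and stepping a fixed fraction of a
voxel.  A streamline terminates on grid exit, on exceeding the step budget,
on a curvature violation, or where the field is undefined; a streamline that
touches any exclusion mask is rejected entirely and contributes no counts.
Surviving streamlines increment each visited voxel once (visitation, not
dwell time).  Directions are looked up at the nearest voxel (no
interpolation), which keeps the tracker exactly comparable to a
deterministic ray-marching oracle in the zero-dispersion limit.

The first step follows the stored orientation sign; subsequent steps choose
the antipodal sign that minimises the turning angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import TractogramStack
from .synthdata import OrientationField, seed_scan_order


@dataclass
class TrackingParams:
    n_streamlines: int = 5000
    step_size_voxels: float = 0.5
    max_steps: int = 200
    curvature_stop_deg: float = 80.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.step_size_voxels <= 0:
            raise ValueError("step_size_voxels must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not (0 < self.curvature_stop_deg <= 180):
            raise ValueError("curvature_stop_deg must be in (0, 180]")


@dataclass
class Tractogram:
    counts: np.ndarray          # int, 3D
    seed_index: tuple[int, int, int]
    n_started: int
    n_survived: int = 0
    target_hits: dict[str, int] | None = None


def _sample_vmf(axes: np.ndarray, kappa: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """One von Mises-Fisher draw per row of ``axes`` (unit vectors).

    Uses the closed-form inverse CDF of the cosine w = cos(angle to axis):
    w = 1 + log(u + (1-u) e^{-2 kappa}) / kappa.  kappa = inf returns the
    axis itself.
    """
    m = len(axes)
    u = rng.uniform(np.finfo(float).tiny, 1.0, size=m)
    finite = np.isfinite(kappa)
    kap = np.where(finite, np.maximum(kappa, 1e-12), 1.0)
    w = np.where(
        finite,
        1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kap)) / kap,
        1.0,
    )
    w = np.clip(w, -1.0, 1.0)
    # random tangent direction perpendicular to the axis
    g = rng.normal(size=(m, 3))
    g -= np.sum(g * axes, axis=1, keepdims=True) * axes
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    norm[norm < 1e-12] = 1.0
    tang = g / norm
    return w[:, None] * axes + np.sqrt(np.clip(1 - w ** 2, 0, None))[:, None] * tang


def track_seed(field: OrientationField, seed, params: TrackingParams,
               exclusion_masks=(), target_rois: dict | None = None,
               rng: np.random.Generator | None = None) -> Tractogram:
    """Track ``params.n_streamlines`` probabilistic streamlines from one
    seed voxel and return its visitation-count tractogram.

    With ``target_rois`` given (name -> binary volume), the tractogram also
    records, per target, how many surviving streamlines intersected it
    (target mode, used for winner-takes-all counting).
    """
    shape = field.grid_shape
    seed = tuple(int(v) for v in seed)
    if any(not (0 <= seed[d] < shape[d]) for d in range(3)):
        raise ValueError(f"seed {seed} outside grid {shape}")
    for m in exclusion_masks:
        if m[seed]:
            raise ValueError(f"seed {seed} lies inside an exclusion mask")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    n = params.n_streamlines
    nvox = int(np.prod(shape))
    dims = np.array(shape)
    excl = None
    if exclusion_masks:
        excl = np.zeros(shape, dtype=bool)
        for m in exclusion_masks:
            excl |= m
    excl_flat = excl.ravel() if excl is not None else None
    dir_flat = field.directions.reshape(nvox, 3)
    kap_flat = field.concentration.ravel()

    cos_stop = np.cos(np.deg2rad(params.curvature_stop_deg))
    pos = np.tile(np.asarray(seed, float) + 0.5, (n, 1))
    prev = np.zeros((n, 3))
    alive = np.ones(n, dtype=bool)
    rejected = np.zeros(n, dtype=bool)
    stream_ids_all: list[np.ndarray] = []
    vox_all: list[np.ndarray] = []

    for step in range(params.max_steps + 1):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        vox = np.floor(pos[idx]).astype(int)
        inside = np.all((vox >= 0) & (vox < dims), axis=1)
        alive[idx[~inside]] = False
        idx = idx[inside]
        vox = vox[inside]
        if len(idx) == 0:
            break
        flat = np.ravel_multi_index(tuple(vox.T), shape)
        if excl_flat is not None:
            hit = excl_flat[flat]
            rejected[idx[hit]] = True
            alive[idx[hit]] = False
            idx, flat = idx[~hit], flat[~hit]
            if len(idx) == 0:
                break
        stream_ids_all.append(idx)
        vox_all.append(flat)
        if step == params.max_steps:
            alive[idx] = False
            break
        axes = dir_flat[flat]
        kappa = kap_flat[flat]
        bad = (kappa <= 0) | (np.linalg.norm(axes, axis=1) < 0.5)
        alive[idx[bad]] = False
        idx, axes, kappa = idx[~bad], axes[~bad], kappa[~bad]
        if len(idx) == 0:
            break
        d = _sample_vmf(axes, kappa, rng)
        if step > 0:
            dots = np.sum(d * prev[idx], axis=1)
            d[dots < 0] *= -1.0
            dots = np.abs(dots)
            stop = dots < cos_stop
            alive[idx[stop]] = False
            idx, d = idx[~stop], d[~stop]
            if len(idx) == 0:
                break
        prev[idx] = d
        pos[idx] += params.step_size_voxels * d

    streams = np.concatenate(stream_ids_all) if stream_ids_all else \
        np.empty(0, dtype=int)
    voxels = np.concatenate(vox_all) if vox_all else np.empty(0, dtype=int)
    keep = ~rejected[streams]
    streams, voxels = streams[keep], voxels[keep]
    # count each voxel once per streamline
    uniq = np.unique(streams.astype(np.int64) * nvox + voxels)
    counts = np.bincount((uniq % nvox).astype(int), minlength=nvox)
    counts = counts.reshape(shape).astype(np.int32)
    n_survived = int(n - rejected.sum())

    hits = None
    if target_rois is not None:
        hits = {}
        uniq_streams = (uniq // nvox).astype(int)
        uniq_vox = (uniq % nvox).astype(int)
        for name, roi in target_rois.items():
            roi_flat = roi.ravel().astype(bool)
            touched = np.zeros(n, dtype=bool)
            touched[uniq_streams[roi_flat[uniq_vox]]] = True
            hits[name] = int(touched.sum())
    return Tractogram(counts=counts, seed_index=seed, n_started=n,
                      n_survived=n_survived, target_hits=hits)


def track_all_seeds(field: OrientationField, seed_mask: np.ndarray,
                    params: TrackingParams, exclusion_masks=(),
                    target_rois: dict | None = None,
                    subject_id: str = "") -> TractogramStack:
    """Track every voxel of ``seed_mask`` in the canonical scan order
    (x fastest) and concatenate the tractograms into a stack."""
    if not np.any(seed_mask):
        raise ValueError("empty seed mask")
    from .stack import concatenate
    seeds = seed_scan_order(seed_mask)
    children = np.random.SeedSequence(params.rng_seed).spawn(len(seeds))
    tracks = []
    for seed, child in zip(seeds, children):
        rng = np.random.default_rng(child)
        tracks.append(track_seed(field, seed, params, exclusion_masks,
                                 target_rois=target_rois, rng=rng))
    return concatenate(tracks, subject_id=subject_id)
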