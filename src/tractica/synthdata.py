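"""Synthetic tractography phantoms with known ground truth.

A phantom emulates the data-generating situation of a multi-subject
connectivity-parcellation study: a compact seed structure (a stand-in for
the thalamus) contains K spatially coherent "bundles", each owned by a
contiguous sub-region of seed voxels and projecting to one of seven
cortical-like target ROIs on the grid boundary.  Per subject, each bundle
carries a lognormal amplitude; visitation maps are Poisson counts around the
amplitude-weighted bundle densities plus a uniform noise floor.

Bundle pathways are quadratic Bezier tubes rasterised with a Gaussian
cross-section (sigma = 1 voxel by default) whose skirt is truncated at 1% of
the peak density: the low-density skirt is then visible per subject only
when that subject's amplitude lifts its Poisson rate above zero, which is
what makes across-subject population thresholds progressively shrink the
apparent tract extent, as they do in real group tractography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stack import TractogramStack, _default_affine

ROI_NAMES = ("frontal", "sma", "precentral", "postcentral",
             "parietal", "occipital", "temporal")


@dataclass
class OrientationField:
    """Per-voxel principal fibre direction with angular concentration.

    ``directions`` holds a unit 3-vector per voxel (axial: v and -v are the
    same orientation); ``concentration`` is the von Mises-Fisher kappa of
    the local orientation distribution (np.inf = no dispersion).
    """

    directions: np.ndarray      # (X, Y, Z, 3)
    concentration: np.ndarray   # (X, Y, Z)

    def __post_init__(self) -> None:
        if self.directions.shape[:3] != self.concentration.shape:
            raise ValueError("directions/concentration grid mismatch")
        if self.directions.shape[-1] != 3:
            raise ValueError("directions must be 3-vectors")
        norms = np.linalg.norm(self.directions, axis=-1)
        active = self.concentration > 0
        if np.any(np.abs(norms[active] - 1.0) > 1e-6):
            raise ValueError("directions must be unit norm where "
                             "concentration > 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.concentration.shape


@dataclass
class GroundTruthBundle:
    bundle_id: int
    seed_subregion: np.ndarray          # bool (X, Y, Z)
    pathway_map: np.ndarray             # float, sums to 1
    target_roi_ids: frozenset[str]
    subject_amplitudes: np.ndarray      # (n_subjects,), positive

    def __post_init__(self) -> None:
        if not np.any(self.seed_subregion):
            raise ValueError("seed_subregion must be non-empty")
        if abs(float(self.pathway_map.sum()) - 1.0) > 1e-6:
            raise ValueError("pathway_map must sum to 1")
        if np.any(self.subject_amplitudes <= 0):
            raise ValueError("subject amplitudes must be positive")

    @property
    def support(self) -> np.ndarray:
        """Binary ground-truth extent of the pathway."""
        return self.pathway_map > 0


@dataclass
class Phantom:
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    orientation_field: OrientationField
    seed_mask: np.ndarray
    exclusion_masks: list[np.ndarray]
    target_rois: dict[str, np.ndarray]
    bundles: list[GroundTruthBundle]
    n_subjects: int
    rng_seed: int
    noise_floor: float = 0.0
    spatial_jitter: bool = False

    def __post_init__(self) -> None:
        for name, roi in self.target_rois.items():
            if roi.shape != tuple(self.grid_shape):
                raise ValueError(f"target ROI {name!r} grid mismatch")
        for m in self.exclusion_masks:
            if np.any(m & self.seed_mask):
                raise ValueError("seed mask and exclusion masks overlap")
        for b in self.bundles:
            if np.any(b.seed_subregion & ~self.seed_mask):
                raise ValueError("bundle subregion escapes the seed mask")

    @property
    def affine(self) -> np.ndarray:
        return _default_affine(self.voxel_size_mm)


@dataclass
class PhantomConfig:
    """Study conditions of the default phantom.

    ``noise_floor`` is the expected spurious count per voxel per tractogram
    (probabilistic streamlines that wander off the pathway); ``overlap`` is
    the target mean fraction of each bundle's seed sub-region shared with
    another bundle (0 = disjoint sub-regions).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    n_bundles: int = 3
    n_subjects: int = 6
    overlap: float = 0.0
    amplitude_sigma: float = 0.5        # lognormal scale, location 0
    noise_floor: float = 2e-4
    tube_sigma: float = 1.0             # Gaussian cross-section, voxels
    tube_cut_frac: float = 0.01         # truncate skirt below this x peak
    bundle_concentration: float = 40.0
    background_concentration: float = 5.0
    subregion_radius: float = 2.0
    allow_shared_targets: bool = False
    spatial_jitter: bool = False        # +-1 voxel per-subject translation
    rng_seed: int = 0


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d = sum(((grids[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3))
    return d <= 1.0


def _ball(shape, center, radius) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d = sum((grids[i] - center[i]) ** 2 for i in range(3))
    return d <= radius ** 2


def _default_target_rois(shape) -> dict[str, np.ndarray]:
    """Seven ROI slabs on the grid boundary (six face centres + one extra
    corner patch on the +z face), mirroring seven cortical targets."""
    nx, ny, nz = shape
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    h = max(2, min(shape) // 8)  # half-extent of a patch
    rois: dict[str, np.ndarray] = {}

    def slab(xs, ys, zs):
        m = np.zeros(shape, dtype=bool)
        m[xs, ys, zs] = True
        return m

    sl = lambda c: slice(max(c - h, 0), min(c + h + 1, max(shape)))
    rois["frontal"] = slab(slice(0, 2), sl(cy), sl(cz))
    rois["occipital"] = slab(slice(nx - 2, nx), sl(cy), sl(cz))
    rois["temporal"] = slab(sl(cx), slice(0, 2), sl(cz))
    rois["parietal"] = slab(sl(cx), slice(ny - 2, ny), sl(cz))
    rois["precentral"] = slab(sl(cx), sl(cy), slice(0, 2))
    rois["sma"] = slab(sl(cx), sl(cy), slice(nz - 2, nz))
    rois["postcentral"] = slab(slice(1, 2 * h), slice(1, 2 * h),
                               slice(nz - 2, nz))
    return rois


def _farthest_point_centres(mask: np.ndarray, k: int,
                            rng: np.random.Generator) -> np.ndarray:
    coords = np.argwhere(mask).astype(float)
    centres = [coords[rng.integers(len(coords))]]
    for _ in range(k - 1):
        d = np.min(
            [np.sum((coords - c) ** 2, axis=1) for c in centres], axis=0)
        centres.append(coords[int(np.argmax(d))])
    return np.array(centres)


def _place_subregions(seed_mask: np.ndarray, k: int, radius: float,
                      overlap: float, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    # centres inside an eroded mask so the balls fit; shrink centres toward
    # their centroid (bisection) until the requested mean overlap is reached
    inner = ndimage.binary_erosion(seed_mask,
                                   iterations=max(1, int(radius)))
    if not np.any(inner):
        inner = seed_mask
    centres = _farthest_point_centres(inner, k, rng)

    def build(shrink: float) -> list[np.ndarray]:
        centroid = centres.mean(axis=0)
        moved = centroid + (centres - centroid) * shrink
        return [_ball(seed_mask.shape, c, radius) & seed_mask for c in moved]

    def achieved(subs: list[np.ndarray]) -> float:
        counts = np.sum(subs, axis=0)
        fracs = [np.mean(counts[s] >= 2) if s.sum() else 0.0 for s in subs]
        return float(np.mean(fracs))

    if overlap <= 0:
        return build(1.0)
    # overlap decreases with shrink: bisect for the largest shrink that
    # still reaches the requested overlap fraction
    lo, hi = 0.05, 1.0
    best = build(lo)
    if achieved(best) < overlap:
        return best  # geometry cannot reach the target; closest attempt
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        subs = build(mid)
        if achieved(subs) >= overlap:
            best, lo = subs, mid
        else:
            hi = mid
    return best


def _bezier_tube(shape, start, end, rng, sigma, cut_frac):
    """Rasterise a curved tube from start to end; returns a unit-sum map
    and the tangent field samples (points, tangents) for orientations."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    chord = end - start
    # control point offset perpendicular to the chord -> curvature
    ref = rng.normal(size=3)
    perp = np.cross(chord, ref)
    n = np.linalg.norm(perp)
    perp = perp / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    bow = rng.uniform(0.08, 0.18) * np.linalg.norm(chord)
    ctrl = 0.5 * (start + end) + bow * perp

    t = np.linspace(0.0, 1.0, 600)[:, None]
    pts = ((1 - t) ** 2) * start + 2 * t * (1 - t) * ctrl + (t ** 2) * end
    tangents = 2 * (1 - t) * (ctrl - start) + 2 * t * (end - ctrl)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    density = np.zeros(shape)
    vox = np.rint(pts).astype(int)
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    np.add.at(density, tuple(vox[ok].T), 1.0)
    density = ndimage.gaussian_filter(density, sigma=sigma)
    density[density < cut_frac * density.max()] = 0.0
    density /= density.sum()
    return density, pts[ok], tangents[ok]


def make_phantom(config: PhantomConfig | None = None, **overrides) -> Phantom:
    """Build a phantom with K ground-truth bundles; deterministic for a
    fixed ``rng_seed``.

    Raises if K exceeds the number of target ROIs (unless shared targets
    are allowed) or the grid is too small for non-degenerate tubes.
    """
    if config is None:
        config = PhantomConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    shape = tuple(config.grid_shape)
    if min(shape) < 12:
        raise ValueError(f"grid {shape} too small to place non-degenerate "
                         "tubes (need every dimension >= 12)")
    k = int(config.n_bundles)
    if k < 1:
        raise ValueError("need at least one bundle")
    rois = _default_target_rois(shape)
    if k > len(rois) and not config.allow_shared_targets:
        raise ValueError(
            f"{k} bundles exceed {len(rois)} target ROIs; enable "
            "allow_shared_targets to reuse targets")

    rng = np.random.default_rng(config.rng_seed)
    centre = np.array(shape) / 2.0
    semi = np.maximum(np.array(shape) / 4.5, 3.0)
    seed_mask = _ellipsoid_mask(shape, centre, semi)

    subregions = _place_subregions(seed_mask, k, config.subregion_radius,
                                   config.overlap, rng)
    roi_order = [ROI_NAMES[i % len(ROI_NAMES)] for i in range(k)]

    directions = rng.normal(size=shape + (3,))
    directions /= np.linalg.norm(directions, axis=-1, keepdims=True)
    concentration = np.full(shape, config.background_concentration)

    bundles = []
    for b in range(k):
        sub = subregions[b]
        start = np.argwhere(sub).mean(axis=0)
        roi = rois[roi_order[b]]
        end = np.argwhere(roi).mean(axis=0)
        density, pts, tans = _bezier_tube(shape, start, end, rng,
                                          config.tube_sigma,
                                          config.tube_cut_frac)
        support = density > 0
        # orientation field follows the bundle tangent on its support
        sup_idx = np.argwhere(support)
        d2 = np.sum((sup_idx[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        nearest = np.argmin(d2, axis=1)
        directions[tuple(sup_idx.T)] = tans[nearest]
        concentration[support] = config.bundle_concentration
        hit = frozenset(name for name, m in rois.items()
                        if np.any(m & support))
        amps = rng.lognormal(mean=0.0, sigma=config.amplitude_sigma,
                             size=config.n_subjects)
        bundles.append(GroundTruthBundle(
            bundle_id=b, seed_subregion=sub, pathway_map=density,
            target_roi_ids=hit, subject_amplitudes=amps))

    field = OrientationField(directions=directions,
                             concentration=concentration)
    return Phantom(grid_shape=shape, voxel_size_mm=config.voxel_size_mm,
                   orientation_field=field, seed_mask=seed_mask,
                   exclusion_masks=[], target_rois=rois, bundles=bundles,
                   n_subjects=config.n_subjects, rng_seed=config.rng_seed,
                   noise_floor=config.noise_floor,
                   spatial_jitter=config.spatial_jitter)


# ---------------------------------------------------------------------------
# Direct tractogram sampling (fast path bypassing the tracker)

def seed_scan_order(seed_mask: np.ndarray) -> np.ndarray:
    """Seed voxel indices in the canonical scan order (x fastest)."""
    zyx = np.argwhere(seed_mask.transpose(2, 1, 0))
    return zyx[:, ::-1].copy()


def expected_rate_map(phantom: Phantom, seed_index, subject: int
                      ) -> np.ndarray:
    """Expected per-streamline visitation density for one seed voxel:
    the amplitude-weighted sum of the pathway maps of the bundles owning
    that seed (zero map if no bundle owns it)."""
    i, j, kk = (int(v) for v in seed_index)
    out = np.zeros(phantom.grid_shape)
    for b in phantom.bundles:
        if b.seed_subregion[i, j, kk]:
            out += b.subject_amplitudes[subject] * b.pathway_map
    return out


def sample_tractograms_direct(phantom: Phantom,
                              n_streamlines_equiv: int = 5000,
                              rng_seed: int = 0,
                              noise: str = "poisson"
                              ) -> list[TractogramStack]:
    """Sample per-subject tractogram stacks directly from the ground truth.

    For each seed voxel the expected tractogram is
    ``n_streamlines_equiv * sum_k a_ks * pathway_k`` over owning bundles
    plus the uniform noise floor; counts are Poisson draws around it
    (``noise="none"`` returns the expectations themselves, for oracle
    tests).  A seed owned by no bundle yields pure noise-floor counts.

    With ``phantom.spatial_jitter`` enabled, each subject's pathway maps
    are translated by an integer shift drawn uniformly from {-1, 0, 1}^3,
    emulating residual anatomical misalignment between subjects (the
    mechanism behind across-subject shrinkage of population tract masks).
    """
    n = int(n_streamlines_equiv)
    if n < 1:
        raise ValueError("n_streamlines_equiv must be >= 1")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    seeds = seed_scan_order(phantom.seed_mask)
    n_seeds = len(seeds)
    nvox = int(np.prod(phantom.grid_shape))
    rng = np.random.default_rng(rng_seed)

    # group seeds by the set of bundles owning them: one rate map per group
    ownership = np.zeros((n_seeds, len(phantom.bundles)), dtype=bool)
    for b, bun in enumerate(phantom.bundles):
        ownership[:, b] = bun.seed_subregion[tuple(seeds.T)]
    keys = [tuple(np.flatnonzero(row)) for row in ownership]
    groups: dict[tuple, list[int]] = {}
    for v, key in enumerate(keys):
        groups.setdefault(key, []).append(v)

    stacks = []
    for s in range(phantom.n_subjects):
        if phantom.spatial_jitter:
            shift = tuple(rng.integers(-1, 2, size=3))
        else:
            shift = (0, 0, 0)
        data = np.zeros(phantom.grid_shape + (n_seeds,), dtype=np.float32)
        flat = data.reshape(nvox, n_seeds)
        for key, members in groups.items():
            lam = np.full(nvox, phantom.noise_floor)
            for b in key:
                bun = phantom.bundles[b]
                pw = bun.pathway_map
                if shift != (0, 0, 0):
                    pw = np.roll(pw, shift, axis=(0, 1, 2))
                lam += n * bun.subject_amplitudes[s] * pw.ravel()
            if noise == "poisson":
                draws = rng.poisson(lam=lam,
                                    size=(len(members), nvox)).astype(
                                        np.float32)
            else:
                draws = np.broadcast_to(
                    lam.astype(np.float32), (len(members), nvox))
            flat[:, members] = draws.T
        stacks.append(TractogramStack(
            data=data, seed_table=seeds, subject_id=f"sub-{s:02d}",
            space_tag="phantom", affine=phantom.affine))
    return stacks


# ---------------------------------------------------------------------------
# Phantom I/O (NIfTI volumes + JSON ground-truth sidecar)

def write_phantom(phantom: Phantom, out_dir: str | Path) -> None:
    from . import stack as _stack
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = phantom.affine
    _stack.save_volume(phantom.seed_mask.astype(np.uint8),
                       out / "seed_mask.nii", aff)
    _stack.save_volume(phantom.orientation_field.directions,
                       out / "orientations.nii", aff)
    _stack.save_volume(phantom.orientation_field.concentration,
                       out / "concentration.nii", aff)
    for name, roi in phantom.target_rois.items():
        _stack.save_volume(roi.astype(np.uint8),
                           out / f"roi_{name}.nii", aff)
    truth = {
        "grid_shape": list(phantom.grid_shape),
        "voxel_size_mm": phantom.voxel_size_mm,
        "n_subjects": phantom.n_subjects,
        "rng_seed": phantom.rng_seed,
        "noise_floor": phantom.noise_floor,
        "bundles": [
            {
                "bundle_id": b.bundle_id,
                "target_roi_ids": sorted(b.target_roi_ids),
                "subject_amplitudes": b.subject_amplitudes.tolist(),
                "n_subregion_voxels": int(b.seed_subregion.sum()),
            }
            for b in phantom.bundles
        ],
    }
    for b in phantom.bundles:
        _stack.save_volume(b.seed_subregion.astype(np.uint8),
                           out / f"bundle_{b.bundle_id}_subregion.nii", aff)
        _stack.save_volume(b.pathway_map,
                           out / f"bundle_{b.bundle_id}_pathway.nii", aff)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
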