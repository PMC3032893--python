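"""Group ICA decomposition of multi-subject tractogram stacks.

The multi-subject model follows the tensorial (three-way) picture: each
independent spatial source map is expressed in the data through a mixing
weight that factorises into a seed loading times a subject loading, i.e.
the spatial pattern and the seed cluster expressing it are assumed
consistent across subjects.  In practice this is realised the standard way:
subjects are concatenated along the seed dimension, a spatial ICA is run on
the concatenated matrix, and each component's mixing column is reduced to
its best rank-1 seed x subject factorisation (the fraction of squared norm
captured by the rank-1 term is reported per component, so departures from
the factorised model are visible rather than silent).

The ICA core is fixed-point negentropy maximisation with the tanh contrast
and symmetric decorrelation.  Spatial maps are unit-variance with a
positive-skew sign convention (tract maps are non-negative structures, so
signal lives in the positive tail); subject loadings are unit-norm with the
scale carried by the seed loadings.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.extmath import randomized_svd

from .stack import GroupStack

logger = logging.getLogger(__name__)


def _assemble_matrix(group, mask=None):
    """Stack subjects along the seed dimension: rows are the (subject, seed)
    tractograms over in-mask voxels, ordered subject-major so that a mixing
    column reshapes to (n_subjects, n_seeds)."""
    if isinstance(group, GroupStack):
        nvox_mask = None
        rows = []
        for sub in group.subjects:
            flat = sub.data.reshape(-1, sub.n_seeds).T  # (n_seeds, nvox)
            if mask is not None:
                flat = flat[:, np.asarray(mask).ravel().astype(bool)]
            rows.append(flat)
        X = np.concatenate(rows, axis=0).astype(float)
        n_subjects, n_seeds = group.n_subjects, len(group.seed_table)
    else:
        arr = np.asarray(group, dtype=float)
        if arr.ndim != 3:
            raise ValueError("expected a GroupStack or an array of shape "
                             "(n_subjects, n_seeds, n_voxels)")
        n_subjects, n_seeds = arr.shape[:2]
        X = arr.reshape(n_subjects * n_seeds, arr.shape[2])
        if mask is not None:
            X = X[:, np.asarray(mask).ravel().astype(bool)]
    return X, n_subjects, n_seeds


def _preprocess_rows(X, var_norm=True):
    X = np.array(X, dtype=float)
    if var_norm:
        sd = X.std(axis=1)
        ok = sd > 1e-12 * max(sd.max(), 1e-300)
        X[ok] /= sd[ok, None]
    X -= X.mean(axis=1, keepdims=True)
    if not np.any(np.abs(X) > 0):
        raise ValueError("degenerate stack: zero variance everywhere")
    return X


def _sym_decorrelate(W):
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u * (1.0 / np.sqrt(s))) @ u.T @ W


def _fastica_core(Z, tol, max_iter, rng):
    """Fixed-point ICA on whitened data Z (k x n). Returns (W, converged,
    n_iter); sources are W @ Z."""
    k, n = Z.shape
    W = _sym_decorrelate(rng.normal(size=(k, k)))
    lim = np.inf
    for it in range(max_iter):
        WZ = W @ Z
        G = np.tanh(WZ)
        g_prime = (1.0 - G ** 2).mean(axis=1)
        W_new = (G @ Z.T) / n - g_prime[:, None] * W
        W_new = _sym_decorrelate(W_new)
        lim = float(np.max(np.abs(np.abs(np.sum(W_new * W, axis=1)) - 1.0)))
        W = W_new
        if lim < tol:
            return W, True, it + 1
    return W, False, max_iter


def estimate_n_components(group, mask=None, multiplier: float = 2.0,
                          var_norm: bool = True,
                          max_voxels: int | None = None,
                          rng_seed: int = 0) -> int:
    """Heuristic model-order estimate: the number of eigenvalues of the
    row-covariance exceeding ``multiplier`` times the median eigenvalue
    (eigenvalues below 1e-9 of the largest are treated as numerically
    zero).  Floor of 1; a stand-in for Bayesian order estimation."""
    X, _, _ = _assemble_matrix(group, mask)
    X = _preprocess_rows(X, var_norm=var_norm)
    if max_voxels is not None and X.shape[1] > max_voxels:
        cols = np.random.default_rng(rng_seed).choice(
            X.shape[1], size=max_voxels, replace=False)
        X = X[:, np.sort(cols)]
    gram = X @ X.T / X.shape[1]
    evals = np.linalg.eigvalsh(gram)[::-1]
    evals = np.clip(evals, 0.0, None)
    if len(evals) < 3:
        raise ValueError("need at least 3 eigenvalues to estimate the "
                         "model order")
    med = float(np.median(evals))
    floor = 1e-9 * float(evals[0])
    k = int(np.sum((evals > multiplier * med) & (evals > floor)))
    return max(k, 1)


class GroupICA(BaseEstimator):
    """Group spatial ICA with rank-1 seed x subject mixing factorisation.

    Parameters
    ----------
    n_components : int or "auto"
        Model order; "auto" uses :func:`estimate_n_components` and falls
        back to ``default_components`` (with a warning) when the spectrum
        shows no eigen-gap.
    mask : binary volume or flat boolean array, optional
        Analysis mask restricting the voxels entering the decomposition.
    var_norm : bool
        Variance-normalise each tractogram row before PCA so high-count
        seeds do not dominate.
    tol, max_iter, n_restarts : ICA fixed-point settings; on
        non-convergence the ICA restarts with an incremented seed.

    Attributes (after fit)
    ----------------------
    components_ : (n_components, n_voxels_in_mask) unit-variance spatial
        maps, positive-skew sign convention.
    seed_loadings_ : (n_components, n_seeds); carries the mixing scale.
    subject_loadings_ : (n_components, n_subjects), unit-norm rows.
    rank1_fit_fraction_ : per component, fraction of the mixing column's
        squared norm captured by the rank-1 factorisation.
    whitening_ : dict with retained eigenvalues and rank.
    """

    def __init__(self, n_components="auto", *, mask=None, var_norm=True,
                 tol=1e-6, max_iter=1000, n_restarts=5, random_state=0,
                 eigen_multiplier=2.0, default_components=5):
        self.n_components = n_components
        self.mask = mask
        self.var_norm = var_norm
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.eigen_multiplier = eigen_multiplier
        self.default_components = default_components

    def fit(self, X, y=None):
        M, n_subjects, n_seeds = _assemble_matrix(X, self.mask)
        if n_seeds < 2:
            raise ValueError("need at least 2 seeds")
        M = _preprocess_rows(M, var_norm=self.var_norm)
        n_rows, n_vox = M.shape

        if self.n_components == "auto":
            try:
                k = estimate_n_components(
                    X, self.mask, multiplier=self.eigen_multiplier,
                    var_norm=self.var_norm, max_voxels=4000,
                    rng_seed=self.random_state)
            except ValueError:
                raise
            if k < 2:
                warnings.warn(
                    "no usable eigen-gap; falling back to "
                    f"default_components={self.default_components}")
                k = self.default_components
        else:
            k = int(self.n_components)
        if k < 1 or k >= n_rows or k >= n_vox:
            raise ValueError(
                f"n_components={k} must be >= 1, < n_seeds*n_subjects="
                f"{n_rows} and < n_voxels={n_vox}")

        U, s, Vt = randomized_svd(M, n_components=k, n_oversamples=10,
                                  random_state=self.random_state)
        nonzero = s > 1e-12 * max(s[0], 1e-300)
        if not nonzero.all():
            raise ValueError(
                f"requested {k} components but data rank is only "
                f"{int(nonzero.sum())}")
        Z = Vt * np.sqrt(n_vox)   # whitened: rows unit variance, orthogonal

        rng_seed = (self.random_state if isinstance(self.random_state, int)
                    else 0)
        converged, W = False, None
        for attempt in range(self.n_restarts):
            rng = np.random.default_rng(rng_seed + attempt)
            W, converged, n_iter = _fastica_core(
                Z, self.tol, self.max_iter, rng)
            if converged:
                break
            logger.warning("ICA did not converge (attempt %d); restarting "
                           "with incremented seed", attempt + 1)
        self.converged_ = converged
        self.n_iter_ = n_iter

        S = W @ Z
        S /= S.std(axis=1, keepdims=True)
        A = M @ S.T / n_vox                     # mixing, (n_rows, k)

        seed_loadings = np.zeros((k, n_seeds))
        subject_loadings = np.zeros((k, n_subjects))
        frac = np.zeros(k)
        for c in range(k):
            col = A[:, c].reshape(n_subjects, n_seeds)
            uu, ss, vv = np.linalg.svd(col, full_matrices=False)
            subj = uu[:, 0]
            seed = ss[0] * vv[0]
            if subj.sum() < 0:
                subj, seed = -subj, -seed
            total = float(np.sum(ss ** 2))
            frac[c] = float(ss[0] ** 2 / total) if total > 0 else 0.0
            subject_loadings[c] = subj
            seed_loadings[c] = seed
        # positive-skew sign convention on spatial maps; the compensating
        # flip goes into the seed loadings so map x seed x subject is fixed
        skews = stats.skew(S, axis=1)
        flip = skews < 0
        S[flip] *= -1.0
        seed_loadings[flip] *= -1.0
        A[:, flip] *= -1.0

        self.components_ = S
        self.mixing_ = A
        self.seed_loadings_ = seed_loadings
        self.subject_loadings_ = subject_loadings
        self.rank1_fit_fraction_ = frac
        self.n_components_ = k
        self.n_subjects_ = n_subjects
        self.n_seeds_ = n_seeds
        self.whitening_ = {
            "eigenvalues": (s ** 2 / n_vox).tolist(),
            "rank": int(nonzero.sum()),
            "n_components": k,
        }
        self.mask_ = (np.asarray(self.mask).ravel().astype(bool)
                      if self.mask is not None else None)
        return self

    def component_volume(self, k: int, grid_shape) -> np.ndarray:
        """Re-embed spatial map ``k`` into a 3D volume (zeros off-mask)."""
        nvox = int(np.prod(grid_shape))
        out = np.zeros(nvox)
        if self.mask_ is not None:
            out[self.mask_] = self.components_[k]
        else:
            out[:] = self.components_[k]
        return out.reshape(grid_shape)


def fit_group_ica(group, n_components="auto", mask=None, rng_seed=0,
                  **kwargs) -> GroupICA:
    """Thin functional wrapper over :class:`GroupICA`."""
    return GroupICA(n_components=n_components, mask=mask,
                    random_state=rng_seed, **kwargs).fit(group)
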