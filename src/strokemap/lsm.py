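"""Multivariate lesion-behaviour mapping by ridge regression on voxel features.

Subjects' binary lesion masks become an n x v feature matrix over analysis
voxels (lesioned in at least ``min_lesion_count`` subjects). A ridge model
predicts each behavioural component score from all voxels jointly; the
penalty is selected by nested cross-validation inside leave-one-out CV, and
explained variance is the squared Pearson correlation between held-out
predictions and observations. Voxel weights are back-projected to brain
space and post-processed (Gaussian smoothing, scaling to [-1, 1], display
threshold) for anatomical weight maps.

Because the voxel count dwarfs the subject count, all fitting runs in the
n-dimensional dual space through the Gram matrix; the primal and dual
solutions coincide algebraically and the equivalence is covered by tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .images import LesionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "RidgeLesionMapper",
    "build_feature_matrix",
    "fit_ridge",
    "select_lambda",
    "loocv_explained_variance",
    "backproject",
    "postprocess_map",
    "apply_display_threshold",
    "spatial_correlation",
    "default_lambda_grid",
]


def default_lambda_grid(low: float = 1e-2, high: float = 1e4, num: int = 20) -> np.ndarray:
    """20 log-spaced penalties spanning [1e-2, 1e4] on standardized features."""
    return np.logspace(np.log10(low), np.log10(high), num)


@dataclass
class FeatureMatrix:
    """Subjects x analysis-voxels binary matrix plus its spatial bookkeeping."""

    X: np.ndarray                  # n x v, {0,1} floats
    voxel_coords: np.ndarray       # v x 3, lexicographic order
    analysis_mask: np.ndarray      # 3D bool
    subject_ids: list[str]
    min_lesion_count: int
    grid_shape: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.grid_shape = self.analysis_mask.shape
        if self.X.shape != (len(self.subject_ids), self.voxel_coords.shape[0]):
            raise ValidationError("feature matrix dimensions are inconsistent")


def build_feature_matrix(cohort: LesionCohort, min_lesion_count: int = 2) -> FeatureMatrix:
    """Binary feature matrix over voxels lesioned in >= min_lesion_count subjects.

    Subjects with empty masks are excluded (and logged); columns follow
    lexicographic voxel-coordinate order.
    """
    kept = [im for im in cohort.images if im.mask.any()]
    n_empty = len(cohort.images) - len(kept)
    if n_empty:
        logger.info("excluding %d subjects with empty lesion masks from LSM", n_empty)
    if not kept:
        raise ValidationError("no subjects with non-empty lesions")
    stack = np.stack([im.mask for im in kept])
    counts = stack.sum(axis=0)
    analysis_mask = counts >= min_lesion_count
    if not analysis_mask.any():
        raise ValidationError(
            f"no voxel is lesioned in >= {min_lesion_count} subjects"
        )
    coords = np.argwhere(analysis_mask)          # lexicographic by construction
    X = stack[:, analysis_mask].astype(float)
    return FeatureMatrix(
        X=X,
        voxel_coords=coords,
        analysis_mask=analysis_mask,
        subject_ids=[im.subject_id for im in kept],
        min_lesion_count=min_lesion_count,
    )


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Solve (X'X + lam I) w = X'y on column-centered X and centered y.

    Returns (weights, intercept) with intercept = mean(y). ``lam = 0`` is
    permitted only when X has full column rank. When v > n the system is
    solved in the dual space (identical solution by the Woodbury identity).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in ridge inputs")
    if lam < 0:
        raise ValidationError("lambda must be nonnegative")
    n, v = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    yc = y - y.mean()
    if lam == 0:
        if np.linalg.matrix_rank(Xc) < v:
            raise ValidationError("lambda = 0 requires full column rank")
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    elif v <= n:
        w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(v), Xc.T @ yc)
    else:
        alpha = np.linalg.solve(Xc @ Xc.T + lam * np.eye(n), yc)
        w = Xc.T @ alpha
    return w, float(y.mean())


def _fold_indices(n: int, folds: int) -> list[np.ndarray]:
    """Deterministic striped fold assignment by position."""
    return [np.arange(n)[f::folds] for f in range(folds)]


def _centered_kernel(K: np.ndarray, tr: np.ndarray, te: np.ndarray):
    """Training-centered Gram blocks: Kc[tr,tr] and Kc[te,tr]."""
    Ktt = K[np.ix_(tr, tr)]
    r = Ktt.mean(axis=1)
    s = r.mean()
    Kc = Ktt - r[:, None] - r[None, :] + s
    Kte = K[np.ix_(te, tr)]
    rte = Kte.mean(axis=1)
    Kte_c = Kte - rte[:, None] - r[None, :] + s
    return Kc, Kte_c


def _kernel_ridge_predict_grid(
    K: np.ndarray, y: np.ndarray, tr: np.ndarray, te: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Held-out predictions for every lambda at once via eigh of the centered Gram."""
    Kc, Kte_c = _centered_kernel(K, tr, te)
    ybar = y[tr].mean()
    yc = y[tr] - ybar
    w, V = np.linalg.eigh(Kc)
    w = np.maximum(w, 0.0)
    Vty = V.T @ yc
    preds = np.empty((len(lams), len(te)))
    for i, lam in enumerate(lams):
        alpha = V @ (Vty / (w + lam))
        preds[i] = Kte_c @ alpha + ybar
    return preds


def select_lambda(
    X: np.ndarray | None,
    y: np.ndarray,
    lambda_grid: np.ndarray,
    inner_cv_folds: int = 5,
    K: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> float:
    """Pick the penalty minimizing inner k-fold CV mean squared error.

    Ties resolve to the larger lambda. ``K``/``subset`` allow reuse of a
    precomputed Gram matrix; otherwise K is built from X. With fewer
    subjects than folds the fold count is reduced with a warning.
    """
    lams = np.sort(np.asarray(lambda_grid, dtype=float))
    if lams.size == 1:
        return float(lams[0])
    if K is None:
        X = np.asarray(X, dtype=float)
        K = X @ X.T
    idx = np.arange(K.shape[0]) if subset is None else np.asarray(subset)
    y = np.asarray(y, dtype=float).ravel()
    n = len(idx)
    folds = inner_cv_folds
    if n < folds:
        folds = max(2, n)
        warnings.warn(f"reducing inner CV folds to {folds} (n={n})", stacklevel=2)
    sse = np.zeros(lams.size)
    for fold in _fold_indices(n, folds):
        te = idx[fold]
        tr = np.delete(idx, fold)
        preds = _kernel_ridge_predict_grid(K, y, tr, te, lams)
        sse += ((preds - y[te][None, :]) ** 2).sum(axis=1)
    # ascending grid + '<=' => ties go to the larger penalty
    best = 0
    for i in range(1, lams.size):
        if sse[i] <= sse[best]:
            best = i
    return float(lams[best])


class RidgeLesionMapper(BaseEstimator, RegressorMixin):
    """Ridge lesion-behaviour model with nested-LOOCV explained variance.

    ``fit`` runs leave-one-out CV where, for each held-out subject, the
    penalty is re-selected by inner k-fold CV on the remaining subjects
    (so held-out predictions never see the held-out case), then refits on
    all subjects with a penalty selected the same way.

    Features are scaled by their cohort standard deviation (a fixed feature
    definition) and centered per training fold; computation runs in the dual
    space through the Gram matrix.

    Attributes after fit: ``coef_`` (weights on scaled features),
    ``intercept_``, ``lambda_`` (full-data penalty), ``fold_lambdas_``,
    ``loocv_predictions_``, ``pearson_r_``, ``explained_variance_`` (squared
    Pearson r of LOOCV predictions vs observations, zero when the
    correlation is negative), ``in_sample_r2_``.
    """

    def __init__(
        self,
        lambda_grid: np.ndarray | None = None,
        inner_cv_folds: int = 5,
        run_loocv: bool = True,
    ):
        self.lambda_grid = lambda_grid
        self.inner_cv_folds = inner_cv_folds
        self.run_loocv = run_loocv

    def _grid(self) -> np.ndarray:
        return default_lambda_grid() if self.lambda_grid is None else np.asarray(self.lambda_grid, float)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeLesionMapper":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValidationError("non-finite values in inputs")
        n, v = X.shape
        lams = self._grid()

        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        Xs = X / self.scale_[None, :]
        K = Xs @ Xs.T
        all_idx = np.arange(n)

        if self.run_loocv:
            if n < 10:
                raise ValidationError("LOOCV requires n >= 10")
            preds = np.empty(n)
            fold_lams = np.empty(n)
            for i in range(n):
                tr = np.delete(all_idx, i)
                lam_i = select_lambda(
                    None, y, lams, self.inner_cv_folds, K=K, subset=tr
                )
                fold_lams[i] = lam_i
                preds[i] = _kernel_ridge_predict_grid(
                    K, y, tr, np.array([i]), np.array([lam_i])
                )[0, 0]
            self.loocv_predictions_ = preds
            self.fold_lambdas_ = fold_lams
            if np.std(preds) < 1e-12 or np.std(y) < 1e-12:
                warnings.warn("zero-variance LOOCV predictions; explained variance 0", stacklevel=2)
                self.pearson_r_ = 0.0
                self.explained_variance_ = 0.0
            else:
                r = float(np.corrcoef(preds, y)[0, 1])
                self.pearson_r_ = r
                # anti-correlated predictions explain nothing: near-constant
                # LOO predictions are exactly negatively correlated with the
                # held-out values (slope -1/(n-1)), and the scale-free r^2
                # would otherwise credit that artifact as signal
                self.explained_variance_ = r**2 if r > 0 else 0.0
        else:
            self.loocv_predictions_ = None
            self.fold_lambdas_ = None
            self.explained_variance_ = None

        # full-data model
        self.lambda_ = select_lambda(None, y, lams, self.inner_cv_folds, K=K)
        mu = Xs.mean(axis=0)
        Xc = Xs - mu
        yc = y - y.mean()
        alpha = np.linalg.solve(Xc @ Xc.T + self.lambda_ * np.eye(n), yc)
        self.coef_ = Xc.T @ alpha
        self.feature_means_ = mu
        self.intercept_ = float(y.mean())
        fitted = Xc @ self.coef_ + self.intercept_
        ss_res = ((y - fitted) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        self.in_sample_r2_ = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
        self.n_features_in_ = v
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xs = np.asarray(X, dtype=float) / self.scale_[None, :]
        return (Xs - self.feature_means_) @ self.coef_ + self.intercept_


def loocv_explained_variance(
    X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray | None = None
) -> RidgeLesionMapper:
    """Convenience wrapper: fit a RidgeLesionMapper with nested LOOCV."""
    return RidgeLesionMapper(lambda_grid=lambda_grid).fit(X, y)


def backproject(weights: np.ndarray, fm: FeatureMatrix) -> np.ndarray:
    """Place per-voxel weights at their 3D coordinates; zero elsewhere."""
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != fm.voxel_coords.shape[0]:
        raise ValidationError("weight vector length does not match feature matrix")
    out = np.zeros(fm.grid_shape)
    out[tuple(fm.voxel_coords.T)] = weights
    return out


def postprocess_map(raw: np.ndarray, sigma: float = 1.0, truncate: float = 4.0) -> np.ndarray:
    """Gaussian smoothing (variance sigma^2 = 1 voxel^2) then scaling to [-1, 1].

    The kernel is truncated at ``truncate`` standard deviations and
    renormalized (scipy's sampled-Gaussian convention). An all-zero map is
    returned unchanged (no division).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValidationError("weight map contains non-finite values")
    smoothed = ndimage.gaussian_filter(raw, sigma=sigma, truncate=truncate, mode="constant")
    peak = np.abs(smoothed).max()
    return smoothed / peak if peak > 0 else smoothed


def apply_display_threshold(processed: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Zero out |values| below the display threshold (export layer only)."""
    out = np.asarray(processed, dtype=float).copy()
    out[np.abs(out) < threshold] = 0.0
    return out


def spatial_correlation(
    map_a: np.ndarray,
    map_b: np.ndarray,
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Pearson correlation of two aligned maps with a torus-shift permutation p.

    The correlation runs over voxels where either map is nonzero. The null
    distribution translates map_b by random 3D circular shifts, preserving
    its spatial autocorrelation; p = (1 + #{|r_perm| >= |r|}) / (1 + n_perm).
    """
    A = np.asarray(map_a, dtype=float)
    B = np.asarray(map_b, dtype=float)
    if A.shape != B.shape:
        raise ValidationError("maps must share a grid; resample first")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        supp = (a != 0) | (b != 0)
        if supp.sum() < 10:
            raise ValidationError("fewer than 10 voxels in the support union")
        av, bv = a[supp], b[supp]
        if av.std() < 1e-15 or bv.std() < 1e-15:
            return 0.0
        return float(np.corrcoef(av, bv)[0, 1])

    r = _corr(A, B)
    if n_permutations <= 0:
        return r, float("nan")
    count = 0
    shape = A.shape
    for _ in range(n_permutations):
        shift = tuple(int(rng.integers(s)) for s in shape)
        Bs = np.roll(B, shift, axis=(0, 1, 2))
        supp = (A != 0) | (Bs != 0)
        if supp.sum() < 10:
            continue
        av, bv = A[supp], Bs[supp]
        if av.std() < 1e-15 or bv.std() < 1e-15:
            rp = 0.0
        else:
            rp = float(np.corrcoef(av, bv)[0, 1])
        if abs(rp) >= abs(r):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return r, p
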