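"""Behavioural battery reduction: deficit transform, PCA, PROMAX rotation.

The pipeline is: raw subtest scores -> deficit scores (1 - score/max, so
higher = more impaired) -> column z-scores -> PCA on the subtest correlation
matrix -> varimax -> PROMAX oblique rotation -> sign orientation (positive
loadings = worse performance) -> Thurstone regression component scores.

``PromaxPCA`` packages the whole chain as a scikit-learn style transformer;
the module-level functions expose each step individually.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BatteryTable",
    "DeficitMatrix",
    "PromaxPCA",
    "deficit_transform",
    "zscore_columns",
    "fit_pca",
    "varimax",
    "promax",
    "component_scores",
    "orient_components",
    "ordered_correlation_matrix",
    "tucker_congruence",
]


@dataclass
class BatteryTable:
    """Raw battery: per-subject subtest scores plus per-subtest maxima."""

    subject_ids: list[str]
    subtest_names: list[str]
    scores: np.ndarray          # n x p
    maxima: np.ndarray          # p

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        n, p = self.scores.shape
        if len(self.subject_ids) != n or len(self.subtest_names) != p or len(self.maxima) != p:
            raise ValidationError("battery dimensions are inconsistent")
        if np.isnan(self.scores).any():
            raise ValidationError("battery contains missing values; complete cases only")
        if (self.maxima <= 0).any():
            bad = self.subtest_names[int(np.argmax(self.maxima <= 0))]
            raise ValidationError(f"subtest {bad!r} has non-positive maximum")

    @classmethod
    def from_csv(cls, battery_csv: str | Path, maxima_csv: str | Path) -> "BatteryTable":
        """Read ``subject_id,<subtest>...`` scores plus a ``subtest,maximum`` sidecar."""
        scores = pd.read_csv(battery_csv)
        maxima = pd.read_csv(maxima_csv).set_index("subtest")["maximum"]
        names = [c for c in scores.columns if c != "subject_id"]
        missing = [n for n in names if n not in maxima.index]
        if missing:
            raise ValidationError(f"maxima missing for subtests: {missing}")
        return cls(
            subject_ids=[str(s) for s in scores["subject_id"]],
            subtest_names=names,
            scores=scores[names].to_numpy(float),
            maxima=maxima.loc[names].to_numpy(float),
        )


@dataclass
class DeficitMatrix:
    """Z-scored deficit matrix; zero-variance subtests are dropped, not jittered."""

    values: np.ndarray
    subtest_names: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)
    subject_ids: list[str] | None = None


def deficit_transform(battery: BatteryTable) -> pd.DataFrame:
    """Normalize scores to their maxima and sign-invert: deficit = 1 - score/max.

    0 means intact performance, 1 the worst possible deficit.
    """
    over = battery.scores > battery.maxima[None, :] + 1e-12
    if over.any():
        i, j = np.argwhere(over)[0]
        raise ValidationError(
            f"score exceeds maximum for subject {battery.subject_ids[i]!r}, "
            f"subtest {battery.subtest_names[j]!r}"
        )
    if (battery.scores < -1e-12).any():
        i, j = np.argwhere(battery.scores < -1e-12)[0]
        raise ValidationError(
            f"negative score for subject {battery.subject_ids[i]!r}, "
            f"subtest {battery.subtest_names[j]!r}"
        )
    deficits = 1.0 - battery.scores / battery.maxima[None, :]
    return pd.DataFrame(deficits, index=battery.subject_ids, columns=battery.subtest_names)


def zscore_columns(deficits: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> DeficitMatrix:
    """Standardize each column to mean 0, sd 1 (denominator n-1).

    Zero-variance columns (e.g. a subtest at ceiling for everyone) are moved
    to ``dropped_columns`` with a warning; if all columns are constant this is
    an error.
    """
    if isinstance(deficits, pd.DataFrame):
        names = list(deficits.columns)
        subject_ids = [str(i) for i in deficits.index]
        X = deficits.to_numpy(float)
    else:
        X = np.asarray(deficits, dtype=float)
        names = names if names is not None else [f"var{j}" for j in range(X.shape[1])]
        subject_ids = None
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 subjects to z-score")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 1e-12
    dropped = [names[j] for j in np.flatnonzero(~keep)]
    if not keep.any():
        raise ValidationError("all subtests have zero variance")
    if dropped:
        warnings.warn(f"dropping zero-variance subtests: {dropped}", stacklevel=2)
        logger.info("dropped %d zero-variance subtests: %s", len(dropped), dropped)
    Z = (X[:, keep] - means[keep]) / sds[keep]
    return DeficitMatrix(
        values=Z,
        subtest_names=[names[j] for j in np.flatnonzero(keep)],
        column_means=means[keep],
        column_sds=sds[keep],
        dropped_columns=dropped,
        subject_ids=subject_ids,
    )


def fit_pca(Z: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the p x p correlation matrix of standardized data.

    Returns (loadings p x k, eigenvalues all p, variance proportions k,
    unrotated scores n x k). Loadings are eigenvectors scaled by
    sqrt(eigenvalue); score c is ``Z v_c / sqrt(lambda_c)``.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    rank = int((eigvals > 1e-10).sum())
    if not 1 <= k <= rank:
        raise ValidationError(f"k={k} exceeds rank {rank} of the correlation matrix")
    lam = eigvals[:k]
    V = eigvecs[:, :k]
    loadings = V * np.sqrt(lam)[None, :]
    scores = Z @ V / np.sqrt(lam)[None, :]
    return loadings, eigvals, lam / p, scores


def _varimax_criterion(L: np.ndarray) -> float:
    p = L.shape[0]
    sq = L**2
    return float(np.sum(np.sum(sq**2, axis=0) - np.sum(sq, axis=0) ** 2 / p))


def varimax(
    loadings: np.ndarray,
    tol: float = 1e-8,
    max_sweeps: int = 200,
    kaiser: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by pairwise planar rotations with Kaiser normalization.

    Each column pair is rotated by the closed-form optimal angle; sweeps
    repeat until the criterion gain falls below ``tol``. Returns the rotated
    loadings and the accumulated orthogonal rotation matrix T
    (rotated = loadings @ T). For k = 1 the rotation is the identity.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    T = np.eye(k)
    if k < 2:
        return L, T
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h = np.where(h > 1e-12, h, 1.0)
        L = L / h[:, None]

    crit = _varimax_criterion(L)
    for _ in range(max_sweeps):
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = L[:, a], L[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = (u**2 - v**2).sum()
                D = 2.0 * (u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [a, b]] = L[:, [a, b]] @ rot
                T[:, [a, b]] = T[:, [a, b]] @ rot
        new_crit = _varimax_criterion(L)
        if new_crit - crit < tol:
            break
        crit = new_crit

    if kaiser:
        L = L * h[:, None]
    return L, T


def promax(
    varimax_loadings: np.ndarray, power: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PROMAX oblique rotation of varimax-rotated loadings.

    The target raises each varimax loading to ``power`` preserving sign;
    the pattern is the oblique Procrustes fit to that target, with the
    transformation rescaled so the factor correlation matrix phi has a unit
    diagonal. Returns (pattern, structure, phi).
    """
    X = np.asarray(varimax_loadings, dtype=float)
    if power < 1:
        raise ValidationError("promax power must be >= 1")
    target = np.sign(X) * np.abs(X) ** power
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            "varimax loadings are near-singular; try fewer components"
        )
    U = np.linalg.solve(XtX, X.T @ target)        # oblique Procrustes transformation
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]                    # diag((U'U)^{-1}) = 1
    pattern = X @ U
    phi = np.linalg.inv(U.T @ U)
    phi = (phi + phi.T) / 2.0
    structure = pattern @ phi
    return pattern, structure, phi


def component_scores(
    Z: np.ndarray, structure: np.ndarray, R: np.ndarray | None = None
) -> np.ndarray:
    """Thurstone regression factor scores: ``Z R^{-1} structure``.

    R is the subtest correlation matrix (recomputed from Z when omitted); a
    near-singular R is ridge-stabilized by 1e-8 on the diagonal with a log
    message.
    """
    Z = np.asarray(Z, dtype=float)
    if R is None:
        R = np.corrcoef(Z, rowvar=False)
    try:
        cond = np.linalg.cond(R)
        if cond > 1e10:
            raise np.linalg.LinAlgError
        W = np.linalg.solve(R, structure)
    except np.linalg.LinAlgError:
        logger.info("correlation matrix near-singular; ridge-stabilizing (1e-8)")
        W = np.linalg.solve(R + 1e-8 * np.eye(R.shape[0]), structure)
    return Z @ W


def orient_components(pattern: np.ndarray) -> np.ndarray:
    """Sign flips (one per component) making each column's loading sum positive."""
    sums = pattern.sum(axis=0)
    flips = np.where(sums < 0, -1.0, 1.0)
    return flips


def ordered_correlation_matrix(
    Z: np.ndarray, pattern: np.ndarray, names: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subtest correlation matrix ordered by dominant component.

    Subtests are assigned to the component with their largest absolute
    pattern loading and sorted (component, then loading size) so correlated
    blocks line up along the diagonal.
    """
    Z = np.asarray(Z, dtype=float)
    R = np.corrcoef(Z, rowvar=False)
    p = R.shape[0]
    names = names if names is not None else [f"var{j}" for j in range(p)]
    assign = np.argmax(np.abs(pattern), axis=1)
    strength = np.abs(pattern)[np.arange(p), assign]
    order = np.lexsort((-strength, assign))
    ordered = pd.DataFrame(
        R[np.ix_(order, order)],
        index=[names[j] for j in order],
        columns=[names[j] for j in order],
    )
    return ordered, order


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence (cosine similarity) between two loading vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float(a @ b / denom) if denom > 0 else 0.0


class PromaxPCA(BaseEstimator, TransformerMixin):
    """PCA with PROMAX oblique rotation, scikit-learn style.

    Fit on a standardized deficit matrix (subjects x subtests). After
    fitting, components are sign-oriented so positive loadings indicate
    worse performance.

    Parameters
    ----------
    n_components : number of retained components (default 3).
    rotate : apply varimax + PROMAX; when False the unrotated solution is
        reported as pattern/structure with phi = I.
    power : PROMAX power (default 4).

    Attributes (after fit)
    ----------------------
    unrotated_loadings_ : p x k eigenvector loadings (scaled by sqrt eigenvalue).
    eigenvalues_ : first k eigenvalues; eigenvalues_all_ holds all p.
    variance_explained_ : proportions of total variance (eigenvalue / p).
    pattern_, structure_, phi_ : PROMAX pattern/structure loadings and
        factor correlations.
    scores_ : n x k Thurstone regression scores of the training data.
    sign_convention_ : per-component +-1 flips applied during orientation.
    """

    def __init__(self, n_components: int = 3, rotate: bool = True, power: int = 4):
        self.n_components = n_components
        self.rotate = rotate
        self.power = power

    def fit(self, X: np.ndarray, y=None) -> "PromaxPCA":
        Z = np.asarray(X, dtype=float)
        if Z.ndim != 2:
            raise ValidationError("expected a 2D subjects x subtests matrix")
        k = self.n_components
        loadings, eigvals_all, var_prop, unrot_scores = fit_pca(Z, k)
        self.correlation_ = np.corrcoef(Z, rowvar=False)
        self.eigenvalues_all_ = eigvals_all
        self.eigenvalues_ = eigvals_all[:k]
        self.variance_explained_ = var_prop

        if self.rotate and k >= 2:
            vmax, self.rotation_ = varimax(loadings)
            pattern, structure, phi = promax(vmax, power=self.power)
        else:
            pattern, structure, phi = loadings.copy(), loadings.copy(), np.eye(k)
            self.rotation_ = np.eye(k)

        flips = orient_components(pattern)
        pattern = pattern * flips[None, :]
        structure = structure * flips[None, :]
        phi = phi * np.outer(flips, flips)

        self.unrotated_loadings_ = loadings
        self.pattern_ = pattern
        self.structure_ = structure
        self.phi_ = phi
        self.sign_convention_ = flips
        self.scores_ = component_scores(Z, structure, R=self.correlation_)
        self.n_features_in_ = Z.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Thurstone regression scores of (already standardized) data."""
        check_is_fitted(self, "structure_")
        Z = np.asarray(X, dtype=float)
        if Z.shape[1] != self.n_features_in_:
            raise ValidationError("feature count differs from fit")
        return component_scores(Z, self.structure_, R=self.correlation_)

    def loading_table(self, names: list[str]) -> pd.DataFrame:
        check_is_fitted(self, "pattern_")
        k = self.pattern_.shape[1]
        cols = {}
        for c in range(k):
            cols[f"pattern_{c + 1}"] = self.pattern_[:, c]
        for c in range(k):
            cols[f"structure_{c + 1}"] = self.structure_[:, c]
        for c in range(k):
            cols[f"unrotated_{c + 1}"] = self.unrotated_loadings_[:, c]
        return pd.DataFrame(cols, index=names)
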