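"""Vascular-territory control analysis.

Tests whether the distribution of lesions across the three middle-cerebral-
artery territories (deep perforating, anterior-superior branch,
posterior-inferior branch) explains the behavioural component scores:
per-subject territory overlap vectors, k-means clustering with
silhouette / Davies-Bouldin selection of k, and a split-plot (mixed) ANOVA
with component (3 levels) as the within-subject factor and lesion cluster
as the between-subject factor, followed by Bonferroni-corrected pairwise
interaction contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .errors import ValidationError
from .images import LesionCohort
from .synthetic import TERRITORY_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "territory_overlap",
    "overlap_vectors",
    "silhouette_index",
    "davies_bouldin_index",
    "VascularClusterer",
    "cluster_subjects",
    "MixedAnovaResult",
    "mixed_anova",
    "posthoc_interaction",
]


def territory_overlap(lesion: np.ndarray, territory_atlas: np.ndarray) -> np.ndarray:
    """Percentage of the lesion inside each of the 3 pooled territories.

    Hemisphere-specific labels (1..3 left, 4..6 right) are pooled, so the
    result is a 3-vector (deep, anterior-superior, posterior-inferior) whose
    sum may be below 100 when the lesion extends outside the atlas.
    """
    lesion = np.asarray(lesion, dtype=bool)
    labels = np.asarray(territory_atlas)
    n = lesion.sum()
    if n == 0:
        raise ValidationError("empty lesion has no territory overlap")
    if lesion.shape != labels.shape:
        raise ValidationError("lesion and atlas are on different grids")
    out = np.empty(3)
    for t in range(3):
        pooled = (labels == t + 1) | (labels == t + 4)
        out[t] = 100.0 * (lesion & pooled).sum() / n
    return out


def overlap_vectors(cohort: LesionCohort, territory_atlas: np.ndarray) -> pd.DataFrame:
    """Overlap vectors for a cohort; all-zero-overlap subjects are excluded.

    A lesion with no overlap with any territory says nothing about MCA
    branch territory, so those subjects are dropped with a logged count.
    """
    rows, excluded = [], 0
    for im in cohort.images:
        if not im.mask.any():
            excluded += 1
            continue
        pct = territory_overlap(im.mask, territory_atlas)
        if pct.sum() == 0:
            excluded += 1
            continue
        rows.append({"subject_id": im.subject_id, **dict(zip(TERRITORY_NAMES, pct))})
    if excluded:
        logger.info("excluded %d subjects with no territory overlap", excluded)
    return pd.DataFrame(rows)


def silhouette_index(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b); singleton points contribute 0."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton convention: s = 0
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        m = max(a, b)
        s[i] = (b - a) / m if m > 0 else 0.0
    return float(s.mean())


def davies_bouldin_index(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of max_j (s_i + s_j) / d(c_i, c_j).

    s is the mean distance of members to their centroid. Coincident
    centroids make the ratio infinite; the index is then the inf sentinel.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValidationError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    spread = np.array(
        [np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            worst = max(worst, (spread[i] + spread[j]) / d if d > 0 else np.inf)
        ratios[i] = worst
    return float(ratios.mean())


class VascularClusterer(BaseEstimator, ClusterMixin):
    """k-means over territory-overlap vectors with index-based choice of k.

    For each candidate k, k-means (Euclidean, ``n_restarts`` initialisations,
    best inertia) is fitted; the chosen k maximizes the silhouette index with
    Davies-Bouldin (lower wins) breaking ties. Deterministic given
    ``random_state``.

    Attributes after fit: ``k_``, ``labels_`` (1-based, per the domain
    convention), ``silhouette_``, ``davies_bouldin_``, ``k_candidates_``
    (DataFrame of both indices per candidate k), ``cluster_centers_``.
    """

    def __init__(
        self,
        k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
        n_restarts: int = 50,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "VascularClusterer":
        X = np.asarray(X, dtype=float)
        k_range = sorted(set(int(k) for k in self.k_range))
        if min(k_range) < 2:
            raise ValidationError("k_range must start at 2 or above")
        if len(X) < 2 * max(k_range):
            raise ValidationError(
                f"need at least {2 * max(k_range)} subjects for k up to {max(k_range)}"
            )
        if np.allclose(X, X[0]):
            raise ValidationError("all overlap vectors are identical; nothing to cluster")

        rows = []
        best = None
        for ki, k in enumerate(k_range):
            import warnings as _warnings
            from sklearn.exceptions import ConvergenceWarning

            with _warnings.catch_warnings():
                # duplicate overlap vectors can make k-means return fewer
                # distinct clusters than requested; the index-based selection
                # below handles that degeneracy
                _warnings.simplefilter("ignore", ConvergenceWarning)
                km = KMeans(
                    n_clusters=k,
                    n_init=self.n_restarts,
                    random_state=self.random_state + ki,
                ).fit(X)
            labels = km.labels_
            sil = silhouette_index(X, labels)
            db = davies_bouldin_index(X, labels)
            rows.append({"k": k, "silhouette": sil, "davies_bouldin": db, "inertia": km.inertia_})
            cand = (sil, -db if np.isfinite(db) else -np.inf, k, km)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand

        self.k_candidates_ = pd.DataFrame(rows)
        sil, negdb, k, km = best
        self.k_ = int(k)
        self.labels_ = km.labels_ + 1
        self.silhouette_ = float(sil)
        self.davies_bouldin_ = float(-negdb) if np.isfinite(negdb) else float("inf")
        self.cluster_centers_ = km.cluster_centers_
        self._kmeans_ = km
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._kmeans_.predict(np.asarray(X, dtype=float)) + 1


def cluster_subjects(
    vectors: np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
) -> VascularClusterer:
    """Fit a :class:`VascularClusterer` (thin functional wrapper)."""
    return VascularClusterer(k_range=k_range, random_state=seed).fit(vectors)


@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA table plus sphericity correction and post hocs."""

    table: pd.DataFrame                 # rows: between, subjects, within, interaction, residual
    gg_epsilon: float
    posthoc: pd.DataFrame | None = None

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def _split_plot_ss(scores: np.ndarray, groups: np.ndarray):
    """Exact cell-mean decomposition of the split-plot design.

    Works for unbalanced group sizes; the five components sum to SS_total
    exactly for any input (cross terms cancel algebraically).
    """
    Y = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    n, p = Y.shape
    uniq, ginv = np.unique(groups, return_inverse=True)
    a = uniq.size
    sizes = np.bincount(ginv)
    if (sizes < 2).any():
        bad = uniq[np.argmin(sizes)]
        raise ValidationError(f"cluster {bad!r} has fewer than 2 subjects")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)                        # n
    level_means = Y.mean(axis=0)                       # p
    group_means = np.array([Y[ginv == g].mean() for g in range(a)])
    cell_means = np.stack([Y[ginv == g].mean(axis=0) for g in range(a)])  # a x p

    ss_between = p * float((sizes * (group_means - grand) ** 2).sum())
    ss_subjects = p * float(((subj_means - group_means[ginv]) ** 2).sum())
    ss_within = n * float(((level_means - grand) ** 2).sum())
    inter = cell_means - group_means[:, None] - level_means[None, :] + grand
    ss_inter = float((sizes[:, None] * inter**2).sum())
    resid = Y - subj_means[:, None] - cell_means[ginv] + group_means[ginv][:, None]
    ss_resid = float((resid**2).sum())

    df = {
        "between": a - 1,
        "subjects": n - a,
        "within": p - 1,
        "interaction": (a - 1) * (p - 1),
        "residual": (n - a) * (p - 1),
    }
    ss = {
        "between": ss_between,
        "subjects": ss_subjects,
        "within": ss_within,
        "interaction": ss_inter,
        "residual": ss_resid,
    }
    return ss, df, ginv, a


def _gg_epsilon(scores: np.ndarray, ginv: np.ndarray, a: int) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    Y = np.asarray(scores, dtype=float)
    n, p = Y.shape
    resid = np.concatenate([Y[ginv == g] - Y[ginv == g].mean(axis=0) for g in range(a)])
    S = resid.T @ resid / (n - a)
    H = np.eye(p) - np.ones((p, p)) / p
    Sc = H @ S @ H
    tr = np.trace(Sc)
    denom = (p - 1) * (Sc**2).sum()
    return float(tr**2 / denom) if denom > 1e-300 else 1.0


def mixed_anova(scores: np.ndarray, clusters: np.ndarray) -> MixedAnovaResult:
    """Split-plot ANOVA: components within subjects, lesion cluster between.

    The between effect is tested against the subjects-within-clusters mean
    square; the within (component) and interaction effects against the
    component x subject-within-cluster residual mean square.
    Greenhouse-Geisser epsilon is reported alongside the uncorrected
    p-values (p_gg columns for the within-subject effects).
    """
    ss, df, ginv, a = _split_plot_ss(scores, clusters)
    ms = {k: ss[k] / df[k] if df[k] > 0 else np.nan for k in ss}
    eps = _gg_epsilon(scores, ginv, a)

    rows = []
    for effect, err in (("between", "subjects"), ("within", "residual"), ("interaction", "residual")):
        if ms[err] > 0:
            F = ms[effect] / ms[err]
            p_unc = stats.f.sf(F, df[effect], df[err])
        else:
            F, p_unc = 0.0, 1.0
        row = {
            "SS": ss[effect],
            "df1": df[effect],
            "df2": df[err],
            "MS": ms[effect],
            "F": F,
            "p": p_unc,
        }
        if err == "residual":
            row["p_gg"] = float(stats.f.sf(F, df[effect] * eps, df[err] * eps)) if ms[err] > 0 else 1.0
        else:
            row["p_gg"] = np.nan
        rows.append((effect, row))
    for extra in ("subjects", "residual"):
        rows.append(
            (extra, {"SS": ss[extra], "df1": df[extra], "df2": np.nan, "MS": ms[extra],
                     "F": np.nan, "p": np.nan, "p_gg": np.nan})
        )
    table = pd.DataFrame({name: row for name, row in rows}).T
    return MixedAnovaResult(table=table, gg_epsilon=eps)


def posthoc_interaction(scores: np.ndarray, clusters: np.ndarray) -> pd.DataFrame:
    """Pairwise 2 x p interaction contrasts, Bonferroni-corrected by C(k,2)."""
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    pairs = list(combinations(uniq, 2))
    m = len(pairs)
    rows = []
    for c1, c2 in pairs:
        sel = (clusters == c1) | (clusters == c2)
        res = mixed_anova(scores[sel], clusters[sel])
        F = res.F("interaction")
        p_raw = res.p("interaction")
        rows.append(
            {
                "cluster_a": c1,
                "cluster_b": c2,
                "F": F,
                "df1": res.table.loc["interaction", "df1"],
                "df2": res.table.loc["interaction", "df2"],
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw),
            }
        )
    return pd.DataFrame(rows)
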