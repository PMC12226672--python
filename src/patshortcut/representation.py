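"""Representation-similarity analysis of trained encoders.

How strongly does an encoder separate sex subgroups versus disease subgroups?
Penultimate features of a balanced subject subset are projected onto their
first two principal components, and the separation of each grouping (F vs M,
H vs D) is measured as the exact order-2 Wasserstein distance between the two
projected point clouds (uniform weights, Euclidean ground metric). Repeating
this over many balanced draws gives a distribution of distance pairs
(w_sex, w_disease); the run whose pair lies closest to the geometric median of
all pairs is kept as the representative projection for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .metrics import auroc
from .modeling import Ensemble, TrainedModel, extract_features, labels_for
from .synthgen import Subject, cohort_metadata

__all__ = [
    "ProjectionResult",
    "RepresentationSummary",
    "select_representative_model",
    "draw_balanced_subsets",
    "pca_project",
    "wasserstein_2d",
    "geometric_median",
    "representation_experiment",
]


@dataclass(frozen=True)
class ProjectionResult:
    """2-D PCA projection with explained-variance fractions and loadings."""

    points: np.ndarray = field(repr=False)  # (n, 2)
    explained_variance_fractions: tuple[float, float]
    loadings: np.ndarray = field(repr=False)  # (2, d_feat)

    def __post_init__(self) -> None:
        f1, f2 = self.explained_variance_fractions
        if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0 and f1 + f2 <= 1.0 + 1e-9):
            raise ValueError("explained-variance fractions must be in [0,1], sum <= 1")


def select_representative_model(
    ensemble: Ensemble, in_distribution_test_set: Sequence[Subject]
) -> TrainedModel:
    """Member whose test AUROC is closest to the median member AUROC.

    With an even member count no member attains the median exactly; the
    closest one wins, ties broken by lowest member index.
    """
    y = labels_for(in_distribution_test_set, ensemble.task)
    aurocs = [auroc(m.predict_proba(in_distribution_test_set), y) for m in ensemble.members]
    med = float(np.median(aurocs))
    best = min(range(len(aurocs)), key=lambda i: (abs(aurocs[i] - med), i))
    return ensemble.members[best]


def draw_balanced_subsets(
    test_pool: Sequence[Subject] | pd.DataFrame,
    per_stratum: int = 7,
    n_runs: int = 1000,
    seed: int = 0,
) -> list[list[str]]:
    """Balanced (PR = 1) subject-id subsets: ``per_stratum`` per sex-disease
    stratum, drawn without replacement within each run; runs independent."""
    meta = test_pool if isinstance(test_pool, pd.DataFrame) else cohort_metadata(test_pool)
    key = meta["sex"].astype(str) + meta["disease"].astype(str)
    strata = {}
    for k in ("FH", "FD", "MH", "MD"):
        ids = sorted(meta.loc[key == k, "subject_id"])
        if len(ids) < per_stratum:
            raise ValueError(f"stratum {k} has {len(ids)} subjects, {per_stratum} needed")
        strata[k] = np.array(ids)
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        subset: list[str] = []
        for k in ("FH", "FD", "MH", "MD"):
            subset.extend(rng.choice(strata[k], size=per_stratum, replace=False).tolist())
        runs.append(subset)
    return runs


def pca_project(features: np.ndarray, n_components: int = 2) -> ProjectionResult:
    """Project centered (not variance-scaled) features onto the top-2 PCs.

    Sign convention: each component's largest-magnitude loading is positive.
    Raises on inputs of rank < 2, where a 2-D projection is meaningless.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 samples")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < n_components:
        raise ValueError("feature matrix has rank < 2 after centering")
    pca = PCA(n_components=n_components, svd_solver="full")
    pts = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] = -loadings[c]
            pts[:, c] = -pts[:, c]
    evf = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    return ProjectionResult(points=pts, explained_variance_fractions=evf, loadings=loadings)


def wasserstein_2d(points_a: np.ndarray, points_b: np.ndarray, order: int = 2) -> float:
    """Exact Wasserstein distance between two planar empirical distributions.

    Uniform weights, Euclidean ground metric, order ``order`` (default 2).
    Equal-size sets reduce to a linear assignment; unequal sizes solve the
    transportation LP exactly.
    """
    A = np.atleast_2d(np.asarray(points_a, dtype=float))
    B = np.atleast_2d(np.asarray(points_b, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("point sets must be non-empty")
    m, k = A.shape[0], B.shape[0]
    cost = cdist(A, B) ** order
    if m == k:
        ri, ci = linear_sum_assignment(cost)
        return float((cost[ri, ci].mean()) ** (1.0 / order))
    # transportation LP: minimize <cost, P> s.t. row sums 1/m, col sums 1/k
    c = cost.ravel()
    A_eq = np.zeros((m + k, m * k))
    for i in range(m):
        A_eq[i, i * k : (i + 1) * k] = 1.0
    for j in range(k):
        A_eq[m + j, j::k] = 1.0
    b_eq = np.concatenate([np.full(m, 1.0 / m), np.full(k, 1.0 / k)])
    res = linprog(c, A_eq=A_eq[:-1], b_eq=b_eq[:-1], bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun ** (1.0 / order))


def geometric_median(points: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000) -> np.ndarray:
    """Point minimizing total Euclidean distance (Weiszfeld iteration).

    Iterates from the centroid; when the iterate lands on a data point the
    Vardi-Zhang correction decides whether that point is the minimizer.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.shape[0] == 1:
        return X[0].copy()
    y = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - y, axis=1)
        on_point = d < 1e-12
        if on_point.any():
            # Vardi-Zhang: stay if the pull of the others is weaker than the
            # multiplicity of the coincident point
            others = ~on_point
            if not others.any():
                return y
            r = np.sum((X[others] - y) / d[others, None], axis=0)
            rnorm = np.linalg.norm(r)
            eta = float(on_point.sum())
            if rnorm <= eta:
                return y
            y_new = y + max(0.0, 1.0 - eta / rnorm) * r / np.sum(1.0 / d[others])
        else:
            w = 1.0 / d
            y_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


@dataclass(frozen=True)
class RepresentationSummary:
    """Per-run subgroup Wasserstein distances for one model, with the
    geometric-median-representative run retained for display."""

    per_run_w_sex: tuple
    per_run_w_disease: tuple
    median_w_sex: float
    iqr_w_sex: tuple[float, float]
    median_w_disease: float
    iqr_w_disease: tuple[float, float]
    representative_run_index: int
    representative_projection: ProjectionResult = field(repr=False)
    representative_subject_ids: tuple = ()

    def to_dict(self) -> dict:
        return {
            "median_w_sex": self.median_w_sex,
            "iqr_w_sex": list(self.iqr_w_sex),
            "median_w_disease": self.median_w_disease,
            "iqr_w_disease": list(self.iqr_w_disease),
            "representative_run_index": self.representative_run_index,
            "explained_variance_fractions": list(
                self.representative_projection.explained_variance_fractions
            ),
            "n_runs": len(self.per_run_w_sex),
        }


def _summarize_model(
    model: TrainedModel,
    subsets: list[list[str]],
    by_id: dict[str, Subject],
) -> RepresentationSummary:
    w_sex, w_disease, projections = [], [], []
    for subset in subsets:
        subjects = [by_id[sid] for sid in subset]
        feats = extract_features(model, subjects)
        try:
            proj = pca_project(feats)
        except ValueError:
            # degenerate (rank < 2) feature cloud: a collapsed encoder — the
            # projection is a point mass and every subgroup distance is 0
            proj = ProjectionResult(
                points=np.zeros((feats.shape[0], 2)),
                explained_variance_fractions=(0.0, 0.0),
                loadings=np.zeros((2, feats.shape[1])),
            )
        sex_is_f = np.array([s.sex == "F" for s in subjects])
        dis_is_d = np.array([s.disease == "D" for s in subjects])
        w_sex.append(wasserstein_2d(proj.points[sex_is_f], proj.points[~sex_is_f]))
        w_disease.append(wasserstein_2d(proj.points[dis_is_d], proj.points[~dis_is_d]))
        projections.append(proj)
    pairs = np.column_stack([w_sex, w_disease])
    med = geometric_median(pairs)
    dists = np.linalg.norm(pairs - med, axis=1)
    rep = int(np.argmin(dists))  # argmin takes the lowest index on ties
    qs_lo, qs_hi = np.percentile(w_sex, [25, 75])
    qd_lo, qd_hi = np.percentile(w_disease, [25, 75])
    return RepresentationSummary(
        per_run_w_sex=tuple(w_sex),
        per_run_w_disease=tuple(w_disease),
        median_w_sex=float(np.median(w_sex)),
        iqr_w_sex=(float(qs_lo), float(qs_hi)),
        median_w_disease=float(np.median(w_disease)),
        iqr_w_disease=(float(qd_lo), float(qd_hi)),
        representative_run_index=rep,
        representative_projection=projections[rep],
        representative_subject_ids=tuple(subsets[rep]),
    )


def representation_experiment(
    model_pr1: TrainedModel,
    model_prinf: TrainedModel,
    test_pool: Sequence[Subject],
    per_stratum: int = 7,
    n_runs: int = 1000,
    seed: int = 0,
) -> dict[str, RepresentationSummary]:
    """Compare subgroup separation in the feature spaces of a balanced-trained
    and an extreme-PR-trained model over many balanced subject draws.

    Both models see the *same* subsets (common random draws), PCA is refit per
    subset on its 28 points, and each grouping's Wasserstein distance is
    computed between the two 14-point clouds.
    """
    by_id = {s.subject_id: s for s in test_pool}
    subsets = draw_balanced_subsets(test_pool, per_stratum=per_stratum,
                                    n_runs=n_runs, seed=seed)
    return {
        "pr1": _summarize_model(model_pr1, subsets, by_id),
        "prinf": _summarize_model(model_prinf, subsets, by_id),
    }
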