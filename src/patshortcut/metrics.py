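"""AUROC with PR-stratified bootstrap CIs, prevalence-shift matrices, and the
underdiagnosis-disparity statistic.

Evaluation never refits anything: subject scores are computed once and the
bootstrap resamples only the index set, drawing the per-stratum counts of the
target prevalence ratio with replacement so every replicate respects that PR.
The underdiagnosis disparity is (FN/FP for females) - (FN/FP for males) on
binarized predictions; positive values mean females are disproportionately
missed. When either sex has zero false positives the statistic is undefined
and reported as such rather than smoothed — an optional epsilon smoothing
exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .sampling import SamplingPlan, StratumCounts
from .seeding import BOOTSTRAP, TRAINING, derive_seed

__all__ = [
    "BootstrapSummary",
    "DisparitySummary",
    "auroc",
    "stratified_bootstrap_auroc",
    "shift_matrix",
    "underdiagnosis_disparity",
    "disparity_experiment",
]


def auroc(scores, labels) -> float:
    """Area under the ROC curve: P(random positive outscores random negative),
    ties counted half. Raises on single-class input."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class BootstrapSummary:
    """Mean AUROC and percentile 95% CI from PR-respecting resampling."""

    mean_auroc: float
    ci_low: float
    ci_high: float
    n_iter: int
    test_pr: object = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValueError("CI bounds must satisfy 0 <= low <= high <= 1")
        if not 0.0 <= self.mean_auroc <= 1.0:
            raise ValueError("mean AUROC must lie in [0, 1]")

    def to_dict(self) -> dict:
        from .sampling import pr_label

        return {
            "mean_auroc": self.mean_auroc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_iter": self.n_iter,
            "test_pr": None if self.test_pr is None else pr_label(self.test_pr),
            "n_skipped": self.n_skipped,
        }


def stratified_bootstrap_auroc(
    scores: Mapping[str, float],
    test_pool_metadata: pd.DataFrame,
    test_counts: StratumCounts,
    task: str = "disease",
    n_iter: int = 1000,
    seed: int = 0,
    test_pr=None,
) -> BootstrapSummary:
    """Bootstrap AUROC at fixed per-stratum counts.

    Each iteration draws ``test_counts`` subjects per sex-by-disease stratum
    from the pool with replacement and scores the AUROC of ``task`` labels.
    Iterations where only one class is drawn are skipped and counted.
    """
    meta = test_pool_metadata
    key = meta["sex"].astype(str) + meta["disease"].astype(str)
    wanted = {"FH": test_counts.fh, "FD": test_counts.fd,
              "MH": test_counts.mh, "MD": test_counts.md}
    strata_scores, strata_labels = [], []
    label_col = "sex" if task == "sex" else "disease"
    pos = "M" if task == "sex" else "D"
    for k, n in wanted.items():
        if n == 0:
            continue
        sub = meta.loc[key == k].sort_values("subject_id")
        if sub.empty:
            raise ValueError(f"test pool has no subjects in stratum {k}")
        strata_scores.append(np.array([scores[sid] for sid in sub["subject_id"]]))
        strata_labels.append((sub[label_col] == pos).to_numpy().astype(float))

    rng = np.random.default_rng(seed)
    counts = [wanted[k] for k in wanted if wanted[k] > 0]
    vals = []
    skipped = 0
    for _ in range(n_iter):
        s_parts, y_parts = [], []
        for sc, lb, n in zip(strata_scores, strata_labels, counts):
            idx = rng.integers(0, sc.size, size=n)
            s_parts.append(sc[idx])
            y_parts.append(lb[idx])
        y = np.concatenate(y_parts)
        if y.min() == y.max():
            skipped += 1
            continue
        vals.append(roc_auc_score(y, np.concatenate(s_parts)))
    if not vals:
        raise ValueError("every bootstrap iteration was single-class")
    vals = np.asarray(vals)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapSummary(
        mean_auroc=float(vals.mean()), ci_low=float(lo), ci_high=float(hi),
        n_iter=n_iter, test_pr=test_pr, n_skipped=skipped,
    )


def shift_matrix(
    ensembles: Mapping,
    test_pool,
    plans: Mapping,
    task: str = "disease",
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Train-PR x test-PR grid of bootstrap summaries.

    ``ensembles`` maps each training PR to its ensemble; ``plans`` maps each
    PR to the :class:`SamplingPlan` whose ``test_counts`` define the test-side
    stratification. Each ensemble's subject scores are computed once.
    """
    from .synthgen import cohort_metadata

    meta = cohort_metadata(test_pool)
    matrix: dict = {}
    for i, (pr_train, ens) in enumerate(ensembles.items()):
        probs = ens.predict_proba(test_pool)
        score_map = dict(zip(meta["subject_id"], probs))
        for j, (pr_test, plan) in enumerate(plans.items()):
            matrix[(pr_train, pr_test)] = stratified_bootstrap_auroc(
                score_map, meta, plan.test_counts, task=task, n_iter=n_iter,
                seed=derive_seed(seed, BOOTSTRAP, i, j), test_pr=pr_test,
            )
    return matrix


def underdiagnosis_disparity(
    binary_predictions,
    disease_labels,
    sex_labels,
    epsilon: float = 0.0,
) -> float | None:
    """(FN_F / FP_F) - (FN_M / FP_M), counted within each sex.

    ``disease_labels`` uses 1/'D' for diseased, ``sex_labels`` 'F'/'M'.
    Returns None (undefined) when either sex has zero false positives and no
    smoothing is requested.
    """
    pred = np.asarray(binary_predictions).astype(int)
    disease = np.asarray(disease_labels)
    if disease.dtype.kind in "UO":
        disease = (disease == "D").astype(int)
    sex = np.asarray(sex_labels)
    ratios = {}
    for s in ("F", "M"):
        m = sex == s
        if not m.any():
            raise ValueError(f"no subjects of sex {s}")
        fn = int(np.sum((pred == 0) & (disease == 1) & m))
        fp = int(np.sum((pred == 1) & (disease == 0) & m))
        if fp == 0 and epsilon == 0.0:
            return None
        ratios[s] = (fn + epsilon) / (fp + epsilon)
    return float(ratios["F"] - ratios["M"])


@dataclass(frozen=True)
class DisparitySummary:
    """Underdiagnosis disparity over repeated independently trained ensembles."""

    per_run: tuple
    mean: float
    median: float
    iqr_low: float
    iqr_high: float
    undefined_run_count: int
    pr: object = None

    @classmethod
    def from_runs(cls, values: Sequence, pr=None) -> "DisparitySummary":
        defined = np.array([v for v in values if v is not None], dtype=float)
        if defined.size == 0:
            return cls(per_run=tuple(values), mean=np.nan, median=np.nan,
                       iqr_low=np.nan, iqr_high=np.nan,
                       undefined_run_count=len(values), pr=pr)
        lo, hi = np.percentile(defined, [25, 75])
        return cls(
            per_run=tuple(values), mean=float(defined.mean()),
            median=float(np.median(defined)), iqr_low=float(lo),
            iqr_high=float(hi), undefined_run_count=len(values) - defined.size,
            pr=pr,
        )

    def to_dict(self) -> dict:
        from .sampling import pr_label

        return {
            "per_run": [None if v is None else float(v) for v in self.per_run],
            "mean": self.mean, "median": self.median,
            "iqr_low": self.iqr_low, "iqr_high": self.iqr_high,
            "undefined_run_count": self.undefined_run_count,
            "pr": None if self.pr is None else pr_label(self.pr),
        }


def disparity_experiment(
    train_pool,
    val_pool,
    test_pool,
    plans: Mapping,
    spec=None,
    n_models: int = 10,
    n_runs: int = 10,
    master_seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Per-PR disparity over ``n_runs`` freshly trained ensembles.

    Every run trains a new ensemble at the plan's PR and evaluates the
    disparity on the ENTIRE test pool (never a PR-resampled subset), with
    ensemble mean probabilities binarized at ``threshold``.
    """
    from .modeling import train_ensemble
    from .synthgen import cohort_metadata

    meta = cohort_metadata(test_pool)
    disease = meta["disease"].to_numpy()
    sex = meta["sex"].to_numpy()
    out = {}
    for k, (pr, plan) in enumerate(plans.items()):
        runs = []
        for r in range(n_runs):
            ens = train_ensemble(
                train_pool, val_pool, plan, task="disease", spec=spec,
                n_models=n_models,
                master_seed=derive_seed(master_seed, TRAINING, k, r),
            )
            pred = (ens.predict_proba(test_pool) >= threshold).astype(int)
            runs.append(underdiagnosis_disparity(pred, disease, sex))
        out[pr] = DisparitySummary.from_runs(runs, pr=pr)
    return out
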