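"""End-to-end audit pipelines.

Four experiment drivers, each runnable from one config and one master seed:

* RQ1 — can a classifier decode sex at all, and does a sex classifier
  generalize to other body sites (out-of-distribution site profiles)?
* RQ2 — how does disease-classification AUROC move across a train-PR x
  test-PR grid of sex-specific prevalence ratios?
* RQ3 — how does the underdiagnosis disparity between sexes grow with the
  training PR?
* RQ4 — are sex and disease encodings interchangeable (frozen-encoder head
  transfer), and does extreme-PR training make the feature space more
  sex-separated (PCA + Wasserstein)?

All randomness is derived from ``master_seed`` via documented stream paths
(:mod:`patshortcut.seeding`), so a rerun with the same config and seed
produces byte-identical report JSONs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics, representation
from .modeling import ClassifierSpec, retrain_head, train_ensemble
from .sampling import (INFINITY, SamplingPlan, StratumCounts, pr_label,
                       solve_stratum_counts)
from .seeding import BOOTSTRAP, EXPERIMENT, GENERATOR, SAMPLING, SUBSETS, TRAINING, derive_seed
from .synthgen import GeneratorConfig, Subject, cohort_metadata, generate_pool

__all__ = ["ExperimentConfig", "PROFILES", "build_pools", "default_plans",
           "run_rq1", "run_rq2", "run_rq3", "run_rq4", "run_all", "write_report"]

_PR_GRID = (1, 2, 5, INFINITY)


@dataclass(frozen=True)
class ExperimentConfig:
    """Every protocol constant of the audit in one place.

    Pool strata are the synthetic stand-ins for the clinical pools
    (86/21/40 subjects with near-even sex-disease strata, arranged so every
    PR in the grid is drawable without replacement from the training and
    validation pools).
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_totals: tuple[int, int, int] = (48, 12, 24)
    train_pool_strata: tuple[int, int, int, int] = (24, 19, 19, 24)
    val_pool_strata: tuple[int, int, int, int] = (6, 5, 4, 6)
    test_pool_strata: tuple[int, int, int, int] = (10, 10, 10, 10)
    pr_grid: tuple = _PR_GRID
    n_models: int = 10
    n_iter: int = 1000
    n_runs_disparity: int = 10
    n_runs_representation: int = 1000
    per_stratum: int = 7
    n_ood_per_sex: int = 24
    d_feat: int = 32
    conv_channels: tuple[int, int, int] = (8, 16, 16)
    learning_rate: float = 3e-3
    batch_size: int = 16
    max_epochs: int = 80
    patience: int = 12
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_models", "n_iter", "n_runs_disparity",
                     "n_runs_representation", "per_stratum", "n_ood_per_sex"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        self.validate_pr_grid()

    # -- feasibility is checked up front, before any training ----------------
    def validate_pr_grid(self) -> None:
        pools = (self.train_pool_strata, self.val_pool_strata, self.test_pool_strata)
        for pr in self.pr_grid:
            for total, pool in zip(self.split_totals, pools):
                counts = solve_stratum_counts(total, pr)  # raises if non-integer
                # test sets are drawn with replacement; train/val are not
                if pool is not self.test_pool_strata:
                    for have, want in zip(pool, counts.as_tuple()):
                        if want > have:
                            raise ValueError(
                                f"PR={pr_label(pr)}: split needs {want} subjects in a "
                                f"stratum holding only {have}"
                            )

    @property
    def pool_sizes(self) -> tuple[int, int, int]:
        return (sum(self.train_pool_strata), sum(self.val_pool_strata),
                sum(self.test_pool_strata))

    def make_spec(self, task: str) -> ClassifierSpec:
        g = self.generator
        return ClassifierSpec(
            image_shape=(g.n_channels, g.image_height, g.image_width),
            task=task, d_feat=self.d_feat, conv_channels=self.conv_channels,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
        )

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pr_grid"] = [pr_label(pr) for pr in self.pr_grid]
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExperimentConfig":
        data = dict(data)
        if "generator" in data and isinstance(data["generator"], Mapping):
            data["generator"] = GeneratorConfig(**data["generator"])
        if "pr_grid" in data:
            data["pr_grid"] = tuple(
                INFINITY if str(p) in ("inf", "Infinity") else int(p)
                for p in data["pr_grid"]
            )
        for key in ("split_totals", "train_pool_strata", "val_pool_strata",
                    "test_pool_strata", "conv_channels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


#: Named configurations: the full study protocol, and a desk-scale profile for
#: quick runs and continuous testing.
PROFILES: dict[str, ExperimentConfig] = {
    "paper": ExperimentConfig(),
    "fast": ExperimentConfig(
        generator=GeneratorConfig(image_height=32, image_width=32),
        n_models=2, n_iter=100, n_runs_disparity=5,
        n_runs_representation=50, max_epochs=30, patience=6,
    ),
}


def default_plans(config: ExperimentConfig) -> dict:
    """One :class:`SamplingPlan` per PR in the grid."""
    return {
        pr: SamplingPlan.from_totals(pr, config.split_totals, config.pool_sizes)
        for pr in config.pr_grid
    }


def build_pools(config: ExperimentConfig):
    """Generate the three fixed subject pools (train / val / test)."""
    seed0 = derive_seed(config.master_seed, GENERATOR, 0)
    pools = []
    for k, (strata, prefix) in enumerate(
        zip((config.train_pool_strata, config.val_pool_strata, config.test_pool_strata),
            ("TR", "VA", "TE"))
    ):
        counts = StratumCounts(*strata)
        pools.append(
            generate_pool(counts, config.generator,
                          seed=derive_seed(seed0, k), id_prefix=prefix)
        )
    return tuple(pools)


def _plan_pr1(config: ExperimentConfig) -> SamplingPlan:
    return SamplingPlan.from_totals(1, config.split_totals, config.pool_sizes)


# --------------------------------------------------------------------------
# RQ1: sex separability + out-of-distribution body sites
# --------------------------------------------------------------------------

def run_rq1(config: ExperimentConfig, pools=None) -> dict:
    """Sex vs disease separability at PR=1, plus OOD site generalization."""
    train_pool, val_pool, test_pool = pools or build_pools(config)
    plan = _plan_pr1(config)
    test_meta = cohort_metadata(test_pool)
    report: dict = {"in_distribution": {}, "ood_sex": {}}
    ensembles = {}
    for t, task in enumerate(("sex", "disease")):
        ens = train_ensemble(
            train_pool, val_pool, plan, task=task, spec=config.make_spec(task),
            n_models=config.n_models,
            master_seed=derive_seed(config.master_seed, EXPERIMENT, 1, t),
        )
        ensembles[task] = ens
        probs = ens.predict_proba(test_pool)
        summary = metrics.stratified_bootstrap_auroc(
            dict(zip(test_meta["subject_id"], probs)), test_meta,
            plan.test_counts, task=task, n_iter=config.n_iter,
            seed=derive_seed(config.master_seed, BOOTSTRAP, 1, t), test_pr=1,
        )
        report["in_distribution"][task] = summary.to_dict()

    # healthy-volunteer cohorts at three body sites, sex task only
    n = config.n_ood_per_sex
    ood_counts = StratumCounts(fh=n, fd=0, mh=n, md=0)
    eval_counts = StratumCounts(fh=min(n, plan.test_counts.total // 2), fd=0,
                                mh=min(n, plan.test_counts.total // 2), md=0)
    for s, site in enumerate(("calf", "forearm", "neck")):
        gen = config.generator.replace(site_profile=site)
        cohort = generate_pool(
            ood_counts, gen,
            seed=derive_seed(config.master_seed, GENERATOR, 1, s),
            id_prefix=f"OOD{site[:2].upper()}",
        )
        meta = cohort_metadata(cohort)
        probs = ensembles["sex"].predict_proba(cohort)
        summary = metrics.stratified_bootstrap_auroc(
            dict(zip(meta["subject_id"], probs)), meta, eval_counts,
            task="sex", n_iter=config.n_iter,
            seed=derive_seed(config.master_seed, BOOTSTRAP, 1, 10 + s),
        )
        report["ood_sex"][site] = summary.to_dict()
    return report


# --------------------------------------------------------------------------
# RQ2: train-PR x test-PR shift matrix
# --------------------------------------------------------------------------

def run_rq2(config: ExperimentConfig, pools=None) -> dict:
    """Disease ensembles at each training PR, evaluated at every test PR."""
    train_pool, val_pool, test_pool = pools or build_pools(config)
    plans = default_plans(config)
    ensembles = {
        pr: train_ensemble(
            train_pool, val_pool, plan, task="disease",
            spec=config.make_spec("disease"), n_models=config.n_models,
            master_seed=derive_seed(config.master_seed, EXPERIMENT, 2, k),
        )
        for k, (pr, plan) in enumerate(plans.items())
    }
    matrix = metrics.shift_matrix(
        ensembles, test_pool, plans, task="disease", n_iter=config.n_iter,
        seed=derive_seed(config.master_seed, BOOTSTRAP, 2),
    )
    report = {"matrix": {}}
    for (pr_tr, pr_te), summary in matrix.items():
        report["matrix"].setdefault(pr_label(pr_tr), {})[pr_label(pr_te)] = summary.to_dict()
    return report


# --------------------------------------------------------------------------
# RQ3: underdiagnosis disparity vs training PR
# --------------------------------------------------------------------------

def run_rq3(config: ExperimentConfig, pools=None) -> dict:
    """Per-PR disparity over freshly trained ensembles, whole test pool."""
    train_pool, val_pool, test_pool = pools or build_pools(config)
    plans = default_plans(config)
    summaries = metrics.disparity_experiment(
        train_pool, val_pool, test_pool, plans,
        spec=config.make_spec("disease"), n_models=config.n_models,
        n_runs=config.n_runs_disparity,
        master_seed=derive_seed(config.master_seed, EXPERIMENT, 3),
    )
    return {"disparity": {pr_label(pr): s.to_dict() for pr, s in summaries.items()}}


# --------------------------------------------------------------------------
# RQ4: frozen-encoder transfer + representation analysis
# --------------------------------------------------------------------------

def _in_distribution_subjects(test_pool: Sequence[Subject], counts: StratumCounts):
    """Test-pool subjects in the strata that a PR's test counts actually use."""
    wanted = {("F", "H"): counts.fh, ("F", "D"): counts.fd,
              ("M", "H"): counts.mh, ("M", "D"): counts.md}
    return [s for s in test_pool if wanted[(s.sex, s.disease)] > 0]


def run_rq4(config: ExperimentConfig, pools=None) -> dict:
    """(a) cross-task head retraining at PR=1; (b) PCA/Wasserstein subgroup
    separation of PR=1- vs PR=inf-trained disease models."""
    train_pool, val_pool, test_pool = pools or build_pools(config)
    plan1 = _plan_pr1(config)
    test_meta = cohort_metadata(test_pool)
    seed4 = derive_seed(config.master_seed, EXPERIMENT, 4)

    ensembles = {
        task: train_ensemble(
            train_pool, val_pool, plan1, task=task, spec=config.make_spec(task),
            n_models=config.n_models, master_seed=derive_seed(seed4, t),
        )
        for t, task in enumerate(("sex", "disease"))
    }

    # one balanced PR=1 training draw shared by every head refit
    train_meta = cohort_metadata(train_pool)
    by_id = {s.subject_id: s for s in train_pool}
    from .sampling import sample_at_pr

    head_ids = sample_at_pr(train_meta, plan1.train_counts,
                            derive_seed(seed4, SAMPLING, 99))
    head_set = [by_id[i] for i in head_ids]

    def _boot(ens, task, tag):
        probs = ens.predict_proba(test_pool)
        return metrics.stratified_bootstrap_auroc(
            dict(zip(test_meta["subject_id"], probs)), test_meta,
            plan1.test_counts, task=task, n_iter=config.n_iter,
            seed=derive_seed(seed4, BOOTSTRAP, tag), test_pr=1,
        ).to_dict()

    report: dict = {"transfer": {}, "representation": {}}
    other = {"sex": "disease", "disease": "sex"}
    for t, task in enumerate(("sex", "disease")):
        ens = ensembles[task]
        new_task = other[task]
        transferred = dataclasses.replace(
            ens,
            members=[
                retrain_head(m, head_set, new_task, seed=derive_seed(seed4, TRAINING, t, i))
                for i, m in enumerate(ens.members)
            ],
            task=new_task,
        )
        report["transfer"][f"{task}_before"] = _boot(ens, task, t)
        report["transfer"][f"{task}_to_{new_task}"] = _boot(transferred, new_task, 10 + t)

    # representation analysis: disease models trained at PR=1 vs PR=inf
    plan_inf = SamplingPlan.from_totals(INFINITY, config.split_totals, config.pool_sizes)
    ens_inf = train_ensemble(
        train_pool, val_pool, plan_inf, task="disease",
        spec=config.make_spec("disease"), n_models=config.n_models,
        master_seed=derive_seed(seed4, 5),
    )
    rep1 = representation.select_representative_model(
        ensembles["disease"], _in_distribution_subjects(test_pool, plan1.test_counts))
    repinf = representation.select_representative_model(
        ens_inf, _in_distribution_subjects(test_pool, plan_inf.test_counts))
    summaries = representation.representation_experiment(
        rep1, repinf, test_pool, per_stratum=config.per_stratum,
        n_runs=config.n_runs_representation,
        seed=derive_seed(seed4, SUBSETS),
    )
    report["representation"] = {k: v.to_dict() for k, v in summaries.items()}
    report["_representation_summaries"] = summaries  # full objects, not serialized
    return report


def run_all(config: ExperimentConfig, pools=None) -> dict:
    pools = pools or build_pools(config)
    return {
        "rq1": run_rq1(config, pools),
        "rq2": run_rq2(config, pools),
        "rq3": run_rq3(config, pools),
        "rq4": run_rq4(config, pools),
    }


# --------------------------------------------------------------------------
# report serialization
# --------------------------------------------------------------------------

def write_report(report: dict, out_dir, name: str) -> Path:
    """Write ``<name>.json`` (sorted keys, no timestamps — reruns are
    byte-identical) plus figure-analog CSVs where the report carries them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    path = out_dir / f"{name}.json"
    path.write_text(json.dumps(clean, indent=2, sort_keys=True) + "\n")

    if "matrix" in report:
        rows = [
            {"pr_train": tr, "pr_test": te, **cell}
            for tr, row in report["matrix"].items()
            for te, cell in row.items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"{name}_matrix.csv", index=False)
    if "disparity" in report:
        rows = [
            {"pr_train": pr, "run": i, "disparity": v}
            for pr, s in report["disparity"].items()
            for i, v in enumerate(s["per_run"])
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"{name}_disparity_runs.csv", index=False)
    if "_representation_summaries" in report:
        rows = []
        for model_tag, s in report["_representation_summaries"].items():
            for i, (ws, wd) in enumerate(zip(s.per_run_w_sex, s.per_run_w_disease)):
                rows.append({"model": model_tag, "run": i, "w_sex": ws, "w_disease": wd})
        pd.DataFrame(rows).to_csv(out_dir / f"{name}_wasserstein_runs.csv", index=False)
        for model_tag, s in report["_representation_summaries"].items():
            proj = s.representative_projection
            pd.DataFrame({
                "subject_id": list(s.representative_subject_ids),
                "pc1": proj.points[:, 0], "pc2": proj.points[:, 1],
            }).to_csv(out_dir / f"{name}_projection_{model_tag}.csv", index=False)
    return path
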