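"""Binary sex / disease classifiers, ensembles, and frozen-encoder transfer.

The classifier is a small convolutional network (three conv-pool blocks into a
pooled feature vector, plus one affine sigmoid head) trained with binary
cross-entropy and Adam, early-stopped on validation loss. Ensembles of
``n_models`` members are trained on independent prevalence-ratio-preserving
draws from the train/validation pools and aggregated by the arithmetic mean of
member probabilities.

Transfer analysis freezes the encoder and re-estimates only the affine head on
a new task's labels; penultimate features can be extracted for representation
analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._nn import Adam, SmallCNN, sigmoid
from .sampling import SamplingPlan, sample_at_pr
from .seeding import SAMPLING, TRAINING, derive_seed
from .synthgen import Subject, cohort_metadata

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "Ensemble",
    "stack_dataset",
    "train_classifier",
    "train_ensemble",
    "retrain_head",
    "extract_features",
    "save_model",
    "load_model",
]

_TASKS = ("sex", "disease")
#: label coding: positive class per task
_POSITIVE = {"sex": "M", "disease": "D"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training hyperparameters for one classifier.

    Hyperparameters were tuned manually once on the balanced-prevalence
    disease task and then frozen for every other condition (both tasks, all
    prevalence ratios), so no condition gets task-specific tuning.
    """

    image_shape: tuple[int, int, int]  # (C, H, W)
    task: str = "disease"
    d_feat: int = 32
    conv_channels: tuple[int, int, int] = (8, 16, 16)
    learning_rate: float = 3e-3
    batch_size: int = 16
    max_epochs: int = 80
    patience: int = 12

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"task must be one of {_TASKS}")
        if self.d_feat < 2:
            raise ValueError("d_feat must be >= 2")


@dataclass
class TrainedModel:
    """A trained classifier: spec, parameters, input normalization, history."""

    spec: ClassifierSpec
    net: SmallCNN = field(repr=False)
    norm_mean: np.ndarray = field(repr=False)
    norm_sd: np.ndarray = field(repr=False)
    history: pd.DataFrame = field(repr=False)
    seed: int = 0

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_mean[None, :, None, None]) / self.norm_sd[None, :, None, None]

    def predict_proba(self, subjects_or_X) -> np.ndarray:
        X = _as_array(subjects_or_X)
        return self.net.predict_proba(self._prepare(X))

    def features(self, subjects_or_X) -> np.ndarray:
        X = _as_array(subjects_or_X)
        return self.net.features(self._prepare(X))

    def encoder_checksum(self) -> float:
        """Sum over all encoder (non-head) parameters; head changes leave it fixed."""
        return float(
            sum(v.sum() for k, v in self.net.params.items() if k not in ("Wh", "bh"))
        )


@dataclass
class Ensemble:
    """A set of classifiers for one (task, training-PR); mean-probability vote."""

    members: list[TrainedModel]
    task: str
    pr_train: object = None
    member_train_ids: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if any(m.spec.task != self.task for m in self.members):
            raise ValueError("all members must share the ensemble task")

    def predict_proba(self, subjects_or_X) -> np.ndarray:
        X = _as_array(subjects_or_X)
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)


def _as_array(subjects_or_X) -> np.ndarray:
    if isinstance(subjects_or_X, np.ndarray):
        return subjects_or_X.astype(float)
    return np.stack([s.image for s in subjects_or_X]).astype(float)


def labels_for(subjects: Sequence[Subject], task: str) -> np.ndarray:
    """0/1 labels for a task (positive class: M for sex, D for disease)."""
    attr = "sex" if task == "sex" else "disease"
    pos = _POSITIVE[task]
    return np.array([1.0 if getattr(s, attr) == pos else 0.0 for s in subjects])


def stack_dataset(subjects: Sequence[Subject], task: str):
    """(X, y) arrays for training: X is (N, C, H, W), y in {0, 1}."""
    return _as_array(subjects), labels_for(subjects, task)


def train_classifier(
    train_set: Sequence[Subject],
    val_set: Sequence[Subject],
    spec: ClassifierSpec,
    seed: int,
) -> TrainedModel:
    """Fit one classifier by minibatch Adam on binary cross-entropy.

    The parameter snapshot with the best validation loss is kept (early
    stopping after ``spec.patience`` epochs without improvement). Fully
    reproducible given ``seed``.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    Xtr, ytr = stack_dataset(train_set, spec.task)
    Xva, yva = stack_dataset(val_set, spec.task)
    if len(np.unique(ytr)) < 2:
        raise ValueError(f"training set contains a single {spec.task} class")

    mean = Xtr.mean(axis=(0, 2, 3))
    sd = Xtr.std(axis=(0, 2, 3))
    sd[sd == 0] = 1.0
    Xtr_n = (Xtr - mean[None, :, None, None]) / sd[None, :, None, None]
    Xva_n = (Xva - mean[None, :, None, None]) / sd[None, :, None, None]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    net = SmallCNN(spec.image_shape, d_feat=spec.d_feat,
                   conv_channels=spec.conv_channels, rng=rng)
    opt = Adam(net.params.keys(), lr=spec.learning_rate)

    n = Xtr_n.shape[0]
    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = -1
    rows = []
    since_best = 0
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            loss, grads = net.loss_and_grads(Xtr_n[idx], ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            opt.step(net.params, grads)
            losses.append(loss)
        zva = net.logits(Xva_n)
        val_loss = float(np.mean(np.logaddexp(0.0, zva) - yva * zva))
        val_auroc = (
            float(roc_auc_score(yva, sigmoid(zva))) if len(np.unique(yva)) == 2 else np.nan
        )
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": val_loss, "val_auroc": val_auroc}
        )
        if val_loss < best_val - 1e-12:
            best_val, best_params, best_epoch = val_loss, net.copy_params(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > spec.patience:
                break
    net.set_params(best_params)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return TrainedModel(spec=spec, net=net, norm_mean=mean, norm_sd=sd,
                        history=history, seed=int(seed))


def train_ensemble(
    train_pool: Sequence[Subject],
    val_pool: Sequence[Subject],
    plan: SamplingPlan,
    task: str,
    spec: ClassifierSpec | None = None,
    n_models: int = 10,
    master_seed: int = 0,
) -> Ensemble:
    """Train ``n_models`` members, each on its own PR-preserving pool draw.

    Member ``i`` samples its training and validation sets (at the plan's
    stratum counts, hence its PR) with seeds derived from ``master_seed`` and
    ``i``, then trains with its own derived seed — members differ both in
    data draw and in initialization/batching.
    """
    if spec is None:
        spec = ClassifierSpec(image_shape=train_pool[0].image.shape, task=task)
    elif spec.task != task:
        spec = dataclasses.replace(spec, task=task)
    by_id = {s.subject_id: s for s in [*train_pool, *val_pool]}
    train_meta = cohort_metadata(train_pool)
    val_meta = cohort_metadata(val_pool)
    members, member_ids = [], []
    for i in range(n_models):
        tr_ids = sample_at_pr(train_meta, plan.train_counts,
                              derive_seed(master_seed, SAMPLING, i, 0))
        va_ids = sample_at_pr(val_meta, plan.val_counts,
                              derive_seed(master_seed, SAMPLING, i, 1))
        model = train_classifier(
            [by_id[j] for j in tr_ids],
            [by_id[j] for j in va_ids],
            spec,
            seed=derive_seed(master_seed, TRAINING, i),
        )
        members.append(model)
        member_ids.append(tr_ids)
    return Ensemble(members=members, task=task, pr_train=plan.pr,
                    member_train_ids=member_ids)


def retrain_head(
    model: TrainedModel,
    dataset: Sequence[Subject],
    new_task: str,
    seed: int,
    epochs: int = 500,
    lr: float = 0.05,
) -> TrainedModel:
    """Refit only the affine head on ``new_task`` labels; encoder frozen.

    The encoder (and input normalization) is reused bit-identically; the head
    is re-estimated by full-batch Adam on cross-entropy over the precomputed
    features — a plain logistic regression in feature space. ``new_task`` may
    equal the original task (self-transfer control).
    """
    if new_task not in _TASKS:
        raise ValueError(f"task must be one of {_TASKS}")
    feats = model.features(dataset)
    y = labels_for(dataset, new_task)
    if len(np.unique(y)) < 2:
        raise ValueError(f"dataset contains a single {new_task} class")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEAD5]))
    Wh = rng.normal(0.0, 0.01, size=(1, feats.shape[1]))
    bh = np.zeros(1)
    params = {"Wh": Wh, "bh": bh}
    opt = Adam(params.keys(), lr=lr)
    n = feats.shape[0]
    for _ in range(epochs):
        z = (feats @ params["Wh"].T + params["bh"]).ravel()
        p = sigmoid(z)
        dz = (p - y)[:, None] / n
        grads = {"Wh": dz.T @ feats, "bh": dz.sum(axis=0)}
        opt.step(params, grads)

    net = SmallCNN(model.spec.image_shape, d_feat=model.spec.d_feat,
                   conv_channels=model.spec.conv_channels,
                   rng=np.random.default_rng(0))
    new_params = model.net.copy_params()
    new_params["Wh"] = params["Wh"].copy()
    new_params["bh"] = params["bh"].copy()
    net.set_params(new_params)
    new_spec = dataclasses.replace(model.spec, task=new_task)
    history = pd.DataFrame([{"epoch": epochs - 1, "note": "head-only refit"}])
    return TrainedModel(spec=new_spec, net=net, norm_mean=model.norm_mean.copy(),
                        norm_sd=model.norm_sd.copy(), history=history, seed=int(seed))


def extract_features(model: TrainedModel, subjects: Sequence[Subject]) -> np.ndarray:
    """Penultimate (pooled encoder) features, rows in input order."""
    return model.features(subjects)


def save_model(model: TrainedModel, path) -> None:
    path = Path(path)
    spec_json = json.dumps(dataclasses.asdict(model.spec))
    np.savez_compressed(
        path,
        __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8),
        __seed__=np.array([model.seed]),
        norm_mean=model.norm_mean,
        norm_sd=model.norm_sd,
        **{f"p_{k}": v for k, v in model.net.params.items()},
    )


def load_model(path) -> TrainedModel:
    with np.load(Path(path)) as data:
        spec_dict = json.loads(bytes(data["__spec__"]).decode())
        spec_dict["image_shape"] = tuple(spec_dict["image_shape"])
        spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
        spec = ClassifierSpec(**spec_dict)
        net = SmallCNN(spec.image_shape, d_feat=spec.d_feat,
                       conv_channels=spec.conv_channels,
                       rng=np.random.default_rng(0))
        net.set_params({k[2:]: data[k] for k in data.files if k.startswith("p_")})
        return TrainedModel(
            spec=spec, net=net,
            norm_mean=data["norm_mean"], norm_sd=data["norm_sd"],
            history=pd.DataFrame(), seed=int(data["__seed__"][0]),
        )
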