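"""Prevalence-ratio-controlled dataset construction.

The audit manipulates a single variable: the sex-specific prevalence ratio

    PR = (proportion of diseased males) / (proportion of diseased females),

with PR = inf meaning every diseased subject is male. Datasets are always
sex-balanced and disease-balanced in total; only the allocation of diseased
subjects between the sexes changes. For a split of even total size ``n`` the
four sex-by-disease stratum counts are then fully determined:

    fd = n / (2 (1 + PR)),   fh = n/2 - fd,   md = n/2 - fd...

more precisely fh = n/2 - fd, md = PR * fd, mh = n/2 - md, which for
PR = inf degenerates to fd = 0, md = n/2. Non-integer solutions are rejected
rather than rounded — rounding would silently change the experimental
condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INFINITY",
    "StratumCounts",
    "SamplingPlan",
    "InfeasiblePRError",
    "solve_stratum_counts",
    "stratified_split",
    "sample_at_pr",
    "pr_label",
]

#: Distinguished prevalence-ratio value: all diseased subjects are male.
INFINITY = math.inf

_STRATA = (("F", "H"), ("F", "D"), ("M", "H"), ("M", "D"))


class InfeasiblePRError(ValueError):
    """The requested (split size, PR) pair has no integer stratum counts."""


def pr_label(pr) -> str:
    """Stable string form of a PR for report keys ('1', '2', '5', 'inf')."""
    if pr == INFINITY:
        return "inf"
    frac = _as_fraction(pr)
    return str(frac.numerator) if frac.denominator == 1 else f"{frac.numerator}/{frac.denominator}"


def _as_fraction(pr) -> Fraction:
    if isinstance(pr, Fraction):
        return pr
    if isinstance(pr, int):
        return Fraction(pr)
    if isinstance(pr, float):
        if not math.isfinite(pr):
            raise ValueError("use sampling.INFINITY explicitly")
        return Fraction(pr).limit_denominator(10**6)
    raise TypeError(f"unsupported PR type {type(pr)!r}")


@dataclass(frozen=True)
class StratumCounts:
    """Counts of the four sex-by-disease strata for one data split.

    fh/fd/mh/md = female-healthy, female-diseased, male-healthy,
    male-diseased.
    """

    fh: int
    fd: int
    mh: int
    md: int

    def __post_init__(self) -> None:
        if min(self.fh, self.fd, self.mh, self.md) < 0:
            raise ValueError("stratum counts must be non-negative")

    @property
    def total(self) -> int:
        return self.fh + self.fd + self.mh + self.md

    @property
    def pr(self):
        """Prevalence ratio implied by the counts (md/fd; inf when fd = 0)."""
        if self.fd == 0:
            return INFINITY if self.md > 0 else 1
        return Fraction(self.md, self.fd)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.fh, self.fd, self.mh, self.md)

    def validate_balanced(self) -> None:
        """Check the two balance invariants (sex totals, disease totals)."""
        if self.fh + self.fd != self.mh + self.md:
            raise ValueError("sex totals are not balanced")
        if self.fh + self.mh != self.fd + self.md:
            raise ValueError("disease totals are not balanced")


def solve_stratum_counts(split_total: int, pr) -> StratumCounts:
    """Unique sex- and disease-balanced stratum counts at a given PR.

    Parameters
    ----------
    split_total : positive even integer >= 4, the split size.
    pr : positive int/float/Fraction, or :data:`INFINITY`.

    Raises
    ------
    InfeasiblePRError
        When the closed form gives non-integer counts (e.g. total 48 at
        PR = 4, where fd would be 4.8).
    """
    if split_total < 4 or split_total % 2:
        raise ValueError("split_total must be an even integer >= 4")
    half = split_total // 2
    if pr == INFINITY:
        return StratumCounts(fh=half, fd=0, mh=0, md=half)
    frac = _as_fraction(pr)
    if frac <= 0:
        raise ValueError("PR must be positive")
    fd = Fraction(split_total) / (2 * (1 + frac))
    md = frac * fd
    if fd.denominator != 1 or md.denominator != 1:
        raise InfeasiblePRError(
            f"split_total={split_total}, PR={pr}: female-diseased count {float(fd):g} "
            "is not an integer"
        )
    fd_i, md_i = int(fd), int(md)
    counts = StratumCounts(fh=half - fd_i, fd=fd_i, mh=half - md_i, md=md_i)
    counts.validate_balanced()
    return counts


@dataclass(frozen=True)
class SamplingPlan:
    """Stratum counts for the train/val/test splits at one training PR.

    The validation split always uses the same PR as training; the test pool
    is resampled at possibly different PRs during evaluation.
    """

    pr: object
    train_counts: StratumCounts
    val_counts: StratumCounts
    test_counts: StratumCounts
    n_train_pool: int = 86
    n_val_pool: int = 21
    n_test_pool: int = 40

    def __post_init__(self) -> None:
        for counts, pool in (
            (self.train_counts, self.n_train_pool),
            (self.val_counts, self.n_val_pool),
            (self.test_counts, self.n_test_pool),
        ):
            if counts.total > pool:
                raise ValueError("split counts exceed pool size")

    @classmethod
    def from_totals(
        cls,
        pr,
        totals: tuple[int, int, int] = (48, 12, 24),
        pool_sizes: tuple[int, int, int] = (86, 21, 40),
    ) -> "SamplingPlan":
        """Build the standard plan: 48/12/24 split sizes at one PR."""
        train, val, test = (solve_stratum_counts(n, pr) for n in totals)
        return cls(
            pr=pr,
            train_counts=train,
            val_counts=val,
            test_counts=test,
            n_train_pool=pool_sizes[0],
            n_val_pool=pool_sizes[1],
            n_test_pool=pool_sizes[2],
        )


def _stratum_key(meta: pd.DataFrame) -> pd.Series:
    return meta["sex"].astype(str) + meta["disease"].astype(str)


def stratified_split(
    pool_metadata: pd.DataFrame,
    sizes: tuple[int, int, int],
    seed: int,
) -> pd.Series:
    """Confounder-matched split: keep every sex-by-disease stratum as evenly
    represented across splits as integer rounding allows.

    Parameters
    ----------
    pool_metadata : table with subject_id, sex, disease columns.
    sizes : (n_train, n_val, n_test); must sum to the pool size.
    seed : shuffling seed; same seed, same assignment.

    Returns
    -------
    pandas.Series mapping subject_id -> split tag in {train, val, test}.
    """
    names = ("train", "val", "test")
    n_total = len(pool_metadata)
    if sum(sizes) != n_total:
        raise ValueError(f"sizes {sizes} do not sum to pool size {n_total}")
    key = _stratum_key(pool_metadata)
    strata = {k: pool_metadata.loc[key == k, "subject_id"].tolist() for k in sorted(key.unique())}

    # Floor quotas per (stratum, split); leftovers are then placed one unit at
    # a time into the split that best preserves sex and disease balance, never
    # giving a stratum two extra units in the same split (keeps every cell
    # within one subject of exact proportionality).
    quota = {}
    need = dict(zip(names, sizes))
    for k, ids in strata.items():
        for name, size in zip(names, sizes):
            quota[(k, name)] = int(math.floor(len(ids) * size / n_total))
    for name in names:
        need[name] -= sum(quota[(k, name)] for k in strata)
    leftover = {k: len(ids) - sum(quota[(k, n)] for n in names) for k, ids in strata.items()}
    extra = {key: 0 for key in quota}

    def split_counts(name):
        f = sum(quota[(k, name)] for k in strata if k.startswith("F"))
        m = sum(quota[(k, name)] for k in strata if k.startswith("M"))
        h = sum(quota[(k, name)] for k in strata if k.endswith("H"))
        d = sum(quota[(k, name)] for k in strata if k.endswith("D"))
        return f, m, h, d

    for k in sorted(strata):
        while leftover[k] > 0:
            candidates = [n for n in names if need[n] > 0 and extra[(k, n)] == 0]
            if not candidates:  # stratum has > len(splits) leftovers: impossible
                candidates = [n for n in names if need[n] > 0]

            def imbalance(name):
                f, m, h, d = split_counts(name)
                f += k.startswith("F")
                m += k.startswith("M")
                h += k.endswith("H")
                d += k.endswith("D")
                return abs(f - m) + abs(h - d)

            name = min(candidates, key=lambda n: (imbalance(n), -need[n], n))
            quota[(k, name)] += 1
            extra[(k, name)] += 1
            leftover[k] -= 1
            need[name] -= 1

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for k, ids in strata.items():
        ids = sorted(ids)
        rng.shuffle(ids)
        pos = 0
        for name in names:
            for sid in ids[pos : pos + quota[(k, name)]]:
                assignment[sid] = name
            pos += quota[(k, name)]
    out = pd.Series(assignment, name="split")
    out.index.name = "subject_id"
    return out.loc[pool_metadata["subject_id"]]


def sample_at_pr(
    pool_metadata: pd.DataFrame,
    counts: StratumCounts,
    seed: int,
) -> list[str]:
    """Uniform without-replacement draw of exact per-stratum counts.

    Raises ValueError when a stratum cannot supply its requested count.
    Deterministic given ``seed``; ids are returned in stratum order
    (F-H, F-D, M-H, M-D).
    """
    rng = np.random.default_rng(seed)
    key = _stratum_key(pool_metadata)
    wanted = dict(zip(_STRATA, (counts.fh, counts.fd, counts.mh, counts.md)))
    chosen: list[str] = []
    for (sex, disease), n in wanted.items():
        ids = sorted(pool_metadata.loc[key == f"{sex}{disease}", "subject_id"])
        if len(ids) < n:
            raise ValueError(
                f"stratum {sex}-{disease} has {len(ids)} subjects, {n} requested"
            )
        if n:
            chosen.extend(rng.choice(ids, size=n, replace=False).tolist())
    return chosen
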