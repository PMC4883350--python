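"""10-fold cross-validated Acc/Se/Sp evaluation and the 8-kernel comparison.

The positive class (label 1) is "drunk": sensitivity is the fraction of
drunk windows detected, specificity the fraction of normal windows cleared.
Folds are class-stratified; when window provenance includes subject groups,
all windows of a subject stay in one fold so overlapping windows of the
same recording never straddle the train/validation boundary.  Within each
fold, class balancing, feature standardization and correlation weights are
fit on the training rows only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import Dataset, balance_classes
from .kernels import KernelSpec
from .svm import WeightedKernelSVC

__all__ = ["ConfusionCounts", "Metrics", "CVReport", "kfold_partition", "group_kfold_partition", "confusion", "metrics", "cross_validate", "compare_kernels", "KERNEL_TABLE"]

#: Table-2-style kernel naming: K<family><a=prime, b=weighted>
KERNEL_TABLE = [
    ("K1a", "linear", False),
    ("K1b", "linear", True),
    ("K2a", "quadratic", False),
    ("K2b", "quadratic", True),
    ("K3a", "poly3", False),
    ("K3b", "poly3", True),
    ("K4a", "rbf", False),
    ("K4b", "rbf", True),
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    acc: float
    se: float
    sp: float
    undefined: tuple[str, ...] = ()


@dataclass
class CVReport:
    kernel: KernelSpec
    seed: int
    folds: list[ConfusionCounts] = field(default_factory=list)
    fold_metrics: list[Metrics] = field(default_factory=list)

    @property
    def mean_acc(self) -> float:
        return float(np.mean([m.acc for m in self.fold_metrics]))

    @property
    def mean_se(self) -> float:
        return float(np.mean([m.se for m in self.fold_metrics]))

    @property
    def mean_sp(self) -> float:
        return float(np.mean([m.sp for m in self.fold_metrics]))


def kfold_partition(labels: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Stratified random partition into k validation groups (sizes differ <= 1)."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros((n, 1)), labels)]


def group_kfold_partition(labels: np.ndarray, groups: np.ndarray, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Group-aware partition: every group's windows land in exactly one fold.

    Groups are shuffled (seeded) then greedily assigned, largest first, to
    the currently smallest fold; with one subject per group and both classes
    present per subject the folds remain class-balanced.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} groups, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    sizes = np.array([np.sum(groups == g) for g in uniq])
    by_size = sorted(order, key=lambda i: -sizes[i])
    fold_of = {}
    load = np.zeros(k)
    for gi in by_size:
        f = int(np.argmin(load))
        fold_of[uniq[gi]] = f
        load[f] += sizes[gi]
    return [np.flatnonzero([fold_of[g] == f for g in groups]) for f in range(k)]


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must align")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Acc = (Tp+Tn)/total, Se = Tp/(Tp+Fn), Sp = Tn/(Tn+Fp).

    A metric with an empty denominator is NaN and named in ``undefined``.
    """
    undef = []
    acc = (c.tp + c.tn) / c.total if c.total else math.nan
    if not c.total:
        undef.append("acc")
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    if not (c.tp + c.fn):
        undef.append("se")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    if not (c.tn + c.fp):
        undef.append("sp")
    return Metrics(acc, se, sp, tuple(undef))


def cross_validate(
    ds: Dataset,
    spec: KernelSpec,
    k: int = 10,
    seed: int = 0,
    C: float = 10.0,
    gamma: float = 0.5,
) -> CVReport:
    """k-fold CV with per-fold balancing/standardization/weighting.

    Each fold's validation rows never touch the balancing draw, the z-score
    statistics, the correlation weights or the dual solution.
    """
    if ds.groups is not None and len(np.unique(ds.groups)) >= k:
        folds = group_kfold_partition(ds.y, ds.groups, k, seed)
    else:
        folds = kfold_partition(ds.y, k, seed)
    report = CVReport(kernel=spec, seed=seed)
    all_idx = np.arange(len(ds))
    for fold_no, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        tr = balance_classes(ds.subset(train_idx), seed=seed * 1000 + fold_no)
        clf = WeightedKernelSVC(kernel=spec.family, weighted=spec.weighted, C=C, gamma=gamma)
        clf.fit(tr.X, tr.y)
        pred = clf.predict(ds.X[val_idx])
        c = confusion(pred, ds.y[val_idx])
        report.folds.append(c)
        report.fold_metrics.append(metrics(c))
    return report


def compare_kernels(
    ds: Dataset,
    k: int = 10,
    seed: int = 0,
    C: float = 10.0,
    gamma: float = 0.5,
) -> pd.DataFrame:
    """The 8-row kernel comparison table (4 families x {prime, weighted}).

    Columns: id, kernel, weighted, acc, se, sp, best (True on the
    highest-accuracy row).
    """
    rows = []
    for kid, family, weighted in KERNEL_TABLE:
        rep = cross_validate(ds, KernelSpec(family=family, weighted=weighted, gamma=gamma), k, seed, C, gamma)
        rows.append(
            {"id": kid, "kernel": family, "weighted": weighted,
             "acc": rep.mean_acc, "se": rep.mean_se, "sp": rep.mean_sp}
        )
    df = pd.DataFrame(rows)
    df["best"] = df["acc"] == df["acc"].max()
    return df
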