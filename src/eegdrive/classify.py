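"""Leakage-safe classification of engagement states.

A random-forest ensemble is trained on wavelet features with a two-stage
feature selection (model-based importance ranking, refined by univariate
ANOVA F), under validation schemes that respect the grouped, temporally
ordered structure of driving data:

* ``group-kfold`` - 5-fold GroupKFold with lap-level grouping plus a
  purged gap: training epochs temporally adjacent to held-out segments
  (within ``purge_gap`` positions in the same subject's timeline) are
  excluded.
* ``split-sample`` - a single group-aware train/test split.
* LOSO - leave-one-subject-out, for cross-person generalization, on four
  binary tasks (mode, pooled difficulty, difficulty within MD, within AD).
* cross-mode transfer - train Easy-vs-Hard on MD epochs, test on AD.

Everything that carries dataset statistics (feature scaler, selection,
classifier) is fitted on the training rows of each fold only; an internal
audit re-derives the scaler statistics from the training rows and verifies
the fold contract on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support
from sklearn.model_selection import GroupKFold, GroupShuffleSplit
from sklearn.preprocessing import StandardScaler

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan", "ClassifierSpec", "EvalReport", "LosoReport",
    "two_stage_select", "run_cv", "run_loso", "cross_mode_transfer",
    "chance_test", "task_labels", "LOSO_TASKS",
]

LOSO_TASKS = ("mode", "difficulty", "difficulty-md", "difficulty-ad")


@dataclass(frozen=True)
class FoldPlan:
    scheme: str = "group-kfold"       # group-kfold | split-sample
    n_folds: int = 5
    group_key: str = "lap"            # lap | segment grouping for group-kfold
    purge_gap: int = 1                # epochs excluded on each side of held-out data
    class_balancing: bool = True
    test_fraction: float = 0.3        # split-sample only
    seed: int = 0


@dataclass(frozen=True)
class ClassifierSpec:
    n_trees: int = 500
    max_depth: int | None = None
    k1: int = 200                     # stage-1 (importance) keep count
    k2: int = 100                     # stage-2 (ANOVA F) keep count
    selector_trees: int = 200
    seed: int = 0


@dataclass
class EvalReport:
    scheme: str
    classes: tuple[str, ...]
    accuracy: float                  # pooled over held-out epochs
    fold_accuracies: list[float]
    macro_f1: float
    precision: dict[str, float]
    recall: dict[str, float]
    confusion: np.ndarray            # row-normalized, rows = true labels
    n_test: int
    n_correct: int
    chance_p: float
    importances: pd.Series           # fold-averaged, full feature vector
    leakage_audit: list[dict] = field(default_factory=list)

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "classes": list(self.classes),
            "accuracy": self.accuracy, "accuracy_sd": self.accuracy_sd,
            "fold_accuracies": self.fold_accuracies, "macro_f1": self.macro_f1,
            "precision": self.precision, "recall": self.recall,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test, "n_correct": self.n_correct,
            "chance_p": self.chance_p,
            "top_features": self.importances.sort_values(ascending=False)[:20].to_dict(),
            "leakage_audit": self.leakage_audit,
        }


def chance_test(n_correct: int, n_total: int, chance_p: float) -> float:
    """One-sided exact binomial tail P(X >= n_correct) under chance."""
    if not 0 < chance_p < 1:
        raise ValueError("chance_p must lie in (0, 1)")
    if not 0 <= n_correct <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_correct <= n_total with n_total > 0")
    return float(sps.binomtest(n_correct, n_total, chance_p,
                               alternative="greater").pvalue)


def grouped_permutation_test(y_true: np.ndarray, y_pred: np.ndarray,
                             groups: np.ndarray, n_perm: int = 1000,
                             seed: int = 0) -> float:
    """Permutation alternative to the binomial chance test for grouped data.

    Epochs within a group (e.g. a lap) share slow dynamics, so Bernoulli
    independence is optimistic; here whole groups of true labels are
    permuted jointly and the observed accuracy is ranked in the null
    distribution (one-sided, add-one corrected).
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    groups = np.asarray(groups)
    if not (len(y_true) == len(y_pred) == len(groups)):
        raise ValueError("inputs must align")
    observed = np.mean(y_true == y_pred)
    uniq = np.unique(groups)
    blocks = [y_true[groups == g] for g in uniq]
    if len({len(b) for b in blocks}) != 1:
        raise ValueError("grouped permutation requires equal-sized groups")
    order = np.concatenate([np.flatnonzero(groups == g) for g in uniq])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(blocks))
        y_null = np.empty_like(y_true)
        y_null[order] = np.concatenate([blocks[i] for i in perm])
        exceed += np.mean(y_null == y_pred) >= observed
    return float((1 + exceed) / (1 + n_perm))


def task_labels(labels: np.ndarray, task: str) -> tuple[np.ndarray, np.ndarray]:
    """(row mask, binary/4-class labels) for a named task."""
    labels = np.asarray(labels)
    mode = np.array([lab.split("-")[0] for lab in labels])
    difficulty = np.array([lab.split("-")[1] for lab in labels])
    if task == "fourclass":
        return np.ones(len(labels), bool), labels
    if task == "mode":
        return np.ones(len(labels), bool), mode
    if task == "difficulty":
        return np.ones(len(labels), bool), difficulty
    if task == "difficulty-md":
        return mode == "MD", difficulty
    if task == "difficulty-ad":
        return mode == "AD", difficulty
    raise ValueError(f"unknown task {task!r}")


def two_stage_select(x_train: np.ndarray, y_train: np.ndarray, k1: int, k2: int,
                     seed: int = 0, selector_trees: int = 200) -> np.ndarray:
    """Stage 1: top-k1 by forest importance; stage 2: top-k2 of those by ANOVA F.

    Deterministic given the seed; returns sorted column indices.
    """
    n_features = x_train.shape[1]
    k1 = min(k1, n_features)
    if k2 > k1:
        raise ValueError(f"k2 ({k2}) must not exceed k1 ({k1})")
    forest = RandomForestClassifier(n_estimators=selector_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(x_train, y_train)
    stage1 = np.argsort(forest.feature_importances_)[::-1][:k1]
    f_vals, _ = f_classif(x_train[:, stage1], y_train)
    f_vals = np.nan_to_num(f_vals, nan=0.0)
    stage2 = stage1[np.argsort(f_vals)[::-1][:k2]]
    return np.sort(stage2)


def _temporal_order(groups: pd.DataFrame) -> np.ndarray:
    """Within-subject temporal position of every epoch (lap-major order)."""
    order = np.empty(len(groups), dtype=int)
    for _, idx in groups.groupby("subject").groups.items():
        sub = groups.loc[idx].sort_values(["lap", "segment"])
        order[sub.index] = np.arange(len(sub))
    return order


def _purge(train_idx: np.ndarray, test_idx: np.ndarray, groups: pd.DataFrame,
           order: np.ndarray, purge_gap: int) -> np.ndarray:
    """Drop training epochs within ``purge_gap`` positions of held-out epochs."""
    if purge_gap <= 0:
        return train_idx
    subj = groups["subject"].to_numpy()
    keep = []
    for i in train_idx:
        near = (subj[test_idx] == subj[i]) & (np.abs(order[test_idx] - order[i]) <= purge_gap)
        if not near.any():
            keep.append(i)
    return np.array(keep, dtype=int)


def _balance(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random down-sampling of majority classes within the training fold."""
    classes, counts = np.unique(y[idx], return_counts=True)
    n_min = counts.min()
    out = []
    for c in classes:
        members = idx[y[idx] == c]
        out.append(rng.choice(members, size=n_min, replace=False))
    return np.sort(np.concatenate(out))


def _fit_and_eval(x: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
                  test_idx: np.ndarray, spec: ClassifierSpec,
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Nested scaler + selection + forest on train rows only; predict test."""
    scaler = StandardScaler().fit(x[train_idx])
    xt = scaler.transform(x)
    sel = two_stage_select(xt[train_idx], y[train_idx], spec.k1, spec.k2,
                           seed=spec.seed, selector_trees=spec.selector_trees)
    model = RandomForestClassifier(n_estimators=spec.n_trees, max_depth=spec.max_depth,
                                   random_state=spec.seed, n_jobs=1)
    model.fit(xt[np.ix_(train_idx, sel)], y[train_idx])
    pred = model.predict(xt[np.ix_(test_idx, sel)])
    # train-only recomputation audit of the scaler statistics
    audit_ok = bool(np.allclose(scaler.mean_, x[train_idx].mean(axis=0)) and
                    np.allclose(scaler.var_, x[train_idx].var(axis=0)))
    importances = np.zeros(x.shape[1])
    importances[sel] = model.feature_importances_
    return pred, importances, {"scaler_train_only": audit_ok}


def _folds(ft: FeatureTable, plan: FoldPlan, y: np.ndarray):
    groups = ft.groups
    if plan.group_key == "lap":
        gid = (groups["subject"].astype(str) + "/" + groups["lap"].astype(str)).to_numpy()
    elif plan.group_key == "segment":
        gid = (groups["subject"].astype(str) + "/" + groups["lap"].astype(str)
               + "/" + groups["segment"].astype(str)).to_numpy()
    else:
        raise ValueError(f"unknown group_key {plan.group_key!r}")
    if plan.scheme == "group-kfold":
        cv = GroupKFold(n_splits=plan.n_folds)
        yield from cv.split(np.zeros(len(y)), y, groups=gid)
    elif plan.scheme == "split-sample":
        cv = GroupShuffleSplit(n_splits=1, test_size=plan.test_fraction,
                               random_state=plan.seed)
        yield from cv.split(np.zeros(len(y)), y, groups=gid)
    else:
        raise ValueError(f"unknown scheme {plan.scheme!r}")


def run_cv(ft: FeatureTable, plan: FoldPlan = FoldPlan(),
           spec: ClassifierSpec = ClassifierSpec(),
           task: str = "fourclass") -> EvalReport:
    """Grouped, purged, nested cross-validation of the feature table."""
    mask, y_all = task_labels(ft.labels, task)
    ft = ft.subset(np.flatnonzero(mask))
    y = y_all[mask]
    x = ft.features.to_numpy()
    classes = tuple(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    order = _temporal_order(ft.groups)
    rng = np.random.default_rng(plan.seed)

    y_true_all, y_pred_all = [], []
    fold_acc, audits, importances = [], [], []
    for k, (train_idx, test_idx) in enumerate(_folds(ft, plan, y)):
        if len(np.unique(y[test_idx])) < 2:
            logger.warning("fold %d skipped: single class in test", k)
            continue
        purged = _purge(train_idx, test_idx, ft.groups, order, plan.purge_gap)
        if plan.class_balancing:
            fit_idx = _balance(purged, y, rng)
        else:
            fit_idx = purged
        if len(np.unique(y[fit_idx])) < 2:
            logger.warning("fold %d skipped: single class in training", k)
            continue
        pred, imp, audit = _fit_and_eval(x, y, fit_idx, test_idx, spec)
        # fold-contract audit
        subj = ft.groups["subject"].to_numpy()
        gid_train = set(zip(subj[fit_idx], ft.groups["lap"].to_numpy()[fit_idx]))
        gid_test = set(zip(subj[test_idx], ft.groups["lap"].to_numpy()[test_idx]))
        sep = (np.abs(order[test_idx][:, None] - order[fit_idx][None, :])
               * (subj[test_idx][:, None] == subj[fit_idx][None, :]))
        min_gap = int(sep[sep > 0].min()) if (sep > 0).any() else plan.purge_gap + 1
        audit.update({
            "fold": k,
            "disjoint_groups": not (gid_train & gid_test) if plan.group_key == "lap" else
                               len(set(fit_idx) & set(test_idx)) == 0,
            "min_temporal_gap": min_gap,
            "purge_respected": min_gap > plan.purge_gap,
        })
        if not (audit["disjoint_groups"] and audit["purge_respected"]
                and audit["scaler_train_only"]):
            raise RuntimeError(f"leakage audit failed in fold {k}: {audit}")
        audits.append(audit)
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        importances.append(imp)
    if not y_true_all:
        raise ValueError("no usable folds")
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    return _report(plan.scheme, classes, y_true, y_pred, fold_acc,
                   np.mean(importances, axis=0), ft.features.columns, audits)


def _report(scheme, classes, y_true, y_pred, fold_acc, importances, feature_names,
            audits) -> EvalReport:
    n_correct = int(np.sum(y_true == y_pred))
    conf = confusion_matrix(y_true, y_pred, labels=list(classes), normalize="true")
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0)
    return EvalReport(
        scheme=scheme, classes=classes,
        accuracy=float(np.mean(y_true == y_pred)),
        fold_accuracies=fold_acc,
        macro_f1=float(f1_score(y_true, y_pred, labels=list(classes), average="macro")),
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        confusion=conf,
        n_test=len(y_true), n_correct=n_correct,
        chance_p=chance_test(n_correct, len(y_true), 1.0 / len(classes)),
        importances=pd.Series(importances, index=feature_names),
        leakage_audit=audits,
    )


@dataclass
class LosoReport:
    """Leave-one-subject-out summary for one binary task."""

    task: str
    subject_accuracies: dict[int, float]
    mean_accuracy: float
    sd: float
    ci95: tuple[float, float]
    t: float
    p: float
    cohen_d: float
    excluded_subjects: list[int]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "subject_accuracies": {str(k): v for k, v in self.subject_accuracies.items()},
            "mean_accuracy": self.mean_accuracy, "sd": self.sd,
            "ci95": list(self.ci95), "t": self.t, "p": self.p,
            "cohen_d": self.cohen_d, "excluded_subjects": self.excluded_subjects,
        }


def run_loso(ft: FeatureTable, task: str, spec: ClassifierSpec = ClassifierSpec(),
             class_balancing: bool = True, chance: float = 0.5) -> LosoReport:
    """Hold out each subject; train (with nested preprocessing) on the rest."""
    if task not in LOSO_TASKS:
        raise ValueError(f"task must be one of {LOSO_TASKS}")
    mask, y_all = task_labels(ft.labels, task)
    ft = ft.subset(np.flatnonzero(mask))
    y = y_all[mask]
    x = ft.features.to_numpy()
    subjects = np.unique(ft.groups["subject"])
    if len(subjects) < 3:
        raise ValueError("LOSO needs >= 3 subjects")
    rng = np.random.default_rng(spec.seed)
    accs: dict[int, float] = {}
    excluded = []
    subj = ft.groups["subject"].to_numpy()
    for s in subjects:
        test_idx = np.flatnonzero(subj == s)
        train_idx = np.flatnonzero(subj != s)
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            logger.warning("LOSO %s: subject %s excluded (single class)", task, s)
            excluded.append(int(s))
            continue
        if class_balancing:
            train_idx = _balance(train_idx, y, rng)
        pred, _, audit = _fit_and_eval(x, y, train_idx, test_idx, spec)
        if not audit["scaler_train_only"]:
            raise RuntimeError("leakage audit failed in LOSO fold")
        accs[int(s)] = float(np.mean(pred == y[test_idx]))
    vals = np.array(list(accs.values()))
    n = len(vals)
    mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if n > 1 else 0.0
    if sd > 0:
        t_stat, p = sps.ttest_1samp(vals, chance, alternative="greater")
        d = (mean - chance) / sd
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        t_stat, p, d, ci = np.nan, np.nan, np.nan, (mean, mean)
    return LosoReport(task=task, subject_accuracies=accs, mean_accuracy=mean,
                      sd=sd, ci95=ci, t=float(t_stat), p=float(p),
                      cohen_d=float(d), excluded_subjects=excluded)


def cross_mode_transfer(ft: FeatureTable, spec: ClassifierSpec = ClassifierSpec(),
                        ) -> dict:
    """Train Easy-vs-Hard on MD epochs only; test on AD epochs only."""
    mode = np.array([lab.split("-")[0] for lab in ft.labels])
    difficulty = np.array([lab.split("-")[1] for lab in ft.labels])
    if not (("MD" in mode) and ("AD" in mode)):
        raise ValueError("both modes must be present for transfer")
    train_idx = np.flatnonzero(mode == "MD")
    test_idx = np.flatnonzero(mode == "AD")
    x = ft.features.to_numpy()
    pred, _, audit = _fit_and_eval(x, difficulty, train_idx, test_idx, spec)
    if not audit["scaler_train_only"]:
        raise RuntimeError("leakage audit failed in transfer fit")
    n_correct = int(np.sum(pred == difficulty[test_idx]))
    n_total = len(test_idx)
    return {
        "accuracy": n_correct / n_total,
        "n_test": n_total,
        "n_correct": n_correct,
        "chance_p": chance_test(n_correct, n_total, 0.5),
    }
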