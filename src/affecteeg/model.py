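"""Cross-validated random-forest classification of valence and arousal.

Per feature family (single-channel, channel-pair, multiscale-entropy)
and for the combined model, a stratified 5-fold cross-validation is run
at the epoch level (subject-dependent: epochs of one subject may land
in both training and test folds).  Inside each training fold, features
are ranked by mutual information with the binary target and the top 10
feed a random forest; the held-out fold is scored with the
class-support-weighted F1.  Feature selection never sees the test fold.

Family performances are compared with a one-sided rank-sum test on the
per-fold F1 samples (exact enumeration for combined n <= 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    n_top: int = 10
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0
    mi_bins: int = 10

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass
class ModelReport:
    target: str
    family: str
    fold_f1: list
    selected: list = field(default_factory=list)  # per-fold feature lists

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def ci95(self) -> tuple:
        """t-based 95% CI of the mean fold F1."""
        f1 = np.asarray(self.fold_f1, dtype=float)
        k = len(f1)
        if k < 2:
            return (self.mean_f1, self.mean_f1)
        half = stats.t.ppf(0.975, k - 1) * f1.std(ddof=1) / np.sqrt(k)
        return (self.mean_f1 - half, self.mean_f1 + half)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "target": self.target,
            "family": self.family,
            "fold_f1": [float(v) for v in self.fold_f1],
            "mean_f1": self.mean_f1,
            "ci95": [lo, hi],
            "selected": self.selected,
        }


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """MI (nats) between a continuous feature and a discrete label.

    The feature is discretized into up to ``bins`` equal-frequency bins
    (rank-based, so strictly monotone transforms leave the value
    unchanged); a constant feature has MI 0.
    """
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    if len(edges) == 0:
        return 0.0
    xb = np.searchsorted(edges, x, side="right")
    joint = pd.crosstab(xb, y).to_numpy().astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px @ py))
    return float(np.nansum(terms))


def mi_rank(X: pd.DataFrame, y, bins: int = 10) -> list:
    """Features ordered by decreasing MI with ``y``; ties keep column order."""
    y = np.asarray(y)
    mis = np.array([mutual_information(X[c].to_numpy(), y, bins) for c in X.columns])
    order = np.argsort(-mis, kind="stable")
    return [X.columns[i] for i in order]


def _fit_score_fold(X_tr, y_tr, X_te, y_te, selected, config: CVConfig) -> float:
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
    )
    rf.fit(X_tr[selected].to_numpy(), y_tr)
    pred = rf.predict(X_te[selected].to_numpy())
    return float(f1_score(y_te, pred, average="weighted"))


def _folds(y: np.ndarray, config: CVConfig):
    skf = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=config.seed)
    return skf.split(np.zeros(len(y)), y)


def run_cv(
    X: pd.DataFrame, y, target: str, family: str, config: CVConfig = CVConfig()
) -> ModelReport:
    """Stratified k-fold CV with in-fold MI feature selection.

    ``y`` is the binary class label sequence aligned with the rows of
    ``X`` (no missing values allowed).  Raises if a class is missing
    from the data or a fold.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError(f"target {target!r} has a single class; cannot cross-validate")
    if X.isna().any().any():
        raise ValueError("X contains missing values; run assembly first")
    fold_f1, selected = [], []
    for tr, te in _folds(y, config):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold is missing a class; too few rows per class")
        ranked = mi_rank(X.iloc[tr], y[tr], bins=config.mi_bins)
        top = ranked[: config.n_top]
        fold_f1.append(_fit_score_fold(X.iloc[tr], y[tr], X.iloc[te], y[te], top, config))
        selected.append(list(top))
    return ModelReport(target=target, family=family, fold_f1=fold_f1, selected=selected)


def run_combined(
    family_X: dict, y, target: str, config: CVConfig = CVConfig()
) -> ModelReport:
    """Combined model: per fold, union of each family's top-10 MI features.

    All family tables must share identical row keys (same epochs in the
    same order).
    """
    keys = list(family_X)
    base = family_X[keys[0]].index
    for k in keys[1:]:
        if not family_X[k].index.equals(base):
            raise ValueError(f"row keys of family {k!r} do not match {keys[0]!r}")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError(f"target {target!r} has a single class; cannot cross-validate")
    X_all = pd.concat(family_X.values(), axis=1)
    fold_f1, selected = [], []
    for tr, te in _folds(y, config):
        union = []
        for k in keys:
            ranked = mi_rank(family_X[k].iloc[tr], y[tr], bins=config.mi_bins)
            union += [c for c in ranked[: config.n_top] if c not in union]
        fold_f1.append(
            _fit_score_fold(X_all.iloc[tr], y[tr], X_all.iloc[te], y[te], union, config)
        )
        selected.append(union)
    return ModelReport(target=target, family="combined", fold_f1=fold_f1, selected=selected)


def compare_reports(a: ModelReport, b: ModelReport) -> float:
    """One-sided rank-sum p-value that ``a``'s fold F1s exceed ``b``'s.

    Exact enumeration when the combined sample size is at most 10,
    normal approximation otherwise.
    """
    if len(a.fold_f1) < 3 or len(b.fold_f1) < 3:
        raise ValueError("need at least 3 fold scores per report")
    method = "exact" if len(a.fold_f1) + len(b.fold_f1) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a.fold_f1, b.fold_f1, alternative="greater", method=method)
    return float(res.pvalue)


def comparison_matrix(reports: list) -> pd.DataFrame:
    """Pairwise one-sided p-values (row family > column family)."""
    names = [r.family for r in reports]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for ra in reports:
        for rb in reports:
            if ra is not rb:
                out.loc[ra.family, rb.family] = compare_reports(ra, rb)
    return out
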