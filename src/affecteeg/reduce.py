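"""Unsupervised feature reduction: PCA variance filter + correlation pruning.

Both steps are label-blind and run per feature family on the pooled
dataset.  First, features are standardized and the principal components
explaining at least 95% of the variance are kept; every feature whose
absolute Pearson correlation with at least one retained component score
vector exceeds 0.7 survives.  Second, while any surviving pair
correlates at |r| >= 0.95, the member of the worst pair with the larger
mean absolute correlation to all remaining features is removed
(greedily; ties keep the earlier column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class ReductionReport:
    retained: list
    n_components: int = 0
    max_component_corr: dict = field(default_factory=dict)
    removed_constant: list = field(default_factory=list)
    removed_by_pca: list = field(default_factory=list)
    removed_by_corr: list = field(default_factory=list)
    corr_pairs: list = field(default_factory=list)


def pca_filter(
    X: pd.DataFrame,
    var_target: float = 0.95,
    loading_r: float = 0.7,
    mode: str = "scores",
) -> ReductionReport:
    """Keep features tracking the components that carry ``var_target``
    of the variance.

    ``mode="scores"`` correlates each (standardized) feature column with
    the retained component score vectors; ``mode="loadings"`` instead
    thresholds the component loadings scaled to correlation units.
    Constant columns cannot be standardized and are removed up front
    with a warning.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    const = [c for c in X.columns if np.std(X[c].to_numpy()) == 0.0]
    if const:
        warnings.warn(f"removing constant columns before PCA: {const}")
    cols = [c for c in X.columns if c not in const]
    if not cols:
        return ReductionReport(retained=[], removed_constant=const)
    if len(cols) == 1:
        # a single feature is its own component explaining 100%
        return ReductionReport(
            retained=cols, n_components=1,
            max_component_corr={cols[0]: 1.0}, removed_constant=const,
        )
    Z = (X[cols] - X[cols].mean()) / X[cols].std(ddof=0)
    Zv = Z.to_numpy()
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(Zv)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_target) + 1)
    n_comp = min(n_comp, scores.shape[1])
    if mode == "scores":
        # correlation of each feature with each retained score vector
        s = scores[:, :n_comp]
        s_sd = s.std(axis=0)
        s_sd[s_sd == 0] = np.inf
        corr = (Zv.T @ ((s - s.mean(axis=0)) / s_sd)) / len(Zv)
    elif mode == "loadings":
        # loadings scaled to feature-component correlations
        corr = (
            pca.components_[:n_comp].T
            * np.sqrt(pca.explained_variance_[:n_comp])[None, :]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    max_corr = np.max(np.abs(corr), axis=1)
    retained = [c for c, r in zip(cols, max_corr) if r > loading_r]
    return ReductionReport(
        retained=retained,
        n_components=n_comp,
        max_component_corr=dict(zip(cols, max_corr.tolist())),
        removed_constant=const,
        removed_by_pca=[c for c in cols if c not in retained],
    )


def corr_prune(X: pd.DataFrame, cutoff: float = 0.95) -> ReductionReport:
    """Greedily break up feature pairs with |Pearson r| >= cutoff.

    At each step the most-correlated pair is found and the member with
    the larger mean absolute correlation to all remaining features is
    dropped (ties keep the earlier column).  Afterwards no remaining
    pair reaches the cutoff.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    cols = list(X.columns)
    corr = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
    if corr.ndim == 0:  # single column
        return ReductionReport(retained=cols)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(cols)))
    removed = []
    pairs = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() < cutoff:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[i_loc], alive[j_loc]
        mean_i = sub[i_loc].mean()
        mean_j = sub[j_loc].mean()
        # drop the member more redundant overall; tie keeps earlier column
        drop = j if mean_j >= mean_i else i
        if np.isclose(mean_i, mean_j):
            drop = max(i, j)
        pairs.append((cols[i], cols[j], float(corr[i, j])))
        removed.append(cols[drop])
        alive.remove(drop)
    return ReductionReport(
        retained=[cols[k] for k in alive],
        removed_by_corr=removed,
        corr_pairs=pairs,
    )


def reduce_features(
    X: pd.DataFrame,
    var_target: float = 0.95,
    loading_r: float = 0.7,
    corr_cutoff: float = 0.95,
    mode: str = "scores",
) -> ReductionReport:
    """Full reduction: PCA variance filter followed by correlation pruning."""
    rep1 = pca_filter(X, var_target=var_target, loading_r=loading_r, mode=mode)
    if not rep1.retained:
        return rep1
    rep2 = corr_prune(X[rep1.retained], cutoff=corr_cutoff)
    return ReductionReport(
        retained=rep2.retained,
        n_components=rep1.n_components,
        max_component_corr=rep1.max_component_corr,
        removed_constant=rep1.removed_constant,
        removed_by_pca=rep1.removed_by_pca,
        removed_by_corr=rep2.removed_by_corr,
        corr_pairs=rep2.corr_pairs,
    )
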