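"""s-PANAS scoring, binary affect labels, imputation and pooling.

The short PANAS has ten items rated 1-5: five positive-affect items
(alert, inspired, determined, attentive, active) and five
negative-affect items (upset, hostile, nervous, ashamed, afraid).
Valence score = sum(positive) - sum(negative), in [-20, 20]; a positive
score means positive valence.  Arousal score = sum of all ten items, in
[10, 50]; the scale midline 30 separates low (< 30, including exactly
30) from high arousal.

Per movie, feature rows are cleaned per the quality-driven rules: an
epoch with more than 50% bad channels is dropped entirely; a feature
column with at most 20% missing values within the movie is mean-imputed
from the observed values; rows carrying misses in columns that exceed
20% missingness are dropped.  Cleaned blocks from all subjects are then
pooled per feature family and joined to the labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import NEGATIVE_ITEMS, PANAS_ITEMS, POSITIVE_ITEMS


def _validate_items(items) -> dict:
    out = {}
    for name in PANAS_ITEMS:
        if name not in items:
            raise ValueError(f"missing s-PANAS item {name!r}")
        v = int(items[name])
        if not 1 <= v <= 5:
            raise ValueError(f"item {name!r}={v} outside the 1..5 scale")
        out[name] = v
    return out


def score_valence(items) -> int:
    """Sum of positive-affect items minus sum of negative-affect items."""
    v = _validate_items(items)
    return sum(v[i] for i in POSITIVE_ITEMS) - sum(v[i] for i in NEGATIVE_ITEMS)


def score_arousal(items) -> int:
    """Sum of all ten items (minimum 10, maximum 50)."""
    v = _validate_items(items)
    return sum(v[i] for i in PANAS_ITEMS)


def binarize(valence_score: float, arousal_score: float) -> tuple:
    """Map scores to classes.

    Valence is positive iff the score exceeds 0 (a score of exactly 0
    counts as negative, i.e. non-positive).  Arousal is low iff the
    score is below the midline 30; exactly 30 also counts as low.
    """
    valence_class = "positive" if valence_score > 0 else "negative"
    arousal_class = "high" if arousal_score > 30 else "low"
    return valence_class, arousal_class


def labels_from_panas(responses: pd.DataFrame, label_source: str = "subjective") -> pd.DataFrame:
    """Per-(subject, movie) labels from questionnaire rows.

    ``responses`` needs columns ``subject``, ``movie`` and the ten item
    columns.  Returns scores, classes and the label source tag.
    """
    rows = []
    for _, r in responses.iterrows():
        vs = score_valence(r)
        ar = score_arousal(r)
        vc, ac = binarize(vs, ar)
        rows.append(
            {
                "subject": r["subject"],
                "movie": r["movie"],
                "valence_score": vs,
                "arousal_score": ar,
                "valence_class": vc,
                "arousal_class": ac,
                "label_source": label_source,
            }
        )
    return pd.DataFrame(rows)


def labels_from_raters(rater_scores: pd.DataFrame, subjects) -> pd.DataFrame:
    """Per-movie rater labels broadcast to every subject.

    ``rater_scores`` holds per-movie *mean* item scores from the
    independent rating panel; means are scored with the same formulas
    and binarized with the same thresholds, then assigned to each
    subject's movies (the rater path replaces only the labels, never the
    features).
    """
    rows = []
    for _, r in rater_scores.iterrows():
        pos = sum(float(r[i]) for i in POSITIVE_ITEMS)
        neg = sum(float(r[i]) for i in NEGATIVE_ITEMS)
        vs, ar = pos - neg, pos + neg
        vc, ac = binarize(vs, ar)
        for s in subjects:
            rows.append(
                {
                    "subject": s,
                    "movie": r["movie"],
                    "valence_score": vs,
                    "arousal_score": ar,
                    "valence_class": vc,
                    "arousal_class": ac,
                    "label_source": "rater",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# imputation

@dataclass
class MovieBlock:
    """One (subject, movie)'s feature rows plus channel-level badness.

    ``bad_channel_count`` aligns with ``features`` rows and counts the
    quality-masked channels of each epoch; ``n_channels`` is the montage
    size the >50% rule is taken against.
    """

    features: pd.DataFrame
    bad_channel_count: pd.Series
    n_channels: int = 8


def impute_movie(block: MovieBlock) -> pd.DataFrame:
    """Apply the per-movie missing-value rules; output has no NaN.

    1. drop epochs with more than 50% of channels bad;
    2. drop rows that are entirely missing (an epoch unusable for this
       feature family, e.g. a masked frontal channel in the multiscale
       family);
    3. columns with <= 20% missing values within the movie: impute with
       the column mean of the observed values;
    4. columns with more: drop the rows carrying those misses.

    Raises ``ValueError`` if nothing survives (the movie is excluded by
    the caller and logged).
    """
    df = block.features.copy()
    keep = block.bad_channel_count.to_numpy() <= block.n_channels / 2.0
    df = df.loc[keep]
    df = df.loc[~df.isna().all(axis=1)]
    if not len(df):
        raise ValueError("all epochs of the movie were dropped")
    miss_frac = df.isna().mean(axis=0)
    impute_cols = miss_frac[(miss_frac > 0) & (miss_frac <= 0.2)].index
    for c in impute_cols:
        df[c] = df[c].fillna(df[c].mean())
    drop_cols = miss_frac[miss_frac > 0.2].index
    if len(drop_cols):
        df = df.loc[~df[drop_cols].isna().any(axis=1)]
    if not len(df):
        raise ValueError("all epochs of the movie were dropped")
    assert not df.isna().any().any()
    return df


def assemble_family(
    features: pd.DataFrame,
    bad_channel_count: pd.Series,
    labels: pd.DataFrame,
    n_channels: int = 8,
) -> tuple:
    """Clean every (subject, movie) block and pool with labels.

    ``features`` is indexed by (subject, movie, epoch); returns
    ``(pooled, dropped_movies, stats)`` where ``pooled`` carries the
    feature columns plus the label columns, ``dropped_movies`` lists
    movies excluded because no epoch survived, and ``stats`` counts raw,
    channel-rule-removed, imputation-removed and surviving rows (the
    four always sum: raw = removed + surviving).
    """
    lab = labels.set_index(["subject", "movie"])
    blocks = []
    dropped = []
    stats = {
        "raw_rows": int(len(features)),
        "removed_channel_rule": 0,
        "removed_imputation": 0,
        "surviving_rows": 0,
    }
    for (subj, movie), grp in features.groupby(level=["subject", "movie"], sort=False):
        if (subj, movie) not in lab.index:
            raise ValueError(f"no labels for subject={subj!r} movie={movie!r}")
        bad = bad_channel_count.loc[grp.index]
        n_chan_drop = int((bad.to_numpy() > n_channels / 2.0).sum())
        stats["removed_channel_rule"] += n_chan_drop
        try:
            clean = impute_movie(MovieBlock(grp, bad, n_channels))
        except ValueError:
            dropped.append((subj, movie))
            stats["removed_imputation"] += len(grp) - n_chan_drop
            continue
        stats["removed_imputation"] += len(grp) - n_chan_drop - len(clean)
        stats["surviving_rows"] += len(clean)
        for col in (
            "valence_score", "arousal_score",
            "valence_class", "arousal_class", "label_source",
        ):
            clean[col] = lab.loc[(subj, movie), col]
        blocks.append(clean)
    if not blocks:
        raise ValueError("no movie block survived assembly")
    return pd.concat(blocks, axis=0), dropped, stats


LABEL_COLUMNS = (
    "valence_score", "arousal_score", "valence_class", "arousal_class", "label_source",
)


def split_features_labels(pooled: pd.DataFrame) -> tuple:
    """Separate a pooled dataset into (features, labels) frames."""
    label_cols = [c for c in LABEL_COLUMNS if c in pooled.columns]
    return pooled.drop(columns=label_cols), pooled[label_cols]
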