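"""Per-channel-epoch signal quality scoring on a 0-1 scale.

Dry-electrode recordings in a naturalistic setting lose a substantial
share of epochs to ocular, motion and contact artifacts, so every
channel-epoch gets a quality score in [0, 1] (0 best, 1 worst) before
features are pooled.  The score is the fraction of tripped binary flags:

* **amplitude**: any sample exceeds ``a_max`` in magnitude,
* **flatline**: sample variance below ``v_min``,
* **hf_noise**: fraction of spectral power above 40 Hz exceeds ``h_max``,
* **clipping**: at least ``k_clip`` consecutive identical extreme samples.

Only channel-epochs scoring exactly 1 (every flag tripped — certain of
low quality) are masked as missing; partially flagged data is kept and
left to the downstream imputation rules.  An optional contact-impedance
flag participates when an impedance trace is supplied and is ignored
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import EpochSet


@dataclass(frozen=True)
class QualityThresholds:
    a_max: float = 150.0          # amplitude bound, signal units
    v_min: float = 1e-8           # flatline variance floor, units^2
    h_max: float = 0.3            # max tolerated power fraction above hf_cut
    hf_cut: float = 40.0          # Hz
    k_clip: int = 20              # consecutive identical extreme samples
    clip_level: float = 0.95      # "extreme" = |x| >= clip_level * a_max
    z_max: float = 50.0           # impedance bound (arbitrary kOhm), optional flag


def _clipping_run(x: np.ndarray, thr: QualityThresholds) -> bool:
    """True if >= k_clip consecutive identical extreme samples occur."""
    if len(x) < 2:
        return False
    extreme = np.abs(x) >= thr.clip_level * thr.a_max
    g = extreme[1:] & extreme[:-1] & (np.diff(x) == 0.0)
    edges = np.diff(np.concatenate(([0], g.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    if not len(starts):
        return False
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max()) + 1 >= thr.k_clip


def score_channel_epoch(
    x: np.ndarray,
    fs: float,
    thresholds: QualityThresholds = QualityThresholds(),
    impedance: float | None = None,
    epoch_s: float = 8.0,
) -> tuple:
    """Score one channel-epoch; returns ``(value, flags)``.

    ``value`` is (number of tripped flags) / (number of flags) and equals
    1 only when every flag trips.
    """
    x = np.asarray(x, dtype=np.float64)
    expected = int(round(epoch_s * fs))
    if x.shape != (expected,):
        raise ValueError(
            f"epoch must be exactly {epoch_s} s at fs={fs} "
            f"({expected} samples); got {x.shape}"
        )
    flags = {}
    flags["amplitude"] = bool(np.max(np.abs(x)) > thresholds.a_max)
    flags["flatline"] = bool(np.var(x) < thresholds.v_min)
    if np.var(x) > 0:
        f, psd = sps.welch(x, fs=fs, nperseg=min(len(x), int(2 * fs)))
        total = psd.sum()
        hf_frac = psd[f > thresholds.hf_cut].sum() / total if total > 0 else 0.0
    else:
        hf_frac = 0.0
    flags["hf_noise"] = bool(hf_frac > thresholds.h_max)
    flags["clipping"] = _clipping_run(x, thresholds)
    if impedance is not None:
        flags["impedance"] = bool(impedance > thresholds.z_max)
    value = sum(flags.values()) / len(flags)
    return value, flags


def score_epochset(
    es: EpochSet, thresholds: QualityThresholds = QualityThresholds()
) -> pd.DataFrame:
    """Long-format scores: one row per (subject, movie, epoch, channel)."""
    rows = []
    for i in range(es.n_epochs):
        meta = es.index.iloc[i]
        for ci, ch in enumerate(es.channels):
            value, flags = score_channel_epoch(es.epochs[i, ci], es.fs, thresholds)
            rows.append(
                {
                    "subject": meta["subject"],
                    "movie": meta["movie"],
                    "epoch": meta["epoch"],
                    "channel": ch,
                    "score": value,
                    **{f"flag_{k}": v for k, v in flags.items()},
                }
            )
    return pd.DataFrame(rows)


def apply_quality(es: EpochSet, scores: pd.DataFrame) -> EpochSet:
    """Mask channel-epochs whose score is exactly 1 (certain-bad).

    Nothing else is removed here; epoch-level removal (>50% bad channels)
    happens during dataset assembly.  Scores must cover every
    channel-epoch of ``es``.
    """
    lut = scores.set_index(["movie", "epoch", "channel"])["score"].to_dict()
    mask = np.zeros(es.epochs.shape[:2], dtype=bool)
    movies = es.index["movie"].to_numpy()
    epoch_ids = es.index["epoch"].to_numpy()
    for i in range(es.n_epochs):
        for ci, ch in enumerate(es.channels):
            key = (movies[i], epoch_ids[i], ch)
            if key not in lut:
                raise ValueError(f"missing quality score for {key}")
            mask[i, ci] = lut[key] == 1.0
    return EpochSet(
        subject_id=es.subject_id,
        epochs=es.epochs,
        index=es.index,
        fs=es.fs,
        channels=es.channels,
        mask=mask,
    )
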