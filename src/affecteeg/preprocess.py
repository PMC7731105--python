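"""Filtering, movie segmentation and 8-s epoching.

The raw session is band-passed 2-45 Hz and notch-filtered 49-51 Hz with
5th-order Butterworth filters, applied forward-backward (zero phase) as
second-order sections.  Movie segments are then cut by the timeline
markers (neutral lead-ins are excluded) and divided into non-overlapping
8-s epochs; a trailing remainder shorter than 8 s is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import EpochSet, Recording

EPOCH_S = 8.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass + power-line notch."""

    order: int = 5
    band_hz: tuple = (2.0, 45.0)
    notch_hz: tuple = (49.0, 51.0)

    def __post_init__(self):
        lo, hi = self.band_hz
        if not lo < hi:
            raise ValueError("band low edge must be below high edge")
        nlo, nhi = self.notch_hz
        if not nlo < nhi:
            raise ValueError("notch low edge must be below high edge")


def _design(spec: FilterSpec, fs: float):
    if fs / 2.0 <= spec.notch_hz[1]:
        raise ValueError(
            f"fs={fs} too low: Nyquist must exceed the notch upper edge "
            f"{spec.notch_hz[1]} Hz"
        )
    band = sps.butter(spec.order, spec.band_hz, btype="bandpass", fs=fs, output="sos")
    notch = sps.butter(spec.order, spec.notch_hz, btype="bandstop", fs=fs, output="sos")
    return band, notch


def filter_recording(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase band-pass and notch filter every channel.

    Forward-backward application keeps epoch boundaries phase-aligned at
    the cost of doubling the effective attenuation.
    """
    band, notch = _design(spec, rec.fs)
    data = sps.sosfiltfilt(band, rec.data, axis=1)
    data = sps.sosfiltfilt(notch, data, axis=1)
    return replace(rec, data=data, markers=rec.markers)


def segment_by_movie(rec: Recording) -> list:
    """Cut the session into per-movie segments ``(movie_id, data)``.

    Markers must be strictly ordered, non-overlapping and inside the
    recording; segment length follows each movie's own marker span.
    """
    segments = []
    prev_stop = 0
    for _, m in rec.markers.iterrows():
        start, stop = int(m["start"]), int(m["stop"])
        if start < prev_stop or stop <= start or stop > rec.n_samples:
            raise ValueError(
                f"marker {m['movie_id']!r} invalid or overlapping: "
                f"[{start}, {stop}) with previous stop {prev_stop}, "
                f"session length {rec.n_samples}"
            )
        segments.append((m["movie_id"], rec.data[:, start:stop]))
        prev_stop = stop
    return segments


def make_epochs(segment: np.ndarray, fs: float) -> np.ndarray:
    """Split one movie segment into non-overlapping 8-s epochs.

    Returns (n_epochs, n_channels, 8*fs); the trailing remainder shorter
    than 8 s is discarded.  A segment shorter than 8 s yields zero
    epochs with a warning.
    """
    epoch_len = int(round(EPOCH_S * fs))
    n = segment.shape[1]
    n_epochs = n // epoch_len
    if n_epochs == 0:
        warnings.warn(f"segment of {n / fs:.1f} s is shorter than one 8-s epoch")
        return np.empty((0, segment.shape[0], epoch_len))
    trimmed = segment[:, : n_epochs * epoch_len]
    return trimmed.reshape(segment.shape[0], n_epochs, epoch_len).transpose(1, 0, 2)


def build_epochset(rec: Recording) -> EpochSet:
    """Segment a filtered recording and epoch every movie."""
    all_epochs = []
    rows = []
    for movie_id, seg in segment_by_movie(rec):
        eps = make_epochs(seg, rec.fs)
        for i in range(eps.shape[0]):
            rows.append({"subject": rec.subject_id, "movie": movie_id, "epoch": i})
        if eps.shape[0]:
            all_epochs.append(eps)
    epoch_len = int(round(EPOCH_S * rec.fs))
    epochs = (
        np.concatenate(all_epochs, axis=0)
        if all_epochs
        else np.empty((0, len(rec.channels), epoch_len))
    )
    index = pd.DataFrame(rows, columns=["subject", "movie", "epoch"])
    return EpochSet(
        subject_id=rec.subject_id,
        epochs=epochs,
        index=index,
        fs=rec.fs,
        channels=rec.channels,
    )
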