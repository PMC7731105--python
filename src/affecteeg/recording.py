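"""Core containers: multichannel recordings and fixed-length epoch sets.

A :class:`Recording` holds one subject's continuous session (channels x
samples) together with the sampling rate, channel names and per-movie
timing markers.  An :class:`EpochSet` holds the non-overlapping analysis
windows cut from the movie segments, plus a per-channel missingness mask
filled in by the quality stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: canonical channel order of the 8-channel frontal/central montage
CHANNELS = ("F3", "F4", "Fz", "F7", "F8", "C3", "C4", "Cz")

#: the five frontal channels used for the multiscale decomposition
FRONTAL_CHANNELS = ("F3", "F4", "Fz", "F7", "F8")


@dataclass
class Recording:
    """One subject's continuous EEG session.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-like arbitrary units.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Channel names, same order as rows of ``data``.
    markers : pandas.DataFrame
        One row per movie clip with columns ``movie_id``, ``start``,
        ``stop`` (sample indices, ``stop`` exclusive).  Neutral lead-in
        clips are not marked; everything outside a marker is ignored by
        the analysis.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channels: tuple = CHANNELS
    markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["movie_id", "start", "stop"])
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels={len(self.channels)}, n_samples); "
                f"got {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs cut from movie segments.

    ``epochs`` is (n_epochs, n_channels, n_samples_per_epoch); ``index``
    has one row per epoch with columns ``subject``, ``movie``, ``epoch``
    (the 0-based epoch index within its movie).  ``mask`` is True where a
    channel-epoch has been flagged certain-bad by the quality stage and
    must be treated as missing downstream.
    """

    subject_id: str
    epochs: np.ndarray
    index: pd.DataFrame
    fs: float
    channels: tuple = CHANNELS
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.epochs.shape[:2], dtype=bool)
        if self.epochs.shape[0] != len(self.index):
            raise ValueError("index length must match number of epochs")
        if self.mask.shape != self.epochs.shape[:2]:
            raise ValueError("mask must be (n_epochs, n_channels)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]


def write_recording(path, rec: Recording) -> None:
    """Write a recording to HDF5 (groups /eeg, /markers, /meta)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg/data", data=rec.data)
        g = f.create_group("markers")
        g.create_dataset(
            "movie_id",
            data=np.asarray(rec.markers["movie_id"], dtype=h5py.string_dtype()),
        )
        g.create_dataset("start", data=np.asarray(rec.markers["start"], dtype=np.int64))
        g.create_dataset("stop", data=np.asarray(rec.markers["stop"], dtype=np.int64))
        m = f.create_group("meta")
        m.attrs["fs"] = rec.fs
        m.attrs["subject_id"] = rec.subject_id
        m.create_dataset(
            "channels", data=np.asarray(rec.channels, dtype=h5py.string_dtype())
        )


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        data = f["eeg/data"][()]
        markers = pd.DataFrame(
            {
                "movie_id": [s.decode() for s in f["markers/movie_id"][()]],
                "start": f["markers/start"][()],
                "stop": f["markers/stop"][()],
            }
        )
        channels = tuple(s.decode() for s in f["meta/channels"][()])
        fs = float(f["meta"].attrs["fs"])
        subject_id = str(f["meta"].attrs["subject_id"])
    return Recording(
        subject_id=subject_id, data=data, fs=fs, channels=channels, markers=markers
    )


def write_epochset(path, es: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=es.epochs)
        f.create_dataset("mask", data=es.mask)
        g = f.create_group("index")
        g.create_dataset(
            "movie", data=np.asarray(es.index["movie"], dtype=h5py.string_dtype())
        )
        g.create_dataset("epoch", data=np.asarray(es.index["epoch"], dtype=np.int64))
        f.attrs["fs"] = es.fs
        f.attrs["subject_id"] = es.subject_id
        f.create_dataset(
            "channels", data=np.asarray(es.channels, dtype=h5py.string_dtype())
        )


def read_epochset(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        subject_id = str(f.attrs["subject_id"])
        index = pd.DataFrame(
            {
                "subject": subject_id,
                "movie": [s.decode() for s in f["index/movie"][()]],
                "epoch": f["index/epoch"][()],
            }
        )
        return EpochSet(
            subject_id=subject_id,
            epochs=f["epochs"][()],
            index=index,
            fs=float(f.attrs["fs"]),
            channels=tuple(s.decode() for s in f["channels"][()]),
            mask=f["mask"][()],
        )
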