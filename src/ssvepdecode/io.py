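"""Epoch container and portable on-disk storage.

The universal currency of every stage in this package is the
:class:`EpochSet`: a 4-way real array indexed
``(class, trial, channel, sample)`` together with the sampling rate, the
channel labels, the stimulus frequencies and the time of the first retained
sample relative to stimulus onset.  Epoch sets are stored one-per-file in a
self-describing HDF5 container (dataset ``/data`` plus attributes), so no
bespoke parser is needed and round-trips are bit-exact.

An explicit adapter is provided for per-subject matrices laid out in the
common public-benchmark axis order ``(channel, sample, class, block)``;
adaptation is a pure axis permutation plus a class reordering and is always
logged, never silent.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "EpochSet",
    "EpochFormatError",
    "read_epochs",
    "write_epochs",
    "adapt_benchmark_record",
    "benchmark_frequency_table",
]


class EpochFormatError(ValueError):
    """Raised when an on-disk container is missing metadata or malformed."""


@dataclass
class EpochSet:
    """Multichannel EEG epochs organized by stimulus class.

    Parameters
    ----------
    data : ndarray, shape (n_classes, n_trials, n_channels, n_samples)
        Real-valued EEG epochs.  ``data[i, t]`` is one trial of class ``i``
        as a ``channels x samples`` matrix.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique 10-20 channel names, one per channel row.
    stim_freqs : ndarray, shape (n_classes,)
        Stimulation frequency of each class in Hz, strictly increasing.
    t0 : float
        Time in seconds of the first retained sample relative to stimulus
        onset.  Window extraction updates it so latency bookkeeping stays
        auditable.
    preprocessing_log : list of str
        Append-only record of the operations applied so far, serialized
        with the data.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    stim_freqs: np.ndarray
    t0: float = 0.0
    preprocessing_log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.stim_freqs = np.asarray(self.stim_freqs, dtype=np.float64)
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 4:
            raise EpochFormatError(
                f"data must be 4-way (class, trial, channel, sample); got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise EpochFormatError(f"all dimensions must be >= 1; got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise EpochFormatError("data contains non-finite values")
        if self.fs <= 0:
            raise EpochFormatError(f"fs must be positive; got {self.fs}")
        nf, _, nc, _ = self.data.shape
        if len(self.stim_freqs) != nf:
            raise EpochFormatError(
                f"stim_freqs length {len(self.stim_freqs)} != n_classes {nf}"
            )
        if nf > 1 and not np.all(np.diff(self.stim_freqs) > 0):
            raise EpochFormatError("stim_freqs must be strictly increasing")
        if len(self.channel_labels) != nc:
            raise EpochFormatError(
                f"channel_labels length {len(self.channel_labels)} != n_channels {nc}"
            )
        if len(set(self.channel_labels)) != nc:
            raise EpochFormatError("channel labels must be unique")

    # -- convenience ---------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, log_entry: str | None = None, **kw) -> "EpochSet":
        """Return a copy carrying ``data``, appending ``log_entry`` to the log."""
        log = list(self.preprocessing_log)
        if log_entry:
            log.append(log_entry)
        return replace(self, data=data, preprocessing_log=log, **kw)


_REQUIRED_ATTRS = ("fs", "channel_labels", "stim_freqs", "t0")


def write_epochs(epochs: EpochSet, path) -> str:
    """Write an :class:`EpochSet` to an HDF5 container, atomically.

    The file holds the 4-way array under ``/data`` with attributes ``fs``,
    ``channel_labels``, ``stim_freqs``, ``t0`` and ``preprocessing_log``.
    Overwrites via rename so a crash never leaves a half-written file.
    """
    epochs.validate()
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise IOError(f"directory does not exist: {directory}")
    if not os.access(directory, os.W_OK):
        raise IOError(f"directory is not writable: {directory}")
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".h5.tmp")
    os.close(fd)
    try:
        # track_times=False keeps the byte content independent of wall time
        with h5py.File(tmp, "w", track_order=True) as f:
            ds = f.create_dataset("data", data=epochs.data, track_times=False)
            ds.attrs["fs"] = float(epochs.fs)
            ds.attrs["channel_labels"] = [s.encode() for s in epochs.channel_labels]
            ds.attrs["stim_freqs"] = epochs.stim_freqs
            ds.attrs["t0"] = float(epochs.t0)
            ds.attrs["preprocessing_log"] = [s.encode() for s in epochs.preprocessing_log]
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`.

    Raises
    ------
    EpochFormatError
        If the container lacks ``/data`` or any required attribute, or the
        stored array is not 4-way.
    """
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise EpochFormatError("container has no /data dataset")
        ds = f["data"]
        for name in _REQUIRED_ATTRS:
            if name not in ds.attrs:
                raise EpochFormatError(f"missing required attribute: {name}")
        data = np.asarray(ds)
        if data.ndim != 4:
            raise EpochFormatError(f"/data must be 4-way; got ndim={data.ndim}")
        labels = tuple(
            s.decode() if isinstance(s, bytes) else str(s) for s in ds.attrs["channel_labels"]
        )
        log = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in ds.attrs.get("preprocessing_log", [])
        ]
        return EpochSet(
            data=data,
            fs=float(ds.attrs["fs"]),
            channel_labels=labels,
            stim_freqs=np.asarray(ds.attrs["stim_freqs"], dtype=np.float64),
            t0=float(ds.attrs["t0"]),
            preprocessing_log=log,
        )


def benchmark_frequency_table(n_classes: int = 40) -> np.ndarray:
    """Stimulus frequencies of the 40-target speller in recorded class order.

    The speller grid spans 8.0-15.8 Hz in 0.2 Hz steps; in the distributed
    per-subject matrices class ``k`` (0-based) flickers at
    ``8.0 + (k % 8) * 1.0 + (k // 8) * 0.2`` Hz, i.e. classes run through
    8,9,...,15 Hz before the offset increments by 0.2 Hz.
    """
    k = np.arange(n_classes)
    return 8.0 + (k % 8) * 1.0 + (k // 8) * 0.2


_BENCHMARK_AXES = ("channel", "sample", "class", "block")


def adapt_benchmark_record(
    raw: np.ndarray,
    channel_labels,
    fs: float,
    freqs_hz=None,
    axes=_BENCHMARK_AXES,
    t0: float = 0.0,
) -> EpochSet:
    """Adapt a public-benchmark per-subject matrix to an :class:`EpochSet`.

    Parameters
    ----------
    raw : ndarray, 4-way
        Per-subject matrix.  The distributed layout is
        ``(channel, sample, class, block)``; pass ``axes`` explicitly if the
        array at hand is laid out differently.  Unknown axis names raise —
        the order is never guessed.
    channel_labels : sequence of str
        One label per channel row (64 in the public recordings).
    fs : float
        The sampling rate the file declares.  The declared rate is trusted
        over any nominal acquisition rate, because distributed copies are
        commonly resampled.
    freqs_hz : sequence of float, optional
        Stimulus frequency of each class in recorded order.  Defaults to
        :func:`benchmark_frequency_table`.  Classes are re-sorted so the
        resulting ``stim_freqs`` are strictly increasing.
    """
    raw = np.asarray(raw)
    if raw.ndim != 4:
        raise EpochFormatError(f"benchmark record must be 4-way; got ndim={raw.ndim}")
    axes = tuple(axes)
    if sorted(axes) != sorted(_BENCHMARK_AXES):
        raise EpochFormatError(
            f"unknown axis order {axes!r}; expected a permutation of {_BENCHMARK_AXES}"
        )
    perm = [axes.index(name) for name in ("class", "block", "channel", "sample")]
    data = np.transpose(raw, perm)
    nf = data.shape[0]
    if freqs_hz is None:
        freqs_hz = benchmark_frequency_table(nf)
    freqs_hz = np.asarray(freqs_hz, dtype=np.float64)
    if len(freqs_hz) != nf:
        raise EpochFormatError(f"frequency table length {len(freqs_hz)} != n_classes {nf}")
    order = np.argsort(freqs_hz, kind="stable")
    return EpochSet(
        data=data[order],
        fs=float(fs),
        channel_labels=tuple(channel_labels),
        stim_freqs=freqs_hz[order],
        t0=t0,
        preprocessing_log=[
            f"adapt_benchmark_record(axes={axes}, class_order_sorted_by_freq)"
        ],
    )
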