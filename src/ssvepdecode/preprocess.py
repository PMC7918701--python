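"""Band-pass filtering and latency-aware window extraction.

SSVEP analysis conventionally band-passes the raw epochs (7-90 Hz here,
wide enough to keep all usable harmonics) with a zero-phase Chebyshev
type-I IIR filter, then cuts the analysis window starting at a fixed
visual-pathway latency (0.64 s) after stimulus onset.  Filtering is applied
to the full epoch *before* windowing so filter transients stay outside the
analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochSet

__all__ = [
    "IIRSpec",
    "WindowSpec",
    "bandpass",
    "extract_window",
    "select_channels",
    "DEFAULT_BAND",
    "DEFAULT_LATENCY_S",
]

DEFAULT_BAND = (7.0, 90.0)
DEFAULT_LATENCY_S = 0.64


@dataclass(frozen=True)
class IIRSpec:
    """Chebyshev type-I band-pass design.

    ``order`` and ``ripple_db`` are per filtering direction; with
    ``zero_phase`` the filter runs forward-backward (sosfiltfilt), doubling
    the effective order and cancelling group delay.
    """

    low_hz: float = DEFAULT_BAND[0]
    high_hz: float = DEFAULT_BAND[1]
    order: int = 4
    ripple_db: float = 1.0
    zero_phase: bool = True

    def sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if not (0.0 < self.low_hz < self.high_hz < nyq):
            raise ValueError(
                f"passband [{self.low_hz}, {self.high_hz}] Hz invalid for fs={fs} Hz "
                f"(Nyquist {nyq} Hz)"
            )
        return signal.cheby1(
            self.order, self.ripple_db, [self.low_hz, self.high_hz],
            btype="bandpass", output="sos", fs=fs,
        )


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: ``latency_s`` after onset, ``tw_s`` long."""

    latency_s: float = DEFAULT_LATENCY_S
    tw_s: float = 0.5

    def indices(self, fs: float) -> tuple[int, int]:
        """Half-open sample range [start, stop) using nearest-integer rounding."""
        if self.latency_s < 0:
            raise ValueError(f"latency_s must be >= 0; got {self.latency_s}")
        if self.tw_s <= 0:
            raise ValueError(f"tw_s must be > 0; got {self.tw_s}")
        start = int(round(self.latency_s * fs))
        length = int(round(self.tw_s * fs))
        if length < 2:
            raise ValueError(f"window of {self.tw_s} s at fs={fs} Hz is under 2 samples")
        return start, start + length


def bandpass(epochs: EpochSet, spec: IIRSpec = IIRSpec()) -> EpochSet:
    """Filter each channel of each trial independently along the sample axis."""
    sos = spec.sos(epochs.fs)
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        out = signal.sosfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(
        np.ascontiguousarray(out),
        log_entry=(
            f"bandpass(cheby1, {spec.low_hz}-{spec.high_hz} Hz, order={spec.order}, "
            f"ripple={spec.ripple_db} dB, zero_phase={spec.zero_phase})"
        ),
    )


def extract_window(epochs: EpochSet, spec: WindowSpec) -> EpochSet:
    """Cut the analysis window, updating ``t0`` to the new first-sample time."""
    start, stop = spec.indices(epochs.fs)
    if stop > epochs.n_samples:
        raise ValueError(
            f"window needs samples [{start}, {stop}) but epoch has only "
            f"{epochs.n_samples} samples"
        )
    return epochs.with_data(
        epochs.data[..., start:stop].copy(),
        log_entry=f"extract_window(latency={spec.latency_s}s, tw={spec.tw_s}s)",
        t0=epochs.t0 + start / epochs.fs,
    )


def select_channels(epochs: EpochSet, labels) -> EpochSet:
    """Reduce and reorder the channel axis to ``labels`` (duplicates rejected)."""
    labels = [str(c) for c in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ValueError(f"duplicate channel labels requested: {dupes}")
    index = {c: i for i, c in enumerate(epochs.channel_labels)}
    missing = [c for c in labels if c not in index]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    sel = [index[c] for c in labels]
    return epochs.with_data(
        epochs.data[:, :, sel, :].copy(),
        log_entry=f"select_channels({labels})",
        channel_labels=tuple(labels),
    )
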