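"""Sub-band decomposition and weighted score combination.

The filter-bank scheme used here decomposes the epoch into ``Nb`` nested
sub-bands ``[b*8, 90]`` Hz (the "M3" harmonic scheme: band ``b`` drops the
first ``b-1`` harmonic regions while keeping the high-frequency content),
runs the base recognizer separately on each band, and combines the per-band
class scores with weights ``s_b = b**-1.25 + 0.25`` that compensate for the
falling SNR of higher SSVEP harmonics.

The combination is ``score[i] = sum_b s_b * sign(r_i^b) * (r_i^b)**2``.
The signed square coincides with the conventional plain square for
non-negative base scores (CCA correlations) while remaining rank-preserving
for base methods whose scores can go negative (TRCA-family ensembles); see
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cca import ScoreVector
from .io import EpochSet
from .preprocess import IIRSpec, bandpass

__all__ = [
    "FilterBankSpec",
    "SubbandScores",
    "subband_weight",
    "decompose",
    "fb_combine",
    "fb_scores",
]


@dataclass(frozen=True)
class FilterBankSpec:
    """Sub-band layout and combination weights.

    Band ``b`` (1-based) spans ``[b * low_base_hz, high_hz]`` Hz.  With the
    defaults and 5 bands the lowest cutoffs are 8, 16, 24, 32, 40 Hz.
    """

    n_bands: int = 5
    low_base_hz: float = 8.0
    high_hz: float = 90.0
    weight_a: float = 1.25
    weight_b: float = 0.25
    iir: IIRSpec = field(default_factory=IIRSpec)

    def __post_init__(self):
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.n_bands * self.low_base_hz >= self.high_hz:
            raise ValueError(
                f"{self.n_bands} bands with base {self.low_base_hz} Hz reach "
                f"{self.n_bands * self.low_base_hz} Hz >= high cutoff {self.high_hz} Hz"
            )

    def band_edges(self, b: int) -> tuple[float, float]:
        return (b * self.low_base_hz, self.high_hz)

    def weights(self) -> np.ndarray:
        return np.array([
            subband_weight(b, self.weight_a, self.weight_b)
            for b in range(1, self.n_bands + 1)
        ])


@dataclass(frozen=True)
class SubbandScores:
    """Per-band base-method scores, shape (n_bands, n_classes)."""

    per_band: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.per_band, dtype=np.float64)
        if a.ndim != 2:
            raise ValueError("per_band must be 2-D (n_bands, n_classes)")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite sub-band score")
        object.__setattr__(self, "per_band", a)


def subband_weight(b: int, a: float = 1.25, c: float = 0.25) -> float:
    """Weight ``b**-a + c`` of sub-band ``b`` (1-based)."""
    if b < 1:
        raise ValueError(f"band index must be >= 1; got {b}")
    return float(b) ** (-a) + c


def decompose(epochs: EpochSet, spec: FilterBankSpec) -> list[EpochSet]:
    """Zero-phase band-pass the epochs into each sub-band ``[b*8, 90]`` Hz."""
    nyq = epochs.fs / 2.0
    out = []
    for b in range(1, spec.n_bands + 1):
        low, high = spec.band_edges(b)
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"sub-band {b} ([{low}, {high}] Hz) infeasible at fs={epochs.fs} Hz"
            )
        iir = replace(spec.iir, low_hz=low, high_hz=high)
        out.append(bandpass(epochs, iir))
    return out


def fb_combine(subband: SubbandScores, spec: FilterBankSpec) -> ScoreVector:
    """Combine per-band scores with the ``s_b`` weights (signed square)."""
    if subband.per_band.shape[0] != spec.n_bands:
        raise ValueError(
            f"got {subband.per_band.shape[0]} bands of scores for a "
            f"{spec.n_bands}-band spec"
        )
    w = spec.weights()
    r = subband.per_band
    combined = np.einsum("b,bi->i", w, np.sign(r) * r * r)
    return ScoreVector(scores=combined, method_tag="filterbank")


def fb_scores(test_bands, score_fn_per_band, spec: FilterBankSpec) -> ScoreVector:
    """Score one trial through the filter bank.

    Parameters
    ----------
    test_bands : list of ndarray
        The test trial band-passed into each sub-band (same decomposition
        the per-band models were fitted on), one channels-x-samples matrix
        per band.
    score_fn_per_band : list of callables
        One fitted scoring function per band; each maps a trial matrix to a
        :class:`ScoreVector` over classes.
    """
    if len(test_bands) != spec.n_bands or len(score_fn_per_band) != spec.n_bands:
        raise ValueError(
            f"need {spec.n_bands} test bands and fitted models; got "
            f"{len(test_bands)} and {len(score_fn_per_band)}"
        )
    per_band = np.vstack([
        score_fn_per_band[b](test_bands[b]).scores for b in range(spec.n_bands)
    ])
    return fb_combine(SubbandScores(per_band=per_band), spec)
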