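"""Leave-one-block-out evaluation, accuracy, ITR and summary metrics.

Each of the ``Nt`` recording blocks serves once as test data while the
remaining blocks train templates and spatial filters; every one of the
``Nf`` test trials in the held-out block is classified, so a run yields
``Nf * Nt`` decisions.  Accuracy is averaged per fold (with balanced folds
this equals the pooled fraction correct); the information transfer rate is
computed per fold from that fold's accuracy and then averaged, matching
per-block averaging conventions — which is why mean accuracy and mean ITR
need not jointly satisfy the ITR formula.

The ITR of an ``Nf``-target selection with accuracy ``P`` and selection
time ``T`` seconds (stimulation window plus gaze-shift time) is::

    ITR = [log2 Nf + P log2 P + (1-P) log2((1-P)/(Nf-1))] * 60 / T

in bits per minute, with ``x log2 x = 0`` at ``x = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cca import (
    build_templates,
    cca_scores,
    classify,
    extcca_scores,
    make_reference,
)
from .filterbank import FilterBankSpec, decompose, fb_combine, SubbandScores
from .io import EpochSet
from .preprocess import DEFAULT_LATENCY_S, IIRSpec, WindowSpec, bandpass, extract_window, select_channels
from .trca import fit_trca, trca_score, tstrca_scores

__all__ = [
    "EvalConfig",
    "EvalResult",
    "METHOD_TAGS",
    "loocv",
    "itr",
    "prf_metrics",
    "sweep",
    "scramble_labels",
]

METHOD_TAGS = ("cca", "extcca", "trca", "tstrca", "fbtrca", "fbtstrca")
_FB_TAGS = ("fbtrca", "fbtstrca")


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation protocol parameters.

    ``tw_s`` is the analysis window used by :func:`loocv`; ``tw_grid_s``
    is the grid swept by :func:`sweep`.  ``gaze_shift_s`` is added to the
    window length when converting accuracy to ITR.
    """

    tw_s: float = 0.5
    tw_grid_s: tuple = tuple(round(0.2 + 0.1 * k, 1) for k in range(9))
    latency_s: float = DEFAULT_LATENCY_S
    gaze_shift_s: float = 0.5
    band: tuple = (7.0, 90.0)
    n_harmonics: int = 5
    channel_subset: Optional[tuple] = None
    apply_bandpass: bool = True
    trca_ensemble: bool = False
    fb: FilterBankSpec = field(default_factory=FilterBankSpec)
    seed: int = 0

    def __post_init__(self):
        if any(t <= 0 for t in (self.tw_s, *self.tw_grid_s)):
            raise ValueError("time windows must be positive")
        if self.gaze_shift_s < 0:
            raise ValueError("gaze_shift_s must be >= 0")


@dataclass(frozen=True)
class EvalResult:
    """Outcome of one leave-one-block-out run."""

    confusion: np.ndarray          # Nf x Nf counts, rows = true class
    accuracy: float
    itr_bits_per_min: float
    per_fold_accuracy: np.ndarray  # Nt values
    precision: float
    recall: float
    f1: float

    def __post_init__(self):
        conf = np.asarray(self.confusion)
        if conf.sum() == 0:
            raise ValueError("empty confusion matrix")
        expected = conf.trace() / conf.sum()
        if abs(expected - self.accuracy) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion matrix")


def itr(P: float, n_targets: int, T_s: float) -> float:
    """Information transfer rate in bits per minute.

    ``T_s`` is the full selection time in seconds, including gaze shift.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1]; got {P}")
    if n_targets < 2:
        raise ValueError("ITR needs at least 2 targets")
    if T_s <= 0:
        raise ValueError("selection time must be positive")
    bits = np.log2(n_targets)
    if P > 0.0:
        bits += P * np.log2(P)
    if P < 1.0:
        bits += (1.0 - P) * np.log2((1.0 - P) / (n_targets - 1))
    return float(bits * 60.0 / T_s)


def prf_metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """Macro-averaged precision, recall and F1 from a count confusion matrix.

    Per-class ratios with a zero denominator are defined as 0.  Macro
    averaging weights classes equally, appropriate for the balanced
    block design.
    """
    conf = np.asarray(confusion, dtype=np.float64)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(conf < 0):
        raise ValueError("negative counts")
    if conf.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    tp = np.diag(conf)
    pred = conf.sum(axis=0)
    true = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return float(precision.mean()), float(recall.mean()), float(f1.mean())


def _make_scorer(method_tag: str, train: EpochSet, cfg: EvalConfig):
    """Fit one band's model and return a trial -> ScoreVector callable."""
    if method_tag == "cca":
        refs = [
            make_reference(f, cfg.n_harmonics, train.n_samples, train.fs)
            for f in train.stim_freqs
        ]
        return lambda x: cca_scores(x, refs)
    if method_tag == "extcca":
        refs = [
            make_reference(f, cfg.n_harmonics, train.n_samples, train.fs)
            for f in train.stim_freqs
        ]
        templates = build_templates(train)
        return lambda x: extcca_scores(x, templates, refs)
    if method_tag == "trca":
        bank, templates = fit_trca(train)
        return lambda x: trca_score(x, bank, templates, ensemble=cfg.trca_ensemble)
    if method_tag == "tstrca":
        bank, templates = fit_trca(train)
        return lambda x: tstrca_scores(x, bank, templates)
    raise ValueError(f"unknown method tag {method_tag!r}; valid tags: {METHOD_TAGS}")


def _windowed_bands(epochs: EpochSet, method_tag: str, cfg: EvalConfig) -> list[EpochSet]:
    """Full preprocessing for one method: channels, filtering, windowing."""
    if cfg.channel_subset is not None:
        epochs = select_channels(epochs, cfg.channel_subset)
    if method_tag in _FB_TAGS:
        bands = decompose(epochs, cfg.fb)
    elif cfg.apply_bandpass:
        bands = [bandpass(epochs, IIRSpec(low_hz=cfg.band[0], high_hz=cfg.band[1]))]
    else:
        bands = [epochs]
    win = WindowSpec(latency_s=cfg.latency_s, tw_s=cfg.tw_s)
    return [extract_window(b, win) for b in bands]


def _drop_trial(epochs: EpochSet, t: int) -> EpochSet:
    keep = [k for k in range(epochs.n_trials) if k != t]
    return epochs.with_data(epochs.data[:, keep])


def loocv(epochs: EpochSet, method_tag: str, cfg: EvalConfig = EvalConfig()) -> EvalResult:
    """Leave-one-block-out evaluation of one method on one subject.

    ``epochs`` are raw (unfiltered) full-length epochs; the configured
    band-pass (or sub-band decomposition), channel subset and analysis
    window are applied here so that training and test always see the same
    preprocessing.  Deterministic given data and config.
    """
    if method_tag not in METHOD_TAGS:
        raise ValueError(f"unknown method tag {method_tag!r}; valid tags: {METHOD_TAGS}")
    if epochs.n_trials < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")
    base_tag = {"fbtrca": "trca", "fbtstrca": "tstrca"}.get(method_tag, method_tag)
    bands = _windowed_bands(epochs, method_tag, cfg)
    nf, nt = epochs.n_classes, epochs.n_trials
    confusion = np.zeros((nf, nf), dtype=np.int64)
    per_fold = np.empty(nt)
    for t in range(nt):
        scorers = [_make_scorer(base_tag, _drop_trial(b, t), cfg) for b in bands]
        correct = 0
        for i in range(nf):
            if len(bands) == 1:
                scores = scorers[0](bands[0].data[i, t])
            else:
                per_band = np.vstack([
                    scorers[b](bands[b].data[i, t]).scores for b in range(len(bands))
                ])
                scores = fb_combine(SubbandScores(per_band=per_band), cfg.fb)
            pred = classify(scores)
            confusion[i, pred] += 1
            correct += int(pred == i)
        per_fold[t] = correct / nf
    accuracy = float(per_fold.mean())
    T_s = cfg.tw_s + cfg.gaze_shift_s
    fold_itrs = [itr(p, nf, T_s) for p in per_fold] if nf >= 2 else [0.0] * nt
    precision, recall, f1 = prf_metrics(confusion)
    return EvalResult(
        confusion=confusion,
        accuracy=accuracy,
        itr_bits_per_min=float(np.mean(fold_itrs)),
        per_fold_accuracy=per_fold,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def scramble_labels(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Randomly permute the class assignment within each block.

    Destroys the label/content association while preserving the balanced
    block structure, for chance-level checks.
    """
    rng = np.random.default_rng(seed)
    data = epochs.data.copy()
    for t in range(epochs.n_trials):
        data[:, t] = data[rng.permutation(epochs.n_classes), t]
    return epochs.with_data(data, log_entry=f"scramble_labels(seed={seed})")


def sweep(subjects, methods, cfg: EvalConfig = EvalConfig(), out_csv=None) -> pd.DataFrame:
    """Evaluate a method x time-window grid over one or more subjects.

    Returns a long-format table with one row per (subject, method, tw):
    columns ``subject, method, tw, n_channels, accuracy, itr, precision,
    recall, f1``.  Written as comma-separated UTF-8 text when ``out_csv``
    is given.
    """
    if isinstance(subjects, EpochSet):
        subjects = [subjects]
    rows = []
    from dataclasses import replace as _replace
    for s, epochs in enumerate(subjects):
        n_channels = (
            len(cfg.channel_subset) if cfg.channel_subset is not None else epochs.n_channels
        )
        for method in methods:
            for tw in cfg.tw_grid_s:
                res = loocv(epochs, method, _replace(cfg, tw_s=tw))
                rows.append({
                    "subject": s,
                    "method": method,
                    "tw": tw,
                    "n_channels": n_channels,
                    "accuracy": res.accuracy,
                    "itr": res.itr_bits_per_min,
                    "precision": res.precision,
                    "recall": res.recall,
                    "f1": res.f1,
                })
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
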