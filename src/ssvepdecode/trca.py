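"""Task-related component analysis and its two-step ensemble extension.

TRCA learns, per stimulus frequency, the channel weight vector ``w`` whose
projection is maximally reproducible across training trials: with ``S`` the
summed inter-trial cross-covariance and ``Q`` the covariance of the
concatenated (per-trial centered) trials, ``w`` is the leading eigenvector
of the generalized problem ``S w = lambda Q w``.  Standard TRCA scoring
correlates the test trial and the class template through that class's own
filter only.

The two-step variant reuses the whole filter set as an ensemble: for each
candidate class ``i`` the template/test pair is passed through *every*
class's filter (plus one unfiltered correlation), giving a vector
``beta_i = (beta_{i,0}, beta_{i,1}, ..., beta_{i,Nf})`` that is fused by
the signed-square sum.  Averaging over all the (independently estimated,
near-collinear) filters is what buys robustness at short time windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .cca import ScoreVector, TemplateBank, build_templates, classify, pearson, signed_square_fuse
from .io import EpochSet

__all__ = [
    "TRCAMatrices",
    "SpatialFilterBank",
    "trca_matrices",
    "trca_filter",
    "fit_trca",
    "trca_score",
    "tstrca_beta",
    "tstrca_score",
    "tstrca_scores",
    "tstrca_classify",
    "save_model",
    "load_model",
    "TRCA_RIDGE",
]

TRCA_RIDGE = 1e-8


@dataclass(frozen=True)
class TRCAMatrices:
    """The pair (S, Q) defining one class's generalized eigenproblem.

    ``S`` sums the inter-trial cross-covariances over all ordered trial
    pairs; ``Q`` is the channel covariance of the horizontally concatenated
    per-trial-centered trials.  Both are symmetric; Q is PSD.
    """

    S: np.ndarray
    Q: np.ndarray


@dataclass(frozen=True)
class SpatialFilterBank:
    """Per-frequency TRCA weight vectors (unit norm, canonical sign)."""

    filters: tuple          # Nf vectors of length Nc
    eigenvalues: np.ndarray  # Nf leading generalized eigenvalues

    def __len__(self) -> int:
        return len(self.filters)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.filters[i]

    def as_matrix(self) -> np.ndarray:
        """Stack filters into an Nf x Nc matrix (ensemble projections)."""
        return np.vstack(self.filters)


def trca_matrices(trials) -> TRCAMatrices:
    """Build (S, Q) from >= 2 equally-shaped channels-x-samples trials.

    Covariances divide by the number of samples (population normalizer);
    rankings are invariant to the choice and a fixed convention keeps runs
    bit-reproducible.  Per-trial means are removed before both S and Q so
    inter-trial offsets cannot masquerade as reproducible signal.
    """
    trials = [np.asarray(t, dtype=np.float64) for t in trials]
    if len(trials) < 2:
        raise ValueError("inter-trial covariance needs at least 2 trials")
    shape = trials[0].shape
    if any(t.shape != shape for t in trials):
        raise ValueError("all trials must share the same (channels, samples) shape")
    ns = shape[1]
    centered = [t - t.mean(axis=1, keepdims=True) for t in trials]
    total = np.sum(centered, axis=0)
    # sum over ordered pairs t1 != t2 of X_t1 X_t2' / Ns
    S = (total @ total.T - sum(t @ t.T for t in centered)) / ns
    concat = np.hstack(centered)
    concat = concat - concat.mean(axis=1, keepdims=True)
    Q = concat @ concat.T / concat.shape[1]
    S = (S + S.T) / 2.0
    Q = (Q + Q.T) / 2.0
    return TRCAMatrices(S=S, Q=Q)


def _lead_eigenpair(S: np.ndarray, Q: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    nc = S.shape[0]
    Qr = Q + (ridge * np.trace(Q) / nc + np.finfo(float).tiny) * np.eye(nc)
    try:
        vals, vecs = linalg.eigh(S, Qr)
    except linalg.LinAlgError as e:  # pragma: no cover - ridge repair failed
        raise np.linalg.LinAlgError(f"Q singular beyond ridge repair: {e}") from e
    w = vecs[:, -1]
    w = w / np.linalg.norm(w)
    i = int(np.argmax(np.abs(w)))
    if w[i] < 0:
        w = -w
    return w, float(vals[-1])


def trca_filter(trials, ridge: float = TRCA_RIDGE) -> tuple[np.ndarray, float]:
    """Leading generalized eigenvector of (S, Q) for one class.

    Returns the unit-norm, sign-canonicalized weight vector and its
    eigenvalue (the Rayleigh quotient ``w'Sw / w'Qw`` at the optimum).
    """
    m = trca_matrices(trials)
    return _lead_eigenpair(m.S, m.Q, ridge)


def fit_trca(train: EpochSet, ridge: float = TRCA_RIDGE) -> tuple[SpatialFilterBank, TemplateBank]:
    """Learn one spatial filter and one template per stimulus frequency."""
    if train.n_trials < 2:
        raise ValueError(
            f"TRCA needs >= 2 training trials per class; got {train.n_trials}"
        )
    filters, eigvals = [], []
    for i in range(train.n_classes):
        w, lam = trca_filter(list(train.data[i]), ridge=ridge)
        filters.append(w)
        eigvals.append(lam)
    bank = SpatialFilterBank(filters=tuple(filters), eigenvalues=np.array(eigvals))
    return bank, build_templates(train)


def trca_score(
    test: np.ndarray,
    bank: SpatialFilterBank,
    templates: TemplateBank,
    ensemble: bool = False,
) -> ScoreVector:
    """Standard TRCA decision scores.

    ``scores[i]`` is the Pearson correlation of the test trial and template
    ``i`` projected through class ``i``'s filter alone.  With
    ``ensemble=True`` the full filter matrix projects both operands and the
    multichannel correlation is taken instead (the ensemble-TRCA variant).
    """
    test = np.asarray(test, dtype=np.float64)
    if len(bank) != len(templates):
        raise ValueError("filter bank and template bank disagree on class count")
    if ensemble:
        W = bank.as_matrix()
        scores = [pearson(W @ test, W @ templates[i]) for i in range(len(templates))]
    else:
        scores = [pearson(bank[i] @ test, bank[i] @ templates[i]) for i in range(len(templates))]
    return ScoreVector(scores=np.array(scores), method_tag="trca")


def tstrca_beta(test: np.ndarray, template_i: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Correlation vector of one candidate template against the test trial.

    ``beta[0]`` correlates the raw matrices (no spatial filter); ``beta[k]``
    for ``k = 1..Nf`` correlates the 1-D projections of the *same* pair
    through class ``k``'s filter.  Entries lie in [-1, 1].
    """
    test = np.asarray(test, dtype=np.float64)
    template_i = np.asarray(template_i, dtype=np.float64)
    if test.shape != template_i.shape:
        raise ValueError(f"shape mismatch: test {test.shape} vs template {template_i.shape}")
    beta = np.empty(len(bank) + 1)
    beta[0] = pearson(template_i, test)
    for k in range(len(bank)):
        beta[k + 1] = pearson(bank[k] @ template_i, bank[k] @ test)
    return beta


def tstrca_score(beta: np.ndarray) -> float:
    """Ensemble score ``sum_k sign(beta_k) * beta_k**2`` of one candidate."""
    return signed_square_fuse(beta)


def tstrca_scores(test: np.ndarray, bank: SpatialFilterBank, templates: TemplateBank) -> ScoreVector:
    """Two-step TRCA decision scores for every candidate class."""
    scores = np.array([
        tstrca_score(tstrca_beta(test, templates[i], bank)) for i in range(len(templates))
    ])
    return ScoreVector(scores=scores, method_tag="tstrca")


def tstrca_classify(test: np.ndarray, bank: SpatialFilterBank, templates: TemplateBank) -> int:
    """Predicted class: argmax of the two-step ensemble scores."""
    return classify(tstrca_scores(test, bank, templates))


def save_model(path, bank: SpatialFilterBank, templates: TemplateBank, fs: float,
               stim_freqs) -> str:
    """Serialize fitted filters and templates to an HDF5 container."""
    import h5py
    import os
    path = os.fspath(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=bank.as_matrix(), track_times=False)
        f.create_dataset("eigenvalues", data=bank.eigenvalues, track_times=False)
        f.create_dataset("templates", data=np.stack(templates.templates), track_times=False)
        f.attrs["fs"] = float(fs)
        f.attrs["stim_freqs"] = np.asarray(stim_freqs, dtype=np.float64)
        f.attrs["n_train_trials"] = int(templates.n_train_trials)
    return path


def load_model(path):
    """Load a model written by :func:`save_model`.

    Returns ``(bank, templates, fs, stim_freqs)``.
    """
    import h5py
    with h5py.File(path, "r") as f:
        filters = np.asarray(f["filters"])
        eigvals = np.asarray(f["eigenvalues"])
        temps = np.asarray(f["templates"])
        fs = float(f.attrs["fs"])
        stim_freqs = np.asarray(f.attrs["stim_freqs"])
        n_train = int(f.attrs["n_train_trials"])
    bank = SpatialFilterBank(filters=tuple(filters), eigenvalues=eigvals)
    templates = TemplateBank(templates=tuple(temps), n_train_trials=n_train)
    return bank, templates, fs, stim_freqs
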