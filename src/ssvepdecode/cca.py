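"""Canonical-correlation methods for SSVEP frequency recognition.

Standard CCA scores a single-trial test matrix ``X`` (channels x samples)
against per-frequency sinusoidal references ``Z_i`` (stacked sin/cos
harmonics) by the largest canonical correlation; the predicted frequency is
the argmax over classes.  Extended CCA additionally uses the subject's
individual templates ``Y_i`` (trial averages of the training data): three
CCA weight pairs — (X, Z_i), (X, Y_i), (Y_i, Z_i) — provide spatial filters
whose projected Pearson correlations form a 4-vector that is fused by the
signed-square sum ``sum_k sign(r_k) r_k^2``.

The CCA solver whitens the two auto-covariances (with a small ridge for
rank safety) and takes the leading singular pair of the whitened
cross-covariance; this is algebraically the classical generalized
eigenproblem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import EpochSet

__all__ = [
    "SinusoidalReference",
    "CCAResult",
    "TemplateBank",
    "ScoreVector",
    "make_reference",
    "canonical_correlation",
    "build_templates",
    "cca_scores",
    "extcca_correlation_vector",
    "extcca_scores",
    "signed_square_fuse",
    "pearson",
    "classify",
    "DEFAULT_N_HARMONICS",
    "DEFAULT_RIDGE",
]

logger = logging.getLogger(__name__)

DEFAULT_N_HARMONICS = 5
DEFAULT_RIDGE = 1e-8


@dataclass(frozen=True)
class SinusoidalReference:
    """Reference matrix for one stimulus frequency.

    ``matrix`` has ``2 * n_harmonics`` rows; rows alternate
    ``sin(2*pi*h*f*t)``, ``cos(2*pi*h*f*t)`` for harmonic ``h = 1..Nh``
    evaluated at ``t = n / fs`` for ``n = 1..Ns``.
    """

    matrix: np.ndarray
    f_hz: float
    n_harmonics: int
    fs: float
    n_samples: int


@dataclass(frozen=True)
class CCAResult:
    """Leading canonical correlation ``rho`` and its weight pair."""

    rho: float
    wx: np.ndarray
    wy: np.ndarray


@dataclass(frozen=True)
class TemplateBank:
    """Per-frequency individual templates (trial averages), channels x samples."""

    templates: tuple
    n_train_trials: int

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.templates[i]


@dataclass(frozen=True)
class ScoreVector:
    """Per-frequency decision scores feeding the argmax classifier."""

    scores: np.ndarray
    method_tag: str = ""

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))


def make_reference(f_hz: float, n_harmonics: int, n_samples: int, fs: float) -> SinusoidalReference:
    """Build the stacked sin/cos harmonic reference for one frequency."""
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if f_hz * n_harmonics >= fs / 2.0:
        raise ValueError(
            f"harmonic {n_harmonics} of {f_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    t = np.arange(1, n_samples + 1) / fs
    rows = []
    for h in range(1, n_harmonics + 1):
        phase = 2.0 * np.pi * h * f_hz * t
        rows.append(np.sin(phase))
        rows.append(np.cos(phase))
    return SinusoidalReference(
        matrix=np.vstack(rows), f_hz=float(f_hz), n_harmonics=int(n_harmonics),
        fs=float(fs), n_samples=int(n_samples),
    )


def _canonical_sign(w: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude entry is positive (ties: first wins)."""
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w


def _center_rows(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a - a.mean(axis=1, keepdims=True)


def _whitener(c: np.ndarray, ridge: float) -> np.ndarray:
    """Inverse principal square root of a symmetric PSD matrix, ridged."""
    d = c.shape[0]
    c = c + (ridge * np.trace(c) / d + np.finfo(float).tiny) * np.eye(d)
    vals, vecs = linalg.eigh(c)
    vals = np.maximum(vals, np.finfo(float).tiny)
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def canonical_correlation(X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> CCAResult:
    """Largest canonical correlation between row spaces of ``X`` and ``Y``.

    Rows are centered internally; the solution is the leading singular pair
    of the whitened cross-covariance.  A ridge of ``ridge * trace / dim`` on
    each auto-covariance keeps rank-deficient inputs solvable (a warning is
    emitted when it is actually doing work); pass ``ridge=0`` to get a hard
    singularity error instead.
    """
    X = _center_rows(X)
    Y = _center_rows(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"sample-count mismatch: {X.shape[1]} vs {Y.shape[1]}")
    T = X.shape[1]
    cxx = X @ X.T / T
    cyy = Y @ Y.T / T
    cxy = X @ Y.T / T
    for name, c in (("X", cxx), ("Y", cyy)):
        rank = np.linalg.matrix_rank(c)
        if rank < c.shape[0]:
            if ridge <= 0:
                raise np.linalg.LinAlgError(
                    f"{name} auto-covariance is rank deficient ({rank}/{c.shape[0]}) "
                    "and regularization is disabled"
                )
            warnings.warn(
                f"{name} auto-covariance rank deficient ({rank}/{c.shape[0]}); ridge applied",
                RuntimeWarning, stacklevel=2,
            )
    wxh = _whitener(cxx, ridge)
    wyh = _whitener(cyy, ridge)
    u, s, vt = np.linalg.svd(wxh @ cxy @ wyh)
    wx = _canonical_sign(wxh @ u[:, 0])
    wy = _canonical_sign(wyh @ vt[0, :])
    rho = float(min(s[0], 1.0 + 1e-9))
    return CCAResult(rho=rho, wx=wx, wy=wy)


def build_templates(train: EpochSet) -> TemplateBank:
    """Average training trials per class into individual templates ``Y_i``."""
    if train.n_trials < 1:
        raise ValueError("at least one training trial per class is required")
    templates = tuple(train.data[i].mean(axis=0) for i in range(train.n_classes))
    return TemplateBank(templates=templates, n_train_trials=train.n_trials)


def cca_scores(test: np.ndarray, refs, ridge: float = DEFAULT_RIDGE) -> ScoreVector:
    """Score a test trial against each reference by canonical correlation.

    ``refs`` may be a list of :class:`SinusoidalReference`, a
    :class:`TemplateBank`, or a list of plain arrays.
    """
    mats = [r.matrix if isinstance(r, SinusoidalReference) else np.asarray(r) for r in refs]
    scores = np.array([canonical_correlation(test, m, ridge=ridge).rho for m in mats])
    return ScoreVector(scores=scores, method_tag="cca")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally-shaped arrays.

    Multichannel matrices are vectorized in row-major order after mean
    removal; this single definition backs every projected-pair and
    template/test correlation in the package.  A zero-variance operand
    yields 0 with a warning rather than NaN.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("zero-variance operand in correlation; returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def extcca_correlation_vector(
    test: np.ndarray,
    template: np.ndarray,
    reference: SinusoidalReference | np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    use_template_terms: bool = True,
) -> np.ndarray:
    """The 4-vector of projected correlations behind extended CCA.

    With ``w_{A,B}`` the A-side CCA weight of the pair ``(A, B)``:

    - ``r1 = rho(w_{XZ}' X, v_{XZ}' Z)`` — the plain canonical correlation,
    - ``r2 = rho(w_{XY}' X, w_{XY}' Y)``,
    - ``r3 = rho(w_{XZ}' X, w_{XZ}' Y)``,
    - ``r4 = rho(w_{YZ}' X, w_{YZ}' Y)``.

    ``use_template_terms=False`` zeroes r2-r4, reducing the method to
    standard CCA ranking by r1.
    """
    Z = reference.matrix if isinstance(reference, SinusoidalReference) else np.asarray(reference)
    Y = np.asarray(template, dtype=np.float64)
    X = np.asarray(test, dtype=np.float64)
    xz = canonical_correlation(X, Z, ridge=ridge)
    r1 = xz.rho
    if not use_template_terms:
        return np.array([r1, 0.0, 0.0, 0.0])
    xy = canonical_correlation(X, Y, ridge=ridge)
    yz = canonical_correlation(Y, Z, ridge=ridge)
    r2 = pearson(xy.wx @ X, xy.wx @ Y)
    r3 = pearson(xz.wx @ X, xz.wx @ Y)
    r4 = pearson(yz.wx @ X, yz.wx @ Y)
    return np.array([r1, r2, r3, r4])


def signed_square_fuse(values) -> float:
    """Fuse correlations as ``sum_k sign(v_k) * v_k**2``.

    Squaring emphasizes strong correlations; the sign keeps discriminative
    information carried by negative entries.  Shared by extended CCA and
    the two-step TRCA ensemble score.
    """
    v = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite entry in correlation vector")
    return float(np.sum(np.sign(v) * v * v))


def extcca_scores(
    test: np.ndarray,
    templates: TemplateBank,
    refs,
    ridge: float = DEFAULT_RIDGE,
    use_template_terms: bool = True,
) -> ScoreVector:
    """Extended-CCA decision scores: fused 4-vector per candidate class."""
    if len(refs) != len(templates):
        raise ValueError(f"reference count {len(refs)} != template count {len(templates)}")
    scores = np.array([
        signed_square_fuse(
            extcca_correlation_vector(test, templates[i], refs[i], ridge=ridge,
                                      use_template_terms=use_template_terms)
        )
        for i in range(len(templates))
    ])
    return ScoreVector(scores=scores, method_tag="extcca")


def classify(scores: ScoreVector | np.ndarray) -> int:
    """Index of the maximum score; ties break to the lowest index (logged)."""
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite score")
    winner = int(np.argmax(s))
    if np.sum(s == s[winner]) > 1:
        logger.info("tie among classes %s; choosing lowest index %d",
                    np.flatnonzero(s == s[winner]).tolist(), winner)
    return winner
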