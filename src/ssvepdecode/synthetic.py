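"""Synthetic SSVEP generator.

Emulates the structure that template- and reproducibility-based recognizers
exploit in real recordings.  Each stimulus class drives a harmonic series
``sum_h decay**(h-1) * sin(2*pi*h*f_i*t + phi_i)`` whose phase ``phi_i`` is
drawn once per (subject, class) and frozen across trials — the time-locking
that makes individual templates and inter-trial covariance informative.
The source is projected into the channels by a fixed random unit mixing
vector per subject.

The background is the sum of two noise processes, neither phase-locked to
the stimulus:

* broadband noise (white or 1/f "pink", the realistic EEG spectrum),
  independent across trials and channels;
* a spontaneous alpha rhythm: narrow-band noise centered at a
  subject-specific peak (drawn from ``alpha_band``), projected through its
  own fixed topography.  Alpha sits inside the 8-15.8 Hz stimulation range
  and is the classic confound of sinusoid-referenced CCA decoding; spatial
  filters can suppress it because its topography differs from the
  stimulus-driven one.

The signal-to-noise ratio is prescribed at the sensor level *on the
analysis band* (7-90 Hz by default): the noise mixture is scaled so that
in-band signal power over in-band noise power equals ``snr_db`` exactly.
``snr_db=inf`` gives the noiseless limit.

What this deliberately does not model: nonstationarity, eye blinks,
electrode drift, per-class topography differences.  An optional per-trial
phase jitter stresses the time-locking assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import EpochSet

__all__ = ["SimConfig", "simulate_subject", "simulate_cohort", "DEFAULT_CHANNELS"]

# the 9 occipito-parietal channels conventionally used for SSVEP decoding
DEFAULT_CHANNELS = ("Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2")


def _default_freqs() -> tuple:
    return tuple(8.0 + 0.2 * k for k in range(8))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording session.

    Defaults mirror a small speller block structure: 8 target frequencies
    on the 8.0-9.4 Hz grid, 9 occipito-parietal channels, 6 repeated
    blocks, 250 Hz sampling, and epochs long enough to carry the 0.64 s
    visual latency plus a 1.5 s analysis span.
    """

    freqs_hz: tuple = field(default_factory=_default_freqs)
    n_trials: int = 6
    n_channels: int = 9
    fs: float = 250.0
    duration_s: float = 2.14          # 0.64 s latency padding + 1.5 s window span
    n_harmonics: int = 3
    harmonic_decay: float = 0.5       # amplitude ratio between successive harmonics
    snr_db: float = -10.0             # in-band signal power / noise power at the sensors
    snr_band: tuple = (7.0, 90.0)     # band the SNR is defined on
    noise_spectrum: str = "pink"      # broadband part: "white" | "pink"
    alpha_frac: float = 0.5           # fraction of in-band noise power from the alpha rhythm
    alpha_band: tuple = (9.0, 11.0)   # subject alpha peak drawn uniformly from this range
    alpha_bw_hz: float = 2.0          # spectral width of the alpha rhythm
    phase_jitter_sd: float = 0.0      # per-trial phase noise in radians
    mixing_seed: int = 0
    noise_seed: int = 1

    @property
    def n_classes(self) -> int:
        return len(self.freqs_hz)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ValueError("at least one stimulus frequency required")
        fmax = max(self.freqs_hz) * self.n_harmonics
        if fmax >= self.fs / 2.0:
            raise ValueError(
                f"harmonic {self.n_harmonics} of {max(self.freqs_hz)} Hz "
                f"({fmax} Hz) is at or above Nyquist ({self.fs / 2} Hz)"
            )
        if np.isnan(self.snr_db) or self.snr_db == -np.inf:
            raise ValueError("snr_db must be a number or +inf (noiseless)")
        if self.noise_spectrum not in ("white", "pink"):
            raise ValueError(f"unknown noise_spectrum {self.noise_spectrum!r}")
        if not 0.0 <= self.alpha_frac <= 1.0:
            raise ValueError("alpha_frac must be in [0, 1]")


def _pink_noise(rng: np.random.Generator, shape) -> np.ndarray:
    """1/f-power noise via spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    return out / out.std(axis=-1, keepdims=True)


def _narrowband_noise(rng: np.random.Generator, shape, fs: float, f0: float,
                      bw: float) -> np.ndarray:
    """Gaussian-envelope narrow-band noise centered at ``f0``, unit variance."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1], 1.0 / fs)
    mask = np.exp(-0.5 * ((f - f0) / (bw / 2.0)) ** 2)
    out = np.fft.irfft(spec * mask, n=shape[-1], axis=-1)
    return out / out.std(axis=-1, keepdims=True)


def _band_power(x: np.ndarray, fs: float, band) -> float:
    """Mean per-epoch spectral power inside ``band`` (Hz), via the rFFT."""
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(x.shape[-1], 1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.mean(np.sum(np.abs(spec[..., mask]) ** 2, axis=-1)))


def simulate_subject(cfg: SimConfig, return_parts: bool = False):
    """Generate one subject's :class:`EpochSet`; reproducible from seeds.

    With ``return_parts=True`` also returns the noise-free sensor signal
    and the scaled noise, each shaped like the data, so the realized SNR
    can be audited from the parts.
    """
    cfg.validate()
    mix_rng = np.random.default_rng(cfg.mixing_seed)
    noise_rng = np.random.default_rng(cfg.noise_seed)
    nf, nt, nc, ns = cfg.n_classes, cfg.n_trials, cfg.n_channels, cfg.n_samples

    # subject-level draws, in a fixed order for reproducibility
    mixing = mix_rng.standard_normal(nc)
    mixing /= np.linalg.norm(mixing)
    phases = mix_rng.uniform(0.0, 2.0 * np.pi, size=nf)
    alpha_hz = mix_rng.uniform(*cfg.alpha_band)
    alpha_topo = mix_rng.standard_normal(nc)
    alpha_topo /= np.linalg.norm(alpha_topo)

    t = np.arange(ns) / cfg.fs
    signal = np.empty((nf, nt, nc, ns))
    for i, f in enumerate(cfg.freqs_hz):
        for trial in range(nt):
            phi = phases[i]
            if cfg.phase_jitter_sd > 0.0:
                phi = phi + noise_rng.normal(0.0, cfg.phase_jitter_sd)
            src = np.zeros(ns)
            for h in range(1, cfg.n_harmonics + 1):
                src += cfg.harmonic_decay ** (h - 1) * np.sin(2.0 * np.pi * h * f * t + phi)
            signal[i, trial] = np.outer(mixing, src)

    if cfg.noise_spectrum == "pink":
        broad = _pink_noise(noise_rng, (nf, nt, nc, ns))
    else:
        broad = noise_rng.standard_normal((nf, nt, nc, ns))
    alpha = np.einsum(
        "c,fts->ftcs", alpha_topo,
        _narrowband_noise(noise_rng, (nf, nt, ns), cfg.fs, alpha_hz, cfg.alpha_bw_hz),
    )

    # scale the two noise processes so total in-band noise power hits the SNR
    sig_pow = _band_power(signal, cfg.fs, cfg.snr_band)
    target_noise_pow = sig_pow / 10.0 ** (cfg.snr_db / 10.0)  # 0 when snr_db = inf
    broad_pow = _band_power(broad, cfg.fs, cfg.snr_band)
    alpha_pow = _band_power(alpha, cfg.fs, cfg.snr_band)
    noise = broad * np.sqrt((1.0 - cfg.alpha_frac) * target_noise_pow / broad_pow)
    if cfg.alpha_frac > 0.0:
        noise = noise + alpha * np.sqrt(cfg.alpha_frac * target_noise_pow / alpha_pow)

    epochs = EpochSet(
        data=signal + noise,
        fs=cfg.fs,
        channel_labels=(
            DEFAULT_CHANNELS if nc == len(DEFAULT_CHANNELS)
            else tuple(f"CH{c + 1}" for c in range(nc))
        ),
        stim_freqs=np.asarray(cfg.freqs_hz, dtype=np.float64),
        t0=0.0,
        preprocessing_log=[
            f"simulate_subject(snr_db={cfg.snr_db}, noise={cfg.noise_spectrum}, "
            f"alpha_frac={cfg.alpha_frac}, mixing_seed={cfg.mixing_seed}, "
            f"noise_seed={cfg.noise_seed})"
        ],
    )
    if return_parts:
        return epochs, signal, noise
    return epochs


def simulate_cohort(cfg: SimConfig, n_subjects: int, base_seed: int = 0) -> list[EpochSet]:
    """Independent subjects (mixing and noise) with seeds derived from ``base_seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_subjects)
    cohort = []
    for s in range(n_subjects):
        sub_cfg = replace(
            cfg,
            mixing_seed=int(seeds[2 * s] % (2 ** 31)),
            noise_seed=int(seeds[2 * s + 1] % (2 ** 31)),
        )
        cohort.append(simulate_subject(sub_cfg))
    return cohort
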