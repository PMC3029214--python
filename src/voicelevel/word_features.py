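"""Word-level nonlinear-dynamics and wavelet features.

These are computed once per (trimmed) utterance rather than per frame:
Higuchi fractal dimension, largest Lyapunov exponent of the reconstructed
phase space, and the mean squared continuous-wavelet coefficient at three
dyadic scales of an order-5 Gaussian-derivative mother wavelet.  Together
they form the 5-dimensional input of the word-feature neural classifier.

The dynamical features capture a clinical observation: milder voice
disorder goes with a more stretched, higher-dimensional phase-space
attractor — a more flexible phonatory system — while severe disorder
produces raw, low-complexity phonation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "WORD_FEATURE_NAMES",
    "PhaseSpace",
    "WaveletConfig",
    "reconstruct_phase_space",
    "higuchi_fd",
    "largest_lyapunov",
    "wavelet_energy",
    "gaussian_wavelet",
    "extract_word_features",
]

WORD_FEATURE_NAMES = (
    "fractal_dim",
    "lyapunov",
    "wavelet_energy_s7",
    "wavelet_energy_s8",
    "wavelet_energy_s9",
)


@dataclass(frozen=True)
class PhaseSpace:
    """Delay embedding of a scalar series: point i = (x_i, x_{i+tau}, ...)."""

    points: np.ndarray  # (n_points, dimension)
    delay: int
    dimension: int


def reconstruct_phase_space(x: np.ndarray, delay: int, dimension: int) -> PhaseSpace:
    """Time-delay embedding with ``len(x) - (dimension-1)*delay`` points."""
    x = np.asarray(x, dtype=np.float64)
    if delay < 1 or dimension < 2:
        raise ValueError("delay >= 1 and dimension >= 2 required")
    n_points = x.size - (dimension - 1) * delay
    if n_points < 1:
        raise ValueError(
            f"series of {x.size} samples too short for m={dimension}, tau={delay}"
        )
    cols = [x[i * delay : i * delay + n_points] for i in range(dimension)]
    return PhaseSpace(points=np.column_stack(cols), delay=delay, dimension=dimension)


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a scalar series.

    For each lag k the mean normalized length L(k) of the k subsampled
    curves scales as ``k**(-D)``; D is minus the slope of the least-squares
    fit of log L(k) on log k.  D = 1 for a smooth curve, 2 for a
    plane-filling (white-noise-like) one.
    """
    x = np.asarray(x, dtype=np.float64)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    n = x.size
    if n < 2 * kmax:
        raise ValueError(f"need at least 2*kmax={2 * kmax} samples, got {n}")
    log_k = np.empty(kmax)
    log_l = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        log_k[k - 1] = np.log(1.0 / k)
        mean_len = np.mean(lengths)
        log_l[k - 1] = np.log(mean_len) if mean_len > 0 else -np.inf
    if not np.all(np.isfinite(log_l)):
        return 1.0  # constant signal: zero-length curve, smooth by convention
    slope = np.polyfit(log_k, log_l, 1)[0]
    return float(slope)


def _embedding_delay(x: np.ndarray, max_lag: int) -> int:
    """Delay from the ACF: first zero crossing, else first minimum, else 1.

    The zero crossing (a quarter period for oscillatory signals) is
    preferred over the first minimum: for near-periodic signals the first
    ACF minimum sits at the half period, where the antiphase coordinates
    make the embedding collapse onto a line.
    """
    x = x - x.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    for lag in range(1, max_lag):
        if ac[lag] <= 0.0:
            return lag
        if ac[lag] < ac[lag - 1] and ac[lag] <= ac[lag + 1]:
            return lag
    return 1


def _mean_period(x: np.ndarray) -> float:
    """Reciprocal of the power-weighted mean frequency (samples)."""
    x = x - x.mean()
    freqs = np.fft.rfftfreq(x.size)
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0
    total = power.sum()
    if total <= 0:
        return 1.0
    mean_freq = (freqs * power).sum() / total
    return 1.0 / mean_freq if mean_freq > 0 else float(x.size)


def largest_lyapunov(
    x: np.ndarray,
    delay: int | None = None,
    dimension: int = 5,
    fit_range: int = 10,
    max_points: int = 2000,
) -> float:
    """Largest Lyapunov exponent (1/sample) by the Rosenstein small-data method.

    Each embedded point is paired with its nearest neighbour outside a
    Theiler window of one mean period; the slope of the mean log divergence
    over the first ``fit_range`` steps estimates the exponent.  Positive
    means chaotic (exponential separation), negative means converging
    trajectories, near zero means (a)periodic.

    Long series are strided down to at most ``max_points`` embedded points;
    the exponent is rescaled to per-sample units of the original series.
    """
    x = np.asarray(x, dtype=np.float64)
    if delay is None:
        delay = _embedding_delay(x, max_lag=min(x.size // 4, 500))
    ps = reconstruct_phase_space(x, delay=delay, dimension=dimension)
    pts = ps.points
    stride = max(1, int(np.ceil(pts.shape[0] / max_points)))
    pts = pts[::stride]
    n = pts.shape[0]
    if n < 100:
        raise ValueError(f"too few embedded points for neighbour search ({n})")

    theiler = max(1, int(np.ceil(_mean_period(x) / stride)))
    horizon = fit_range + 1
    n_usable = n - horizon
    if n_usable <= theiler + 1:
        raise ValueError("series too short for the requested fit range")

    # pairwise distances with the Theiler band masked out
    from scipy.spatial.distance import cdist

    d2 = cdist(pts[:n_usable], pts[:n_usable], metric="sqeuclidean")
    i_idx = np.arange(n_usable)
    band = np.abs(i_idx[:, None] - i_idx[None, :]) <= theiler
    d2[band] = np.inf
    nn = np.argmin(d2, axis=1)

    log_div = np.zeros(horizon)
    counts = np.zeros(horizon)
    for step in range(horizon):
        d = np.linalg.norm(pts[i_idx + step] - pts[nn + step], axis=1)
        ok = d > 0
        log_div[step] = np.log(d[ok]).mean() if ok.any() else -np.inf
        counts[step] = ok.sum()
    steps = np.arange(horizon)
    ok = np.isfinite(log_div) & (counts > 0)
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(steps[ok], log_div[ok], 1)[0]
    return float(slope / stride)


@dataclass(frozen=True)
class WaveletConfig:
    """Continuous-wavelet settings: order-N Gaussian-derivative mother,
    dyadic scales ``a0**j``, translation step ``b0`` on the scaled grid."""

    order: int = 5
    scales: tuple[int, ...] = (7, 8, 9)
    a0: float = 2.0
    b0: float = 1.0
    support: float = 5.0  # mother wavelet truncated at |u| <= support
    samples_per_unit: int = 16  # mother sampling density in scaled time


def _gauss_derivative_poly(order: int) -> np.poly1d:
    """Polynomial P with d^n/du^n exp(-u^2) = P(u) exp(-u^2)."""
    p = np.poly1d([1.0])
    gauss_exp = np.poly1d([-2.0, 0.0])  # derivative of -u^2
    for _ in range(order):
        p = p.deriv() + p * gauss_exp
    return p


def gaussian_wavelet(order: int = 5, support: float = 5.0, n: int = 2001):
    """Sampled order-``order`` Gaussian-derivative wavelet, unit L2 norm.

    Returns ``(u, psi)`` with ``u`` spanning ``[-support, support]``.
    """
    u = np.linspace(-support, support, n)
    psi = _gauss_derivative_poly(order)(u) * np.exp(-(u**2))
    du = u[1] - u[0]
    psi = psi / np.sqrt(np.sum(psi**2) * du)
    return u, psi


def wavelet_coefficients(x: np.ndarray, j: int, cfg: WaveletConfig) -> np.ndarray:
    """Coefficients d_{j,k} = a0^{-j/2} * sum_t x[t] psi(a0^{-j} t - k b0).

    Translations k run over the scaled grid, i.e. centres every
    ``b0 * a0**j`` samples of the signal.
    """
    x = np.asarray(x, dtype=np.float64)
    scale = cfg.a0**j
    half_support = cfg.support * scale
    if x.size < 2 * half_support:
        raise ValueError(
            f"signal of {x.size} samples shorter than the scale-{j} wavelet "
            f"support ({2 * half_support:.0f})"
        )
    # psi(a0^{-j} t) sampled at integer t
    t = np.arange(-int(np.floor(half_support)), int(np.floor(half_support)) + 1)
    u, psi = gaussian_wavelet(cfg.order, cfg.support)
    psi_t = np.interp(t / scale, u, psi)
    full = sps.fftconvolve(x, psi_t[::-1], mode="valid") * scale ** (-0.5)
    step = max(1, int(round(cfg.b0 * scale)))
    return full[::step]


def wavelet_energy(x: np.ndarray, cfg: WaveletConfig | None = None) -> dict[int, float]:
    """Mean squared wavelet coefficient per scale index in ``cfg.scales``."""
    if cfg is None:
        cfg = WaveletConfig()
    return {
        j: float(np.mean(wavelet_coefficients(x, j, cfg) ** 2)) for j in cfg.scales
    }


def extract_word_features(
    waveform,
    wavelet_cfg: WaveletConfig | None = None,
    kmax: int = 8,
    lyap_dimension: int = 5,
    lyap_delay: int | None = None,
) -> dict[str, float]:
    """The 5 word-level features of one trimmed utterance.

    The signal is peak-normalized before the wavelet transform so the
    energies reflect spectral shape rather than recording gain (loudness is
    already carried by the frame-level relative intensity).
    """
    x = np.asarray(waveform.samples if hasattr(waveform, "samples") else waveform)
    peak = np.abs(x).max()
    xn = x / peak if peak > 0 else x
    energies = wavelet_energy(xn, wavelet_cfg)
    cfg = wavelet_cfg or WaveletConfig()
    feats = {
        "fractal_dim": higuchi_fd(x, kmax=kmax),
        "lyapunov": largest_lyapunov(x, delay=lyap_delay, dimension=lyap_dimension),
    }
    for j in cfg.scales:
        feats[f"wavelet_energy_s{j}"] = energies[j]
    return feats
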