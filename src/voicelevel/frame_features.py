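"""Frame-based acoustic features: f0, formants, relative intensity, nasality, ApEn.

Each 25 ms Hamming frame yields an 8-dimensional vector
``(f0, f1, f2, f3, f1/f2, RI, nasality, ApEn)`` — the observation sequence
consumed by the per-word hidden Markov models.  Unvoiced frames carry
``f0 = 0`` and are kept in the sequence.

Feature rationale, briefly: hearing-impaired children tend to speak with
elevated and unstable fundamental frequency, excess loudness, hypernasal
resonance (an extra spectral peak near 1 kHz with a valley around
700–800 Hz), and less regular phonation — ApEn quantifies the latter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

try:  # numba accelerates the O(n^2) ApEn template count
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

__all__ = [
    "FRAME_FEATURE_NAMES",
    "NasalityComponents",
    "estimate_f0",
    "estimate_formants",
    "relative_intensity",
    "nasality_score",
    "approximate_entropy",
    "extract_frame_features",
]

FRAME_FEATURE_NAMES = ("f0", "f1", "f2", "f3", "f1f2_ratio", "ri", "nasality", "apen")

#: Peak normalized autocorrelation below which a frame is declared unvoiced.
VOICING_THRESHOLD = 0.45

#: Reciprocal-nasality cap: diff_db below this is clamped so the score stays finite.
NASALITY_EPS_DB = 0.5

#: Target rate for formant analysis; LPC order 12 resolves ~5 resonances below 5 kHz.
FORMANT_ANALYSIS_RATE = 10000.0
LPC_ORDER = 12
FORMANT_MAX_BANDWIDTH_HZ = 400.0


def estimate_f0(
    frame: np.ndarray,
    sample_rate: int,
    fmin: float = 100.0,
    fmax: float = 600.0,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> float:
    """Autocorrelation pitch estimate for one frame; 0.0 means unvoiced.

    The normalized autocorrelation is searched over lags corresponding to
    ``[fmin, fmax]``; the highest peak is refined by parabolic interpolation.
    Frames whose peak falls below ``voicing_threshold`` are unvoiced.

    The frame is assumed Hamming-windowed (the pipeline's framing
    convention); dividing by the window's own autocorrelation removes the
    taper-induced bias toward shorter lags.
    """
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    if fmax >= sample_rate / 2:
        raise ValueError("fmax must be below the Nyquist frequency")
    x = np.asarray(frame, dtype=np.float64)
    x = x - x.mean()
    n = x.size
    if n < 2 or not np.any(x):
        return 0.0
    # FFT autocorrelation, biased estimator
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    if ac[0] <= 0:
        return 0.0
    ac = ac / ac[0]
    # window autocorrelation correction (Boersma): undo the taper decay
    win = np.hamming(n)
    wspec = np.fft.rfft(win, nfft)
    wac = np.fft.irfft(wspec * np.conj(wspec), nfft)[:n]
    ac = np.divide(ac, wac / wac[0], out=np.zeros_like(ac), where=wac > 1e-6 * wac[0])

    lag_min = int(np.floor(sample_rate / fmax))
    lag_max = int(np.ceil(sample_rate / fmin))
    lag_max = min(lag_max, n - 2)
    if lag_min < 2 or lag_min >= lag_max:
        return 0.0
    window = ac[lag_min : lag_max + 1]
    # octave disambiguation: a true period of T makes all multiples of T
    # near-equal peaks; a small per-octave penalty prefers the shortest lag
    lags = np.arange(lag_min, lag_max + 1)
    scores = window - 0.02 * np.log2(lags / lag_min)
    k = int(np.argmax(scores))
    peak = window[k]
    if peak < voicing_threshold:
        return 0.0
    lag = lag_min + k
    # parabolic interpolation around the integer peak
    if 0 < lag < n - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            delta = 0.5 * (y0 - y2) / denom
            lag = lag + float(np.clip(delta, -0.5, 0.5))
    return float(sample_rate / lag)


def _lpc_autocorrelation(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients [1, a1..ap] by the autocorrelation (Yule-Walker) method."""
    n = x.size
    ac = np.correlate(x, x, mode="full")[n - 1 : n + order]
    if ac[0] <= 0:
        raise np.linalg.LinAlgError("zero-energy frame")
    ac = ac / ac[0]
    a = solve_toeplitz((ac[:-1], ac[:-1]), -ac[1:])
    return np.concatenate(([1.0], a))


def estimate_formants(
    frame: np.ndarray,
    sample_rate: int,
    lpc_order: int | None = None,
    n_formants: int = 3,
    max_bandwidth_hz: float = FORMANT_MAX_BANDWIDTH_HZ,
) -> tuple[float, ...]:
    """First ``n_formants`` formant frequencies (Hz) from AR-pole analysis.

    The frame is decimated to ~10 kHz, pre-emphasized, and fit with an
    order-12 all-pole model; poles with positive imaginary part and
    bandwidth under ``max_bandwidth_hz`` give the formants, sorted ascending.
    Missing formants are returned as NaN, as is everything for degenerate
    (e.g. all-zero) frames.
    """
    x = np.asarray(frame, dtype=np.float64)
    absent = tuple([float("nan")] * n_formants)
    if x.size < 8 or not np.any(x):
        return absent

    fs = float(sample_rate)
    q = max(1, int(round(fs / FORMANT_ANALYSIS_RATE)))
    if q > 1:
        x = sps.decimate(x, q, ftype="fir", zero_phase=True)
        fs = fs / q
    if lpc_order is None:
        lpc_order = LPC_ORDER
    if lpc_order >= x.size:
        return absent

    x = np.append(x[0], x[1:] - 0.97 * x[:-1])  # pre-emphasis
    try:
        a = _lpc_autocorrelation(x, lpc_order)
    except np.linalg.LinAlgError:
        return absent
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-6]
    if roots.size == 0:
        return absent
    freqs = np.angle(roots) * fs / (2 * np.pi)
    with np.errstate(divide="ignore"):
        bandwidths = -np.log(np.abs(roots)) * fs / np.pi
    keep = (freqs > 50.0) & (freqs < fs / 2 - 50.0) & (bandwidths < max_bandwidth_hz)
    freqs = np.sort(freqs[keep])
    out = [float(f) for f in freqs[:n_formants]]
    out += [float("nan")] * (n_formants - len(out))
    return tuple(out)


def relative_intensity(frames) -> np.ndarray:
    """Per-frame RMS intensity normalized by the loudest frame of the word."""
    mat = frames.frames if hasattr(frames, "frames") else np.asarray(frames)
    rms = np.sqrt(np.mean(mat**2, axis=1))
    peak = rms.max()
    if peak <= 0:
        raise ValueError("all-zero word: relative intensity undefined")
    return rms / peak


@dataclass(frozen=True)
class NasalityComponents:
    """Spectral amplitudes entering the nasality score (dB)."""

    amp_f1_db: float
    amp_1k_db: float

    @property
    def diff_db(self) -> float:
        return self.amp_f1_db - self.amp_1k_db

    @property
    def score(self) -> float:
        return 1.0 / max(self.diff_db, NASALITY_EPS_DB)


def _smoothed_spectrum_db(frame: np.ndarray, sample_rate: int, smooth_hz: float = 60.0):
    nfft = max(2048, int(2 ** np.ceil(np.log2(frame.size))))
    mag = np.abs(np.fft.rfft(frame, nfft))
    db = 20.0 * np.log10(mag + 1e-12)
    freqs = np.fft.rfftfreq(nfft, 1.0 / sample_rate)
    width = max(1, int(round(smooth_hz / (freqs[1] - freqs[0]))))
    kernel = np.ones(width) / width
    db = np.convolve(db, kernel, mode="same")
    return freqs, db


def nasality_score(
    frame: np.ndarray,
    sample_rate: int,
    f1_hz: float,
    band_1k: tuple[float, float] = (900.0, 1100.0),
) -> NasalityComponents:
    """Hypernasality score of one frame given its first-formant frequency.

    The score is the reciprocal of the dB gap between the spectral peak at
    f1 and the strongest peak in the 900–1100 Hz band: a smaller gap (the
    nasal extra peak approaching the f1 peak) means more nasal.  The
    reciprocal is capped at ``1/NASALITY_EPS_DB`` when the gap collapses.
    """
    if not np.isfinite(f1_hz):
        raise ValueError("f1 undefined: nasality cannot be computed")
    if f1_hz >= band_1k[0]:
        raise ValueError("f1 must lie below the 1 kHz search band")
    freqs, db = _smoothed_spectrum_db(np.asarray(frame, dtype=np.float64), sample_rate)

    # spectral peak nearest f1 (local maxima of the smoothed spectrum)
    peaks, _ = sps.find_peaks(db)
    low_peaks = peaks[freqs[peaks] < band_1k[0]]
    if low_peaks.size:
        f1_idx = low_peaks[np.argmin(np.abs(freqs[low_peaks] - f1_hz))]
    else:
        f1_idx = int(np.argmin(np.abs(freqs - f1_hz)))
    amp_f1 = db[f1_idx]

    band = (freqs >= band_1k[0]) & (freqs <= band_1k[1])
    amp_1k = db[band].max()
    return NasalityComponents(amp_f1_db=float(amp_f1), amp_1k_db=float(amp_1k))


# --- Approximate entropy -------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=False)
    def _apen_phis(x, m, r):
        # Exact template counts, pruned by the first coordinate: only pairs
        # whose leading samples are within r (a necessary condition for the
        # max-norm template match) are examined, found via a sorted sliding
        # window.  O(n * k) with k the mean 1-D neighbourhood size.
        n = x.size
        nm = n - m + 1
        nm1 = n - m
        order = np.argsort(x[:nm])
        xs = x[:nm][order]
        count_m = np.zeros(nm, dtype=np.int64)
        count_m1 = np.zeros(nm, dtype=np.int64)
        lo = 0
        for p in range(nm):
            xi = xs[p]
            while xs[lo] < xi - r:
                lo += 1
            i = order[p]
            for q in range(lo, nm):
                if xs[q] > xi + r:
                    break
                j = order[q]
                ok = True
                for k in range(1, m):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    count_m[i] += 1
                    if i < nm1 and j < nm1 and abs(x[i + m] - x[j + m]) <= r:
                        count_m1[i] += 1
        phi_m = 0.0
        phi_m1 = 0.0
        for i in range(nm):
            phi_m += np.log(count_m[i] / nm)
            if i < nm1:
                phi_m1 += (
                    np.log(count_m1[i] / nm1) if count_m1[i] > 0 else np.log(1.0 / nm1)
                )
        return phi_m / nm, phi_m1 / nm1

else:  # pragma: no cover - vectorized fallback

    def _apen_phis(x, m, r):
        n = x.size
        nm = n - m + 1
        nm1 = n - m
        templ = np.lib.stride_tricks.sliding_window_view(x, m)[:nm]
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        within = d <= r
        count_m = within.sum(axis=1)
        extra = np.abs(x[m:n][:, None] - x[m:n][None, :]) <= r
        count_m1 = (within[:nm1, :nm1] & extra).sum(axis=1)
        phi_m = np.mean(np.log(count_m / nm))
        phi_m1 = np.mean(np.log(np.maximum(count_m1, 1) / nm1))
        return phi_m, phi_m1


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) in nats, with ``r`` in units of SD(x).

    Standard Pincus definition with self-matches included:
    ``ApEn = Phi_m(r) - Phi_{m+1}(r)`` where ``Phi_m`` is the mean log
    fraction of template pairs within max-norm distance ``r * SD(x)``.
    A constant series returns exactly 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0  # all templates match at any positive tolerance
    phi_m, phi_m1 = _apen_phis(x, m, r * sd)
    return float(phi_m - phi_m1)


# --- Per-utterance extraction --------------------------------------------


def _fill_missing(col: np.ndarray) -> np.ndarray:
    """Carry the last defined value forward; seed leading NaNs with the median."""
    col = col.copy()
    finite = np.isfinite(col)
    if not finite.any():
        return np.zeros_like(col)
    median = np.median(col[finite])
    last = median
    for t in range(col.size):
        if np.isfinite(col[t]):
            last = col[t]
        else:
            col[t] = last
    return col


def extract_frame_features(
    waveform,
    frame_length_s: float = 0.025,
    overlap: float = 0.75,
    fmin: float = 100.0,
    fmax: float = 600.0,
    apen_m: int = 2,
    apen_r: float = 0.2,
) -> pd.DataFrame:
    """Extract the full 8-feature frame sequence for one utterance.

    Returns a DataFrame with columns :data:`FRAME_FEATURE_NAMES`, one row per
    frame.  Unvoiced frames keep ``f0 = 0``; undefined formants/nasality are
    filled by carrying the last defined value (HMM observations must be
    complete vectors).
    """
    from .audio_io import frame_signal

    fm = frame_signal(waveform, frame_length_s=frame_length_s, overlap=overlap)
    T = fm.n_frames
    sr = fm.sample_rate

    cols = {name: np.full(T, np.nan) for name in FRAME_FEATURE_NAMES}
    cols["ri"] = relative_intensity(fm)

    for t in range(T):
        frame = fm.frames[t]
        cols["f0"][t] = estimate_f0(frame, sr, fmin=fmin, fmax=fmax)
        f1, f2, f3 = estimate_formants(frame, sr)
        cols["f1"][t], cols["f2"][t], cols["f3"][t] = f1, f2, f3
        if np.isfinite(f1) and np.isfinite(f2) and f2 > 0:
            cols["f1f2_ratio"][t] = f1 / f2
        if np.isfinite(f1) and f1 < 900.0:
            cols["nasality"][t] = nasality_score(frame, sr, f1).score
        cols["apen"][t] = approximate_entropy(frame, m=apen_m, r=apen_r)

    for name in ("f1", "f2", "f3", "nasality"):
        cols[name] = _fill_missing(cols[name])
    # carried values can break the formant ordering; restore it per frame
    triple = np.sort(np.column_stack([cols["f1"], cols["f2"], cols["f3"]]), axis=1)
    cols["f1"], cols["f2"], cols["f3"] = triple.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cols["f1f2_ratio"] = np.where(cols["f2"] > 0, cols["f1"] / cols["f2"], 0.0)
    return pd.DataFrame(cols)
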